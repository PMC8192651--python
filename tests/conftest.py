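import numpy as np
import pytest

from ricepop import GenotypeMatrix, PopulationSpec, SiteRecord, TraitSpec, simulate


def make_gm(dosage, positions=None, chrom="1", quals=None, sample_ids=None):
    """Build a GenotypeMatrix from a plain dosage list for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, n_sites = dosage.shape
    if positions is None:
        positions = range(1, n_sites + 1)
    if quals is None:
        quals = [50.0] * n_sites
    chroms = [chrom] * n_sites if isinstance(chrom, str) else chrom
    sites = [SiteRecord(c, int(p), "A", "C", float(q))
             for c, p, q in zip(chroms, positions, quals)]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    return GenotypeMatrix(sample_ids, sites, dosage)


def random_gm(seed, n=6, n_sites=12, missing_rate=0.1):
    """Random valid GenotypeMatrix (two chromosomes) for property tests."""
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(n, n_sites)).astype(np.int16)
    dosage[rng.random((n, n_sites)) < missing_rate] = -1
    half = n_sites // 2
    sites = []
    for chrom, count in (("1", half), ("2", n_sites - half)):
        pos = np.sort(rng.choice(np.arange(1, 10_000), size=count,
                                 replace=False))
        for p in pos:
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            sites.append(SiteRecord(chrom, int(p), ref, alt,
                                    float(rng.integers(30, 90))))
    return GenotypeMatrix([f"S{i}" for i in range(n)], sites, dosage)


@pytest.fixture(scope="session")
def small_sim():
    """The default small synthetic panel with a planted two-locus trait."""
    spec = PopulationSpec()
    trait = TraitSpec((100, 2600), (1.0, 1.0), 0.5)
    return simulate(spec, trait)
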
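"""Synthetic structured, partially inbred diploid populations.

The generator emulates the statistical structure of a resequenced rice
landrace panel: K ancestral populations diverged under a Balding–Nichols
model, Dirichlet admixture of individual ancestries, strong inbreeding
(Wright's F ~ 0.88 is typical of a selfing crop), random missing calls,
and additive quantitative traits controlled by a few large-effect loci.

Inbreeding is modelled at the genotype level with a per-locus
identical-by-descent indicator: with probability F the two gametes are
copies (the genotype is 2 with probability f and otherwise 0), with
probability 1 - F the genotype is Binomial(2, f), where
f_il = sum_k q_ik p_kl is the individual-specific ALT frequency.  This
reproduces the expected heterozygosity (1 - F) * 2f(1 - f) that the
SNP-filter module's inbreeding estimator inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import MISSING, GenotypeMatrix, SiteRecord, TraitTable

import pandas as pd

_BASES = np.array(list("ACGT"))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions for one simulated panel.

    Defaults are the "small" fixture: a K=3 panel of 120 inbred
    (F = 0.88) individuals typed at 5,000 sites over two chromosomes
    with 2% missing calls — sized so the whole pipeline runs in seconds.
    """

    n_populations: int = 3
    n_samples: int = 120
    n_sites: int = 5000
    #: Balding-Nichols divergence per population (scalar or one per pop).
    fst: float | tuple = 0.15
    #: Dirichlet concentration of individual ancestry proportions.
    alpha: float = 0.2
    #: Wright's inbreeding coefficient F.
    inbreeding: float = 0.88
    missing_rate: float = 0.02
    chrom_lengths: tuple = (10_000_000, 8_000_000)
    seed: int = 1

    def __post_init__(self):
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        fst = np.broadcast_to(np.asarray(self.fst, dtype=float),
                              (self.n_populations,))
        if ((fst <= 0) | (fst >= 1)).any():
            raise ValueError("fst values must lie strictly in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding coefficient must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_sites > sum(self.chrom_lengths):
            raise ValueError("more sites than base pairs available")

    def fst_per_pop(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.fst, dtype=float),
                               (self.n_populations,)).copy()


@dataclass(frozen=True)
class TraitSpec:
    """Additive trait architecture: causal site indices, effects, h2."""

    causal_sites: tuple
    effects: tuple
    h2: float
    name: str = "trait"

    def __post_init__(self):
        if len(self.causal_sites) != len(self.effects):
            raise ValueError("causal_sites and effects lengths differ")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")


def sim_frequencies(spec: PopulationSpec, rng=None) -> np.ndarray:
    """Draw the K x L ancestral ALT-allele frequency matrix.

    Per site an ancestral frequency p0 ~ Uniform(0.05, 0.95), then each
    population's frequency from a Beta with mean p0 and variance
    fst * p0 * (1 - p0) (the Balding-Nichols parameterisation).  Entries
    are clamped to [1e-4, 1 - 1e-4] so no population is exactly fixed.
    """
    rng = _rng(spec.seed if rng is None else rng)
    k, n_sites = spec.n_populations, spec.n_sites
    p0 = rng.uniform(0.05, 0.95, size=n_sites)
    fst = spec.fst_per_pop()
    # Beta(a, b) with mean p0 and a + b = (1 - fst) / fst has the
    # required variance fst * p0 * (1 - p0).
    scale = (1.0 - fst) / fst  # (K,)
    a = p0[None, :] * scale[:, None]
    b = (1.0 - p0[None, :]) * scale[:, None]
    freqs = rng.beta(a, b, size=(k, n_sites))
    return np.clip(freqs, 1e-4, 1 - 1e-4)


def sim_admixture(spec: PopulationSpec, rng=None) -> np.ndarray:
    """Draw the n x K matrix of individual ancestry proportions.

    Rows are Dirichlet(alpha, ..., alpha); small alpha makes most
    individuals nearly pure members of one population, as observed in
    landrace panels.
    """
    rng = _rng(spec.seed if rng is None else rng)
    if spec.n_populations == 1:
        return np.ones((spec.n_samples, 1))
    q = rng.dirichlet(np.full(spec.n_populations, spec.alpha),
                      size=spec.n_samples)
    return q


def sim_sites(spec: PopulationSpec, rng=None) -> list[SiteRecord]:
    """Assign sites uniformly along the configured chromosomes.

    Site counts per chromosome are proportional to length; positions are
    drawn without replacement and sorted, so the container's
    strictly-increasing invariant holds by construction.
    """
    rng = _rng(spec.seed if rng is None else rng)
    lengths = np.asarray(spec.chrom_lengths, dtype=np.int64)
    counts = np.floor(spec.n_sites * lengths / lengths.sum()).astype(int)
    for i in range(spec.n_sites - counts.sum()):
        counts[i % len(counts)] += 1
    sites: list[SiteRecord] = []
    for c, (length, count) in enumerate(zip(lengths, counts), start=1):
        pos = np.array([], dtype=np.int64)
        while len(pos) < count:
            extra = rng.integers(1, length + 1, size=2 * (count - len(pos)))
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=count, replace=False))
        ref_i = rng.integers(0, 4, size=count)
        alt_i = (ref_i + rng.integers(1, 4, size=count)) % 4
        qual = np.round(rng.uniform(30, 60, size=count), 1)
        sites.extend(
            SiteRecord(str(c), int(p), _BASES[r], _BASES[a], float(q))
            for p, r, a, q in zip(pos, ref_i, alt_i, qual)
        )
    return sites


def sim_genotypes(freqs: np.ndarray, q: np.ndarray, inbreeding: float,
                  missing_rate: float = 0.0, seed=0, sites=None,
                  sample_ids=None) -> GenotypeMatrix:
    """Realise dosages from ancestry, frequencies and inbreeding.

    For individual i, site l: with probability F both gametes are
    identical by descent (dosage 2 with probability f_il, else 0);
    otherwise the dosage is Binomial(2, f_il).  Calls are then masked
    missing independently with probability ``missing_rate``.
    """
    if not 0.0 <= inbreeding <= 1.0:
        raise ValueError("inbreeding coefficient must be in [0, 1]")
    if q.shape[1] != freqs.shape[0]:
        raise ValueError("Q and frequency matrices disagree on K")
    rng = _rng(seed)
    f = q @ freqs  # (n, L)
    n, n_sites = f.shape
    ibd = rng.random((n, n_sites)) < inbreeding
    g_ibd = 2 * (rng.random((n, n_sites)) < f)
    g_out = rng.binomial(2, f)
    dosage = np.where(ibd, g_ibd, g_out).astype(np.int16)
    if missing_rate > 0:
        dosage[rng.random((n, n_sites)) < missing_rate] = MISSING
    if sites is None:
        sites = [SiteRecord("1", j + 1, "A", "C") for j in range(n_sites)]
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, sites, dosage)


def sim_trait(gm: GenotypeMatrix, ts: TraitSpec, seed=0) -> TraitTable:
    """Additive trait with environmental noise scaled to the target h2.

    Missing dosages contribute the per-site mean dosage, so every sample
    receives a genetic value.  With h2 = 0 (or all-zero effects) the
    trait is pure noise with variance 1.
    """
    causal = np.asarray(ts.causal_sites, dtype=int)
    if causal.size and (causal.min() < 0 or causal.max() >= gm.n_sites):
        raise ValueError("causal site index out of range")
    rng = _rng(seed)
    n = gm.n_samples
    effects = np.asarray(ts.effects, dtype=float)
    if causal.size:
        d = gm.dosage[:, causal].astype(float)
        miss = d == MISSING
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        d = np.where(miss, col_mean[None, :], d)
        genetic = d @ effects
    else:
        genetic = np.zeros(n)
    var_g = float(np.var(genetic))
    if ts.h2 == 1.0 and var_g == 0.0:
        raise ValueError("h2 = 1 requires non-zero genetic variance")
    if ts.h2 == 0.0 or var_g == 0.0:
        values = rng.standard_normal(n)  # pure noise, unit variance
    elif ts.h2 == 1.0:
        values = genetic
    else:
        var_e = var_g * (1.0 - ts.h2) / ts.h2
        values = genetic + rng.standard_normal(n) * np.sqrt(var_e)
    data = pd.DataFrame({ts.name: values}, index=pd.Index(gm.sample_ids))
    return TraitTable(data)


@dataclass
class SimResult:
    """Simulated panel plus the truth tables used as test oracles."""

    genotypes: GenotypeMatrix
    q_true: np.ndarray
    freqs: np.ndarray
    spec: PopulationSpec
    trait: TraitTable | None = None
    trait_spec: TraitSpec | None = None


def simulate(spec: PopulationSpec, trait_spec: TraitSpec | None = None
             ) -> SimResult:
    """Run the full generator from one seed: sites, Q, P, genotypes, trait."""
    rng = np.random.default_rng(spec.seed)
    sites = sim_sites(spec, rng)
    freqs = sim_frequencies(spec, rng)
    q = sim_admixture(spec, rng)
    gm = sim_genotypes(freqs, q, spec.inbreeding, spec.missing_rate,
                       seed=rng, sites=sites)
    trait = None
    if trait_spec is not None:
        trait = sim_trait(gm, trait_spec, seed=rng)
    return SimResult(gm, q, freqs, spec, trait, trait_spec)
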
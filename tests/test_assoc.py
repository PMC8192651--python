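"""Trait QC, kinship, mixed-model GWAS and the QTL interval rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ricepop as rp
from ricepop.assoc import (
    Segment,
    default_trait_class_map,
    qtl_pipeline,
    regions_to_table,
)
from ricepop.genio import GeneAnnotation, TraitTable

from conftest import make_gm


def trait_table(**cols):
    n = len(next(iter(cols.values())))
    return TraitTable(pd.DataFrame(cols, index=[f"S{i}" for i in range(n)]))


class TestTraitQC:
    def test_cv_screen(self):
        rng = np.random.default_rng(0)
        t = trait_table(
            wide=10 + 6 * rng.standard_normal(200),      # CV ~ 60: excluded
            ok=100 + 28 * rng.standard_normal(200),      # CV ~ 28: eligible
            flat=np.full(200, 5.0),                      # zero variance
        )
        qc = rp.trait_qc(t, cv_max=56).set_index("trait")
        assert not qc.loc["wide", "eligible"]
        assert qc.loc["ok", "eligible"]
        assert qc.loc["flat", "reason"] == "zero variance"

    def test_small_sample_trait_flagged(self):
        t = trait_table(x=np.r_[np.full(190, np.nan), np.arange(10) + 1.0])
        qc = rp.trait_qc(t, min_n=30)
        assert not qc["eligible"].iloc[0] and "n <" in qc["reason"].iloc[0]


class TestSimpleStats:
    def test_identical_groups_t_zero_p_one(self):
        x = np.array([1.0, 2, 3, 4])
        t, p = rp.welch_ttest(x, x)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_welch_matches_direct_formula(self):
        x = np.array([3.1, 2.8, 3.6, 3.0, 2.5])
        y = np.array([2.0, 2.2, 1.7, 2.4])
        t, p = rp.welch_ttest(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_direct = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1)
                               + vy ** 2 / (len(y) - 1))
        assert t == pytest.approx(t_direct)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_direct), df))

    def test_pearson_self_correlation_and_missing(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        assert rp.pearson(x, x) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="zero variance"):
            rp.welch_ttest([1.0, 1.0], [1.0, 1.0])


class TestKinship:
    def test_duplicated_individuals_share_kinship_entries(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(8, 40))
        d[2] = d[5]
        k = rp.vanraden_kinship(make_gm(d))
        assert k[2, 2] == pytest.approx(k[5, 5])
        assert k[2, 5] == pytest.approx(k[2, 2])

    def test_toy_matrix_matches_hand_computation(self):
        d = np.array([[0, 1, 2, 0, 1],
                      [1, 1, 0, 2, 0],
                      [2, 0, 1, 1, 1]])
        k = rp.vanraden_kinship(make_gm(d))
        p = d.mean(axis=0) / 2
        z = d - 2 * p
        expected = z @ z.T / (2 * (p * (1 - p)).sum())
        assert np.allclose(k, expected, atol=1e-12)

    def test_inbreeding_lifts_mean_diagonal(self, small_sim):
        k = rp.vanraden_kinship(small_sim.genotypes)
        assert 1.7 <= np.diag(k).mean() <= 2.0
        assert np.allclose(k, k.T, atol=1e-10)


class TestMixedModel:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.3, size=(50, 200)).astype(float)
        y = rng.standard_normal(50)
        est = rp.MixedLMAssoc(min_samples=10).fit(x, y, kinship=np.eye(50))
        for j in rng.choice(200, size=25, replace=False):
            ols = stats.linregress(x[:, j], y)
            assert est.results_["p"][j] == pytest.approx(ols.pvalue,
                                                         abs=1e-8)
            assert est.results_["effect"][j] == pytest.approx(ols.slope,
                                                              abs=1e-8)

    def test_monomorphic_snp_reported_null(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.4, size=(40, 5)).astype(float)
        x[:, 2] = 1.0
        est = rp.MixedLMAssoc(min_samples=10).fit(x, rng.standard_normal(40))
        assert est.results_["p"][2] == 1.0
        assert est.results_["effect"][2] == 0.0

    def test_singular_covariates_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(2, 0.4, size=(40, 5)).astype(float)
        cov = np.ones((40, 2))  # both collinear with the intercept
        with pytest.raises(ValueError, match="singular"):
            rp.MixedLMAssoc(min_samples=10, drop_covariate_column=None).fit(
                x, rng.standard_normal(40), covariates=cov)

    def test_listwise_exclusion_of_missing_trait(self):
        rng = np.random.default_rng(3)
        x = rng.binomial(2, 0.4, size=(60, 10)).astype(float)
        y = rng.standard_normal(60)
        y[:5] = np.nan
        est = rp.MixedLMAssoc(min_samples=10).fit(x, y)
        assert est.n_used_ == 55 and est.n_dropped_ == 5


class TestSignificanceAndSegments:
    def make_results(self, positions, logs, chrom="6"):
        p = 10.0 ** -np.asarray(logs, dtype=float)
        return pd.DataFrame({"chrom": [chrom] * len(positions),
                             "pos": positions, "effect": 1.0, "se": 0.1,
                             "p": p, "minus_log10_p": np.asarray(logs,
                                                                 dtype=float)})

    def test_threshold_boundary_inclusive(self):
        res = self.make_results([10, 20, 30], [8.0, 7.999, 9.5])
        sig = rp.call_significant(res, 8.0)
        assert sig["pos"].tolist() == [10, 30]

    def test_no_hits_gives_empty(self):
        res = self.make_results([10, 20], [0.3, 0.3])
        assert len(rp.call_significant(res)) == 0

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(4)
        logs = rng.uniform(0, 12, size=300)
        res = self.make_results(np.arange(1, 301), logs)
        assert len(rp.call_significant(res, 8.0)) == (logs >= 8.0).sum()

    def test_hand_traced_chaining(self):
        sig = self.make_results([1_000_000, 1_100_000, 1_500_000],
                                [9, 10, 11])
        segs = rp.build_segments(sig, gap_bp=250_000, min_snps=2)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (1_000_000, 1_100_000)
        assert segs[0].peak_pos == 1_100_000 and segs[0].n_snps == 2

    def test_single_snp_makes_no_segment(self):
        sig = self.make_results([1_000_000], [9])
        assert rp.build_segments(sig) == []

    def test_chains_equal_single_linkage_oracle(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(10_000_000, size=60, replace=False))
        sig = self.make_results(pos, rng.uniform(8, 12, size=60))
        gap = 300_000
        segs = rp.build_segments(sig, gap_bp=gap, min_snps=2)
        # oracle: clusters grown by single linkage at the gap distance
        clusters, current = [], [pos[0]]
        for p in pos[1:]:
            if p - current[-1] <= gap:
                current.append(p)
            else:
                clusters.append(current)
                current = [p]
        clusters.append(current)
        clusters = [c for c in clusters if len(c) >= 2]
        assert [(s.start, s.end, s.n_snps) for s in segs] == \
            [(c[0], c[-1], len(c)) for c in clusters]


class TestExtensionAndMerging:
    def seg(self, start, end, peak, panel="FP", trait="Grain_Length",
            chrom="6"):
        return Segment(chrom, start, end, 2, 1e-9, peak, panel, trait)

    def test_small_segment_extended_to_flanks_of_peak(self):
        s = self.seg(7_463_914, 7_503_914, 7_503_914)
        out = rp.extend_small(s)
        assert (out.start, out.end) == (7_453_914, 7_553_914)
        assert out.end - out.start + 1 == 100_001

    def test_wide_segment_unchanged(self):
        s = self.seg(1_000_000, 2_300_000, 1_500_000)
        assert rp.extend_small(s) is s

    def test_extension_floors_at_chromosome_start(self):
        s = self.seg(15_000, 25_000, 20_000)
        out = rp.extend_small(s)
        assert out.start == 1 and out.end == 70_000

    def test_overlapping_panels_union(self):
        a = self.seg(100_000, 300_000, 200_000, panel="FP")
        b = self.seg(250_000, 400_000, 300_000, panel="Jap")
        regions = rp.merge_panels([a, b])
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (100_000, 400_000)
        assert r.panels == {"FP", "Jap"}

    def test_grain_traits_collapse_to_grain_size(self):
        a = self.seg(100_000, 300_000, 200_000, trait="Grain_Length")
        b = self.seg(250_000, 400_000, 300_000, trait="Grain_Width")
        regions = rp.merge_panels([a, b])
        assert len(regions) == 1
        assert regions[0].trait_class == "Grain_Size"

    def test_merge_count_matches_union_find_oracle(self):
        rng = np.random.default_rng(6)
        segs = []
        for _ in range(40):
            start = int(rng.integers(1, 5_000_000))
            segs.append(self.seg(start, start + int(rng.integers(1, 400_000)),
                                 start))
        regions = rp.merge_panels(segs)
        # oracle: union-find over pairwise interval overlap
        parent = list(range(len(segs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                if (segs[i].start <= segs[j].end
                        and segs[j].start <= segs[i].end):
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(segs))})
        assert len(regions) == n_components

    def test_pipeline_idempotent_on_own_output(self):
        rng = np.random.default_rng(7)
        segs = []
        for _ in range(25):
            start = int(rng.integers(1, 3_000_000))
            segs.append(self.seg(start, start + int(rng.integers(1, 300_000)),
                                 start))
        regions = rp.merge_panels(segs)
        again = rp.merge_panels([
            Segment(r.chrom, r.start, r.end, r.n_snps, r.min_p, r.start,
                    "FP", r.trait_class)
            for r in regions
        ], trait_class_map={"Grain_Size": "Grain_Size"})
        assert [(r.start, r.end) for r in again] == \
            [(r.start, r.end) for r in regions]
        for r in regions:
            assert r.n_snps >= 2


class TestGenes:
    ann = GeneAnnotation(pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"],
        "chrom": ["6", "6", "6"],
        "start": [10, 30, 100],
        "end": [20, 40, 200],
        "strand": ["+", "-", "+"],
    }))

    def region(self, start, end):
        seg = Segment("6", start, end, 2, 1e-9, start)
        return rp.merge_panels([seg])[0]

    def test_overlap_counting_hand_trace(self):
        r = rp.count_genes(self.region(15, 35), self.ann)
        assert r.genes == ("g1", "g2") and r.n_genes == 2

    def test_empty_annotation(self):
        empty = GeneAnnotation(self.ann.genes.iloc[0:0])
        assert rp.count_genes(self.region(1, 10 ** 6), empty).n_genes == 0

    def test_abutting_gene_counts_as_one_bp_overlap(self):
        r = rp.count_genes(self.region(1, 100), self.ann)  # g3 starts at end
        assert "g3" in r.genes


class TestReport:
    def test_fixture_aggregates(self):
        rep = rp.qtl_report(rp.bundled_qtl_table())
        assert rep["total_associations"] == 643
        assert rep["panel_counts"]["FP"] == 17

    def test_empty_table_all_zero(self):
        rep = rp.qtl_report(pd.DataFrame(columns=[
            "name", "trait", "chrom", "panels", "start", "end",
            "n_sig_snps", "min_p", "n_genes"]))
        assert rep["n_qtls"] == 0 and rep["total_associations"] == 0

    def test_regions_roundtrip_through_table_schema(self):
        seg_a = Segment("3", 100_000, 260_000, 5, 1e-10, 150_000, "FP",
                        "Grain_Length")
        seg_b = Segment("3", 200_000, 400_000, 3, 1e-9, 250_000, "Jap",
                        "Grain_Width")
        table = regions_to_table(rp.merge_panels([seg_a, seg_b]))
        rep = rp.qtl_report(table)
        assert rep["n_qtls"] == 1 and rep["total_associations"] == 8
        assert rep["panel_counts"] == {"FP": 1, "Jap": 1}


def test_end_to_end_recovery_of_planted_qtls():
    """Two planted two-SNP loci are found; clean chromosomes stay clean."""
    spec = rp.PopulationSpec(n_populations=3, n_samples=300, n_sites=4000,
                             inbreeding=0.88, seed=21)
    sim = rp.simulate(spec)
    gm = sim.genotypes
    chroms = gm.chroms()
    pos = gm.positions()
    chr1 = np.flatnonzero(chroms == "1")
    # two causal pairs, each pair within the chaining gap on chromosome 1
    pair1 = chr1[np.searchsorted(pos[chr1], 2_000_000) + np.array([0, 1])]
    pair2 = chr1[np.searchsorted(pos[chr1], 7_000_000) + np.array([0, 1])]
    causal = np.r_[pair1, pair2]
    # equalise per-locus variance contributions (h2 >= 0.2 per pair)
    sd = gm.dosage[:, causal].astype(float).std(axis=0)
    trait = rp.TraitSpec(tuple(causal), tuple(1.0 / sd), 0.8)
    t = rp.synthpop.sim_trait(gm, trait, seed=1)
    k = rp.vanraden_kinship(gm)
    res = rp.mlm_assoc(gm, (t, "trait"), covariates=sim.q_true, kinship=k)
    res["chrom"] = chroms
    res["pos"] = pos
    regions = qtl_pipeline({("FP", "trait"): res},
                           trait_class_map={"trait": "trait"})
    assert all(r.chrom == "1" for r in regions)
    covered = [
        any(r.start <= pos[c] <= r.end for r in regions) for c in causal
    ]
    assert all(covered)
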
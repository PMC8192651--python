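"""Trait QC, kinship, mixed-model GWAS and QTL interval construction.

The association model per SNP is the single-variance-component mixed
linear model

    y = W a + x b + g + e,   g ~ N(0, sg2 K),   e ~ N(0, se2 I)

with W fixed covariates (intercept plus ancestry proportions, one column
dropped against the intercept) and K a VanRaden genomic relationship
matrix.  Variance components are estimated once on the null model by
REML through the eigendecomposition of K (the EMMA/EMMAX device); every
SNP is then tested by generalised least squares on the rotated data with
a Wald t-test.

Significant SNPs (-log10 p above a fixed genome-wide threshold, 8.0 by
default) are chained into segments when consecutive hits lie within a
gap, segments need at least two SNPs, sub-100-kb segments are extended
to 50 kb either side of the peak SNP, and overlapping segments of the
same trait class (grain length / width / ratio collapse to grain size)
from different panels merge into final QTL regions, which are annotated
with overlapping genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genio import MISSING, GeneAnnotation, GenotypeMatrix, QTLReportTable, TraitTable


# ---------------------------------------------------------------------------
# phenotype QC and simple comparisons

def trait_qc(table: TraitTable, cv_max: float = 56.0, min_n: int = 30
             ) -> pd.DataFrame:
    """Screen traits for GWAS by coefficient of variation.

    CV = 100 * sd / mean over non-missing values; a trait is eligible
    iff 0 < CV < ``cv_max``, the mean is positive, the variance is
    non-zero and at least ``min_n`` samples are scored.  Ineligible
    traits carry a reason.
    """
    rows = []
    for trait in table.traits:
        x = table.data[trait].dropna().to_numpy(dtype=float)
        n = len(x)
        mean = float(np.mean(x)) if n else np.nan
        sd = float(np.std(x, ddof=1)) if n > 1 else np.nan
        cv = 100.0 * sd / mean if n > 1 and mean > 0 else np.nan
        if n < min_n:
            eligible, reason = False, f"n < {min_n}"
        elif sd == 0:
            eligible, reason = False, "zero variance"
        elif mean <= 0:
            eligible, reason = False, "non-positive mean"
        elif not 0 < cv < cv_max:
            eligible, reason = False, f"CV {cv:.1f} outside (0, {cv_max})"
        else:
            eligible, reason = True, ""
        rows.append((trait, n, mean, sd, cv, eligible, reason))
    return pd.DataFrame(rows, columns=["trait", "n", "mean", "sd", "cv",
                                       "eligible", "reason"])


def welch_ttest(x, y) -> tuple[float, float]:
    """Two-sided Welch t-test (Satterthwaite df) ignoring missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 non-missing values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def pearson(x, y) -> float:
    """Pearson correlation on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete observations")
    return float(stats.pearsonr(x[ok], y[ok])[0])


# ---------------------------------------------------------------------------
# kinship

def vanraden_kinship(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix from centred dosages.

    Z holds dosages centred by 2 p-hat per polymorphic site (missing
    entries are 0 after centring); K = Z Z' / (2 sum p-hat (1 - p-hat)).
    Under inbreeding the mean diagonal approaches 1 + F.
    """
    d = gm.dosage.astype(float)
    mask = d != MISSING
    n_called = np.maximum(mask.sum(axis=0), 1)
    p_hat = np.where(mask, d, 0.0).sum(axis=0) / (2.0 * n_called)
    poly = (p_hat > 0) & (p_hat < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic sites for kinship")
    z = d[:, poly] - 2.0 * p_hat[None, poly]
    z[~mask[:, poly]] = 0.0
    denom = 2.0 * float((p_hat[poly] * (1.0 - p_hat[poly])).sum())
    return (z @ z.T) / denom


def genomic_inflation(pvalues) -> float:
    """Genomic-control lambda: median chi2(1) statistic over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# mixed linear model

class MixedLMAssoc(BaseEstimator):
    """EMMA-style single-variance-component mixed-model GWAS.

    Parameters
    ----------
    drop_covariate_column : int or None
        Index of the ancestry-covariate column dropped against the
        intercept (Q rows sum to 1, so keeping all columns is singular).
        ``None`` keeps all supplied columns.
    ridge : float
        Diagonal shift applied (with a warning) when the kinship is not
        positive semi-definite.

    Attributes
    ----------
    results_ : DataFrame with effect, se, p, minus_log10_p per SNP.
    delta_ : REML estimate of se2 / sg2 on the null model.
    sigma_g2_, sigma_e2_ : variance components.
    null_loglik_ : REML log-likelihood of the null model.
    """

    def __init__(self, drop_covariate_column: int | None = 0,
                 ridge: float = 1e-6, min_samples: int = 30):
        self.drop_covariate_column = drop_covariate_column
        self.ridge = ridge
        self.min_samples = min_samples

    # REML log-likelihood for the rotated null model at a given delta
    @staticmethod
    def _reml_loglik(log_delta, s, wt, yt):
        delta = np.exp(log_delta)
        v = s + delta
        w_v = wt / v[:, None]
        a = wt.T @ w_v
        rhs = w_v.T @ yt
        try:
            alpha = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            return -np.inf
        resid = yt - wt @ alpha
        rss = float((resid ** 2 / v).sum())
        n, p = wt.shape
        df = n - p
        sign, logdet_a = np.linalg.slogdet(a)
        if sign <= 0 or rss <= 0:
            return -np.inf
        return -0.5 * (df * (np.log(2 * np.pi * rss / df) + 1)
                       + np.log(v).sum() + logdet_a)

    def fit(self, X, y, covariates=None, kinship=None):
        """Fit the null model and test every SNP.

        ``X``: GenotypeMatrix or (n, L) dosage array (missing allowed);
        ``y``: trait values aligned to the samples; ``covariates``:
        optional (n, c) matrix (e.g. averaged ancestry proportions);
        ``kinship``: (n, n) genomic relationship matrix (identity
        collapses the model to ordinary least squares).
        """
        if isinstance(X, GenotypeMatrix):
            d = X.dosage.astype(float)
            chrom = X.chroms()
            pos = X.positions()
        else:
            d = np.asarray(X, dtype=float)
            chrom = np.array(["0"] * d.shape[1], dtype=object)
            pos = np.arange(1, d.shape[1] + 1)
        y = np.asarray(y, dtype=float)
        n_all = d.shape[0]
        mask_geno = (d != MISSING) & np.isfinite(d)
        keep = np.isfinite(y) & mask_geno.any(axis=1)
        if keep.sum() < self.min_samples:
            raise ValueError(
                f"only {int(keep.sum())} usable samples; need "
                f">= {self.min_samples}"
            )
        d = d[keep]
        mask_geno = mask_geno[keep]
        y = y[keep]
        n = len(y)
        w_parts = [np.ones((n, 1))]
        if covariates is not None:
            c = np.asarray(covariates, dtype=float)[keep]
            if self.drop_covariate_column is not None and c.shape[1] > 1:
                c = np.delete(c, self.drop_covariate_column, axis=1)
            w_parts.append(c)
        w = np.column_stack(w_parts)
        if np.linalg.matrix_rank(w) < w.shape[1]:
            raise ValueError("singular covariate matrix")
        if kinship is None:
            k = np.eye(n)
        else:
            k = np.asarray(kinship, dtype=float)[np.ix_(keep, keep)]
        if not np.allclose(k, k.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        s, u = np.linalg.eigh((k + k.T) / 2.0)
        if s.min() < -1e-8:
            warnings.warn(
                f"kinship not PSD (min eigenvalue {s.min():.2e}); "
                f"applying ridge {self.ridge}"
            )
            s = s + (self.ridge - s.min())
        s = np.clip(s, 0.0, None)
        yt = u.T @ y
        wt = u.T @ w
        # REML for delta = se2/sg2: coarse log-grid then local refinement
        grid = np.linspace(-10.0, 10.0, 41)
        vals = np.array([self._reml_loglik(g, s, wt, yt) for g in grid])
        i_best = int(np.nanargmax(vals))
        lo = grid[max(i_best - 1, 0)]
        hi = grid[min(i_best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda g: -self._reml_loglik(g, s, wt, yt),
            bounds=(lo, hi), method="bounded")
        log_delta = float(res.x)
        self.null_loglik_ = -float(res.fun)
        self.delta_ = float(np.exp(log_delta))
        v = s + self.delta_
        w_v = wt / v[:, None]
        a = wt.T @ w_v
        a_inv = np.linalg.inv(a)
        alpha = a_inv @ (w_v.T @ yt)
        resid = yt - wt @ alpha
        rss0 = float((resid ** 2 / v).sum())
        df0 = n - w.shape[1]
        sg2 = rss0 / df0
        self.sigma_g2_ = sg2
        self.sigma_e2_ = sg2 * self.delta_
        # per-SNP GLS via partitioned regression on rotated data
        col_mean = np.where(mask_geno, d, np.nan)
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(col_mean, axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        x_imp = np.where(mask_geno, d, col_mean[None, :])
        xt = u.T @ x_imp                       # (n, L)
        wgt = 1.0 / v
        b1 = w_v.T @ xt                        # (p, L)
        c_xx = (wgt[:, None] * xt ** 2).sum(axis=0)
        d_wy = w_v.T @ yt                      # (p,)
        e_xy = (wgt * yt) @ xt                 # (L,)
        f_yy = float((wgt * yt ** 2).sum())
        ainv_b1 = a_inv @ b1
        sxx = c_xx - (b1 * ainv_b1).sum(axis=0)
        sxy = e_xy - d_wy @ ainv_b1
        syy = f_yy - d_wy @ a_inv @ d_wy
        df = n - w.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(sxx > 1e-12, sxy / sxx, 0.0)
            rss = syy - beta ** 2 * sxx
            sigma2 = rss / df
            se = np.sqrt(np.where(sxx > 1e-12, sigma2 / sxx, np.inf))
            tstat = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        self.results_ = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "effect": beta, "se": se,
             "p": pvals, "minus_log10_p": -np.log10(pvals)})
        self.n_used_ = n
        self.n_dropped_ = n_all - n
        return self


def mlm_assoc(gm: GenotypeMatrix, trait, covariates=None, kinship=None,
              **kwargs) -> pd.DataFrame:
    """Functional wrapper over :class:`MixedLMAssoc`; returns results.

    ``trait`` may be a TraitTable column name pair ``(table, name)``, a
    TraitTable with a single column, or a plain vector aligned with the
    samples.
    """
    if isinstance(trait, tuple):
        table, name = trait
        y = table.values_for(name, sample_ids=gm.sample_ids)
    elif isinstance(trait, TraitTable):
        y = trait.values_for(trait.traits[0], sample_ids=gm.sample_ids)
    else:
        y = np.asarray(trait, dtype=float)
    est = MixedLMAssoc(**kwargs).fit(gm, y, covariates=covariates,
                                     kinship=kinship)
    return est.results_


# ---------------------------------------------------------------------------
# QTL construction

@dataclass(frozen=True)
class Segment:
    """A chain of significant SNPs on one chromosome (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    min_p: float
    peak_pos: int
    panel: str = "FP"
    trait: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("segment end before start")
        if self.n_snps < 2:
            raise ValueError("segment needs >= 2 significant SNPs")


@dataclass
class QTLRegion:
    """Union of overlapping same-trait-class segments across panels."""

    chrom: str
    start: int
    end: int
    trait_class: str
    panels: frozenset
    traits: frozenset
    segments: tuple
    genes: tuple = ()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_snps(self) -> int:
        return sum(s.n_snps for s in self.segments)

    @property
    def min_p(self) -> float:
        return min(s.min_p for s in self.segments)


def call_significant(results: pd.DataFrame, threshold_log10p: float = 8.0
                     ) -> pd.DataFrame:
    """Rows with -log10 p at or above the genome-wide threshold, sorted."""
    sig = results[results["minus_log10_p"] >= threshold_log10p]
    return sig.sort_values(["chrom", "pos"]).reset_index(drop=True)


def build_segments(sig: pd.DataFrame, gap_bp: int = 250_000,
                   min_snps: int = 2, panel: str = "FP", trait: str = ""
                   ) -> list[Segment]:
    """Chain consecutive significant SNPs into segments.

    SNPs on one chromosome join a chain while the inter-SNP gap is at
    most ``gap_bp``; chains shorter than ``min_snps`` are discarded.
    The segment spans first to last SNP and records the count, minimum p
    and the position of the most significant SNP.
    """
    segments: list[Segment] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        pv = grp["p"].to_numpy(dtype=float)
        breaks = np.flatnonzero(np.diff(pos) > gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            count = b - a + 1
            if count < min_snps:
                continue
            chunk_p = pv[a:b + 1]
            peak = int(pos[a + int(np.argmin(chunk_p))])
            segments.append(Segment(str(chrom), int(pos[a]), int(pos[b]),
                                    int(count), float(chunk_p.min()), peak,
                                    panel=panel, trait=trait))
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def extend_small(seg: Segment, min_width: int = 100_000,
                 flank: int = 50_000) -> Segment:
    """Extend sub-``min_width`` segments to ``flank`` either side of the
    peak SNP; the start is floored at 1; wider segments pass unchanged."""
    if seg.end - seg.start + 1 >= min_width:
        return seg
    start = max(1, seg.peak_pos - flank)
    return replace(seg, start=start, end=seg.peak_pos + flank)


_GRAIN_TRAITS = ("Grain_Length", "Grain_Width", "GL_GW_Ratio")


def default_trait_class_map(traits) -> dict:
    """Grain length / width / ratio collapse to Grain_Size; others map to
    themselves."""
    return {t: ("Grain_Size" if t in _GRAIN_TRAITS else t) for t in traits}


def merge_panels(segments, trait_class_map: dict | None = None
                 ) -> list[QTLRegion]:
    """Union overlapping same-class, same-chromosome segments into QTLs.

    Any 1-bp overlap merges (single-linkage over the interval overlap
    graph); non-overlapping segments pass through as singleton regions.
    Output is sorted by chromosome then start.
    """
    segments = list(segments)
    if trait_class_map is None:
        trait_class_map = default_trait_class_map({s.trait for s in segments})
    unknown = [s.trait for s in segments if s.trait not in trait_class_map]
    if unknown:
        raise KeyError(f"traits missing from trait_class_map: {set(unknown)}")
    groups: dict[tuple, list[Segment]] = {}
    for s in segments:
        groups.setdefault((trait_class_map[s.trait], s.chrom), []).append(s)
    regions: list[QTLRegion] = []
    for (tclass, chrom), segs in groups.items():
        segs = sorted(segs, key=lambda s: (s.start, s.end))
        cluster: list[Segment] = []
        cluster_end = -1
        for s in segs + [None]:
            if s is not None and (not cluster or s.start <= cluster_end):
                cluster.append(s)
                cluster_end = max(cluster_end, s.end)
                continue
            if cluster:
                regions.append(QTLRegion(
                    chrom=chrom,
                    start=min(c.start for c in cluster),
                    end=max(c.end for c in cluster),
                    trait_class=tclass,
                    panels=frozenset(c.panel for c in cluster),
                    traits=frozenset(c.trait for c in cluster),
                    segments=tuple(cluster),
                ))
            if s is not None:
                cluster = [s]
                cluster_end = s.end
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def count_genes(region: QTLRegion, ann: GeneAnnotation) -> QTLRegion:
    """Attach genes overlapping the region by >= 1 bp (both ends
    inclusive), sorted by start."""
    g = ann.genes
    hit = g[(g["chrom"] == region.chrom)
            & (g["start"] <= region.end)
            & (g["end"] >= region.start)].sort_values("start")
    region.genes = tuple(hit["gene_id"])
    return region


def qtl_pipeline(results_by_panel: dict, threshold_log10p: float = 8.0,
                 gap_bp: int = 250_000, min_snps: int = 2,
                 min_width: int = 100_000, flank: int = 50_000,
                 trait_class_map: dict | None = None,
                 annotation: GeneAnnotation | None = None
                 ) -> list[QTLRegion]:
    """Full rule set: threshold, chain, extend, merge, annotate.

    ``results_by_panel`` maps ``(panel, trait)`` to an association result
    frame.
    """
    segments = []
    for (panel, trait), res in results_by_panel.items():
        sig = call_significant(res, threshold_log10p)
        for seg in build_segments(sig, gap_bp=gap_bp, min_snps=min_snps,
                                  panel=panel, trait=trait):
            segments.append(extend_small(seg, min_width=min_width,
                                         flank=flank))
    regions = merge_panels(segments, trait_class_map=trait_class_map)
    if annotation is not None:
        regions = [count_genes(r, annotation) for r in regions]
    return regions


# ---------------------------------------------------------------------------
# report aggregation

def regions_to_table(regions) -> QTLReportTable:
    """Serialise QTL regions into the tabular report schema."""
    rows = []
    for i, r in enumerate(regions, start=1):
        rows.append((f"{i}", r.trait_class, r.chrom,
                     ",".join(sorted(r.panels)), r.start, r.end,
                     r.n_snps, r.min_p, r.n_genes))
    df = pd.DataFrame(rows, columns=["name", "trait", "chrom", "panels",
                                     "start", "end", "n_sig_snps", "min_p",
                                     "n_genes"])
    return QTLReportTable(df)


def qtl_report(table) -> dict:
    """Aggregate a QTL report table into the headline panel summaries.

    Returns total associations (sum of per-QTL significant-SNP counts),
    the unique QTL count, per-panel counts (a QTL counts for every panel
    flagged on it), panel-exclusive counts, distinct chromosomes, total
    genes and the summed span in bp.
    """
    if isinstance(table, QTLReportTable):
        df = table.data
        panel_sets = table.panel_sets()
    else:
        df = table
        panel_sets = df["panels"].map(
            lambda s: frozenset(p.strip() for p in str(s).split(",")))
    if len(df) == 0:
        return {"n_qtls": 0, "total_associations": 0, "panel_counts": {},
                "panel_only_counts": {}, "n_chromosomes": 0,
                "total_genes": 0, "total_span_bp": 0}
    panels = sorted(set().union(*panel_sets))
    panel_counts = {p: int(sum(p in s for s in panel_sets)) for p in panels}
    panel_only = {p: int(sum(s == {p} for s in panel_sets)) for p in panels}
    return {
        "n_qtls": int(len(df)),
        "total_associations": int(df["n_sig_snps"].sum()),
        "panel_counts": panel_counts,
        "panel_only_counts": panel_only,
        "n_chromosomes": int(df["chrom"].nunique()),
        "total_genes": int(df["n_genes"].sum()),
        "total_span_bp": int((df["end"] - df["start"] + 1).sum()),
    }
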
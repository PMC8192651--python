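"""Per-site statistics and the SNP filtering cascade for inbred panels.

The centrepiece is the inbreeding-aware heterozygosity-excess filter.
In a selfing crop the expected fraction of heterozygous calls at a site
with allele frequency p is not the Hardy-Weinberg 2p(1-p) but
(1 - F) * 2p(1-p), with F Wright's inbreeding coefficient.  F is
estimated as the median of 1 - Hobs/Hexp over sites with Hobs/Hexp < 1
and MAF above 5%; a site whose Hobs/Hexp ratio exceeds ``factor * (1-F)``
(factor 5 by default) carries implausibly many heterozygotes — typically
collapsed paralogs or alignment artefacts — and is removed.

The remaining operations are the standard marker-QC cascade: hard
filters on MAF / missingness / minor-allele count / site quality,
within-window LD pruning on the squared dosage correlation, and physical
distance thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


def site_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site call counts, allele frequency and heterozygosity.

    Statistics are computed from called genotypes only; ``hexp`` is the
    plain 2p(1-p) with no finite-sample correction.  Sites with no calls
    (or ``hexp`` = 0) get NaN for the undefined statistics.

    Columns: n_called, missingness, p_alt, maf, mac, hobs, hexp, ratio.
    """
    d = gm.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)
    n = gm.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        alt = np.where(called, d, 0).sum(axis=0)
        p_alt = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        mac = np.minimum(alt, 2 * n_called - alt)
        hobs = np.where(n_called > 0,
                        (called & (d == 1)).sum(axis=0) / n_called, np.nan)
        hexp = 2.0 * p_alt * (1.0 - p_alt)
        ratio = np.where(hexp > 0, hobs / hexp, np.nan)
    return pd.DataFrame(
        {
            "n_called": n_called,
            "missingness": 1.0 - n_called / n if n else np.nan,
            "p_alt": p_alt,
            "maf": maf,
            "mac": mac,
            "hobs": hobs,
            "hexp": hexp,
            "ratio": ratio,
        }
    )


@dataclass(frozen=True)
class InbreedingEstimate:
    """Dataset-level inbreeding coefficient and the derived filter cutoff."""

    f: float
    n_sites_used: int
    factor: float = 5.0

    @property
    def cutoff(self) -> float:
        """Maximum tolerated Hobs/Hexp ratio: factor * (1 - F)."""
        return self.factor * (1.0 - self.f)


class InbreedingEstimationError(ValueError):
    """No qualifying site — the panel looks outbred or degenerate."""


def estimate_inbreeding(stats: pd.DataFrame, maf_min: float = 0.05,
                        factor: float = 5.0) -> InbreedingEstimate:
    """Median-based F estimate over deficit-of-heterozygotes sites.

    Qualifying sites have a defined Hobs/Hexp ratio < 1 and MAF >
    ``maf_min``; F is the median of 1 - ratio over them (for an even
    count, the usual midpoint average).
    """
    ratio = stats["ratio"].to_numpy(dtype=float)
    maf = stats["maf"].to_numpy(dtype=float)
    qual = np.isfinite(ratio) & (ratio < 1.0) & (maf > maf_min)
    if not qual.any():
        raise InbreedingEstimationError(
            "no site with Hobs/Hexp < 1 and MAF > "
            f"{maf_min}; cannot estimate F"
        )
    f = float(np.median(1.0 - ratio[qual]))
    return InbreedingEstimate(f=f, n_sites_used=int(qual.sum()), factor=factor)


@dataclass
class FilterStep:
    name: str
    removed: int
    remaining: int


@dataclass
class FilterReport:
    """Ordered per-filter removal counts; remaining is non-increasing."""

    steps: list = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1].remaining:
            raise ValueError("remaining site count increased across steps")
        self.steps.append(FilterStep(name, int(removed), int(remaining)))

    def extend(self, other: "FilterReport") -> None:
        for s in other.steps:
            self.add(s.name, s.removed, s.remaining)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.removed, s.remaining) for s in self.steps],
            columns=["filter", "removed", "remaining"],
        )


def het_excess_filter(gm: GenotypeMatrix, stats: pd.DataFrame,
                      est: InbreedingEstimate
                      ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop sites whose Hobs/Hexp ratio exceeds the inbreeding cutoff.

    Monomorphic sites (undefined ratio) are retained by this filter —
    they carry no heterozygosity signal either way.
    """
    ratio = stats["ratio"].to_numpy(dtype=float)
    drop = np.isfinite(ratio) & (ratio > est.cutoff)
    keep = ~drop
    report = FilterReport()
    report.add("het_excess", int(drop.sum()), int(keep.sum()))
    return gm.take_sites(keep), report


def hard_filters(gm: GenotypeMatrix, min_maf: float = 0.0,
                 max_missing: float = 1.0, min_mac: int = 0,
                 min_qual: float = 0.0
                 ) -> tuple[GenotypeMatrix, FilterReport]:
    """One-pass MAF / missingness / allele-count / quality filter.

    A site survives iff maf >= min_maf, missingness <= max_missing,
    minor-allele count >= min_mac and QUAL >= min_qual.  The report
    counts failures per criterion (a site may fail several) plus the
    distinct total removed.
    """
    stats = site_stats(gm)
    maf = np.nan_to_num(stats["maf"].to_numpy(dtype=float), nan=0.0)
    fail_maf = maf < min_maf
    fail_miss = stats["missingness"].to_numpy(dtype=float) > max_missing
    fail_mac = stats["mac"].to_numpy(dtype=float) < min_mac
    fail_qual = gm.quals() < min_qual
    drop = fail_maf | fail_miss | fail_mac | fail_qual
    keep = ~drop
    report = FilterReport()
    report.add("hard_filters", int(drop.sum()), int(keep.sum()))
    report.per_criterion = {
        "maf": int(fail_maf.sum()),
        "missingness": int(fail_miss.sum()),
        "mac": int(fail_mac.sum()),
        "qual": int(fail_qual.sum()),
    }
    return gm.take_sites(keep), report


def _imputed_standardised(gm: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    """Mean-imputed dosage columns (imputation never written back)."""
    d = gm.dosage[:, cols].astype(float)
    miss = d == MISSING
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
    mean = np.nan_to_num(mean, nan=0.0)
    return np.where(miss, mean[None, :], d)


def ld_prune(gm: GenotypeMatrix, window_snps: int, step_snps: int,
             r2_max: float) -> np.ndarray:
    """Within-window LD pruning on squared dosage correlation.

    Windows of ``window_snps`` consecutive sites advance by
    ``step_snps`` along each chromosome.  Within a window, while any
    kept pair has r-squared above ``r2_max``, the member of the worst
    (highest r-squared) pair with the lower MAF is removed (tie broken
    toward the larger coordinate).  Zero-variance sites count as
    uncorrelated with everything.  Returns the kept site indices.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    stats = site_stats(gm)
    maf = np.nan_to_num(stats["maf"].to_numpy(dtype=float), nan=0.0)
    chroms = gm.chroms()
    kept_global: list[int] = []
    for chrom in dict.fromkeys(chroms):  # preserve order of appearance
        idx = np.flatnonzero(chroms == chrom)
        x = _imputed_standardised(gm, idx)
        x = x - x.mean(axis=0)
        norm = np.sqrt((x ** 2).sum(axis=0))
        kept = np.ones(len(idx), dtype=bool)
        for start in range(0, len(idx), step_snps):
            win = np.arange(start, min(start + window_snps, len(idx)))
            if len(win) < 2:
                continue
            while True:
                active = win[kept[win]]
                if len(active) < 2:
                    break
                xa = x[:, active]
                na = norm[active]
                with np.errstate(divide="ignore", invalid="ignore"):
                    corr = (xa.T @ xa) / np.outer(na, na)
                corr = np.nan_to_num(corr, nan=0.0)
                r2 = corr ** 2
                np.fill_diagonal(r2, 0.0)
                a, b = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[a, b] <= r2_max:
                    break
                sa, sb = active[a], active[b]
                ma, mb = maf[idx[sa]], maf[idx[sb]]
                if ma < mb:
                    victim = sa
                elif mb < ma:
                    victim = sb
                else:  # tie: drop the larger coordinate
                    victim = max(sa, sb)
                kept[victim] = False
        kept_global.extend(idx[kept].tolist())
    return np.array(sorted(kept_global), dtype=int)


def thin(gm: GenotypeMatrix, min_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right physical thinning per chromosome.

    A site is kept only if it lies at least ``min_bp`` from the last
    kept site on the same chromosome; ``min_bp`` = 0 is the identity.
    """
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    if min_bp == 0:
        return gm
    keep = np.zeros(gm.n_sites, dtype=bool)
    last: dict[str, int] = {}
    for j, s in enumerate(gm.sites):
        prev = last.get(s.chrom)
        if prev is None or s.pos - prev >= min_bp:
            keep[j] = True
            last[s.chrom] = s.pos
    return gm.take_sites(keep)


def filter_cascade(gm: GenotypeMatrix, min_qual: float = 30.0,
                   min_mac: int = 3, max_missing: float = 0.5,
                   het_factor: float = 5.0, het_maf: float = 0.05,
                   min_maf: float = 0.01,
                   prune_rounds=((10, 1, 0.8), (50, 1, 0.8)),
                   thin_bp: int = 0
                   ) -> tuple[GenotypeMatrix, FilterReport, InbreedingEstimate]:
    """The full marker-QC cascade in its documented order.

    qual/mac/missing -> inbreeding-aware het-excess -> MAF -> one or more
    LD-pruning rounds -> physical thinning.  Each step's removals are
    logged in the returned :class:`FilterReport`.
    """
    report = FilterReport()
    report.add("input", 0, gm.n_sites)
    gm, rep = hard_filters(gm, min_maf=0.0, max_missing=max_missing,
                           min_mac=min_mac, min_qual=min_qual)
    report.extend(rep)
    stats = site_stats(gm)
    est = estimate_inbreeding(stats, maf_min=het_maf, factor=het_factor)
    gm, rep = het_excess_filter(gm, stats, est)
    report.extend(rep)
    if min_maf > 0:
        gm, rep = hard_filters(gm, min_maf=min_maf)
        rep.steps[0].name = "maf"
        report.extend(rep)
    for window_snps, step_snps, r2_max in prune_rounds:
        before = gm.n_sites
        kept = ld_prune(gm, window_snps, step_snps, r2_max)
        gm = gm.take_sites(kept)
        report.add(f"ld_prune_{window_snps}_{step_snps}_{r2_max}",
                   before - gm.n_sites, gm.n_sites)
    if thin_bp > 0:
        before = gm.n_sites
        gm = thin(gm, thin_bp)
        report.add(f"thin_{thin_bp}", before - gm.n_sites, gm.n_sites)
    return gm, report, est
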
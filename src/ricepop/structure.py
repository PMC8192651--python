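"""Admixture-model inference and population-structure embeddings.

The admixture model: individual i's genotype at site l is
Binomial(2, f_il) with f_il = sum_k q_ik p_kl, where q_ik are ancestry
proportions (rows of Q sum to 1) and p_kl are per-population ALT
frequencies.  :class:`AdmixtureEM` maximises the binomial log-likelihood
by the classical multiplicative EM updates, which never decrease the
likelihood.  Replicate runs are reconciled with a label-permutation
alignment (exhaustive for K <= 8) and averaged; the number of
populations is chosen with the Evanno delta-K statistic; samples are
assigned to subpopulations by thresholding the averaged Q, with an
optional major-group fallback rule (e.g. Indica-admixed /
Japonica-admixed).  PCA on standardised dosages and classical
multidimensional scaling (principal coordinates) provide the
complementary geometric view.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genio import MISSING, GenotypeMatrix

_P_EPS = 1e-6
_F_EPS = 1e-9


def _dosage_and_mask(x):
    if isinstance(x, GenotypeMatrix):
        d = x.dosage.astype(float)
    else:
        d = np.asarray(x, dtype=float)
    mask = (d != MISSING) & np.isfinite(d)
    return np.where(mask, d, 0.0), mask


@dataclass
class AdmixtureFit:
    """One converged EM run: Q, P, its likelihood trace and seed."""

    q: np.ndarray
    p: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    seed: int | None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def admixture_loglik(g: np.ndarray, mask: np.ndarray, q: np.ndarray,
                     p: np.ndarray) -> float:
    """Binomial log-likelihood of dosages under (Q, P), missing skipped.

    Includes the binomial coefficient term ln C(2, g) so the value is a
    genuine log-probability (ln 2 per heterozygote).
    """
    f = np.clip(q @ p, _F_EPS, 1 - _F_EPS)
    ll = np.where(mask, g * np.log(f) + (2 - g) * np.log1p(-f), 0.0).sum()
    ll += math.log(2.0) * int(((g == 1) & mask).sum())
    return float(ll)


class AdmixtureEM(BaseEstimator):
    """Maximum-likelihood admixture inference via multiplicative EM.

    Parameters
    ----------
    n_populations : int
        Number of ancestral populations K.
    max_iter, tol : int, float
        EM stops when the log-likelihood gain drops below ``tol`` or
        after ``max_iter`` iterations.
    random_state : int or None
        Seed for the random initialisation of Q and P.

    Attributes
    ----------
    Q_ : ndarray of shape (n_samples, K)
        Ancestry proportions; rows sum to 1.
    P_ : ndarray of shape (K, n_sites)
        Per-population ALT frequencies, clamped to [1e-6, 1 - 1e-6].
    loglik_trace_ : ndarray
        Per-iteration log-likelihood (non-decreasing).
    converged_ : bool
    """

    def __init__(self, n_populations: int = 3, max_iter: int = 2000,
                 tol: float = 1e-6, random_state: int | None = 0):
        self.n_populations = n_populations
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        g, mask = _dosage_and_mask(X)
        n, n_sites = g.shape
        k = self.n_populations
        if k < 1:
            raise ValueError("n_populations must be >= 1")
        if k > n:
            raise ValueError(f"K = {k} exceeds the {n} samples")
        n_called = mask.sum(axis=1)
        if (n_called == 0).any():
            bad = int(np.flatnonzero(n_called == 0)[0])
            raise ValueError(f"sample index {bad} has no called genotypes")
        rng = np.random.default_rng(self.random_state)
        q = rng.dirichlet(np.ones(k), size=n)
        p = np.clip(rng.uniform(0.05, 0.95, size=(k, n_sites)), _P_EPS,
                    1 - _P_EPS)
        if k == 1:
            q = np.ones((n, 1))
        trace = [admixture_loglik(g, mask, q, p)]
        converged = False
        two_l = 2.0 * n_called
        g2 = np.where(mask, 2.0 - g, 0.0)
        g1 = np.where(mask, g, 0.0)
        for _ in range(self.max_iter):
            f = np.clip(q @ p, _F_EPS, 1 - _F_EPS)
            a = g1 / f                  # expected ALT weight per (i, l)
            b = g2 / (1.0 - f)          # expected REF weight per (i, l)
            # E-step responsibilities folded into multiplicative updates
            q_new = q * (a @ p.T + b @ (1.0 - p).T) / two_l[:, None]
            num = p * (q.T @ a)
            den = num + (1.0 - p) * (q.T @ b)
            with np.errstate(invalid="ignore"):
                p_new = np.where(den > 0, num / den, p)
            p_new = np.clip(p_new, _P_EPS, 1 - _P_EPS)
            q_new = q_new / q_new.sum(axis=1, keepdims=True)
            q, p = q_new, p_new
            trace.append(admixture_loglik(g, mask, q, p))
            if trace[-1] - trace[-2] < self.tol:
                converged = True
                break
        self.Q_ = q
        self.P_ = p
        self.loglik_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_iter_ = len(trace) - 1
        return self

    @property
    def loglik_(self) -> float:
        return float(self.loglik_trace_[-1])


def admixture_em(gm, k: int, seed: int | None = 0, max_iter: int = 2000,
                 tol: float = 1e-6) -> AdmixtureFit:
    """Functional wrapper over :class:`AdmixtureEM` returning the fit."""
    est = AdmixtureEM(n_populations=k, max_iter=max_iter, tol=tol,
                      random_state=seed).fit(gm)
    return AdmixtureFit(est.Q_, est.P_, est.loglik_trace_, est.converged_,
                        seed)


def run_replicates(gm, k: int, n_replicates: int, seed: int = 0,
                   **em_kwargs) -> list[AdmixtureFit]:
    """Independent EM restarts with derived seeds."""
    return [admixture_em(gm, k, seed=seed + 1000 * r, **em_kwargs)
            for r in range(n_replicates)]


def align_runs(runs, reference_index: int = 0):
    """Resolve label switching across replicate Q matrices.

    For K <= 8 the exact column permutation minimising the Frobenius
    distance to the reference run is found by exhaustive search; for
    larger K a greedy best-match assignment on column correlations is
    used.  Returns ``(aligned_runs, permutations)`` where permutation
    ``perm`` maps reference column j to run column ``perm[j]``.
    """
    qs = [np.asarray(q, dtype=float) for q in runs]
    shapes = {q.shape for q in qs}
    if len(shapes) != 1:
        raise ValueError(f"Q matrices differ in shape: {shapes}")
    ref = qs[reference_index]
    k = ref.shape[1]
    aligned, perms = [], []
    for q in qs:
        if k <= 8:
            best, best_d = None, np.inf
            for perm in itertools.permutations(range(k)):
                d = float(((q[:, perm] - ref) ** 2).sum())
                if d < best_d:
                    best, best_d = perm, d
            perm = best
        else:
            rc = ref - ref.mean(axis=0)
            qc = q - q.mean(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (rc.T @ qc) / np.outer(
                    np.linalg.norm(rc, axis=0), np.linalg.norm(qc, axis=0))
            corr = np.nan_to_num(corr, nan=-np.inf)
            perm = [-1] * k
            used_r, used_q = set(), set()
            order = np.dstack(np.unravel_index(
                np.argsort(-corr, axis=None), corr.shape))[0]
            for i, j in order:
                if i not in used_r and j not in used_q:
                    perm[i] = int(j)
                    used_r.add(int(i))
                    used_q.add(int(j))
                if len(used_r) == k:
                    break
        aligned.append(q[:, list(perm)])
        perms.append(tuple(perm))
    return aligned, perms


def average_q(aligned_runs) -> np.ndarray:
    """Entrywise mean of aligned runs, rows renormalised to sum to 1."""
    if len(aligned_runs) == 0:
        raise ValueError("no runs to average")
    mean = np.mean([np.asarray(q, dtype=float) for q in aligned_runs], axis=0)
    return mean / mean.sum(axis=1, keepdims=True)


def consensus_q(runs, distance_threshold: float = 0.1,
                max_averaged: int = 10) -> np.ndarray:
    """Align replicate runs, keep the largest mutually consistent cluster
    (mean per-entry distance below ``distance_threshold`` to the cluster
    seed) and average up to ``max_averaged`` of its members."""
    aligned, _ = align_runs(runs)
    n_runs = len(aligned)
    best_cluster: list[int] = []
    for seed_i in range(n_runs):
        ref = aligned[seed_i]
        members = [j for j in range(n_runs)
                   if np.abs(aligned[j] - ref).mean() < distance_threshold]
        if len(members) > len(best_cluster):
            best_cluster = members
    chosen = [aligned[j] for j in best_cluster[:max_averaged]]
    return average_q(chosen)


def evanno(loglik_by_k: dict) -> pd.DataFrame:
    """Evanno delta-K table from replicate log-likelihoods per K.

    Columns: mean_l, sd_l, l_prime (L'(K) = mean(K) - mean(K-1)),
    l_doubleprime_abs (|L'(K+1) - L'(K)|) and delta_k
    (|L''| / sd, defined only at interior K with positive sd and >= 2
    replicates).  K values must be consecutive.
    """
    ks = sorted(loglik_by_k)
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError(f"K values must be consecutive, got {ks}")
    for k in ks:
        if len(loglik_by_k[k]) < 2:
            raise ValueError(f"need >= 2 replicates at K = {k}")
    mean_l = np.array([np.mean(loglik_by_k[k]) for k in ks])
    sd_l = np.array([np.std(loglik_by_k[k], ddof=1) for k in ks])
    l_prime = np.full(len(ks), np.nan)
    l_prime[1:] = np.diff(mean_l)
    l_pp = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        l_pp[i] = abs(l_prime[i + 1] - l_prime[i])
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_k = np.where(sd_l > 0, l_pp / sd_l, np.nan)
    return pd.DataFrame(
        {"mean_l": mean_l, "sd_l": sd_l, "l_prime": l_prime,
         "l_doubleprime_abs": l_pp, "delta_k": delta_k},
        index=pd.Index(ks, name="k"),
    )


def best_k(evanno_table: pd.DataFrame) -> int:
    """K with the largest defined delta-K."""
    dk = evanno_table["delta_k"]
    if dk.isna().all():
        raise ValueError("delta-K undefined at every K")
    return int(dk.idxmax())


def assign_subpops(q: np.ndarray, threshold: float, groups: dict | None = None,
                   group_threshold: float | None = None,
                   labels=None, sample_ids=None) -> pd.DataFrame:
    """Threshold-based subpopulation assignment from an averaged Q.

    A sample joins its argmax column when the maximum component reaches
    ``threshold`` (ties broken toward the lowest column index and
    flagged).  Otherwise, if ``groups`` maps columns to major groups
    (e.g. Indica / Japonica) and some group's summed components reach
    ``group_threshold``, the sample is labelled ``<group>-adm``; all
    remaining samples are ``admix``.
    """
    q = np.asarray(q, dtype=float)
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n, k = q.shape
    if labels is None:
        labels = [f"pop{j + 1}" for j in range(k)]
    if groups is not None:
        unknown = [c for c in groups if not 0 <= c < k]
        if unknown:
            raise ValueError(f"groups reference unknown columns {unknown}")
    amax = q.argmax(axis=1)
    mx = q[np.arange(n), amax]
    tie = (q == mx[:, None]).sum(axis=1) > 1
    out_labels = []
    group_names = sorted(set(groups.values())) if groups else []
    group_sums = {
        g: q[:, [c for c, gg in groups.items() if gg == g]].sum(axis=1)
        for g in group_names
    }
    for i in range(n):
        if mx[i] >= threshold:
            out_labels.append(labels[amax[i]])
        elif groups and group_threshold is not None:
            sums = {g: group_sums[g][i] for g in group_names}
            g_best = max(sums, key=lambda g: (sums[g], g))
            if sums[g_best] >= group_threshold:
                out_labels.append(f"{g_best}-adm")
            else:
                out_labels.append("admix")
        else:
            out_labels.append("admix")
    out = pd.DataFrame({"label": out_labels, "max_component": mx,
                        "argmax_tie": tie})
    for g in group_names:
        out[f"sum_{g}"] = group_sums[g]
    if sample_ids is not None:
        out.index = pd.Index(sample_ids)
    return out


@dataclass
class EmbeddingResult:
    """Sample coordinates plus the eigenvalues of the embedding."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    method: str


class GenotypePCA(BaseEstimator, TransformerMixin):
    """PCA of allele-frequency-standardised dosages.

    Each polymorphic site is centred by twice its allele frequency and
    (optionally) scaled by the binomial standard deviation
    sqrt(2 p (1 - p)); missing calls contribute 0 after centring.
    Scores are the left singular vectors scaled by the singular values.
    The sign convention makes each component's largest-magnitude loading
    positive.
    """

    def __init__(self, n_components: int = 5, standardize: bool = True):
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        g, mask = _dosage_and_mask(X)
        n, n_sites = g.shape
        with np.errstate(invalid="ignore"):
            p_hat = np.where(mask, g, 0.0).sum(axis=0) / (
                2.0 * np.maximum(mask.sum(axis=0), 1))
        poly = (p_hat > 0) & (p_hat < 1) & (mask.sum(axis=0) > 0)
        if poly.sum() < 2:
            raise ValueError("need >= 2 polymorphic sites for PCA")
        if self.n_components > min(n, int(poly.sum())):
            raise ValueError("n_components exceeds matrix rank bound")
        z = g[:, poly] - 2.0 * p_hat[None, poly]
        z[~mask[:, poly]] = 0.0
        if self.standardize:
            z /= np.sqrt(2.0 * p_hat[poly] * (1.0 - p_hat[poly]))[None, :]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        d = self.n_components
        # sign convention: largest-|loading| entry of each component > 0
        for j in range(d):
            i_max = np.argmax(np.abs(vt[j]))
            if vt[j, i_max] < 0:
                vt[j] *= -1
                u[:, j] *= -1
        self.components_ = vt[:d]
        self.singular_values_ = s[:d]
        self.eigenvalues_ = (s[:d] ** 2) / max(n - 1, 1)
        self.scores_ = u[:, :d] * s[:d]
        self.sites_used_ = np.flatnonzero(poly)
        return self.scores_


def pca(gm, n_components: int = 5, standardize: bool = True
        ) -> EmbeddingResult:
    est = GenotypePCA(n_components=n_components, standardize=standardize)
    scores = est.fit_transform(gm)
    return EmbeddingResult(scores, est.eigenvalues_, "pca")


def pco(d: np.ndarray, n_components: int = 5) -> EmbeddingResult:
    """Classical multidimensional scaling (principal coordinates).

    Double-centres the squared distance matrix, B = -1/2 J D^2 J, and
    embeds with the top non-negative eigenpairs; negative eigenvalues
    (non-Euclidean distances) are dropped with a warning.  Exact for a
    matrix of Euclidean distances, up to rotation/reflection.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12
    if (vals < -tol).any():
        warnings.warn(
            f"{int((vals < -tol).sum())} negative eigenvalues dropped "
            "(distances are not Euclidean)"
        )
    n_comp = min(n_components, n)
    lam = np.clip(vals[:n_comp], 0.0, None)
    coords = vecs[:, :n_comp] * np.sqrt(lam)[None, :]
    return EmbeddingResult(coords, lam, "pco")
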
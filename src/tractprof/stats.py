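"""Profile statistics: norms, individual comparison, point-wise inference.

A cohort of Tract Profiles (subjects x nodes) is summarized into a
normative profile (per-node mean, SD, percentile bands). Individuals are
compared to the norm as per-node z-scores and percentile positions, and
flagged as abnormal when a sufficiently long run of consecutive nodes falls
outside a percentile band.

Point-wise group differences (two-sample t) and brain-behavior
correlations (Pearson r) are corrected for multiple comparisons across
nodes with the max-statistic permutation procedure of Nichols & Holmes:
for each relabeling compute the maximum |statistic| over nodes; the
corrected p at node k is (1 + #{perm max >= |observed_k|}) / (nperm + 1).
Because neighboring nodes are strongly correlated, this is far less
conservative than Bonferroni while still controlling family-wise error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .profiles import TractProfile

PERCENTILES = (5, 10, 25, 75, 90, 95)


def _cohort_matrix(cohort: Sequence[TractProfile] | np.ndarray) -> np.ndarray:
    if isinstance(cohort, np.ndarray):
        return np.asarray(cohort, dtype=float)
    arr = np.array([p.values for p in cohort], dtype=float)
    metrics = {p.metric for p in cohort}
    if len(metrics) > 1:
        raise ValueError(f"cohort mixes metrics {metrics}")
    return arr


@dataclass(eq=False)
class StandardProfile:
    """Normative per-node summary of a profile cohort."""

    metric: str
    mean: np.ndarray
    sd: np.ndarray
    percentiles: dict[int, np.ndarray]
    n_subjects: int
    samples: np.ndarray | None = None  # retained cohort matrix for empirical lookups

    def __post_init__(self) -> None:
        for lo, hi in zip(PERCENTILES[:-1], PERCENTILES[1:]):
            if np.any(self.percentiles[lo] > self.percentiles[hi] + 1e-12):
                raise ValueError("percentile bands must be nested")
        if np.any(self.sd < 0):
            raise ValueError("SD must be nonnegative")


@dataclass(eq=False)
class PointwiseResult:
    """Per-node statistic with uncorrected and max-statistic-corrected p-values."""

    statistic: np.ndarray
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    alpha: float
    stat_name: str = "t"


def standardize(cohort: Sequence[TractProfile] | np.ndarray, metric: str = "") -> StandardProfile:
    """Per-node mean, sample SD and empirical percentiles of a cohort.

    Percentiles use the linear-interpolation convention between order
    statistics. The cohort matrix is retained for empirical percentile
    positioning of individuals.
    """
    X = _cohort_matrix(cohort)
    if X.shape[0] < 2:
        raise ValueError("normative profile needs at least 2 subjects")
    if not metric and not isinstance(cohort, np.ndarray):
        metric = cohort[0].metric
    pct = {q: np.percentile(X, q, axis=0, method="linear") for q in PERCENTILES}
    return StandardProfile(
        metric=metric,
        mean=X.mean(axis=0),
        sd=X.std(axis=0, ddof=1),
        percentiles=pct,
        n_subjects=X.shape[0],
        samples=X,
    )


def compare_individual(
    p: TractProfile | np.ndarray, norm: StandardProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node z-scores and empirical percentile positions against the norm.

    z is NaN (flagged via warning) where the normative SD is zero. Percentile
    position is the fraction of normative subjects at or below the value,
    in percent.
    """
    vals = p.values if isinstance(p, TractProfile) else np.asarray(p, dtype=float)
    if vals.shape != norm.mean.shape:
        raise ValueError("profile and norm node counts differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - norm.mean) / norm.sd
    if np.any(norm.sd == 0):
        warnings.warn("zero normative SD at some nodes; z undefined there", stacklevel=2)
        z = np.where(norm.sd == 0, np.nan, z)
    if norm.samples is not None:
        pctl = 100.0 * (norm.samples <= vals[None, :]).mean(axis=0)
    else:  # fall back to the Gaussian summary
        from scipy.stats import norm as _n

        pctl = 100.0 * _n.cdf(z)
    return z, pctl


def flag_abnormal(
    p: TractProfile | np.ndarray,
    norm: StandardProfile,
    band: tuple[int, int] = (10, 90),
    min_run: int = 10,
) -> tuple[bool, list[tuple[int, int]]]:
    """Flag a profile with >= min_run consecutive nodes outside a percentile band.

    ``band`` is (lower, upper) percentile, e.g. (10, 90) or (5, 95). Returns
    (flagged, spans) with spans as half-open [start, stop) node index ranges.
    """
    lo, hi = band
    if lo not in norm.percentiles or hi not in norm.percentiles:
        raise ValueError(f"band {band} not among computed percentiles {PERCENTILES}")
    vals = p.values if isinstance(p, TractProfile) else np.asarray(p, dtype=float)
    outside = (vals < norm.percentiles[lo]) | (vals > norm.percentiles[hi])
    spans: list[tuple[int, int]] = []
    i = 0
    n = outside.size
    while i < n:
        if outside[i]:
            j = i
            while j < n and outside[j]:
                j += 1
            if j - i >= min_run:
                spans.append((i, j))
            i = j
        else:
            i += 1
    return bool(spans), spans


# -- permutation machinery ----------------------------------------------------

def _two_group_permutations(
    n_a: int, n_b: int, nperm: int, rng: np.random.Generator
) -> np.ndarray:
    """(P, n) boolean group-A membership matrices; first row = observed labels.

    Enumerated exhaustively when C(n, n_a) <= nperm, else sampled.
    """
    n = n_a + n_b
    total = math.comb(n, n_a)
    if total <= nperm:
        out = np.zeros((total, n), dtype=bool)
        for i, c in enumerate(combinations(range(n), n_a)):
            out[i, list(c)] = True
        # move the observed labeling (first n_a indices) to row 0
        obs = np.zeros(n, dtype=bool)
        obs[:n_a] = True
        k = int(np.flatnonzero((out == obs).all(axis=1))[0])
        out[[0, k]] = out[[k, 0]]
        return out
    out = np.zeros((nperm, n), dtype=bool)
    out[0, :n_a] = True
    for i in range(1, nperm):
        out[i, rng.permutation(n)[:n_a]] = True
    return out


def _pooled_t(labels: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t per node for each labeling row.

    labels: (P, n) boolean group-A; X: (n, K). Returns (P, K).
    """
    L = labels.astype(float)
    n = X.shape[0]
    n_a = L.sum(axis=1, keepdims=True)
    n_b = n - n_a
    sum_a = L @ X
    sum_all = X.sum(axis=0, keepdims=True)
    sq_a = L @ (X**2)
    sq_all = (X**2).sum(axis=0, keepdims=True)
    mean_a = sum_a / n_a
    mean_b = (sum_all - sum_a) / n_b
    ss_a = sq_a - sum_a**2 / n_a
    ss_b = (sq_all - sq_a) - (sum_all - sum_a) ** 2 / n_b
    sp2 = (ss_a + ss_b) / (n - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    return t


def _welch_t(labels: np.ndarray, X: np.ndarray) -> np.ndarray:
    L = labels.astype(float)
    n_a = L.sum(axis=1, keepdims=True)
    n_b = X.shape[0] - n_a
    sum_a = L @ X
    sq_a = L @ (X**2)
    sum_all = X.sum(axis=0, keepdims=True)
    sq_all = (X**2).sum(axis=0, keepdims=True)
    mean_a, mean_b = sum_a / n_a, (sum_all - sum_a) / n_b
    var_a = (sq_a - sum_a**2 / n_a) / (n_a - 1)
    var_b = ((sq_all - sq_a) - (sum_all - sum_a) ** 2 / n_b) / (n_b - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (mean_a - mean_b) / np.sqrt(var_a / n_a + var_b / n_b)


def _pvalues_from_perm_stats(perm_stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uncorrected and max-statistic corrected p from (P, K) permutation stats.

    Row 0 must hold the observed labeling. Both use the add-one estimator
    over the P-1 true permutations, so corrected >= uncorrected holds exactly.
    """
    obs = np.abs(perm_stats[0])
    null = np.abs(perm_stats[1:])
    nperm = null.shape[0]
    p_unc = (1 + (null >= obs[None, :]).sum(axis=0)) / (nperm + 1)
    max_null = null.max(axis=1)
    p_cor = (1 + (max_null[:, None] >= obs[None, :]).sum(axis=0)) / (nperm + 1)
    return p_unc, p_cor


def permutation_max_correct(
    stat_per_node_fn: Callable[[np.ndarray], np.ndarray],
    permutations: np.ndarray,
    nperm: int | None = None,
    rng_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Max-statistic family-wise correction over an explicit permutation set.

    ``stat_per_node_fn`` maps one row of ``permutations`` (a labeling or an
    index permutation) to the per-node statistic vector; row 0 is the
    observed arrangement. Returns (observed stats, uncorrected p, corrected p),
    both p's with the add-one estimator so corrected p is never zero.
    """
    permutations = np.asarray(permutations)
    n_true = permutations.shape[0] - 1
    if n_true < 100:
        warnings.warn(f"only {n_true} permutations; p-values are coarse", stacklevel=2)
    stats = np.array([stat_per_node_fn(row) for row in permutations])
    p_unc, p_cor = _pvalues_from_perm_stats(stats)
    return stats[0], p_unc, p_cor


def pointwise_group_test(
    group_a: Sequence[TractProfile] | np.ndarray,
    group_b: Sequence[TractProfile] | np.ndarray,
    nperm: int = 1000,
    alpha: float = 0.05,
    rng_seed: int | None = 0,
    welch: bool = False,
) -> PointwiseResult:
    """Point-wise two-sample t test with max-statistic permutation correction.

    Group labels are permuted (exhaustively when feasible); pooled-variance t
    by default, Welch optional. Nodes where the pooled variance degenerates
    are reported as NaN.
    """
    A, B = _cohort_matrix(group_a), _cohort_matrix(group_b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different node counts")
    X = np.vstack([A, B])
    rng = np.random.default_rng(rng_seed)
    labels = _two_group_permutations(A.shape[0], B.shape[0], nperm + 1, rng)
    stat = _welch_t(labels, X) if welch else _pooled_t(labels, X)
    degenerate = ~np.isfinite(stat[0])
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} nodes with degenerate variance skipped", stacklevel=2)
        stat[:, degenerate] = 0.0
    p_unc, p_cor = _pvalues_from_perm_stats(stat)
    t_obs = np.where(degenerate, np.nan, stat[0])
    p_unc = np.where(degenerate, np.nan, p_unc)
    p_cor = np.where(degenerate, np.nan, p_cor)
    return PointwiseResult(
        statistic=t_obs,
        p_uncorrected=p_unc,
        p_corrected=p_cor,
        significant=p_cor <= alpha,
        alpha=alpha,
        stat_name="t(welch)" if welch else "t",
    )


def _partial_out(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residualize columns of v against an intercept + covariate."""
    C = np.column_stack([np.ones(len(covariate)), covariate])
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def pointwise_correlation(
    cohort: Sequence[TractProfile] | np.ndarray,
    behavior: np.ndarray,
    nperm: int = 1000,
    alpha: float = 0.05,
    rng_seed: int | None = 0,
    partial: np.ndarray | None = None,
) -> PointwiseResult:
    """Point-wise Pearson correlation of profiles with a behavioral score.

    Subject labels of the behavior vector are permuted for the max-statistic
    correction. With ``partial`` (e.g. age), both behavior and node values
    are residualized against it first and the partial correlation is tested.
    """
    X = _cohort_matrix(cohort)
    y = np.asarray(behavior, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError("one behavior value per subject required")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.std(y) == 0:
        raise ValueError("behavior has zero variance")
    if partial is not None:
        cov = np.asarray(partial, dtype=float).ravel()
        X = _partial_out(X, cov)
        y = _partial_out(y[:, None], cov).ravel()

    Xs = X - X.mean(axis=0)
    xnorm = np.sqrt((Xs**2).sum(axis=0))
    xnorm[xnorm == 0] = np.inf
    Xs = Xs / xnorm
    ys = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())

    rng = np.random.default_rng(rng_seed)
    total = math.factorial(n) if n <= 12 else nperm + 1
    if total <= nperm:
        from itertools import permutations as _perms

        idx = np.vstack([np.arange(n)[None, :], np.array(list(_perms(range(n))))])
    else:
        idx = np.vstack([np.arange(n)[None, :], np.array([rng.permutation(n) for _ in range(nperm)])])
    r = ys[idx] @ Xs  # (P, K)
    p_unc, p_cor = _pvalues_from_perm_stats(r)
    return PointwiseResult(
        statistic=r[0],
        p_uncorrected=p_unc,
        p_corrected=p_cor,
        significant=p_cor <= alpha,
        alpha=alpha,
        stat_name="r(partial)" if partial is not None else "r",
    )
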
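"""Fiber-group cleaning: 100-node Gaussian core and iterative outlier removal.

Each fiber is resampled to a fixed number of equidistant nodes (default 100)
and oriented so that node k is anatomically equivalent across fibers. The
spread of node-k coordinates across fibers is modeled as a trivariate
Gaussian with mean mu[k] and sample covariance S[k]; a fiber node's
Mahalanobis distance from the core is

    D_m(x) = sqrt((x - mu)' S^-1 (x - mu))

Cleaning iterates: flag fibers whose length exceeds the group mean by more
than ``max_len_sd`` standard deviations (one-sided) or whose maximum
over-node Mahalanobis distance exceeds ``max_dist_sd``; remove them only
when the flagged count exceeds what a Gaussian bundle would produce by
chance; recompute and repeat until no removals occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .segmentation import TractDefinition
from .tracking import FiberGroup, Streamline

COV_EPS = 1e-6  # mm^2 ridge added before inversion (degenerate node clouds)


@dataclass(eq=False)
class FiberCore:
    """Per-node mean coordinate and 3x3 positional covariance of a fiber group."""

    mu: np.ndarray  # (n_nodes, 3) mm
    cov: np.ndarray  # (n_nodes, 3, 3) mm^2

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.isfinite(self.mu).all():
            raise ValueError("core mean contains non-finite values")
        if not np.allclose(self.cov, np.swapaxes(self.cov, -1, -2)):
            raise ValueError("node covariances must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.mu)


@dataclass
class CleaningParams:
    max_len_sd: float = 4.0
    max_dist_sd: float = 5.0
    n_nodes: int = 100

    def __post_init__(self) -> None:
        if self.max_len_sd <= 0 or self.max_dist_sd <= 0:
            raise ValueError("cleaning thresholds must be positive")


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(s: Streamline, n: int = 100) -> Streamline:
    """Resample to n points at equal arc-length spacing; endpoints preserved."""
    if len(s.points) < 2:
        raise ValueError("cannot resample a streamline with fewer than 2 points")
    t = arc_lengths(s.points)
    total = t[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-length streamline")
    targets = np.linspace(0.0, total, n)
    new = np.column_stack([np.interp(targets, t, s.points[:, i]) for i in range(3)])
    new[0], new[-1] = s.points[0], s.points[-1]
    return Streamline(points=new, seed_index=s.seed_index, termination=s.termination)


def resample_group(g: FiberGroup, n: int = 100) -> FiberGroup:
    return FiberGroup(
        name=g.name,
        streamlines=[resample_streamline(s, n) for s in g.streamlines],
        provenance={**g.provenance, "n_nodes": n},
    )


def orient_fiber_group(g: FiberGroup, tract: TractDefinition) -> FiberGroup:
    """Flip fibers so all run roi_start -> roi_end.

    A fiber is reversed when its first point is nearer (to the nearest ROI
    voxel center) the end ROI than the start ROI.
    """
    start_pts = tract.roi_start.voxel_centers_mm()
    end_pts = tract.roi_end.voxel_centers_mm()
    out = []
    for s in g.streamlines:
        p0 = s.points[0]
        d_start = np.linalg.norm(start_pts - p0, axis=1).min()
        d_end = np.linalg.norm(end_pts - p0, axis=1).min()
        if d_end < d_start:
            out.append(
                Streamline(
                    points=s.points[::-1].copy(),
                    seed_index=s.seed_index,
                    termination=s.termination[::-1],
                )
            )
        else:
            out.append(s)
    return FiberGroup(name=g.name, streamlines=out, provenance=dict(g.provenance))


def compute_tract_core(g: FiberGroup, n: int | None = None) -> FiberCore:
    """Per-node mean and sample covariance (divisor N-1) of fiber coordinates.

    Fibers must already be resampled to a common node count and oriented;
    pass ``n`` to resample here as a convenience.
    """
    if len(g) < 2:
        raise ValueError("tract core needs at least 2 fibers (covariance undefined)")
    if n is not None:
        g = resample_group(g, n)
    X = g.coords()  # (F, n_nodes, 3)
    mu = X.mean(axis=0)
    d = X - mu
    cov = np.einsum("fki,fkj->kij", d, d) / (len(g) - 1)
    return FiberCore(mu=mu, cov=cov)


def node_mahalanobis(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Mahalanobis distance of one 3-D point from a node's Gaussian."""
    S = np.asarray(cov, dtype=float) + COV_EPS * np.eye(3)
    try:
        sol = np.linalg.solve(S, np.asarray(x, dtype=float) - mu)
    except np.linalg.LinAlgError as e:
        raise ValueError("node covariance singular even after regularization") from e
    return float(np.sqrt((np.asarray(x) - mu) @ sol))


def group_mahalanobis(g: FiberGroup, core: FiberCore) -> np.ndarray:
    """(n_fibers, n_nodes) Mahalanobis distances from the core, vectorized."""
    X = g.coords()
    S = core.cov + COV_EPS * np.eye(3)
    Sinv = np.linalg.inv(S)  # (n_nodes, 3, 3)
    d = X - core.mu  # (F, K, 3)
    q = np.einsum("fki,kij,fkj->fk", d, Sinv, d)
    return np.sqrt(np.maximum(q, 0.0))


def remove_outliers(
    g: FiberGroup, params: CleaningParams | None = None, max_iter: int = 50
) -> tuple[FiberGroup, dict]:
    """Iteratively drop length and core-distance outliers until stable.

    Flagged fibers are removed only when, per criterion, their count exceeds
    the chance expectation under the Gaussian bundle model: N * p with p the
    one-sided normal tail beyond ``max_len_sd`` for length, and the
    chi(3 dof) tail beyond ``max_dist_sd`` for the 3-D positional distance.

    Returns the cleaned group and a report dict (iterations and removals).
    """
    params = params or CleaningParams()
    if len(g) < 3:
        raise ValueError("outlier removal needs at least 3 fibers")
    # statistics run on resampled copies; survivors are the ORIGINAL streamlines
    resampled = resample_group(g, params.n_nodes)
    X_all = resampled.coords()  # (F, n_nodes, 3)
    len_all = np.array([s.length_mm for s in g.streamlines])
    alive = np.ones(len(g), dtype=bool)
    p_len = stats.norm.sf(params.max_len_sd)
    p_dist = stats.chi2.sf(params.max_dist_sd**2, df=3)
    report: dict = {"iterations": [], "params": vars(params).copy()}

    for _ in range(max_iter):
        idx = np.flatnonzero(alive)
        n = idx.size
        lengths = len_all[idx]
        sd_len = lengths.std(ddof=1)
        flag_len = (
            lengths > lengths.mean() + params.max_len_sd * sd_len
            if sd_len > 0
            else np.zeros(n, bool)
        )

        X = X_all[idx]
        mu = X.mean(axis=0)
        d = X - mu
        cov = np.einsum("fki,fkj->kij", d, d) / (n - 1)
        Sinv = np.linalg.inv(cov + COV_EPS * np.eye(3))
        q = np.einsum("fki,kij,fkj->fk", d, Sinv, d)
        dist = np.sqrt(np.maximum(q, 0.0)).max(axis=1)
        flag_dist = dist > params.max_dist_sd

        remove = np.zeros(n, dtype=bool)
        if flag_len.sum() > n * p_len:
            remove |= flag_len
        if flag_dist.sum() > n * p_dist:
            remove |= flag_dist
        report["iterations"].append(
            {
                "n_fibers": n,
                "flagged_length": int(flag_len.sum()),
                "flagged_distance": int(flag_dist.sum()),
                "removed": int(remove.sum()),
            }
        )
        if not remove.any():
            break
        if remove.all():
            raise ValueError("cleaning would remove every fiber; bundle is unstable")
        alive[idx[remove]] = False

    out = FiberGroup(
        name=g.name,
        streamlines=[s for s, a in zip(g.streamlines, alive) if a],
        provenance={
            **g.provenance,
            "stage": "cleaning",
            "n_input": len(g),
            "n_removed": int((~alive).sum()),
            "n_iterations": len(report["iterations"]),
        },
    )
    report["n_input"] = len(g)
    report["n_output"] = len(out)
    return out, report
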
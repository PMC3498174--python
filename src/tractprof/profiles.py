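"""Tract Profiles: along-tract weighted averages of scalar diffusion metrics.

After cleaning, each fiber is clipped to the portion spanning between the
two defining waypoint ROIs and resampled to ``n_nodes`` equidistant nodes
(default 100). A scalar map (FA, MD, RD, AD, ...) is sampled by spline
interpolation at every fiber's own node coordinates, and the per-node tract
value is the weighted average across fibers. A fiber's weight at node k is a
Gaussian kernel on its Mahalanobis distance from the tract core,

    w[i, k] ∝ exp(-D_m(x[i, k])^2 / 2),   normalized so sum_i w[i, k] = 1,

so near-core fibers (likely pure tract tissue) dominate while divergent
fibers, prone to partial-volume contamination, contribute little.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cleaning import FiberCore, group_mahalanobis, resample_streamline
from .segmentation import TractDefinition
from .tensor import ScalarMap, interpolate_scalar
from .tracking import FiberGroup, Streamline


@dataclass(eq=False)
class TractProfile:
    """Vector of a scalar metric at equidistant nodes along a tract core."""

    tract_name: str
    metric: str
    values: np.ndarray  # (n_nodes,)
    node_coords: np.ndarray | None = None  # (n_nodes, 3) core mm coordinates
    n_fibers: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.node_coords is not None:
            self.node_coords = np.asarray(self.node_coords, dtype=float)
            if self.node_coords.shape != (self.values.size, 3):
                raise ValueError("node_coords must be (n_nodes, 3)")

    @property
    def n_nodes(self) -> int:
        return self.values.size


def clip_to_rois(g: FiberGroup, tract: TractDefinition, n_nodes: int = 100) -> FiberGroup:
    """Clip each oriented fiber to the span between the two waypoint ROIs.

    Keeps the sub-polyline between the point nearest roi_start and the point
    nearest roi_end (inclusive), then re-resamples to ``n_nodes``. Fibers
    whose nearest points come out inverted (end before start despite
    orientation) are dropped with a warning.
    """
    start_pts = tract.roi_start.voxel_centers_mm()
    end_pts = tract.roi_end.voxel_centers_mm()
    out, dropped = [], 0
    for s in g.streamlines:
        d_start = np.linalg.norm(s.points[:, None, :] - start_pts[None], axis=2).min(axis=1)
        d_end = np.linalg.norm(s.points[:, None, :] - end_pts[None], axis=2).min(axis=1)
        i0, i1 = int(np.argmin(d_start)), int(np.argmin(d_end))
        if i1 <= i0:
            dropped += 1
            continue
        clipped = Streamline(
            points=s.points[i0 : i1 + 1], seed_index=s.seed_index, termination=s.termination
        )
        out.append(resample_streamline(clipped, n_nodes))
    if dropped:
        warnings.warn(f"{dropped} fibers dropped: ROI span inverted after orientation", stacklevel=2)
    return FiberGroup(
        name=g.name,
        streamlines=out,
        provenance={**g.provenance, "stage": "clip", "n_dropped_inverted": dropped},
    )


def node_weights(g: FiberGroup, core: FiberCore) -> np.ndarray:
    """(n_fibers, n_nodes) Gaussian-kernel weights, column-normalized to 1."""
    D = group_mahalanobis(g, core)
    w = np.exp(-0.5 * D**2)
    colsum = w.sum(axis=0)
    bad = colsum <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} nodes with all-zero weights; uniform fallback", stacklevel=2)
        w[:, bad] = 1.0
        colsum = w.sum(axis=0)
    return w / colsum


def tract_profile(
    g: FiberGroup,
    scalar: ScalarMap,
    core: FiberCore,
    tract_name: str = "",
    interp_order: int = 3,
) -> TractProfile:
    """Weighted average of the scalar at each node over all fibers.

    The scalar is sampled at each fiber's own node coordinates. Fibers whose
    sample falls outside the map at a node are excluded there (weights
    renormalized); a node with no valid sample at all gets NaN and a warning.
    """
    if len(g) == 0:
        raise ValueError("cannot profile an empty fiber group")
    X = g.coords()  # (F, K, 3)
    F, K, _ = X.shape
    vals = interpolate_scalar(scalar, X.reshape(-1, 3), order=interp_order).reshape(F, K)
    w = node_weights(g, core)
    valid = np.isfinite(vals)
    w = np.where(valid, w, 0.0)
    colsum = w.sum(axis=0)
    empty = colsum <= 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} nodes entirely outside the scalar map", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(empty, np.nan, (w * np.where(valid, vals, 0.0)).sum(axis=0) / colsum)
    return TractProfile(
        tract_name=tract_name or g.name,
        metric=scalar.metric,
        values=out,
        node_coords=core.mu.copy(),
        n_fibers=F,
    )
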
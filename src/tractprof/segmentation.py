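"""Waypoint-ROI tract segmentation and probability-map refinement.

A whole-brain fiber set is segmented into a named tract by retaining the
streamlines that pass through both of the tract's two waypoint ROIs
(logical AND, order-agnostic). Candidates are then scored against a tract
probability map — the score is the mean probability over the unique voxels a
fiber visits — and fibers scoring below a threshold are discarded as
aberrant. ROIs and maps defined in a template space are brought into subject
space by applying a precomputed dense displacement field (never estimated
here): nearest-neighbor resampling for masks, linear for probability maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tensor import mm_to_voxel
from .tracking import FiberGroup, Streamline


@dataclass(eq=False)
class WaypointROI:
    mask: np.ndarray
    affine: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if not self.mask.any():
            raise ValueError(f"waypoint ROI {self.name!r} is empty")

    def contains_points(self, points_mm: np.ndarray) -> np.ndarray:
        """True per point if the point's voxel lies in the mask."""
        vox = np.rint(mm_to_voxel(self.affine, points_mm)).astype(int)
        shp = np.asarray(self.mask.shape)
        ok = np.all((vox >= 0) & (vox < shp), axis=-1)
        out = np.zeros(len(vox), dtype=bool)
        if ok.any():
            v = vox[ok]
            out[ok] = self.mask[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def voxel_centers_mm(self) -> np.ndarray:
        idx = np.argwhere(self.mask).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(eq=False)
class ProbabilityMap:
    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probability values must lie in [0, 1]")


@dataclass(eq=False)
class TractDefinition:
    """Named tract: two waypoint ROIs, optional probability map and NOT-mask."""

    name: str
    roi_start: WaypointROI
    roi_end: WaypointROI
    probability_map: ProbabilityMap | None = None
    score_threshold: float = 0.3
    roi_not: WaypointROI | None = None

    def __post_init__(self) -> None:
        if self.roi_start is self.roi_end:
            raise ValueError("roi_start and roi_end must differ")


def warp_volume(
    vol: np.ndarray,
    deformation: np.ndarray,
    affine: np.ndarray,
    is_mask: bool = False,
) -> np.ndarray:
    """Apply a dense displacement field to a volume on the same grid.

    ``deformation`` has shape (X, Y, Z, 3): mm displacements added to each
    output voxel's mm position to find the source location, which is sampled
    from ``vol`` (nearest-neighbor when is_mask, else linear). Consumes
    precomputed fields only.
    """
    vol = np.asarray(vol)
    deformation = np.asarray(deformation, dtype=float)
    if deformation.shape != vol.shape + (3,):
        raise ValueError(
            f"deformation grid {deformation.shape[:-1]} does not match volume {vol.shape}"
        )
    idx = np.indices(vol.shape, dtype=float).reshape(3, -1).T
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    src_mm = mm + deformation.reshape(-1, 3)
    src_vox = mm_to_voxel(affine, src_mm)
    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(
        vol.astype(float), src_vox.T, order=order, mode="constant", cval=0.0
    ).reshape(vol.shape)
    return out > 0.5 if is_mask else out


def segment_by_waypoints(fibers: FiberGroup, tract: TractDefinition) -> FiberGroup:
    """Retain streamlines with >=1 point in both waypoint ROIs (order-agnostic).

    An optional NOT-ROI excludes any fiber touching it. Zero survivors yields
    an empty group with a warning, not an error — a patient may lack a
    trackable tract.
    """
    kept = []
    for s in fibers.streamlines:
        if not tract.roi_start.contains_points(s.points).any():
            continue
        if not tract.roi_end.contains_points(s.points).any():
            continue
        if tract.roi_not is not None and tract.roi_not.contains_points(s.points).any():
            continue
        kept.append(s)
    if not kept:
        warnings.warn(f"no fibers pass both waypoint ROIs for tract {tract.name!r}", stacklevel=2)
    return FiberGroup(
        name=tract.name,
        streamlines=kept,
        provenance={**fibers.provenance, "stage": "segmentation", "n_candidates": len(fibers)},
    )


def fiber_probability_score(s: Streamline, pmap: ProbabilityMap) -> float:
    """Mean probability over the unique voxels the fiber visits."""
    vox = np.rint(mm_to_voxel(pmap.affine, s.points)).astype(int)
    shp = np.asarray(pmap.values.shape)
    vox = np.clip(vox, 0, shp - 1)
    uniq = np.unique(vox, axis=0)
    return float(pmap.values[uniq[:, 0], uniq[:, 1], uniq[:, 2]].mean())


def score_against_probability_map(
    fibers: FiberGroup,
    pmap: ProbabilityMap,
    threshold: float = 0.3,
) -> tuple[FiberGroup, np.ndarray]:
    """Score fibers against a tract probability map; discard low scorers.

    Returns the surviving group and the scores of *all* input fibers (in
    input order) so callers can audit the cut.
    """
    scores = np.array([fiber_probability_score(s, pmap) for s in fibers.streamlines])
    kept = [s for s, sc in zip(fibers.streamlines, scores) if sc >= threshold]
    group = FiberGroup(
        name=fibers.name,
        streamlines=kept,
        provenance={
            **fibers.provenance,
            "stage": "probability_refinement",
            "score_threshold": threshold,
            "n_discarded": len(fibers) - len(kept),
        },
    )
    return group, scores
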
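"""Deterministic streamline tractography (STT).

Streamlines are integrated through the principal-eigenvector field of the
diffusion tensor with a fourth-order Runge-Kutta scheme at a fixed step
(default 1 mm). Tracking runs in both directions from each seed and halts
when the interpolated FA drops below a threshold (default 0.2), when the
angle between the last path segment and the next step direction exceeds a
threshold (default 30 degrees), when the path leaves the volume, or at a
length cap. Seeds are placed at the centers of voxels whose FA exceeds the
seed threshold (default 0.3, strict inequality).

Eigenvectors are axial (sign-ambiguous); at every RK4 stage the local
principal direction is flipped to have nonnegative dot product with the
incoming direction. The first step from a seed uses the raw eigenvector and
its negation for the two tracking directions.

All streamlines advance in lockstep so the tensor interpolation and the
3x3 eigendecompositions run batched across the active front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import (
    ScalarMap,
    TensorField,
    _inside,
    _trilinear,
    voxel_to_mm,
)


@dataclass
class TrackingParams:
    step_mm: float = 1.0
    fa_stop: float = 0.2
    angle_stop_deg: float = 30.0
    seed_fa: float = 0.3
    max_length_mm: float = 250.0
    min_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not (0 <= self.fa_stop < self.seed_fa <= 1):
            raise ValueError("require 0 <= fa_stop < seed_fa <= 1")
        if not (0 < self.angle_stop_deg < 90):
            raise ValueError("angle_stop_deg must be in (0, 90)")


@dataclass(eq=False)
class Streamline:
    """Ordered polyline in scanner mm space with tracking provenance."""

    points: np.ndarray  # (N, 3)
    seed_index: int = -1
    termination: tuple[str, str] = ("", "")  # (backward end, forward end)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise ValueError("streamline needs at least 1 point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(eq=False)
class FiberGroup:
    """Named collection of streamlines with stage provenance."""

    name: str
    streamlines: list[Streamline]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def coords(self) -> np.ndarray:
        """Stack of (n_fibers, n_points, 3); requires equal point counts."""
        return np.stack([s.points for s in self.streamlines])


def make_seed_mask(fa: ScalarMap, seed_fa: float = 0.3) -> np.ndarray:
    """Boolean white-matter seed mask: FA strictly greater than seed_fa."""
    mask = fa.values > seed_fa
    if not mask.any():
        raise ValueError(
            f"seed mask empty at FA > {seed_fa}; review the threshold or the FA map"
        )
    return mask


class _BatchTracker:
    """Lockstep RK4 integrator over the principal-direction field."""

    def __init__(self, fld: TensorField, fa: ScalarMap, params: TrackingParams):
        self.tensors = fld.tensors
        self.t_shape = fld.shape
        self.t_inv = np.linalg.inv(fld.affine)
        self.fa_values = fa.values
        self.fa_inv = np.linalg.inv(fa.affine)
        self.params = params

    def _vox(self, pts: np.ndarray, inv: np.ndarray) -> np.ndarray:
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def principal(self, pts: np.ndarray, ref: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        """Batched sign-consistent principal directions; also returns inside mask.

        Entries outside the field carry unit dummy directions (flagged False).
        """
        vox = self._vox(pts, self.t_inv)
        inside = _inside(vox, self.t_shape)
        D = _trilinear(self.tensors, np.clip(vox, 0, np.asarray(self.t_shape) - 1.0))
        _, v = np.linalg.eigh(D)
        d = v[:, :, 2].copy()
        if ref is not None:
            flip = np.einsum("ij,ij->i", d, ref) < 0
            d[flip] = -d[flip]
        return d, inside

    def fa_at(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vox = self._vox(pts, self.fa_inv)
        inside = _inside(vox, self.fa_values.shape)
        vals = _trilinear(self.fa_values, np.clip(vox, 0, np.asarray(self.fa_values.shape) - 1.0))
        return vals, inside

    def track_half(
        self, seeds: np.ndarray, dirs0: np.ndarray
    ) -> tuple[list[list[np.ndarray]], list[str]]:
        """Integrate each seed along its initial direction until termination.

        Returns per-seed point lists (seed excluded) and termination reasons.
        The point that would violate a criterion is never emitted.
        """
        p = self.params
        h = p.step_mm
        cos_stop = np.cos(np.deg2rad(p.angle_stop_deg))
        max_steps = int(np.ceil(p.max_length_mm / h))
        n = len(seeds)
        pts: list[list[np.ndarray]] = [[] for _ in range(n)]
        reasons = ["max_length"] * n
        pos = np.asarray(seeds, dtype=float).copy()
        prev = np.asarray(dirs0, dtype=float).copy()
        prev /= np.linalg.norm(prev, axis=1, keepdims=True)
        active = np.ones(n, dtype=bool)

        for _ in range(max_steps):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            pp, pr = pos[idx], prev[idx]
            oob = np.zeros(idx.size, dtype=bool)
            k1, ok = self.principal(pp, pr)
            oob |= ~ok
            k2, ok = self.principal(pp + 0.5 * h * k1, k1)
            oob |= ~ok
            k3, ok = self.principal(pp + 0.5 * h * k2, k2)
            oob |= ~ok
            k4, ok = self.principal(pp + h * k3, k3)
            oob |= ~ok
            step = (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            nrm = np.linalg.norm(step, axis=1)
            degen = nrm < 1e-12
            step = step / np.where(degen, 1.0, nrm)[:, None]
            bend = np.einsum("ij,ij->i", step, pr) < cos_stop
            new = pp + h * step
            fa_new, fa_in = self.fa_at(new)
            low_fa = fa_new < p.fa_stop

            stop_oob = oob | ~fa_in
            stop = stop_oob | degen | bend | low_fa
            for j in np.flatnonzero(stop):
                g = idx[j]
                if stop_oob[j]:
                    reasons[g] = "out_of_bounds"
                elif degen[j]:
                    reasons[g] = "degenerate_direction"
                elif bend[j]:
                    reasons[g] = "angle_stop"
                else:
                    reasons[g] = "fa_stop"
                active[g] = False
            go = ~stop
            for j in np.flatnonzero(go):
                pts[idx[j]].append(new[j])
            pos[idx[go]] = new[go]
            prev[idx[go]] = step[go]
        return pts, reasons


def track_from_seed(
    fld: TensorField,
    fa: ScalarMap,
    seed_mm: np.ndarray,
    params: TrackingParams | None = None,
    seed_index: int = -1,
) -> Streamline:
    """Bidirectional RK4 streamline through a seed point.

    The two half-tracks follow the raw principal eigenvector at the seed and
    its negation; the returned polyline runs backward-end -> seed -> forward-end.
    """
    params = params or TrackingParams()
    seed_mm = np.asarray(seed_mm, dtype=float).reshape(1, 3)
    tracker = _BatchTracker(fld, fa, params)
    d0, inside = tracker.principal(seed_mm, None)
    if not inside[0]:
        raise ValueError("seed point outside tensor field")
    halves, reasons = tracker.track_half(
        np.vstack([seed_mm, seed_mm]), np.vstack([d0, -d0])
    )
    fwd, bwd = halves
    pts = bwd[::-1] + [seed_mm[0]] + fwd
    return Streamline(
        points=np.asarray(pts), seed_index=seed_index, termination=(reasons[1], reasons[0])
    )


def whole_brain_tractography(
    fld: TensorField,
    fa: ScalarMap,
    params: TrackingParams | None = None,
    seeds_per_voxel: int = 1,
    seed: int | None = 0,
) -> FiberGroup:
    """Track from every voxel of the FA > seed_fa mask.

    One seed per voxel at the voxel center by default; with seeds_per_voxel > 1
    additional seeds are uniformly jittered within the voxel using the given
    rng seed (deterministic). Jittered seeds that land outside the field are
    skipped. Streamlines shorter than min_length_mm are dropped.
    """
    params = params or TrackingParams()
    mask = make_seed_mask(fa, params.seed_fa)
    idx = np.argwhere(mask).astype(float)
    seeds = voxel_to_mm(fld.affine, idx)
    if seeds_per_voxel > 1:
        rng = np.random.default_rng(seed)
        jit = rng.uniform(-0.5, 0.5, size=(len(idx), seeds_per_voxel - 1, 3))
        extra = voxel_to_mm(fld.affine, (idx[:, None, :] + jit).reshape(-1, 3))
        seeds = np.vstack([seeds, extra])

    tracker = _BatchTracker(fld, fa, params)
    d0, inside = tracker.principal(seeds, None)
    seeds, d0 = seeds[inside], d0[inside]
    seed_ids = np.flatnonzero(inside)
    fwd_pts, fwd_reasons = tracker.track_half(seeds, d0)
    bwd_pts, bwd_reasons = tracker.track_half(seeds, -d0)

    out: list[Streamline] = []
    for i in range(len(seeds)):
        pts = bwd_pts[i][::-1] + [seeds[i]] + fwd_pts[i]
        if len(pts) < 2:
            continue
        sl = Streamline(
            points=np.asarray(pts),
            seed_index=int(seed_ids[i]),
            termination=(bwd_reasons[i], fwd_reasons[i]),
        )
        if sl.length_mm >= params.min_length_mm:
            out.append(sl)
    return FiberGroup(
        name="wholebrain",
        streamlines=out,
        provenance={
            "stage": "tractography",
            "n_seeds": int(len(seeds)),
            "params": vars(params).copy(),
            "rng_seed": seed,
        },
    )
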
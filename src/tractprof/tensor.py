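"""Diffusion tensor model: gradient tables, tensor fitting, scalar maps, interpolation.

The single-tensor model relates the diffusion-weighted signal S measured with
b-value b and unit gradient direction g to the non-weighted signal S0 through

    S = S0 * exp(-b * g' D g)

where D is the per-voxel symmetric 3x3 diffusion tensor (mm^2/s). Fitting is
linearized least squares on log-signals; an optional robust mode iteratively
sigma-clips log-residual outliers before refitting.

Scalar maps derived from the sorted eigenvalues l1 >= l2 >= l3:

    FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2)
    MD = (l1 + l2 + l3) / 3     RD = (l2 + l3) / 2     AD = l1
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

SCALAR_METRICS = ("FA", "MD", "RD", "AD")


@dataclass(eq=False)
class GradientTable:
    """Diffusion gradient scheme: one direction and b-value per DWI volume.

    Parameters
    ----------
    directions : (N, 3) array
        Unit gradient directions; rows with b=0 may be zero vectors.
    bvalues : (N,) array
        b-values in s/mm^2; 0 marks non-diffusion-weighted volumes.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        if self.directions.shape != (self.bvalues.size, 3):
            raise ValueError(
                f"directions shape {self.directions.shape} does not match "
                f"{self.bvalues.size} b-values"
            )
        dwi = self.bvalues > 0
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("b>0 gradient directions must be unit vectors (tol 1e-6)")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvalues > 0

    def validate_for_fit(self) -> None:
        """Require >=1 b=0 volume and >=6 distinct b>0 directions."""
        if not self.b0_mask.any():
            raise ValueError("gradient table has no b=0 volume")
        dirs = self.directions[self.dwi_mask]
        # Directions are axial (g and -g equivalent); count distinct axes.
        uniq: list[np.ndarray] = []
        for d in dirs:
            if not any(np.allclose(d, u, atol=1e-8) or np.allclose(d, -u, atol=1e-8) for u in uniq):
                uniq.append(d)
        if len(uniq) < 6:
            raise ValueError(f"need >=6 distinct b>0 directions, got {len(uniq)}")

    def design_matrix(self) -> np.ndarray:
        """Rows -b*[gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz] for the b>0 volumes.

        With tensor element vector d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) the
        model reads log(S/S0) = X d.
        """
        g = self.directions[self.dwi_mask]
        b = self.bvalues[self.dwi_mask]
        X = np.column_stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ]
        )
        return -b[:, None] * X


@dataclass(eq=False)
class DiffusionVolume:
    """4-D diffusion-weighted signal with voxel->mm affine and gradient table."""

    signal: np.ndarray
    affine: np.ndarray
    gradients: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        if self.signal.shape[3] != self.gradients.bvalues.size:
            raise ValueError("4th dimension must match number of gradient rows")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    def s0(self) -> np.ndarray:
        """Mean of the b=0 volumes."""
        return self.signal[..., self.gradients.b0_mask].mean(axis=-1)


@dataclass(eq=False)
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors with affine and validity mask."""

    tensors: np.ndarray  # (X, Y, Z, 3, 3), mm^2/s
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have trailing shape (3, 3)")
        if self.mask.shape != self.tensors.shape[:3]:
            raise ValueError("mask shape must match tensor grid")
        asym = np.abs(self.tensors - np.swapaxes(self.tensors, -1, -2))
        if asym[self.mask].size and asym[self.mask].max() > 1e-12:
            raise ValueError("tensors must be symmetric to 1e-12")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]


@dataclass(eq=False)
class ScalarMap:
    """3-D scalar diffusion metric (FA/MD/RD/AD or other) with affine."""

    values: np.ndarray
    metric: str
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("scalar map must be 3-D")


# -- coordinate helpers -------------------------------------------------------

def mm_to_voxel(affine: np.ndarray, points_mm: np.ndarray) -> np.ndarray:
    """Map mm-space points to continuous 0-based voxel indices.

    Integer indices are voxel centers (NIfTI convention: index i maps to
    affine @ [i, 1]).
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    inv = np.linalg.inv(affine)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_mm(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    idx = np.atleast_2d(np.asarray(idx, dtype=float))
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _inside(vox: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """True where a continuous voxel coordinate lies within the grid support."""
    shp = np.asarray(shape, dtype=float)
    return np.all((vox >= 0) & (vox <= shp - 1), axis=-1)


# -- fitting ------------------------------------------------------------------

def _tensor_from_elements(d: np.ndarray) -> np.ndarray:
    """(..., 6) element vectors (Dxx,Dyy,Dzz,Dxy,Dxz,Dyz) -> (..., 3, 3)."""
    out = np.empty(d.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d[..., 0]
    out[..., 1, 1] = d[..., 1]
    out[..., 2, 2] = d[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
    return out


def tensor_elements(D: np.ndarray) -> np.ndarray:
    """(..., 3, 3) tensors -> (..., 6) unique elements (Dxx,Dyy,Dzz,Dxy,Dxz,Dyz)."""
    D = np.asarray(D)
    return np.stack(
        [D[..., 0, 0], D[..., 1, 1], D[..., 2, 2], D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]],
        axis=-1,
    )


def _robust_fit_voxel(X: np.ndarray, y: np.ndarray, max_iter: int = 5) -> np.ndarray:
    """Sigma-clipping least squares: reject |r| > 3*sigma_MAD, refit."""
    keep = np.ones(y.size, dtype=bool)
    d = np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(max_iter):
        r = y - X @ d
        sigma = 1.4826 * np.median(np.abs(r[keep] - np.median(r[keep])))
        if sigma <= 0:
            break
        new_keep = np.abs(r) <= 3.0 * sigma
        if new_keep.sum() < 6 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        d = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
    return d


def fit_tensor_volume(
    dwi: DiffusionVolume,
    robust: bool = False,
    mask: np.ndarray | None = None,
) -> TensorField:
    """Fit a diffusion tensor per voxel by (optionally robust) log-linear least squares.

    Voxels with any nonpositive signal are excluded from the mask with a warning.
    Robust mode iteratively rejects log-residual outliers (|r| > 3 sigma from the
    median absolute deviation) and refits, at most 5 iterations.
    """
    gtab = dwi.gradients
    gtab.validate_for_fit()
    S0 = dwi.s0()

    positive = np.all(dwi.signal > 0, axis=-1) & (S0 > 0)
    if mask is None:
        mask = positive
    else:
        mask = np.asarray(mask, dtype=bool) & positive
    n_bad = int((~positive).sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxels with nonpositive signal masked out", stacklevel=2)
    if not mask.any():
        raise ValueError("no fittable voxels (all signals nonpositive or masked)")

    X = gtab.design_matrix()
    sig = dwi.signal[mask][:, gtab.dwi_mask]
    y = np.log(sig / S0[mask][:, None])  # (n_vox, n_dwi)

    # One shared design matrix: solve all voxels at once via the pseudoinverse.
    pinv = np.linalg.pinv(X)
    d = y @ pinv.T  # (n_vox, 6)

    if robust:
        resid = y - d @ X.T
        med = np.median(resid, axis=1, keepdims=True)
        sigma = 1.4826 * np.median(np.abs(resid - med), axis=1)
        flagged = np.abs(resid).max(axis=1) > 3.0 * np.maximum(sigma, 1e-300)
        for i in np.flatnonzero(flagged):
            d[i] = _robust_fit_voxel(X, y[i])

    tensors = np.zeros(mask.shape + (3, 3), dtype=float)
    tensors[mask] = _tensor_from_elements(d)
    return TensorField(tensors=tensors, affine=dwi.affine, mask=mask)


# -- scalar maps --------------------------------------------------------------

def eigenvalues_descending(tensors: np.ndarray) -> np.ndarray:
    """Sorted (descending) eigenvalues of symmetric tensors, shape (..., 3)."""
    ev = np.linalg.eigvalsh(np.asarray(tensors, dtype=float))
    return ev[..., ::-1]


def fa_from_eigenvalues(ev: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||l - lbar|| / ||l||; 0 where the tensor is zero."""
    ev = np.asarray(ev, dtype=float)
    lbar = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(((ev - lbar) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def scalar_from_eigenvalues(ev: np.ndarray, metric: str) -> np.ndarray:
    if metric == "FA":
        return fa_from_eigenvalues(ev)
    if metric == "MD":
        return ev.mean(axis=-1)
    if metric == "RD":
        return (ev[..., 1] + ev[..., 2]) / 2.0
    if metric == "AD":
        return ev[..., 0]
    raise ValueError(f"unknown metric {metric!r}; expected one of {SCALAR_METRICS}")


def scalar_map(fld: TensorField, metric: str) -> ScalarMap:
    """Derive an FA/MD/RD/AD map from a tensor field (zero outside the mask).

    Negative eigenvalues are kept, not clamped; their count is logged.
    """
    ev = eigenvalues_descending(fld.tensors[fld.mask])
    n_neg = int((ev[..., 2] < 0).sum())
    if n_neg:
        log.info("scalar_map(%s): %d voxels with negative eigenvalues", metric, n_neg)
    vals = np.zeros(fld.shape, dtype=float)
    vals[fld.mask] = scalar_from_eigenvalues(ev, metric)
    return ScalarMap(values=vals, metric=metric, affine=fld.affine)


# -- interpolation ------------------------------------------------------------

def _trilinear(values: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``values`` (X,Y,Z,...) at continuous voxel coords."""
    shp = np.asarray(values.shape[:3])
    i0 = np.clip(np.floor(vox).astype(int), 0, shp - 2)
    f = vox - i0
    out = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                v = values[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                out = out + w.reshape((-1,) + (1,) * (v.ndim - 1)) * v
    return out


def interpolate_tensor(fld: TensorField, points_mm: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate tensors at mm-space points.

    Each unique element is interpolated independently; the result is symmetric
    by construction. Points outside the grid support raise ValueError — the
    tracker checks bounds itself and treats out-of-field as termination.
    """
    pts = np.atleast_2d(points_mm)
    vox = mm_to_voxel(fld.affine, pts)
    if not _inside(vox, fld.shape).all():
        raise ValueError("point outside tensor field bounds")
    out = _trilinear(fld.tensors, vox)
    if np.asarray(points_mm).ndim == 1:
        return out[0]
    return out


def interpolate_scalar(
    smap: ScalarMap, points_mm: np.ndarray, order: int = 3
) -> np.ndarray:
    """Sample a scalar map at mm points with spline interpolation.

    Default cubic (order 3): a tensor-product B-spline with not-a-knot
    boundary conditions along each axis, which interpolates the grid values
    exactly and reproduces polynomial (e.g. linear) fields up to the grid
    edge. An axis shorter than ``order + 1`` voxels degrades gracefully to
    linear along that axis. Points outside the support return NaN.
    """
    from scipy.interpolate import NdBSpline, make_interp_spline

    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    vox = mm_to_voxel(smap.affine, pts)
    if order < 1:
        raise ValueError("spline order must be >= 1")
    c = smap.values
    knots: list[np.ndarray] = []
    degrees: list[int] = []
    for ax, n in enumerate(smap.values.shape):
        k = order if n > order else 1
        spl = make_interp_spline(np.arange(n, dtype=float), np.moveaxis(c, ax, 0), k=k)
        knots.append(spl.t)
        degrees.append(k)
        c = np.moveaxis(spl.c, 0, ax)
    out = NdBSpline(tuple(knots), c, k=tuple(degrees))(vox, extrapolate=False)
    if np.asarray(points_mm).ndim == 1:
        return float(out[0])
    return out


def principal_direction(tensor: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue (sign arbitrary)."""
    w, v = np.linalg.eigh(tensor)
    return v[:, -1]
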
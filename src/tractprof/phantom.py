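"""Synthetic phantoms: tensor fields, DWI signals, and profile cohorts.

Three generators cover the pipeline's test surface without any scan data:

* ``build_tensor_field`` lays axially symmetric tensors along parametric
  bundle centerlines (straight, arc, crossing). Inside a bundle the tensor's
  principal axis is the local centerline tangent and the eigenvalues are
  chosen so FA matches a planted along-tract profile at a prescribed mean
  diffusivity. Where two bundles overlap, tensors are averaged and the trace
  renormalized to the target MD — a deliberate simplification of multi-fiber
  physics that reproduces the FA-lowering effect of crossing tracts.
* ``synthesize_dwi`` forward-simulates Stejskal-Tanner signals
  S = S0 exp(-b g'Dg) with optional Rician noise (magnitude of the complex
  signal with independent Gaussian noise on both channels).
* ``simulate_profile_cohort`` draws subject profiles from a multivariate
  normal over nodes, with optional per-node group effects and a behavioral
  score generated from the profile at a designated node.

For a cylindrically symmetric tensor with eigenvalues m(1+2d), m(1-d),
m(1-d) (mean diffusivity m), FA = d*sqrt(3/(1+2d^2)), so d =
FA/sqrt(3-2FA^2); d <= 1 keeps all eigenvalues nonnegative, which bounds
the feasible FA strictly below 1 for finite anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .tensor import GradientTable, DiffusionVolume, ScalarMap, TensorField
from .tracking import FiberGroup, Streamline

Centerline = Callable[[np.ndarray], np.ndarray]  # t in [0,1] -> (len(t), 3) mm


@dataclass(eq=False)
class BundleSpec:
    """A tube of coherent tensors around a parametric centerline."""

    centerline: Centerline
    radius: float  # mm
    fa_profile: Callable[[np.ndarray], np.ndarray] | float = 0.8
    md: float = 0.7e-3  # mm^2/s, typical white matter
    n_samples: int = 400  # centerline discretization for distance queries

    def fa_at(self, t: np.ndarray) -> np.ndarray:
        if callable(self.fa_profile):
            return np.asarray(self.fa_profile(np.asarray(t)), dtype=float)
        return np.full(np.asarray(t).shape, float(self.fa_profile))


@dataclass(eq=False)
class CohortSpec:
    """Generative description of a cohort of 100-node profiles."""

    n_subjects: int
    mean_profile: np.ndarray
    node_covariance: np.ndarray
    group_effect: np.ndarray | None = None  # added to the second half of subjects
    behavior_slope: float = 0.0
    behavior_noise_sd: float = 1.0
    behavior_node: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.mean_profile = np.asarray(self.mean_profile, dtype=float)
        self.node_covariance = np.asarray(self.node_covariance, dtype=float)
        k = self.mean_profile.size
        if self.node_covariance.shape != (k, k):
            raise ValueError("node_covariance must be (n_nodes, n_nodes)")
        ev = np.linalg.eigvalsh(self.node_covariance)
        if ev.min() < -1e-8 * max(ev.max(), 1.0):
            raise ValueError("node_covariance is not positive semidefinite")
        if self.group_effect is not None:
            self.group_effect = np.asarray(self.group_effect, dtype=float)
            if self.group_effect.size != k:
                raise ValueError("group_effect length mismatch")


def straight_centerline(p0: Sequence[float], p1: Sequence[float]) -> Centerline:
    p0a, p1a = np.asarray(p0, float), np.asarray(p1, float)

    def f(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        return p0a[None] + t[:, None] * (p1a - p0a)[None]

    return f


def arc_centerline(
    center: Sequence[float], radius: float, angle0: float, angle1: float, z: float = 0.0
) -> Centerline:
    """Circular arc in a z-plane, angles in radians."""
    c = np.asarray(center, float)

    def f(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        a = angle0 + t * (angle1 - angle0)
        return np.column_stack(
            [c[0] + radius * np.cos(a), c[1] + radius * np.sin(a), np.full(t.shape, c[2] + z)]
        )

    return f


def anisotropic_eigenvalues(fa: np.ndarray, md: float) -> np.ndarray:
    """Cylindrically symmetric eigenvalues (l1, l2, l2) hitting (fa, md).

    Raises for infeasible pairs (fa outside [0, 1) or nonpositive md).
    """
    fa = np.asarray(fa, dtype=float)
    if md <= 0:
        raise ValueError("mean diffusivity must be positive")
    if np.any(fa < 0) or np.any(fa >= 1):
        raise ValueError("feasible FA range for this construction is [0, 1)")
    d = fa / np.sqrt(3.0 - 2.0 * fa**2)
    l1 = md * (1 + 2 * d)
    l23 = md * (1 - d)
    return np.stack([l1, l23, l23], axis=-1)


def tensor_along_axis(axis: np.ndarray, fa: np.ndarray, md: float) -> np.ndarray:
    """Axially symmetric tensors: D = (l1-l2) a a' + l2 I for unit axes a."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    ev = anisotropic_eigenvalues(fa, md)
    l1, l2 = ev[..., 0], ev[..., 1]
    outer = axis[..., :, None] * axis[..., None, :]
    return (l1 - l2)[..., None, None] * outer + l2[..., None, None] * np.eye(3)


def build_tensor_field(
    bundles: Sequence[BundleSpec],
    shape: tuple[int, int, int],
    voxel_size: float = 2.0,
    background_fa: float = 0.15,
    background_md: float = 0.7e-3,
) -> tuple[TensorField, ScalarMap, list[FiberGroup]]:
    """Rasterize bundle specs into a tensor field with known geometry.

    Returns the field, its exact FA map, and per-bundle ground-truth
    streamlines (the centerlines sampled at ~1 mm). The background is an
    axially symmetric tensor about +z at ``background_fa`` (isotropic when
    0), low enough by default to sit below seeding and stopping thresholds.
    """
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    centers = idx * voxel_size  # affine has zero origin

    bg = tensor_along_axis(np.array([0.0, 0.0, 1.0]), np.array(background_fa), background_md)
    tensors = np.broadcast_to(bg, shape + (3, 3)).copy()
    fa_map = np.full(shape, float(background_fa))
    count = np.zeros(shape, dtype=int)
    acc = np.zeros(shape + (3, 3))

    gt: list[FiberGroup] = []
    for bi, b in enumerate(bundles):
        ts = np.linspace(0, 1, b.n_samples)
        cl = b.centerline(ts)
        seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        length = seg.sum()
        tree = cKDTree(cl)
        dist, nearest = tree.query(centers)
        inside = dist <= b.radius
        ii = np.flatnonzero(inside)
        if ii.size == 0:
            raise ValueError(f"bundle {bi} does not intersect the grid")
        tn = nearest[ii]
        # tangent by central differences on the sampled centerline
        tang_all = np.gradient(cl, axis=0)
        tang = tang_all[tn]
        frac = np.concatenate([[0.0], np.cumsum(seg)]) / length
        fa_t = b.fa_at(frac[tn])
        D = tensor_along_axis(tang, fa_t, b.md)
        flat_acc = acc.reshape(-1, 3, 3)
        flat_acc[ii] += D
        count.reshape(-1)[ii] += 1
        fa_map.reshape(-1)[ii] = fa_t  # overwritten below where bundles overlap

        n_pts = max(int(np.ceil(length)), 2)
        gt_pts = b.centerline(np.linspace(0, 1, n_pts))
        gt.append(FiberGroup(name=f"bundle{bi}", streamlines=[Streamline(points=gt_pts)]))

    single = count >= 1
    tensors[single] = acc[single] / count[single][..., None, None]
    overlap = count > 1
    if overlap.any():
        # renormalize the averaged tensor's trace back to the target MD
        tr = np.trace(tensors[overlap], axis1=-2, axis2=-1)
        target = 3.0 * np.mean([b.md for b in bundles])
        tensors[overlap] *= (target / tr)[:, None, None]
    # exact FA from the final tensors wherever a bundle lives
    from .tensor import eigenvalues_descending, fa_from_eigenvalues

    fa_map[single] = fa_from_eigenvalues(eigenvalues_descending(tensors[single]))

    fld = TensorField(tensors=tensors, affine=affine, mask=np.ones(shape, dtype=bool))
    return fld, ScalarMap(values=fa_map, metric="FA", affine=affine), gt


def default_gradient_table(n_directions: int = 30, bvalue: float = 900.0, n_b0: int = 1) -> GradientTable:
    """b=0 rows plus ``n_directions`` directions spread by a Fibonacci sphere."""
    i = np.arange(n_directions)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n_directions
    r = np.sqrt(1 - z**2)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bvalue)])
    return GradientTable(directions=directions, bvalues=bvals)


def synthesize_dwi(
    fld: TensorField,
    gradients: GradientTable,
    s0: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> DiffusionVolume:
    """Forward-simulate DWI signals from a tensor field, optionally Rician-noisy.

    Rician noise: the noiseless signal is placed on the real channel and
    independent N(0, noise_sd) noise added to both real and imaginary
    channels before taking the magnitude.
    """
    b = gradients.bvalues
    g = gradients.directions
    quad = np.einsum("ni,...ij,nj->...n", g, fld.tensors, g)  # (X,Y,Z,N)
    S = s0 * np.exp(-b * quad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        re = S + rng.normal(0, noise_sd, S.shape)
        im = rng.normal(0, noise_sd, S.shape)
        S = np.sqrt(re**2 + im**2)
    return DiffusionVolume(signal=S, affine=fld.affine, gradients=gradients)


def smooth_node_covariance(n_nodes: int = 100, sd: float = 0.05, length_scale: float = 10.0) -> np.ndarray:
    """Squared-exponential covariance over nodes: realistic smooth profile noise."""
    k = np.arange(n_nodes)
    corr = np.exp(-0.5 * ((k[:, None] - k[None, :]) / length_scale) ** 2)
    return sd**2 * (corr + 1e-10 * np.eye(n_nodes))


def simulate_profile_cohort(spec: CohortSpec) -> tuple[np.ndarray, dict]:
    """Draw a cohort of profiles (+ group labels and behavior) from a CohortSpec.

    Subjects are multivariate normal around ``mean_profile``; when a
    ``group_effect`` is given the second half of subjects receive it (group
    label 1). Behavior = slope * standardized profile value at
    ``behavior_node`` + N(0, behavior_noise_sd); pure noise when slope is 0.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.mean_profile.size
    X = rng.multivariate_normal(np.zeros(k), spec.node_covariance, size=spec.n_subjects, method="svd")
    X = X + spec.mean_profile
    groups = np.zeros(spec.n_subjects, dtype=int)
    if spec.group_effect is not None:
        half = spec.n_subjects // 2
        groups[half:] = 1
        X[half:] += spec.group_effect
    node_vals = X[:, spec.behavior_node]
    sdv = node_vals.std(ddof=1)
    z = (node_vals - node_vals.mean()) / (sdv if sdv > 0 else 1.0)
    behavior = spec.behavior_slope * z + rng.normal(0, spec.behavior_noise_sd, spec.n_subjects)
    meta = {"group": groups, "behavior": behavior, "seed": spec.seed}
    return X, meta
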
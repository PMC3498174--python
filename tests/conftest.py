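"""Shared fixtures: small analytic tensor fields, bundles and fiber groups."""

from __future__ import annotations

import numpy as np
import pytest

import tractprof as tp
from tractprof.phantom import tensor_along_axis


def uniform_field(
    axis=(1.0, 0.0, 0.0),
    fa: float = 0.8,
    shape=(31, 11, 11),
    voxel: float = 2.0,
    md: float = 0.7e-3,
):
    """Constant tensor field with the given principal axis and FA everywhere."""
    aff = np.diag([voxel, voxel, voxel, 1.0])
    D = tensor_along_axis(np.asarray(axis, float), np.asarray(fa), md)
    fld = tp.TensorField(
        tensors=np.broadcast_to(D, shape + (3, 3)).copy(),
        affine=aff,
        mask=np.ones(shape, bool),
    )
    fa_map = tp.ScalarMap(values=np.full(shape, fa), metric="FA", affine=aff)
    return fld, fa_map


def circle_field(shape=(31, 31, 5), voxel: float = 2.0, fa: float = 0.8, center=None):
    """Tensor field whose principal axis is tangent to circles about a z-axis."""
    aff = np.diag([voxel, voxel, voxel, 1.0])
    if center is None:
        center = np.array([(shape[0] - 1) * voxel / 2, (shape[1] - 1) * voxel / 2, (shape[2] - 1) * voxel / 2])
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    mm = idx * voxel
    rel = mm[:, :2] - center[:2]
    r = np.linalg.norm(rel, axis=1)
    tang = np.column_stack([-rel[:, 1], rel[:, 0], np.zeros(len(rel))])
    tang[r < 1e-9] = [1.0, 0.0, 0.0]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    T = tensor_along_axis(tang, np.full(len(tang), fa), 0.7e-3).reshape(shape + (3, 3))
    fld = tp.TensorField(tensors=T, affine=aff, mask=np.ones(shape, bool))
    fa_map = tp.ScalarMap(values=np.full(shape, fa), metric="FA", affine=aff)
    return fld, fa_map, np.asarray(center)


def straight_fiber(y: float = 0.0, z: float = 0.0, x0: float = 0.0, x1: float = 99.0, n: int = 100):
    x = np.linspace(x0, x1, n)
    return tp.Streamline(points=np.column_stack([x, np.full(n, y), np.full(n, z)]))


def parallel_bundle(n_fibers: int = 20, spread: float = 1.0, seed: int = 0, n_pts: int = 100):
    """Straight fibers along +x with Gaussian lateral offsets."""
    rng = np.random.default_rng(seed)
    offs = rng.normal(0, spread, size=(n_fibers, 2))
    sls = [straight_fiber(y=o[0], z=o[1], n=n_pts) for o in offs]
    return tp.FiberGroup(name="bundle", streamlines=sls)


def plane_roi(shape, affine, axis: int, index: int, name: str = "roi"):
    mask = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = index
    mask[tuple(sl)] = True
    return tp.WaypointROI(mask=mask, affine=affine, name=name)


@pytest.fixture(scope="session")
def dip_phantom():
    """Straight-bundle phantom with a planted Gaussian FA dip (center t=0.5)."""
    dip = lambda t: 0.75 - 0.25 * np.exp(-0.5 * ((t - 0.5) / 0.12) ** 2)
    shape, voxel = (40, 16, 16), 2.0
    bundle = tp.BundleSpec(
        centerline=tp.straight_centerline([4, 15, 15], [74, 15, 15]),
        radius=5.0,
        fa_profile=dip,
    )
    fld, fa_true, gt = tp.build_tensor_field([bundle], shape, voxel)
    return {
        "field": fld,
        "fa_true": fa_true,
        "gt": gt,
        "dip": dip,
        "shape": shape,
        "affine": fld.affine,
        "x_range": (4.0, 74.0),
    }


@pytest.fixture(scope="session")
def dip_tract(dip_phantom):
    """Waypoint ROI planes at x=10 and x=68 mm for the dip phantom."""
    shape, aff = dip_phantom["shape"], dip_phantom["affine"]
    return tp.TractDefinition(
        name="bundle",
        roi_start=plane_roi(shape, aff, 0, 5, "start"),
        roi_end=plane_roi(shape, aff, 0, 34, "end"),
    )
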
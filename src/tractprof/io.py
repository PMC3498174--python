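"""Readers and writers for the standard diffusion-MRI formats.

Volumes are NIfTI-1 via nibabel, with the affine always honored (never
assumed identity). Gradient tables are FSL-style bvals/bvecs text files.
Streamlines are TrackVis TRK or MRtrix TCK via nibabel.streamlines; points
are stored and returned in scanner mm (RAS) space. Profiles round-trip as
CSV (rows = nodes) with an optional JSON provenance sidecar.

Voxel coordinate convention, used everywhere in this package: 0-based
indices, integer index = voxel center, world mm coordinates obtained by
applying the NIfTI affine to the (continuous) index.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from .profiles import TractProfile
from .tensor import GradientTable, DiffusionVolume, ScalarMap, TensorField
from .tracking import FiberGroup, Streamline


# -- volumes ------------------------------------------------------------------

def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    affine = img.affine
    if affine is None:
        raise ValueError(f"{path}: NIfTI affine missing; refusing to assume identity")
    return np.asarray(img.get_fdata()), np.asarray(affine)


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_gradient_table(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """FSL convention: bvals one row, bvecs 3 rows (or transposed) of N columns."""
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.ndim == 1:
        bvecs = bvecs.reshape(1, 3)
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 0
    bvecs[nz] = bvecs[nz] / norms[nz, None]
    return GradientTable(directions=bvecs, bvalues=bvals)


def write_gradient_table(bval_path: str | Path, bvec_path: str | Path, gtab: GradientTable) -> None:
    np.savetxt(str(bval_path), gtab.bvalues[None], fmt="%.6g")
    np.savetxt(str(bvec_path), gtab.directions.T, fmt="%.9f")


def read_dwi(dwi_path: str | Path, bval_path: str | Path, bvec_path: str | Path) -> DiffusionVolume:
    data, affine = read_nifti(dwi_path)
    return DiffusionVolume(signal=data, affine=affine, gradients=read_gradient_table(bval_path, bvec_path))


def write_tensor_field(prefix: str | Path, fld: TensorField) -> None:
    """Lower-triangular tensor volume (..., 6) + mask, NIfTI convention."""
    from .tensor import tensor_elements

    prefix = str(prefix)
    write_nifti(prefix + "_tensor.nii.gz", tensor_elements(fld.tensors), fld.affine)
    write_nifti(prefix + "_mask.nii.gz", fld.mask.astype(np.float32), fld.affine)


def read_tensor_field(prefix: str | Path) -> TensorField:
    from .tensor import _tensor_from_elements

    prefix = str(prefix)
    elems, affine = read_nifti(prefix + "_tensor.nii.gz")
    mask, _ = read_nifti(prefix + "_mask.nii.gz")
    return TensorField(tensors=_tensor_from_elements(elems), affine=affine, mask=mask > 0.5)


def read_scalar_map(path: str | Path, metric: str) -> ScalarMap:
    data, affine = read_nifti(path)
    return ScalarMap(values=data, metric=metric, affine=affine)


# -- streamlines --------------------------------------------------------------

def write_streamlines(path: str | Path, group: FiberGroup, affine: np.ndarray | None = None) -> None:
    """Write TRK or TCK (by extension). Points are mm (RAS); TRK records the
    reference affine in its header."""
    path = Path(path)
    tg = Tractogram([s.points for s in group.streamlines], affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = TrkFile.create_empty_header()
        if affine is not None:
            header["voxel_to_ras"] = np.asarray(affine, dtype=np.float32)
            header["voxel_sizes"] = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0).astype(np.float32)
        TrkFile(tg, header=header).save(str(path))
    elif path.suffix == ".tck":
        TckFile(tg).save(str(path))
    else:
        raise ValueError(f"unrecognized streamline format {path.suffix!r} (use .trk or .tck)")


def read_streamlines(path: str | Path, name: str = "") -> FiberGroup:
    path = Path(path)
    if path.suffix not in (".trk", ".tck"):
        raise ValueError(f"unrecognized streamline format {path.suffix!r} (use .trk or .tck)")
    tf = nib.streamlines.load(str(path))
    sls = [Streamline(points=np.asarray(p, dtype=float)) for p in tf.tractogram.streamlines]
    return FiberGroup(name=name or path.stem, streamlines=sls, provenance={"source": str(path)})


# -- profiles -----------------------------------------------------------------

def write_profile_csv(path: str | Path, profile: TractProfile) -> None:
    df = pd.DataFrame({"node": np.arange(profile.n_nodes), profile.metric: profile.values})
    if profile.node_coords is not None:
        df[["x_mm", "y_mm", "z_mm"]] = profile.node_coords
    df.to_csv(str(path), index=False, float_format="%.10g")


def read_profile_csv(path: str | Path, tract_name: str = "") -> TractProfile:
    df = pd.read_csv(str(path))
    metric_cols = [c for c in df.columns if c not in ("node", "x_mm", "y_mm", "z_mm")]
    if not metric_cols:
        raise ValueError(f"{path}: no metric column found")
    metric = metric_cols[0]
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy() if "x_mm" in df.columns else None
    return TractProfile(
        tract_name=tract_name, metric=metric, values=df[metric].to_numpy(), node_coords=coords
    )


def write_json(path: str | Path, obj: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
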
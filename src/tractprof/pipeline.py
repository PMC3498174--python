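"""End-to-end pipeline: fit -> track -> segment -> clean -> clip -> profile.

Driven by a single flat JSON config with no hidden defaults: the effective
parameters of every stage are echoed into the provenance record written next
to the outputs, so any artifact can be re-produced exactly. An empty tract
(no fiber survives segmentation or cleaning) is recorded as missing and the
pipeline continues with the next tract.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cleaning import CleaningParams, compute_tract_core, orient_fiber_group, remove_outliers
from .io import (
    read_dwi,
    read_nifti,
    write_json,
    write_nifti,
    write_profile_csv,
    write_streamlines,
)
from .profiles import clip_to_rois, tract_profile
from .segmentation import ProbabilityMap, TractDefinition, WaypointROI, score_against_probability_map, segment_by_waypoints
from .tensor import SCALAR_METRICS, fit_tensor_volume, scalar_map
from .tracking import TrackingParams, whole_brain_tractography


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_dict`` for the JSON schema)."""

    dwi: Path
    bval: Path
    bvec: Path
    out_dir: Path
    tracts: list[dict]
    robust_fit: bool = False
    tracking: TrackingParams = field(default_factory=TrackingParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    metrics: tuple[str, ...] = ("FA",)
    seeds_per_voxel: int = 1
    rng_seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict, base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")

        def _p(key: str) -> Path:
            if key not in cfg:
                raise ValueError(f"config missing required key {key!r}")
            p = Path(cfg[key])
            return p if p.is_absolute() else base / p

        for key in ("dwi", "bval", "bvec"):
            if not _p(key).exists():
                raise FileNotFoundError(f"config {key}: {_p(key)} does not exist")
        tracts = cfg.get("tracts", [])
        if not tracts:
            raise ValueError("config must define at least one tract")
        for t in tracts:
            for rk in ("roi_start", "roi_end"):
                rp = Path(t[rk])
                rp = rp if rp.is_absolute() else base / rp
                if not rp.exists():
                    raise FileNotFoundError(f"tract {t.get('name')}: {rk} {rp} does not exist")
                t[rk] = str(rp)
            if t.get("probability_map"):
                pp = Path(t["probability_map"])
                pp = pp if pp.is_absolute() else base / pp
                if not pp.exists():
                    raise FileNotFoundError(f"tract {t.get('name')}: probability_map {pp} does not exist")
                t["probability_map"] = str(pp)
        metrics = tuple(cfg.get("metrics", ["FA"]))
        for m in metrics:
            if m not in SCALAR_METRICS:
                raise ValueError(f"unknown metric {m!r}")
        return cls(
            dwi=_p("dwi"),
            bval=_p("bval"),
            bvec=_p("bvec"),
            out_dir=Path(cfg.get("out_dir", "tractprof_out")),
            tracts=tracts,
            robust_fit=bool(cfg.get("robust_fit", False)),
            tracking=TrackingParams(**cfg.get("tracking", {})),
            cleaning=CleaningParams(**cfg.get("cleaning", {})),
            metrics=metrics,
            seeds_per_voxel=int(cfg.get("seeds_per_voxel", 1)),
            rng_seed=int(cfg.get("rng_seed", 0)),
            raw=cfg,
        )


def _load_tract(t: dict) -> TractDefinition:
    m1, a1 = read_nifti(t["roi_start"])
    m2, a2 = read_nifti(t["roi_end"])
    pmap = None
    if t.get("probability_map"):
        pv, pa = read_nifti(t["probability_map"])
        pmap = ProbabilityMap(values=np.clip(pv, 0, 1), affine=pa)
    return TractDefinition(
        name=t.get("name", "tract"),
        roi_start=WaypointROI(mask=m1 > 0.5, affine=a1, name="start"),
        roi_end=WaypointROI(mask=m2 > 0.5, affine=a2, name="end"),
        probability_map=pmap,
        score_threshold=float(t.get("score_threshold", 0.3)),
    )


def run_pipeline(config: PipelineConfig | dict, base: Path | None = None) -> dict:
    """Execute the full tract-quantification pipeline; returns the provenance record."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config, base=base)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    cfg_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    prov: dict = {
        "software": f"tractprof {__version__}",
        "config_hash": cfg_hash,
        "config": config.raw,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "tracts": {},
    }

    dwi = read_dwi(config.dwi, config.bval, config.bvec)
    fld = fit_tensor_volume(dwi, robust=config.robust_fit)
    maps = {m: scalar_map(fld, m) for m in set(config.metrics) | {"FA"}}
    for m, sm in maps.items():
        write_nifti(out / f"{m.lower()}.nii.gz", sm.values, sm.affine)
    prov["stages"]["fit"] = {"robust": config.robust_fit, "n_masked_voxels": int(fld.mask.sum())}

    wb = whole_brain_tractography(
        fld, maps["FA"], config.tracking, seeds_per_voxel=config.seeds_per_voxel, seed=config.rng_seed
    )
    prov["stages"]["tractography"] = {
        "n_streamlines": len(wb),
        "params": vars(config.tracking).copy(),
        "rng_seed": config.rng_seed,
    }

    for t in config.tracts:
        tract = _load_tract(t)
        rec: dict = {}
        g = segment_by_waypoints(wb, tract)
        rec["n_after_waypoints"] = len(g)
        if tract.probability_map is not None and len(g):
            g, _scores = score_against_probability_map(g, tract.probability_map, tract.score_threshold)
            rec["n_after_probability"] = len(g)
        if len(g) < 3:
            rec["status"] = "missing"
            prov["tracts"][tract.name] = rec
            continue
        g = orient_fiber_group(g, tract)
        g, clean_report = remove_outliers(g, config.cleaning)
        rec["cleaning"] = {
            "n_removed": clean_report["n_input"] - clean_report["n_output"],
            "n_iterations": len(clean_report["iterations"]),
        }
        g = clip_to_rois(g, tract, n_nodes=config.cleaning.n_nodes)
        if len(g) < 2:
            rec["status"] = "missing"
            prov["tracts"][tract.name] = rec
            continue
        core = compute_tract_core(g)
        write_streamlines(out / f"{tract.name}_clean.trk", g, affine=fld.affine)
        for m in config.metrics:
            profile = tract_profile(g, maps[m], core, tract_name=tract.name)
            write_profile_csv(out / f"{tract.name}_{m}_profile.csv", profile)
        rec["status"] = "ok"
        rec["n_fibers"] = len(g)
        prov["tracts"][tract.name] = rec

    prov["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    write_json(out / "provenance.json", prov)
    return prov
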
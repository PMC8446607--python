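"""End-to-end orchestration: center -> crop -> segment -> motion -> strain.

Each run writes a manifest (inputs, config, seed, content hashes of every
output, per-stage timings) sufficient to reproduce the outputs bit-exactly
in single-threaded mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .grids import (
    CineSequence,
    DisplacementField,
    SegMask,
    crop_around_center,
    normalize_intensity,
    paste_back,
    resample_to_workspace,
    write_displacement,
    write_mask,
)
from .nn.backbone import CenteringNet, load_checkpoint
from .strain import (
    cylindrical_project,
    define_cardiac_cs,
    detect_es,
    displacement_gradient,
    green_lagrange,
    polar_map,
    strain_curves_from_fields,
    AHA_SEGMENT_NAMES,
)
from .evaluation import volumetrics
from .training import infer_sequence

logger = logging.getLogger("cinestrain")

__all__ = ["PipelineConfig", "run_pipeline", "segment_only", "setup_logging"]


@dataclasses.dataclass
class PipelineConfig:
    workspace_shape: tuple[int, int, int] = (256, 256, 16)
    inplane_spacing: tuple[float, float] = (1.25, 1.25)
    crop_shape: tuple[int, int, int] | None = None   # default: half in-plane
    es_index: int | None = None       # user override beats mask-derived ES
    seed: int = 0
    resample: bool = True


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_nets(checkpoints: dict, kinds=("center", "segment", "motion")):
    nets = {}
    for kind in kinds:
        if kind not in checkpoints:
            raise ValueError(f"missing checkpoint for {kind!r}")
        ck = checkpoints[kind]
        if isinstance(ck, (str, Path)):
            net, loaded_kind, _ = load_checkpoint(ck)
            if loaded_kind != kind:
                raise ValueError(f"checkpoint {ck} is {loaded_kind}, expected {kind}")
            nets[kind] = net
        else:
            nets[kind] = ck
    return nets


def _center_and_crop(sequence: CineSequence, center: CenteringNet,
                     cfg: PipelineConfig):
    if cfg.resample:
        frames = [resample_to_workspace(f, cfg.workspace_shape, cfg.inplane_spacing)
                  for f in sequence.frames]
    else:
        frames = sequence.frames
    heat = center.forward_volume(normalize_intensity(frames[0].values))
    center = CenteringNet.argmax_center(heat)
    logger.info("crop centre (argmax of heatmap): %s", center)
    cropped, window = zip(*[crop_around_center(f, center[:2],
                                              crop_shape=cfg.crop_shape)
                            for f in frames])
    return list(cropped), window[0], center


def segment_only(sequence: CineSequence, checkpoints: dict,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Centering + segmentation only: per-frame masks in the original
    workspace geometry, plus volumetric parameters."""
    cfg = config or PipelineConfig()
    nets = _load_nets(checkpoints, kinds=("center", "segment"))
    cropped, window, center = _center_and_crop(sequence, nets["center"], cfg)
    masks = [SegMask(c.grid, nets["segment"].segment_volume(
        normalize_intensity(c.values))) for c in cropped]
    if not (masks[0].labels > 0).any():
        raise RuntimeError("no LV found: segmentation of the ED frame is empty")
    es = cfg.es_index if cfg.es_index is not None else detect_es(masks)
    vols = volumetrics(masks[0], masks[es])
    full_masks = [paste_back(m, window) for m in masks]
    result = {"masks": full_masks, "cropped_masks": masks, "es_index": es,
              "volumetrics": vols, "center": center, "window": window}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(full_masks):
            write_mask(out_dir / f"mask_{i:02d}.nii.gz", m)
        (out_dir / "volumetrics.json").write_text(json.dumps(vols, indent=2))
    return result


def run_pipeline(sequence: CineSequence, checkpoints: dict,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Full workflow on a cine sequence; returns the strain report bundle.

    Stages: centering -> crop -> per-frame segmentation -> ES detection ->
    motion estimation for every (ED, frame) pair -> strain curves, scalar
    parameters, polar map, volumetrics.
    """
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    nets = _load_nets(checkpoints)
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cropped, window, center = _center_and_crop(sequence, nets["center"], cfg)
    timings["center_crop"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    masks = [SegMask(c.grid, nets["segment"].segment_volume(
        normalize_intensity(c.values))) for c in cropped]
    if not (masks[0].labels == 2).any():
        raise RuntimeError("no LV found: ED segmentation has no myocardium")
    timings["segment"] = time.perf_counter() - t0

    es = cfg.es_index if cfg.es_index is not None else detect_es(masks)
    logger.info("ES index: %d", es)

    t0 = time.perf_counter()
    crop_seq = CineSequence(cropped, sequence.frame_times, es_index=es)
    raw_fields = infer_sequence(nets["motion"], crop_seq)
    grid = cropped[0].grid
    fields = [DisplacementField(grid, f) for f in raw_fields]
    timings["motion"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    curves = strain_curves_from_fields(fields, masks[0], sequence.frame_times, es)
    vols = volumetrics(masks[0], masks[es])
    cs = define_cardiac_cs(masks[0])
    cyl_es = cylindrical_project(
        green_lagrange(displacement_gradient(fields[es])), cs)
    pmap = {}
    if cs.septal_angle is not None:
        for comp in ("e_rr", "e_cc"):
            pmap[comp] = polar_map(cyl_es, masks[0], cs, component=comp)
    timings["strain"] = time.perf_counter() - t0

    result = {"curves": curves, "volumetrics": vols, "polar_maps": pmap,
              "masks": masks, "fields": fields, "es_index": es,
              "center": center, "window": window, "timings": timings}
    if out_dir is not None:
        _write_bundle(Path(out_dir), result, cfg, sequence)
    return result


def _write_bundle(out_dir: Path, result: dict, cfg: PipelineConfig,
                  sequence: CineSequence) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    curves = result["curves"]
    # curves CSV
    cols = ["time_ms"] + [f"strain_{c}" for c in curves.strain] \
        + [f"rate_{c}" for c in curves.strain_rate]
    rows = np.column_stack([curves.time_ms]
                           + [curves.strain[c] for c in curves.strain]
                           + [curves.strain_rate[c] for c in curves.strain_rate])
    lines = [",".join(cols)] + [",".join(f"{v:.6g}" for v in r) for r in rows]
    (out_dir / "strain_curves.csv").write_text("\n".join(lines) + "\n")
    # scalar parameters + volumetrics
    report = {"volumetrics": result["volumetrics"],
              "es_index": result["es_index"],
              "strain_parameters": curves.params}
    (out_dir / "strain_report.json").write_text(json.dumps(report, indent=2))
    # polar maps
    for comp, pm in result["polar_maps"].items():
        pl = ["segment,name,value_percent,voxels"]
        for i, (v, c) in enumerate(zip(pm.values, pm.voxel_counts), start=1):
            pl.append(f"{i},{AHA_SEGMENT_NAMES[i-1]},{v:.4f},{c}")
        (out_dir / f"polar_map_{comp}.csv").write_text("\n".join(pl) + "\n")
    # masks and fields
    for i, m in enumerate(result["masks"]):
        write_mask(out_dir / f"mask_crop_{i:02d}.nii.gz", m)
    for i, f in enumerate(result["fields"]):
        write_displacement(out_dir / f"motion_{i:02d}.nii.gz", f)
    # manifest
    outputs = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
               if p.name != "manifest.json"}
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "n_frames": len(sequence),
        "timings_s": result["timings"],
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
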
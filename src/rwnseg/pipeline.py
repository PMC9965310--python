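"""End-to-end semi-automated segmentation workflow.

Single deterministic entry point reproducing the interactive tool's
stage order: crop -> resample -> membrane placement -> smoothing ->
histogram threshold -> fill-center/spill-level estimation -> niche fill
-> handle -> mesh -> STL + JSON run report.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import bone_segmentation as boneseg
from . import implant_builder, niche_fill, volume_io
from .cochlear_frame import CochlearFiducials, fit_ccs, read_fiducials
from .errors import InputError
from .implant_builder import HandleSpec
from .niche_fill import FillParameters
from .rwm_membrane import (
    MeanMembraneModel,
    RWMPatch,
    patch_center,
    place_mean_patch,
    read_patch,
)
from .volume_io import RegionOfInterest, VolumeImage

AUTO = "auto"

#: candidate voxels within this distance of the membrane patch center
#: define the automatic fill center (their centroid); kept small so the
#: center sits deep in the niche, next to the membrane
FILL_CENTER_RADIUS_MM = 0.5


@dataclass
class PipelineConfig:
    """All knobs of one segmentation run.

    ``volume`` and ``fiducials`` may be file paths or in-memory objects
    (:class:`VolumeImage` / :class:`CochlearFiducials`).
    """

    volume: object
    fiducials: object
    membrane: object = None          # path, RWMPatch, or None -> mean model
    side: str = "right"
    roi_center: object = AUTO        # AUTO = round-window fiducial
    roi_edge: float = volume_io.DEFAULT_ROI_EDGE_MM
    resample_target: float = volume_io.WORKING_RESOLUTION_MM
    smoothing_voxels: float = 0.5
    bone_threshold: object = AUTO
    fill_center: object = AUTO
    fill_level: object = AUTO
    connectivity: int = 26
    handle: HandleSpec = field(default_factory=HandleSpec)
    mean_membrane: MeanMembraneModel = field(default_factory=MeanMembraneModel)
    histogram_seed: int = 0
    smoothing_iterations: int = implant_builder.DEFAULT_SMOOTHING_ITERATIONS
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "volume" not in raw or "fiducials" not in raw:
            raise InputError(f"{path}: config must name 'volume' and 'fiducials'")
        if "handle" in raw and isinstance(raw["handle"], dict):
            raw["handle"] = HandleSpec(**raw["handle"])
        if "mean_membrane" in raw:
            raw["mean_membrane"] = MeanMembraneModel(np.asarray(raw["mean_membrane"]))
        return cls(**raw)


def _stage(report: list, name: str, **info):
    entry = {"stage": name, **info}
    report.append(entry)
    return entry


def _with_stage(exc: Exception, stage: str) -> Exception:
    exc.add_note(f"pipeline stage: {stage}")
    return exc


def run_semiauto_segmentation(config: PipelineConfig) -> dict:
    """Run the full semi-automated workflow.

    Returns a dict with the working volume, frame, patch, masks, the
    :class:`NicheSegmentation`, the implant model + mesh, and the JSON-
    serializable run report. Fully deterministic for a fixed config.
    """
    report: list = []
    stage = "read_volume"
    try:
        vol = (
            config.volume
            if isinstance(config.volume, VolumeImage)
            else volume_io.read_volume(config.volume)
        )
        _stage(report, stage, shape=list(vol.shape),
               spacing=[float(s) for s in vol.spacing])

        stage = "fit_ccs"
        fids = (
            config.fiducials
            if isinstance(config.fiducials, CochlearFiducials)
            else read_fiducials(config.fiducials)
        )
        frame = fit_ccs(fids, side=config.side)
        _stage(report, stage, side=config.side,
               origin=[float(v) for v in frame.origin])

        stage = "crop_roi"
        center = (
            np.asarray(fids.rw_center)
            if isinstance(config.roi_center, str) and config.roi_center == AUTO
            else np.asarray(config.roi_center, dtype=float)
        )
        cropped = volume_io.crop_roi(vol, RegionOfInterest(center, config.roi_edge))
        _stage(report, stage, center=[float(v) for v in center],
               edge=config.roi_edge, shape=list(cropped.shape))

        stage = "resample"
        vol = volume_io.resample_isotropic(cropped, config.resample_target)
        _stage(report, stage, target=config.resample_target,
               spacing=[float(s) for s in vol.spacing], shape=list(vol.shape))

        stage = "membrane"
        if config.membrane is None:
            patch = place_mean_patch(frame, config.mean_membrane)
            source = "mean_model"
        elif isinstance(config.membrane, RWMPatch):
            patch, source = config.membrane, "user"
        else:
            patch, source = read_patch(config.membrane), str(config.membrane)
        _stage(report, stage, source=source,
               corners=[[float(v) for v in p] for p in patch.corners])

        stage = "smoothing"
        smoothed = boneseg.smooth_intensities(vol, config.smoothing_voxels)
        _stage(report, stage, kernel_width_voxels=config.smoothing_voxels)

        stage = "threshold"
        if isinstance(config.bone_threshold, str) and config.bone_threshold == AUTO:
            # peaks are fitted on the raw cropped ROI: resampling and
            # smoothing both spread interface voxels between the peaks
            model = boneseg.fit_histogram_peaks(cropped, seed=config.histogram_seed)
            threshold = boneseg.estimate_bone_threshold(model)
            _stage(report, stage, source="automatic",
                   value=threshold.value, seed=config.histogram_seed,
                   centers=[float(v) for v in model.centers],
                   widths=[float(v) for v in model.widths],
                   weights=[float(v) for v in model.weights])
        else:
            threshold = boneseg.BoneThreshold(float(config.bone_threshold), source="user")
            _stage(report, stage, source="user", value=threshold.value)

        stage = "bone_mask"
        bone = boneseg.bone_mask(smoothed, threshold)
        _stage(report, stage, bone_voxels=int(np.count_nonzero(bone)))

        stage = "classify_side"
        cochlea = niche_fill.compute_cochlea_mask(vol, patch, frame)
        _stage(report, stage, cochlea_voxels=int(np.count_nonzero(cochlea)))

        stage = "fill_center"
        if isinstance(config.fill_center, str) and config.fill_center == AUTO:
            fill_center = _auto_fill_center(vol, bone, cochlea, patch)
        else:
            fill_center = np.asarray(config.fill_center, dtype=float)
        _stage(report, stage, center=[float(v) for v in fill_center])

        stage = "spill_level"
        if isinstance(config.fill_level, str) and config.fill_level == AUTO:
            level = niche_fill.estimate_spill_level(
                vol, bone, patch, frame, fill_center,
                connectivity=config.connectivity, cochlea=cochlea,
            )
            _stage(report, stage, source="automatic", level_mm=level)
        else:
            level = float(config.fill_level)
            _stage(report, stage, source="user", level_mm=level)

        stage = "fill"
        params = FillParameters(fill_center, level, config.connectivity)
        seg = niche_fill.fill_niche(vol, bone, patch, frame, params, cochlea)
        _stage(report, stage, **seg.rule_counts())

        stage = "handle"
        implant = implant_builder.add_handle(seg, bone, vol, frame, config.handle)
        _stage(report, stage, handle_voxels=int(np.count_nonzero(implant.handle_mask)),
               width=config.handle.width, length=config.handle.length,
               height=config.handle.height, tip_fraction=config.handle.tip_fraction)

        stage = "mesh"
        mesh = implant_builder.mask_to_mesh(
            implant.union_mask, vol, config.smoothing_iterations
        )
        implant.mesh = mesh
        _stage(report, stage, vertices=len(mesh.vertices), faces=len(mesh.faces),
               smoothing_iterations=config.smoothing_iterations,
               enclosed_volume_mm3=mesh.volume())
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise unchanged
        raise _with_stage(exc, stage)

    result = {
        "volume": vol,
        "frame": frame,
        "patch": patch,
        "threshold": threshold,
        "bone_mask": bone,
        "cochlea_mask": cochlea,
        "segmentation": seg,
        "implant": implant,
        "mesh": mesh,
        "report": report,
    }
    if config.out_dir:
        _write_outputs(config, result)
    return result


def _auto_fill_center(vol, bone, cochlea, patch) -> np.ndarray:
    """Centroid of candidate voxels near the membrane patch center."""
    centers = vol.voxel_centers()
    near = (
        np.linalg.norm(centers - patch_center(patch), axis=-1) <= FILL_CENTER_RADIUS_MM
    )
    pool = near & ~bone & ~cochlea
    if not np.any(pool):
        # no candidates near the membrane: fall back to the patch center
        # and let the fill itself report the empty segmentation
        return np.asarray(patch_center(patch), dtype=float)
    return centers[pool].mean(axis=0)


def _write_outputs(config: PipelineConfig, result: dict) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    vol = result["volume"]
    seg = result["segmentation"]
    implant = result["implant"]
    volume_io.write_volume(vol, os.path.join(out, "roi.nrrd"))
    volume_io.write_volume(
        vol.with_data(seg.provenance), os.path.join(out, "provenance.nrrd")
    )
    volume_io.write_volume(
        vol.with_data(seg.mask.astype(np.uint8)), os.path.join(out, "niche.nrrd")
    )
    volume_io.write_volume(
        vol.with_data(implant.union_mask.astype(np.uint8)),
        os.path.join(out, "implant.nrrd"),
    )
    implant_builder.write_stl(result["mesh"], os.path.join(out, "implant.stl"))
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(result["report"], fh, indent=2)
        fh.write("\n")
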
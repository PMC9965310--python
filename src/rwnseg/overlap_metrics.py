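"""Comparison metrics: volume, membrane contact area, Dice/Jaccard and
per-rule attribution of segmentation differences."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import GeometryError, InputError
from .niche_fill import FillParameters, NicheSegmentation, apply_niche_rules
from .rwm_membrane import CCSFrame, RWMPatch
from .volume_io import VolumeImage


@dataclass
class OverlapReport:
    """All comparison quantities for a pair of segmentations."""

    volume_a: float
    volume_b: float
    intersection_volume: float
    dsc: float
    jaccard: float
    rwm_area_a: float | None = None
    rwm_area_b: float | None = None
    rule_removals: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def niche_volume(mask: np.ndarray, vol: VolumeImage) -> float:
    """Segmented volume in mm^3: voxel count times voxel volume."""
    return float(np.count_nonzero(mask)) * vol.voxel_volume


def rwm_area(
    mask: np.ndarray,
    cochlea: np.ndarray,
    vol: VolumeImage,
    count_faces: bool = False,
) -> float:
    """Membrane contact area in mm^2.

    Counts kept voxels with at least one face neighbor on the cochlea
    side, times the mean voxel face area (spacing^2 when isotropic).
    With ``count_faces`` each touching face is counted instead of each
    voxel, as a sensitivity alternative.
    """
    mask = np.asarray(mask, dtype=bool)
    cochlea = np.asarray(cochlea, dtype=bool)
    if mask.shape != cochlea.shape:
        raise GeometryError("mask and cochlea label must share a grid")
    contact_faces = np.zeros(mask.shape, dtype=np.int8)
    for axis in range(3):
        for shift in (-1, 1):
            neighbor = np.roll(cochlea, shift, axis=axis)
            # voxels rolled in from the opposite border are not neighbors
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            neighbor[tuple(edge)] = False
            contact_faces += (mask & neighbor).astype(np.int8)
    sx, sy, sz = vol.spacing
    mean_face_area = (sx * sy + sx * sz + sy * sz) / 3.0
    n = int(contact_faces.sum()) if count_faces else int(np.count_nonzero(contact_faces))
    return n * float(mean_face_area)


def overlap(a: np.ndarray, b: np.ndarray) -> tuple:
    """Dice and Jaccard of two masks on the same grid."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na == 0 and nb == 0:
        raise InputError("overlap of two empty masks is undefined")
    inter = int(np.count_nonzero(a & b))
    dsc = 2.0 * inter / (na + nb)
    jaccard = inter / (na + nb - inter)
    return dsc, jaccard


def percent_smaller(reference: float, other: float) -> float:
    """Percent by which ``other`` is smaller than ``reference``.

    Convention (ref - other) / ref * 100, with the manual segmentation
    as the reference in user comparisons.
    """
    if reference == 0:
        raise InputError("reference quantity is zero")
    return 100.0 * (reference - other) / reference


def rule_attribution(
    manual: np.ndarray,
    semi: NicheSegmentation,
    vol: VolumeImage,
    bone: np.ndarray,
    patch: RWMPatch,
    frame: CCSFrame,
    params: FillParameters | None = None,
    cochlea: np.ndarray | None = None,
) -> dict:
    """Fractions of a manual mask removed by each semi-automated rule.

    Applies rule 1 (inside the cochlea), rule 2 (bone) and rule 3 (above
    the filling level) to the manual mask, alone and combined, and
    reports the removed fraction of each plus the residual volume
    difference against the semi-automated mask.
    """
    manual = np.asarray(manual, dtype=bool)
    if not np.any(manual):
        raise InputError("manual mask is empty")
    params = params or semi.params
    rules = apply_niche_rules(manual, vol, bone, patch, frame, params, cochlea)
    total = rules["input_count"]
    out = {
        name: {
            "removed_fraction": rules[name]["removed"] / total,
            "removed_voxels": rules[name]["removed"],
        }
        for name in ("step1_inside_cochlea", "step2_bone", "step3_above_level", "all_steps")
    }
    surviving = rules["all_steps"]["mask"]
    semi_vol = niche_volume(semi.mask, vol)
    out["residual"] = {
        "surviving_volume_mm3": niche_volume(surviving, vol),
        "semi_volume_mm3": semi_vol,
        "volume_difference_vs_semi": (
            (semi_vol - niche_volume(surviving, vol)) / semi_vol if semi_vol else None
        ),
    }
    return out


def compare_masks(
    a: np.ndarray,
    b: np.ndarray,
    vol: VolumeImage,
    cochlea: np.ndarray | None = None,
    rule_removals: dict | None = None,
) -> OverlapReport:
    """Assemble the full overlap report for two masks on one grid."""
    dsc, jac = overlap(a, b)
    report = OverlapReport(
        volume_a=niche_volume(a, vol),
        volume_b=niche_volume(b, vol),
        intersection_volume=niche_volume(np.asarray(a, bool) & np.asarray(b, bool), vol),
        dsc=dsc,
        jaccard=jac,
        rule_removals=rule_removals,
    )
    if cochlea is not None:
        report.rwm_area_a = rwm_area(a, cochlea, vol)
        report.rwm_area_b = rwm_area(b, cochlea, vol)
    return report
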
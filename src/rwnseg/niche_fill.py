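"""Crater-lake filling of the round-window niche.

The niche is modeled as a crater lake whose bottom is the membrane:
candidate voxels are the non-bone, middle-ear-side voxels within a
"water level" — a Euclidean distance (mm) from a fill center — and the
fill is the connected component of candidates seeded next to the
membrane patch center. Every excluded voxel records which rule removed
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptySegmentationError, GeometryError, ParameterError
from .rwm_membrane import CCSFrame, RWMPatch, cochlea_side_mask, patch_center
from .volume_io import VolumeImage

AUTO = "auto"

#: provenance codes, per voxel of the working ROI
PROV_KEPT = 0
PROV_INSIDE_COCHLEA = 1
PROV_BONE = 2
PROV_ABOVE_LEVEL = 3
PROV_DISCONNECTED = 4

PROVENANCE_LABELS = {
    PROV_KEPT: "kept",
    PROV_INSIDE_COCHLEA: "inside_cochlea",
    PROV_BONE: "bone",
    PROV_ABOVE_LEVEL: "above_level",
    PROV_DISCONNECTED: "disconnected",
}

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class FillParameters:
    """Water-level parameters of the crater-lake fill."""

    fill_center: np.ndarray
    level: float
    connectivity: int = 26

    def __post_init__(self):
        object.__setattr__(self, "fill_center", np.asarray(self.fill_center, dtype=float))
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ParameterError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if not (self.level > 0):
            raise ParameterError(f"fill level must be > 0 mm, got {self.level}")


@dataclass
class NicheSegmentation:
    """Binary implant-body label plus per-voxel exclusion provenance."""

    mask: np.ndarray
    provenance: np.ndarray
    params: FillParameters
    seed_index: tuple = field(default=None)

    def rule_counts(self) -> dict:
        return {
            name: int(np.count_nonzero(self.provenance == code))
            for code, name in PROVENANCE_LABELS.items()
        }


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def compute_cochlea_mask(vol: VolumeImage, patch: RWMPatch, frame: CCSFrame) -> np.ndarray:
    """Boolean grid: True where a voxel center is on the cochlea side."""
    centers = vol.voxel_centers().reshape(-1, 3)
    return cochlea_side_mask(patch, frame, centers).reshape(vol.shape)


def _distances(vol: VolumeImage, center) -> np.ndarray:
    centers = vol.voxel_centers()
    return np.linalg.norm(centers - np.asarray(center, dtype=float), axis=-1)


def fill_niche(
    vol: VolumeImage,
    bone: np.ndarray,
    patch: RWMPatch,
    frame: CCSFrame,
    params: FillParameters,
    cochlea: np.ndarray | None = None,
) -> NicheSegmentation:
    """Fill the niche up to the water level.

    Candidates are voxels that are not bone, on the middle-ear side of
    the membrane, and within ``params.level`` mm of the fill center; the
    result is the connected component (``params.connectivity``) of the
    candidates containing the seed voxel nearest the membrane patch
    center. Raises :class:`EmptySegmentationError` with per-rule counts
    when nothing remains.
    """
    bone = np.asarray(bone, dtype=bool)
    if bone.shape != vol.shape:
        raise GeometryError(f"bone mask shape {bone.shape} != volume shape {vol.shape}")
    if cochlea is None:
        cochlea = compute_cochlea_mask(vol, patch, frame)
    dist = _distances(vol, params.fill_center)
    above = dist > params.level
    candidates = ~bone & ~cochlea & ~above

    counts = {
        "inside_cochlea": int(np.count_nonzero(cochlea)),
        "bone": int(np.count_nonzero(bone & ~cochlea)),
        "above_level": int(np.count_nonzero(above & ~bone & ~cochlea)),
        "candidates": int(np.count_nonzero(candidates)),
    }
    if not counts["candidates"]:
        raise EmptySegmentationError(
            "no candidate voxels below the water level "
            f"(rule counts: {counts})", counts,
        )

    # seed: candidate voxel closest to the membrane patch center
    target = patch_center(patch)
    d_membrane = np.linalg.norm(
        vol.voxel_centers()[candidates] - target, axis=-1
    )
    cand_idx = np.argwhere(candidates)
    seed = tuple(cand_idx[int(np.argmin(d_membrane))])

    labels, _ = ndimage.label(candidates, structure=_structure(params.connectivity))
    kept = labels == labels[seed]

    provenance = np.full(vol.shape, PROV_DISCONNECTED, dtype=np.uint8)
    provenance[above & ~bone & ~cochlea] = PROV_ABOVE_LEVEL
    provenance[bone & ~cochlea] = PROV_BONE
    provenance[cochlea] = PROV_INSIDE_COCHLEA
    provenance[kept] = PROV_KEPT

    # hard safety invariants: the implant may never claim bone or cochlea
    assert not np.any(kept & bone), "kept voxels intersect bone"
    assert not np.any(kept & cochlea), "kept voxels intersect the cochlea side"
    return NicheSegmentation(kept, provenance, params, seed)


def estimate_spill_level(
    vol: VolumeImage,
    bone: np.ndarray,
    patch: RWMPatch,
    frame: CCSFrame,
    center,
    connectivity: int = 26,
    cochlea: np.ndarray | None = None,
) -> float:
    """Largest water level whose fill does not spill out of the ROI.

    Spilling is detected as the fill touching any face of the working
    ROI (the ROI is tight around the niche, so escape from the niche
    reaches its faces). Binary search to a quarter-voxel resolution;
    when even the maximal level stays contained, that level is returned.
    """
    if cochlea is None:
        cochlea = compute_cochlea_mask(vol, patch, frame)
    resolution = 0.25 * float(np.min(vol.spacing))
    l_max = float(np.linalg.norm(np.array(vol.shape) * vol.spacing))
    l_min = 0.5 * float(np.min(vol.spacing))

    boundary = np.zeros(vol.shape, dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = 0
        boundary[tuple(sl)] = True
        sl[axis] = -1
        boundary[tuple(sl)] = True

    def touches(level: float) -> bool:
        try:
            seg = fill_niche(
                vol, bone, patch, frame,
                FillParameters(center, level, connectivity), cochlea,
            )
        except EmptySegmentationError:
            return False
        return bool(np.any(seg.mask & boundary))

    if not touches(l_max):
        return l_max
    if touches(l_min):
        raise GeometryError(
            "even a minimal fill reaches the ROI boundary; "
            "the niche is not contained in the working ROI"
        )
    lo, hi = l_min, l_max  # lo contained, hi spills
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if touches(mid):
            hi = mid
        else:
            lo = mid
    return lo


def apply_niche_rules(
    mask: np.ndarray,
    vol: VolumeImage,
    bone: np.ndarray,
    patch: RWMPatch,
    frame: CCSFrame,
    params: FillParameters,
    cochlea: np.ndarray | None = None,
) -> dict:
    """Apply the three niche exclusion rules to an arbitrary segmentation.

    Returns surviving masks and removed-voxel counts for rule 1 alone
    (inside cochlea), rule 2 alone (bone), rule 3 alone (above the
    filling level), and all rules combined.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise GeometryError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    if cochlea is None:
        cochlea = compute_cochlea_mask(vol, patch, frame)
    above = _distances(vol, params.fill_center) > params.level
    bone = np.asarray(bone, dtype=bool)

    result = {}
    total = int(np.count_nonzero(mask))
    for name, removed in (
        ("step1_inside_cochlea", cochlea),
        ("step2_bone", bone),
        ("step3_above_level", above),
        ("all_steps", cochlea | bone | above),
    ):
        surviving = mask & ~removed
        result[name] = {
            "mask": surviving,
            "removed": total - int(np.count_nonzero(surviving)),
        }
    result["input_count"] = total
    return result
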
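"""Synthetic temporal-bone phantom with known ground truth.

A 5 mm cubic ROI emulating the round-window region: a radio-dense bone
block with a carved niche opening toward middle-ear air, a fluid-filled
duct (scala-tympani surrogate) behind a saddle/planar membrane, plus
optional disconnected air cells and a soft-tissue slab so the intensity
histogram shows the clinical air / soft-tissue / bone structure. All
truth masks are evaluated analytically, so they can be regenerated on
any grid (e.g., after degradation to intraoperative resolution).

Geometry is CCS-aligned: +x points from the cochlea through the
membrane into the middle ear, +z along the modiolar axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .cochlear_frame import CochlearFiducials
from .errors import ParameterError
from .rwm_membrane import RWMPatch
from .volume_io import VolumeImage

NICHE_SHAPES = ("box_pit", "hemispherical", "saddle_floor")
MIDDLE_EAR_MODES = ("pocket", "slit", "none")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic ROI."""

    spacing: float = 0.08
    edge: float = 5.0
    niche_shape: str = "box_pit"
    #: (width-y, width-z, depth) mm; for hemispherical: (diameter, -, depth)
    niche_dims: tuple = (1.3, 1.3, 2.0)
    hv_air: float = -1000.0
    hv_soft: float = 0.0
    hv_fluid: float = 50.0
    hv_bone: float = 1500.0
    noise_sigma: float = 100.0
    seed: int = 0
    #: how the niche opens: an open middle-ear air layer under the +x ROI
    #: face (slit), a sealed air pocket, or flush with the +x ROI face
    middle_ear: str = "slit"
    air_gap: float = 0.2          # middle-ear air thickness (slit mode)
    pocket_width: float = 0.8     # lateral size of the sealed pocket
    pocket_height: float = 0.2
    mouth_clearance: float = 0.3  # pocket + bone lid between mouth and +x face
    saddle_amplitude: float = 0.3  # membrane saddle height (saddle_floor)
    duct_radius: float = 1.0
    duct_length: float = 1.0
    patch_half_extent: float = 1.2
    soft_slab_thickness: float = 0.4
    air_cells: bool = True
    #: bone surface falls away from the niche rim with this slope (slit
    #: mode), so no large plane is axis-aligned — large coherent planes
    #: would alias into spurious histogram peaks at coarse voxel sizes
    terrain_slope: float = 0.25
    rim_radius: float = 1.0
    #: pit walls widen by this much half-width per mm of height; set to 0
    #: for exact axis-aligned voxel counts in oracle phantoms
    wall_taper: float = 0.1

    def __post_init__(self):
        if self.niche_shape not in NICHE_SHAPES:
            raise ParameterError(f"niche_shape must be one of {NICHE_SHAPES}")
        if self.middle_ear not in MIDDLE_EAR_MODES:
            raise ParameterError(f"middle_ear must be one of {MIDDLE_EAR_MODES}")
        if self.spacing <= 0 or self.edge <= 0:
            raise ParameterError("spacing and edge must be positive")
        if not (self.hv_air < self.hv_soft <= self.hv_fluid < self.hv_bone):
            raise ParameterError(
                "intensity centers must satisfy air < soft <= fluid < bone"
            )
        wy, wz, depth = self.niche_dims
        if min(wy, wz, depth) <= 0:
            raise ParameterError("niche dimensions must be positive")
        if max(wy, wz) > self.edge or depth + self.mouth_clearance + self.duct_length \
                + self.soft_slab_thickness > self.edge:
            raise ParameterError("niche dimensions exceed the ROI edge")

    # derived planes -------------------------------------------------------
    @property
    def mouth_x(self) -> float:
        """World x of the niche mouth (top of the crater)."""
        if self.middle_ear == "pocket":
            return self.edge / 2 - self.mouth_clearance
        if self.middle_ear == "slit":
            return self.edge / 2 - self.air_gap
        return self.edge / 2

    @property
    def membrane_x(self) -> float:
        """World x of the membrane plane (saddle midplane)."""
        return self.mouth_x - self.niche_dims[2]


@dataclass
class PhantomGroundTruth:
    """Generated volume, analytic truth masks, fiducials and membrane."""

    volume: VolumeImage
    bone_truth: np.ndarray
    niche_truth: np.ndarray
    cochlea_truth: np.ndarray
    fiducials: CochlearFiducials
    membrane_truth: RWMPatch
    spec: PhantomSpec
    class_masks: dict = field(default_factory=dict)


def make_grid(spec: PhantomSpec) -> VolumeImage:
    """Empty native-resolution grid centered on the CCS origin."""
    n = int(round(spec.edge / spec.spacing))
    origin = np.full(3, -spec.edge / 2 + spec.spacing / 2)
    return VolumeImage(np.zeros((n, n, n)), np.full(3, spec.spacing), origin)


def membrane_patch(spec: PhantomSpec) -> RWMPatch:
    """Analytic membrane patch: x = membrane_x + amp*(y/sy)*(z/sz)."""
    s = spec.patch_half_extent
    amp = spec.saddle_amplitude if spec.niche_shape == "saddle_floor" else 0.0
    xm = spec.membrane_x
    return RWMPatch(
        p00=(xm + amp, -s, -s),
        p10=(xm - amp, s, -s),
        p01=(xm - amp, -s, s),
        p11=(xm + amp, s, s),
    )


def fiducials_for(spec: PhantomSpec) -> CochlearFiducials:
    """Fiducials consistent with the CCS: z modiolar, x toward the RWM."""
    xm = spec.membrane_x
    return CochlearFiducials(
        apex=np.array([xm - 1.5, 0.0, 1.5]),
        basal=np.array([xm - 1.5, 0.0, -1.0]),
        rw_center=np.array([xm, 0.0, 0.0]),
    )


def _membrane_height(spec: PhantomSpec, y, z):
    """Membrane surface x at lateral position (y, z)."""
    if spec.niche_shape == "saddle_floor":
        s = spec.patch_half_extent
        return spec.membrane_x + spec.saddle_amplitude * (y / s) * (z / s)
    return spec.membrane_x


def truth_masks_on_grid(spec: PhantomSpec, vol: VolumeImage) -> dict:
    """Evaluate all analytic truth masks on an arbitrary grid.

    Returns a dict with ``niche``, ``cochlea``, ``air``, ``soft``,
    ``bone`` boolean grids (pairwise disjoint, union = everything).
    """
    c = vol.voxel_centers()
    x, y, z = c[..., 0], c[..., 1], c[..., 2]
    e2 = spec.edge / 2
    mouth = spec.mouth_x
    xm = spec.membrane_x
    wy, wz, depth = spec.niche_dims
    surface = _membrane_height(spec, y, z)

    if spec.niche_shape == "hemispherical":
        # cylindrical well roofed by a hemispherical dome narrowing to the
        # mouth: an overhanging rounded rim like the bony lip of the niche
        r = wy / 2.0
        dome_cx = mouth - r
        radial2 = y**2 + z**2
        well = (radial2 < r**2) & (x <= dome_cx)
        dome = ((x - dome_cx) ** 2 + radial2 < r**2) & (x > dome_cx)
        niche = (well | dome) & (x > surface) & (x < mouth)
    else:
        grow = spec.wall_taper * np.maximum(0.0, x - xm)
        footprint = (np.abs(y) < wy / 2 + grow) & (np.abs(z) < wz / 2 + grow)
        niche = footprint & (x > surface) & (x < mouth)

    radial = np.sqrt(y**2 + z**2)
    end_x = xm - spec.duct_length
    duct = (x <= surface) & (
        ((radial < spec.duct_radius) & (x >= end_x))
        | ((x - end_x) ** 2 + radial**2 < spec.duct_radius**2)  # rounded end
    )

    middle_air = np.zeros(vol.shape, dtype=bool)
    if spec.middle_ear == "pocket":
        pw = spec.pocket_width / 2
        middle_air = (
            (x >= mouth) & (x < mouth + spec.pocket_height)
            & (np.abs(y) < pw) & (np.abs(z) < pw)
        )
    elif spec.middle_ear == "slit":
        # bone terrain: flat at the rim, falling away laterally
        x_top = mouth - spec.terrain_slope * np.maximum(0.0, radial - spec.rim_radius)
        middle_air = x >= x_top

    cells = np.zeros(vol.shape, dtype=bool)
    if spec.air_cells:
        # spherical mastoid-like air cells, disconnected from the niche
        cell_r = 0.75
        lat = e2 - 0.95
        if lat > cell_r:
            for cy in (-lat, lat):
                for cz in (-lat, lat):
                    for cx in (xm - 0.9, xm + 0.7):
                        cells |= (
                            (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
                            < cell_r**2
                        )

    # soft-tissue slab behind the cochlea, tilted so its faces cannot
    # alias into coherent partial-volume peaks
    tilt = 0.13 * y + 0.07 * z
    soft = (
        (x >= -e2 + 0.2 + tilt)
        & (x < -e2 + 0.2 + spec.soft_slab_thickness + tilt)
        & ~duct
    )

    air = niche | middle_air | cells
    soft = soft & ~air
    fluid = duct & ~air & ~soft
    bone = ~(air | soft | fluid)
    return {
        "niche": niche,
        "cochlea": fluid,
        "air": air,
        "soft": soft,
        "bone": bone,
    }


def generate_phantom(spec: PhantomSpec) -> PhantomGroundTruth:
    """Generate the phantom volume and its ground truth.

    Deterministic: the same spec (including seed) yields bit-identical
    volumes.
    """
    vol = make_grid(spec)
    masks = truth_masks_on_grid(spec, vol)
    intensity = np.full(vol.shape, spec.hv_bone, dtype=np.float64)
    intensity[masks["air"]] = spec.hv_air
    intensity[masks["soft"]] = spec.hv_soft
    intensity[masks["cochlea"]] = spec.hv_fluid
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    return PhantomGroundTruth(
        volume=vol.with_data(intensity),
        bone_truth=masks["bone"],
        niche_truth=masks["niche"],
        cochlea_truth=masks["cochlea"],
        fiducials=fiducials_for(spec),
        membrane_truth=membrane_patch(spec),
        spec=spec,
        class_masks=masks,
    )


def degrade_to_clinical(gt: PhantomGroundTruth, target_spacing: float) -> VolumeImage:
    """Box-filter the native volume down to an intraoperative resolution.

    Emulates a coarser scanner by averaging native voxels into target
    cells; ground truth stays at native resolution (and can be
    re-evaluated on any grid via :func:`truth_masks_on_grid`).
    """
    vol = gt.volume
    if target_spacing < np.max(vol.spacing) - 1e-12:
        raise ParameterError(
            f"target spacing {target_spacing} is below the native spacing {vol.spacing}"
        )
    if np.allclose(vol.spacing, target_spacing):
        return vol

    data = np.asarray(vol.data, dtype=np.float64)
    shape = np.array(vol.shape)
    extent = shape * vol.spacing
    n_out = np.maximum(1, np.round(extent / target_spacing)).astype(int)
    offsets = (extent - n_out * target_spacing) / 2.0

    # separable box filter with fractional edge overlaps (mean-preserving
    # away from the borders, unlike nearest-cell binning)
    for axis in range(3):
        h = vol.spacing[axis]
        in_edges = np.arange(shape[axis] + 1) * h
        out_edges = offsets[axis] + np.arange(n_out[axis] + 1) * target_spacing
        lo = np.maximum(out_edges[:-1, None], in_edges[None, :-1])
        hi = np.minimum(out_edges[1:, None], in_edges[None, 1:])
        weights = np.clip(hi - lo, 0.0, None)
        weights /= weights.sum(axis=1, keepdims=True)
        data = np.moveaxis(
            np.tensordot(weights, np.moveaxis(data, axis, 0), axes=(1, 0)), 0, axis
        )

    lo_edge = vol.origin - vol.orientation @ (vol.spacing / 2.0)
    new_origin = lo_edge + vol.orientation @ (offsets + target_spacing / 2.0)
    return VolumeImage(data, np.full(3, float(target_spacing)), new_origin, vol.orientation)


def make_oversegmentation(
    gt: PhantomGroundTruth,
    dilation_voxels: int,
    seed: int = 0,
    roughness: float = 0.0,
) -> np.ndarray:
    """Emulate a manual over-segmentation of the niche.

    The truth mask dilated by ``dilation_voxels`` (full 3x3x3 element),
    optionally with a seeded random fraction of the next dilation shell
    added as boundary roughness. Always a superset of the truth.
    """
    if dilation_voxels < 0:
        raise ParameterError("dilation_voxels must be >= 0")
    if not (0 <= roughness <= 1):
        raise ParameterError("roughness must be in [0, 1]")
    mask = np.asarray(gt.niche_truth, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    if dilation_voxels > 0:
        mask = ndimage.binary_dilation(mask, structure, iterations=dilation_voxels)
    if roughness > 0:
        shell = ndimage.binary_dilation(mask, structure) & ~mask
        rng = np.random.default_rng(seed)
        mask = mask | (shell & (rng.random(mask.shape) < roughness))
    return mask


def default_spec(shape: str = "box_pit", **overrides) -> PhantomSpec:
    """Convenience constructor with per-shape default niche dimensions."""
    dims = {
        "box_pit": (1.3, 1.3, 2.0),
        "hemispherical": (1.3, 1.3, 2.0),
        "saddle_floor": (1.3, 1.3, 2.0),
    }[shape]
    return replace(PhantomSpec(niche_shape=shape, niche_dims=dims), **overrides)
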
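"""Forceps-handle construction and voxel-mask to STL surface conversion.

The handle is a cuboid standing on the middle-ear-facing surface of the
implant body, its long axis pointing (by default) toward the basal turn
and its distal end tapered to an arrow-like wedge so the surgeon can
read the implant orientation. Voxel masks are converted to watertight
triangle meshes by marching cubes on a 2x nearest-upsampled grid
(preserving small-feature volume) with optional shrink-free Taubin
smoothing, and exported as binary STL.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from skimage import measure

from .cochlear_frame import CCSFrame
from .errors import InputError, ParameterError, PlacementError
from .niche_fill import NicheSegmentation
from .volume_io import VolumeImage

TAUBIN_LAMBDA = 0.5
TAUBIN_MU = -0.53
DEFAULT_SMOOTHING_ITERATIONS = 10

_STL_TRI_DTYPE = np.dtype(
    [("normal", "<f4", 3), ("v0", "<f4", 3), ("v1", "<f4", 3), ("v2", "<f4", 3),
     ("attr", "<u2")]
)


@dataclass(frozen=True)
class HandleSpec:
    """Dimensions and orientation of the forceps handle.

    ``direction`` is a unit vector in CCS coordinates; the default +y
    points toward the basal turn of the cochlea at the round window.
    ``tip_fraction`` of the length is tapered to the pointed wedge.
    """

    width: float = 1.0
    length: float = 1.5
    height: float = 1.0
    tip_fraction: float = 0.25
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self):
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        if min(self.width, self.length, self.height) <= 0:
            raise ParameterError("handle dimensions must all be positive")
        if not (0 < self.tip_fraction < 1):
            raise ParameterError(f"tip_fraction must be in (0, 1), got {self.tip_fraction}")
        if np.linalg.norm(self.direction) < 1e-12:
            raise ParameterError("handle direction must be a non-zero vector")


@dataclass
class TriangleMesh:
    """An indexed triangle surface, vertices in world mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    def edge_counts(self):
        """Undirected edge multiplicities over all faces."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return counts

    def is_closed_manifold(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        counts = self.edge_counts()
        return bool(counts.size and np.all(counts == 2))

    def euler_characteristic(self) -> int:
        n_edges = len(np.unique(np.sort(np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        ), axis=1), axis=0))
        return int(len(self.vertices) - n_edges + len(self.faces))

    def signed_volume(self) -> float:
        """Signed enclosed volume (positive for outward orientation)."""
        v0 = self.vertices[self.faces[:, 0]]
        v1 = self.vertices[self.faces[:, 1]]
        v2 = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)

    def volume(self) -> float:
        return abs(self.signed_volume())


@dataclass
class ImplantModel:
    """Implant body + handle voxel labels and (optionally) their mesh."""

    body_mask: np.ndarray
    handle_mask: np.ndarray
    mesh: TriangleMesh | None = None

    @property
    def union_mask(self) -> np.ndarray:
        return self.body_mask | self.handle_mask


def _handle_frame(frame: CCSFrame, spec: HandleSpec):
    """Orthonormal (up, long, wide) world axes of the handle."""
    up = frame.x_axis
    world_dir = frame.rotation @ (spec.direction / np.linalg.norm(spec.direction))
    long_axis = world_dir - np.dot(world_dir, up) * up
    norm = np.linalg.norm(long_axis)
    if norm < 1e-9:
        raise ParameterError("handle direction is parallel to the CCS x-axis")
    long_axis /= norm
    wide_axis = np.cross(up, long_axis)
    return up, long_axis, wide_axis


def handle_solid_mask(
    vol: VolumeImage, base: np.ndarray, frame: CCSFrame, spec: HandleSpec,
    embed_mm: float,
) -> np.ndarray:
    """Voxelize the handle solid anchored at the world point ``base``.

    The solid spans ``[-embed, height - embed)`` above the base along
    the CCS x-axis (one-voxel embedding guarantees connectivity to the
    body), is centered on the base along its long axis, and the distal
    ``tip_fraction`` of the length tapers symmetrically to an edge
    perpendicular to the base.
    """
    up, long_axis, wide_axis = _handle_frame(frame, spec)
    q = vol.voxel_centers() - np.asarray(base, dtype=float)
    up_c = q @ up
    lg_c = q @ long_axis
    wd_c = q @ wide_axis

    half_l = spec.length / 2.0
    taper_start = half_l - spec.length * spec.tip_fraction
    half_w = np.where(
        lg_c <= taper_start,
        spec.width / 2.0,
        spec.width / 2.0 * np.clip((half_l - lg_c) / (spec.length * spec.tip_fraction), 0, 1),
    )
    eps = 1e-6  # half-open bounds with float-fuzz tolerance
    return (
        (up_c >= -embed_mm - eps)
        & (up_c < spec.height - embed_mm - eps)
        & (lg_c >= -half_l - eps)
        & (lg_c < half_l - eps)
        & (np.abs(wd_c) < half_w - eps)
    )


def add_handle(
    seg: NicheSegmentation,
    bone: np.ndarray,
    vol: VolumeImage,
    frame: CCSFrame,
    spec: HandleSpec | None = None,
) -> ImplantModel:
    """Attach the forceps handle to the implant body.

    The handle base sits on the kept voxel with the highest CCS-x
    coordinate near the fill-center axis; voxels overlapping bone are
    removed and only handle voxels 26-connected to the body survive.
    """
    spec = spec or HandleSpec()
    body = np.asarray(seg.mask, dtype=bool)
    if not np.any(body):
        raise InputError("implant body mask is empty; nothing to attach a handle to")
    bone = np.asarray(bone, dtype=bool)

    centers = vol.voxel_centers()
    kept_pts = centers[body]
    rel = kept_pts - seg.params.fill_center
    lateral = rel - np.outer(rel @ frame.x_axis, frame.x_axis)
    radius = max(0.5 * min(spec.width, spec.length), 2.0 * float(np.min(vol.spacing)))
    near = np.linalg.norm(lateral, axis=1) <= radius
    pool = kept_pts[near] if np.any(near) else kept_pts
    base = pool[int(np.argmax(pool @ frame.x_axis))]

    embed = float(np.min(vol.spacing))
    handle = handle_solid_mask(vol, base, frame, spec, embed)
    handle &= ~bone
    handle &= ~body  # body voxels keep their own label
    if not np.any(handle):
        raise PlacementError(
            "handle is fully clipped by bone; reduce the handle dimensions"
        )

    # keep only handle voxels 26-connected to the body
    labels, _ = ndimage.label(handle | body, structure=np.ones((3, 3, 3), dtype=bool))
    body_labels = np.unique(labels[body])
    handle &= np.isin(labels, body_labels)
    if not np.any(handle):
        raise PlacementError(
            "no handle voxel remains connected to the implant body; "
            "reduce the handle dimensions or move it"
        )
    return ImplantModel(body_mask=body, handle_mask=handle)


def _taubin_smooth(vertices: np.ndarray, faces: np.ndarray, iterations: int) -> np.ndarray:
    if iterations == 0:
        return vertices
    n = len(vertices)
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1
    inv_deg = sparse.diags(1.0 / degree)
    avg = inv_deg @ adj

    verts = vertices.copy()
    for _ in range(iterations):
        for factor in (TAUBIN_LAMBDA, TAUBIN_MU):
            verts = verts + factor * (avg @ verts - verts)
    return verts


def mask_to_mesh(
    mask: np.ndarray,
    vol: VolumeImage,
    smoothing_iterations: int = DEFAULT_SMOOTHING_ITERATIONS,
) -> TriangleMesh:
    """Triangulate a voxel mask into a closed, outward-oriented surface.

    Marching cubes at iso-level 0.5 on the 3x nearest-upsampled mask
    (so single-voxel features retain most of their volume; plain
    cell-centered marching cubes shrinks a lone voxel to an octahedron),
    followed by shrink-free Taubin smoothing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise InputError("cannot mesh an empty mask")
    if smoothing_iterations < 0:
        raise ParameterError("smoothing_iterations must be >= 0")

    f = 3
    fine = mask.repeat(f, axis=0).repeat(f, axis=1).repeat(f, axis=2)
    padded = np.pad(fine, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    # padded fine index -> original continuous index -> world
    idx = (verts - 1.0) / f - 0.5 + 0.5 / f
    world = vol.origin + (idx * vol.spacing) @ vol.orientation.T
    world = _taubin_smooth(world, faces, smoothing_iterations)

    mesh = TriangleMesh(world, faces)
    if mesh.signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def write_stl(mesh: TriangleMesh, path: str) -> None:
    """Write a binary little-endian STL (84 + 50*n_triangles bytes)."""
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    normals = np.cross(v1 - v0, v2 - v0)
    lengths = np.linalg.norm(normals, axis=1)
    lengths[lengths == 0] = 1.0
    normals = (normals / lengths[:, np.newaxis]).astype("<f4")

    tris = np.zeros(len(mesh.faces), dtype=_STL_TRI_DTYPE)
    tris["normal"] = normals
    tris["v0"] = v0
    tris["v1"] = v1
    tris["v2"] = v2
    header = b"rwnseg binary STL".ljust(80, b"\x00")
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tris)))
            fh.write(tris.tobytes())
    except OSError as exc:
        raise InputError(f"cannot write STL to {path}: {exc}") from exc


def read_stl(path: str) -> TriangleMesh:
    """Read a binary STL written by :func:`write_stl` (vertices merged)."""
    try:
        with open(path, "rb") as fh:
            fh.read(80)
            (count,) = struct.unpack("<I", fh.read(4))
            tris = np.frombuffer(fh.read(count * _STL_TRI_DTYPE.itemsize),
                                 dtype=_STL_TRI_DTYPE)
    except (OSError, struct.error) as exc:
        raise InputError(f"cannot read STL from {path}: {exc}") from exc
    if len(tris) != count:
        raise InputError(f"{path}: truncated STL (expected {count} triangles)")
    soup = np.stack([tris["v0"], tris["v1"], tris["v2"]], axis=1).reshape(-1, 3)
    vertices, inverse = np.unique(soup, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(vertices.astype(np.float64), faces)


def triangle_soup(mesh: TriangleMesh) -> np.ndarray:
    """(F, 3, 3) float32 corner array, for lossless round-trip comparison."""
    return np.stack(
        [mesh.vertices[mesh.faces[:, k]] for k in range(3)], axis=1
    ).astype(np.float32)
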
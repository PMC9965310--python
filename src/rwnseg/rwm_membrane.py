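"""Round-window-membrane model: an oval cut-out of a bilinear saddle patch.

The membrane is a bilinear surface over four control points,

    S(u, v) = (1-u)(1-v) p00 + u(1-v) p10 + (1-u)v p01 + u v p11,

restricted to an oval in the (u, v) parameter plane. It partitions the
working ROI into a cochlea side and a middle-ear side: a point is
projected onto the (extended) surface and labeled by the sign of its
offset along the surface normal, oriented so the normal points with the
CCS x-axis (the middle-ear side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cochlear_frame import CCSFrame, read_named_points, transform_points, write_named_points
from .errors import GeometryError, ParameterError

LABEL_COCHLEA = "cochlea"
LABEL_MIDDLE_EAR = "middle_ear"

#: boundary-tie tolerance in mm: membrane-surface points belong to the
#: middle ear so the implant never claims membrane voxels
TIE_TOL_MM = 1e-9

# Newton projection controls
_NEWTON_ITERS = 60
_NEWTON_TOL = 1e-8
_UV_CLAMP = (-0.5, 1.5)  # extension of the surface beyond the unit square
_GRID_INIT = 9

_POINT_NAMES = ("rwm_00", "rwm_10", "rwm_01", "rwm_11")


@dataclass(frozen=True)
class RWMPatch:
    """Four control points (world mm) plus the oval extent in (u, v)."""

    p00: np.ndarray
    p10: np.ndarray
    p01: np.ndarray
    p11: np.ndarray
    oval_semi_axes: tuple = (0.5, 0.5)

    def __post_init__(self):
        for name in ("p00", "p10", "p01", "p11"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        a, b = self.oval_semi_axes
        limit = 0.5 * np.sqrt(2.0) + 1e-12
        if not (0 < a <= limit and 0 < b <= limit):
            raise ParameterError(
                f"oval semi-axes must lie in (0, 0.5*sqrt(2)], got {self.oval_semi_axes}"
            )
        edges = np.stack([self.p10 - self.p00, self.p01 - self.p00, self.p11 - self.p00])
        if np.linalg.matrix_rank(edges, tol=1e-9) < 2:
            raise GeometryError("the four control points are collinear")

    @property
    def corners(self) -> np.ndarray:
        return np.stack([self.p00, self.p10, self.p01, self.p11])


@dataclass(frozen=True)
class MeanMembraneModel:
    """Mean control-point displacements from the RWM center, in CCS mm."""

    offsets: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [+0.15, -0.75, -0.75],
                [-0.15, +0.75, -0.75],
                [-0.15, -0.75, +0.75],
                [+0.15, +0.75, +0.75],
            ]
        )
    )

    def __post_init__(self):
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if self.offsets.shape != (4, 3):
            raise ParameterError("mean membrane model needs four 3-vector offsets")
        if abs(self.offsets[:, 0].mean()) > 1e-3:
            raise GeometryError(
                "mean membrane offsets must be centered on the RWM center "
                f"(mean x-offset {self.offsets[:, 0].mean():.4f} mm)"
            )


def eval_surface(patch: RWMPatch, u, v) -> np.ndarray:
    """Evaluate the bilinear surface at parameters (u, v) in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(u > 1) or np.any(v < 0) or np.any(v > 1):
        raise ParameterError("surface parameters must lie in [0, 1]")
    return _eval_unchecked(patch, u, v)


def _eval_unchecked(patch, u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    scalar = u.ndim == 0 and v.ndim == 0
    u, v = u[..., np.newaxis], v[..., np.newaxis]
    out = (
        (1 - u) * (1 - v) * patch.p00
        + u * (1 - v) * patch.p10
        + (1 - u) * v * patch.p01
        + u * v * patch.p11
    )
    return out[0] if scalar and out.ndim > 1 else out


def place_mean_patch(frame: CCSFrame, model: MeanMembraneModel | None = None) -> RWMPatch:
    """Instantiate the mean membrane model in world space via the CCS frame."""
    model = model or MeanMembraneModel()
    pts = transform_points(frame, model.offsets, "from_ccs")
    return RWMPatch(pts[0], pts[1], pts[2], pts[3])


def project_to_surface(patch: RWMPatch, points) -> tuple:
    """Nearest-point (u, v) on the extended bilinear surface per point.

    Damped Newton in (u, v) seeded from the best of a 9x9 grid, iterates
    clamped to a bounded extension of the unit square; points never move
    uphill so the grid minimum is a guaranteed fallback.

    Returns ``(u, v, foot)`` arrays.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    p00, p10, p01, p11 = patch.corners
    A = p10 - p00
    B = p01 - p00
    C = p11 - p10 - p01 + p00

    def surf(u, v):
        return p00 + np.outer(u, A) + np.outer(v, B) + np.outer(u * v, C)

    # grid initialization over the unit square
    g = np.linspace(0.0, 1.0, _GRID_INIT)
    best_u = np.zeros(len(pts))
    best_v = np.zeros(len(pts))
    best_f = np.full(len(pts), np.inf)
    for gu in g:
        for gv in g:
            s = p00 + gu * A + gv * B + gu * gv * C
            f = np.sum((pts - s) ** 2, axis=1)
            better = f < best_f
            best_f[better] = f[better]
            best_u[better] = gu
            best_v[better] = gv

    u, v, fval = best_u, best_v, best_f
    lo, hi = _UV_CLAMP
    alive = np.arange(len(pts))  # points still iterating
    for _ in range(_NEWTON_ITERS):
        if alive.size == 0:
            break
        ua, va = u[alive], v[alive]
        pa = pts[alive]
        d = (p00 + np.outer(ua, A) + np.outer(va, B) + np.outer(ua * va, C)) - pa
        Su = A + np.outer(va, C)
        Sv = B + np.outer(ua, C)
        gu_ = np.einsum("ij,ij->i", Su, d)
        gv_ = np.einsum("ij,ij->i", Sv, d)
        h11 = np.einsum("ij,ij->i", Su, Su)
        h22 = np.einsum("ij,ij->i", Sv, Sv)
        gn12 = np.einsum("ij,ij->i", Su, Sv)
        h12 = gn12 + d @ C
        det = h11 * h22 - h12 * h12
        # regularize indefinite/singular Hessians toward Gauss-Newton
        bad = det <= 1e-14
        if np.any(bad):
            h12 = np.where(bad, gn12, h12)
            det = h11 * h22 - h12 * h12
            det = np.where(np.abs(det) < 1e-14, 1e-14, det)
        du = -(h22 * gu_ - h12 * gv_) / det
        dv = -(h11 * gv_ - h12 * gu_) / det

        converged = np.hypot(du, dv) < _NEWTON_TOL
        moving = alive[~converged]
        du, dv = du[~converged], dv[~converged]
        step = np.ones(moving.size)
        active = np.arange(moving.size)
        improved_any = np.zeros(moving.size, dtype=bool)
        for _ in range(12):  # backtracking halves; keep only improving moves
            idx = moving[active]
            cu = np.clip(u[idx] + step[active] * du[active], lo, hi)
            cv = np.clip(v[idx] + step[active] * dv[active], lo, hi)
            s = surf(cu, cv)
            f_new = np.sum((pts[idx] - s) ** 2, axis=1)
            improved = f_new < fval[idx]
            took = idx[improved]
            u[took] = cu[improved]
            v[took] = cv[improved]
            fval[took] = f_new[improved]
            improved_any[active[improved]] = True
            active = active[~improved]
            if active.size == 0:
                break
            step[active] *= 0.5
        # stalled points (no improving step exists) are done too
        alive = moving[improved_any]
    return u, v, surf(u, v)


def signed_offsets(patch: RWMPatch, frame: CCSFrame, points) -> tuple:
    """Per-point signed normal offset (mm) and inside-oval flag.

    The normal is oriented to have a positive dot product with the CCS
    x-axis, so positive offsets are on the middle-ear side.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, v, foot = project_to_surface(patch, pts)
    p00, p10, p01, p11 = patch.corners
    A = p10 - p00
    B = p01 - p00
    C = p11 - p10 - p01 + p00
    Su = A + np.outer(v, C)
    Sv = B + np.outer(u, C)
    normals = np.cross(Su, Sv)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms < 1e-12):
        raise GeometryError("degenerate (zero-area) membrane patch")
    normals /= norms[:, np.newaxis]
    sign = normals @ frame.x_axis
    mean_normal = np.cross(A + (p11 - p01), B + (p11 - p10))
    fallback = np.sign(mean_normal @ frame.x_axis) or 1.0
    orient = np.where(np.abs(sign) < 1e-12, fallback, np.sign(sign))
    normals *= orient[:, np.newaxis]

    offsets = np.einsum("ij,ij->i", pts - foot, normals)
    a, b = patch.oval_semi_axes
    inside_oval = ((u - 0.5) / a) ** 2 + ((v - 0.5) / b) ** 2 <= 1.0
    return offsets, inside_oval


def classify_side(patch: RWMPatch, frame: CCSFrame, points) -> np.ndarray:
    """Label points as 'cochlea' or 'middle_ear'.

    Points whose (u, v) projection falls outside the oval cut-out are not
    bounded by the membrane and are labeled middle_ear; boundary ties
    (|offset| < 1e-9 mm) also go to the middle ear so the implant can
    rest on, but never claim, the membrane.
    """
    offsets, inside_oval = signed_offsets(patch, frame, points)
    cochlea = inside_oval & (offsets <= -TIE_TOL_MM)
    labels = np.where(cochlea, LABEL_COCHLEA, LABEL_MIDDLE_EAR)
    return labels if np.asarray(points).ndim > 1 else labels[0]


def cochlea_side_mask(patch: RWMPatch, frame: CCSFrame, points) -> np.ndarray:
    """Boolean array: True where a point lies on the cochlea side."""
    offsets, inside_oval = signed_offsets(patch, frame, points)
    return inside_oval & (offsets <= -TIE_TOL_MM)


def patch_center(patch: RWMPatch) -> np.ndarray:
    """World point at the patch parameter center (u = v = 1/2)."""
    return _eval_unchecked(patch, 0.5, 0.5)


def read_patch(path: str, oval_semi_axes=(0.5, 0.5)) -> RWMPatch:
    """Read membrane control points from a Slicer markups JSON file."""
    named = read_named_points(path)
    missing = [n for n in _POINT_NAMES if n not in named]
    if missing:
        raise GeometryError(f"{path}: missing membrane points {missing}")
    return RWMPatch(*[named[n] for n in _POINT_NAMES], oval_semi_axes=tuple(oval_semi_axes))


def write_patch(path: str, patch: RWMPatch) -> None:
    write_named_points(path, dict(zip(_POINT_NAMES, patch.corners)))
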
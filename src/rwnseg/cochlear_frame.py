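"""Cochlear coordinate system (CCS) fitting and point transforms.

The frame is fitted from three fiducials: the z-axis runs along the
modiolar axis from the basal-turn point toward the apex (helicotrema),
the x-axis points from that axis toward the round-window center, and the
origin sits at the round-window center. The y-axis completes a
right-handed frame (``y = z x x``); for left ears it can be mirrored so
"toward the basal turn" keeps its anatomical meaning.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError

_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class CochlearFiducials:
    """Three anatomical landmarks in world mm (LPS)."""

    apex: np.ndarray
    basal: np.ndarray
    rw_center: np.ndarray

    def __post_init__(self):
        for name in ("apex", "basal", "rw_center"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise GeometryError(f"fiducial {name!r} must be a 3-vector")


@dataclass(frozen=True)
class CCSFrame:
    """Orthonormal cochlear frame; origin at the round-window center."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise GeometryError("CCS axes must be orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are (x, y, z) axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])


def fit_ccs(fids: CochlearFiducials, side: str = "right") -> CCSFrame:
    """Fit the cochlear frame from apex / basal-turn / round-window fiducials.

    ``side`` mirrors the y-axis for left ears so the handle direction
    "toward the basal turn" is consistent across working orientations.
    """
    if side not in ("left", "right"):
        raise InputError(f"side must be 'left' or 'right', got {side!r}")
    modiolar = fids.apex - fids.basal
    length = np.linalg.norm(modiolar)
    if length < _DEGENERATE_TOL:
        raise GeometryError("apex and basal fiducials coincide")
    z_axis = modiolar / length

    to_rw = fids.rw_center - fids.basal
    radial = to_rw - np.dot(to_rw, z_axis) * z_axis
    rlen = np.linalg.norm(radial)
    if rlen < _DEGENERATE_TOL:
        raise GeometryError("round-window center lies on the modiolar axis")
    x_axis = radial / rlen
    y_axis = np.cross(z_axis, x_axis)
    if side == "left":
        y_axis = -y_axis
    return CCSFrame(np.array(fids.rw_center), x_axis, y_axis, z_axis)


def transform_points(frame: CCSFrame, points, direction: str = "to_ccs") -> np.ndarray:
    """Transform points between world and CCS coordinates.

    ``to_ccs`` maps ``p -> R.T @ (p - origin)``; ``from_ccs`` is its
    exact inverse.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3:
        raise InputError("points must have shape (..., 3)")
    R = frame.rotation
    if direction == "to_ccs":
        out = (pts - frame.origin) @ R
    elif direction == "from_ccs":
        out = pts @ R.T + frame.origin
    else:
        raise InputError(f"direction must be 'to_ccs' or 'from_ccs', got {direction!r}")
    return out if np.asarray(points).ndim > 1 else out[0]


# ---------------------------------------------------------------------------
# fiducial file I/O

_REQUIRED_NAMES = ("apex", "basal", "rw_center")


def _from_named_points(named: dict, path: str) -> CochlearFiducials:
    missing = [n for n in _REQUIRED_NAMES if n not in named]
    if missing:
        raise InputError(f"{path}: missing fiducials {missing}; found {sorted(named)}")
    return CochlearFiducials(named["apex"], named["basal"], named["rw_center"])


def read_fiducials(path: str) -> CochlearFiducials:
    """Read fiducials from a Slicer markups JSON or a name,x,y,z CSV (LPS mm)."""
    named = read_named_points(path)
    return _from_named_points(named, path)


def read_named_points(path: str) -> dict:
    """Read {name: world point} from .mrk.json or CSV."""
    if path.endswith(".json"):
        with open(path) as fh:
            doc = json.load(fh)
        named = {}
        for markup in doc.get("markups", []):
            ras_like = markup.get("coordinateSystem", "LPS").upper()
            for cp in markup.get("controlPoints", []):
                pos = np.asarray(cp["position"], dtype=float)
                if ras_like == "RAS":
                    pos = pos * np.array([-1.0, -1.0, 1.0])
                named[cp["label"]] = pos
        return named
    named = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0].lower() == "name":
                continue
            if len(row) < 4:
                raise InputError(f"{path}: fiducial rows need name,x,y,z")
            named[row[0].strip()] = np.array([float(v) for v in row[1:4]])
    return named


def write_named_points(path: str, named: dict) -> None:
    """Write {name: point} as a Slicer markups JSON file (LPS)."""
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "LPS",
                "controlPoints": [
                    {"id": str(i + 1), "label": name,
                     "position": [float(v) for v in pos]}
                    for i, (name, pos) in enumerate(named.items())
                ],
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def write_fiducials(path: str, fids: CochlearFiducials) -> None:
    write_named_points(
        path, {"apex": fids.apex, "basal": fids.basal, "rw_center": fids.rw_center}
    )
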
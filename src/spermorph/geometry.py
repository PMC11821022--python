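"""Core geometric records shared across the package.

A sperm cell is modelled as three parts: an elliptical head, a short thick
midpiece and a long thin tail (flagellum).  Part labels are fixed integers
used in every label map: 0 background, 1 head, 2 midpiece, 3 tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

BACKGROUND, HEAD, MIDPIECE, TAIL = 0, 1, 2, 3
PART_NAMES = {HEAD: "head", MIDPIECE: "midpiece", TAIL: "tail"}
PART_LABELS = (HEAD, MIDPIECE, TAIL)

#: Column order of the per-instance measurement record (head, midpiece, tail).
MORPH_COLUMNS = (
    "head_length_um",
    "head_width_um",
    "head_ellipticity",
    "mid_length_um",
    "mid_width_um",
    "mid_angle_deg",
    "tail_length_um",
    "tail_width_um",
    "tail_angle_deg",
)


@dataclass
class MorphParams:
    """The nine per-instance morphological parameters.

    Lengths and widths are in micrometres; head ellipticity is the
    major/minor axis ratio (dimensionless, >= 1); angles are in degrees.
    A field is ``None`` when the corresponding part mask was missing.
    """

    head_length_um: Optional[float] = None
    head_width_um: Optional[float] = None
    head_ellipticity: Optional[float] = None
    mid_length_um: Optional[float] = None
    mid_width_um: Optional[float] = None
    mid_angle_deg: Optional[float] = None
    tail_length_um: Optional[float] = None
    tail_width_um: Optional[float] = None
    tail_angle_deg: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_row(self) -> list:
        """Values in the fixed report column order (head, midpiece, tail)."""
        return [getattr(self, c) for c in MORPH_COLUMNS]

    @property
    def missing_parts(self) -> list[str]:
        out = []
        if self.head_length_um is None:
            out.append("head")
        if self.mid_length_um is None:
            out.append("midpiece")
        if self.tail_length_um is None:
            out.append("tail")
        return out


@dataclass
class SpermGeometry:
    """Analytic description of one synthetic sperm instance.

    Coordinates are 0-based ``(row, col)`` pixels with pixel centres at
    integer positions; angles are radians internally.
    """

    instance_id: int
    head_center: tuple[float, float]
    head_semi_major_px: float
    head_semi_minor_px: float
    head_orientation_rad: float
    midpiece_points: np.ndarray  # (N, 2) float, starts at the head boundary
    midpiece_width_px: float
    tail_points: np.ndarray  # (M, 2) float, starts at the midpiece end
    tail_width_px: float
    params: MorphParams = field(default_factory=MorphParams)

    def __post_init__(self) -> None:
        if self.instance_id <= 0:
            raise ValueError("instance_id must be a positive integer")
        if not (self.head_semi_major_px >= self.head_semi_minor_px > 0):
            raise ValueError("head semi-major must be >= semi-minor > 0")
        if self.midpiece_width_px <= 0 or self.tail_width_px <= 0:
            raise ValueError("part widths must be positive")
        self.midpiece_points = np.asarray(self.midpiece_points, dtype=float)
        self.tail_points = np.asarray(self.tail_points, dtype=float)


def polyline_length(points: np.ndarray) -> float:
    """Arc length of an ordered point sequence."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def chord_angle_deg(points: np.ndarray, frac: float = 0.15) -> float:
    """Absolute angle between the chords at the two ends of a curve.

    Used as the tail "angle" (a folding/curvature proxy): 0 for a straight
    line, approaching 180 for a hairpin fold.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return 0.0
    k = max(2, int(round(frac * len(points))))
    v0 = points[k - 1] - points[0]
    v1 = points[-1] - points[-k]
    n0, n1 = np.linalg.norm(v0), np.linalg.norm(v1)
    if n0 == 0 or n1 == 0:
        return 0.0
    cosang = np.clip(np.dot(v0, v1) / (n0 * n1), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def acute_angle_deg(a_rad: float, b_rad: float) -> float:
    """Acute angle in degrees between two undirected axes given in radians."""
    d = abs(a_rad - b_rad) % np.pi
    if d > np.pi / 2:
        d = np.pi - d
    return float(np.degrees(d))
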
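"""Per-instance morphometry from part masks.

Head and midpiece are measured by fitting: an ellipse from the second-order
image moments of the mask (for ellipticity), and the minimum-area enclosing
rectangle of the sub-pixel mask contour (for length, width and orientation).
The tail is measured by Steger centerline tracing on the mask's distance
transform (arc length, mean ridge width, end-chord folding angle).

All pixel measurements are converted to micrometres through the pixel size;
angles are degrees in the output record.  The output column order is
head (length, width, ellipticity), midpiece (length, width, angle),
tail (length, width, angle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from shapely.geometry import MultiPoint
from skimage import measure as skmeasure

from .geometry import MorphParams, acute_angle_deg
from .steger import Centerline, EmptyCenterlineError, steger_centerline

#: WHO normal range for head length, um; used only for the normality flag.
NORMAL_HEAD_LENGTH_UM = (3.7, 4.7)


class DegenerateMaskError(ValueError):
    """Mask too small to fit (fewer than 5 foreground pixels)."""


@dataclass
class EllipseFit:
    """Moments-based ellipse: centre, full axis lengths, orientation."""

    center: tuple[float, float]
    major_px: float
    minor_px: float
    orientation_rad: float  # long-axis angle from the column axis, [0, pi)

    def __post_init__(self) -> None:
        if not (self.major_px >= self.minor_px > 0):
            raise ValueError("ellipse axes must satisfy major >= minor > 0")


@dataclass
class RectFit:
    """Minimum-area enclosing rectangle of the mask contour."""

    center: tuple[float, float]
    length_px: float
    width_px: float
    angle_rad: float  # long-side angle from the column axis, [0, pi)

    def __post_init__(self) -> None:
        if not (self.length_px >= self.width_px > 0):
            raise ValueError("rectangle must satisfy length >= width > 0")


@dataclass
class PartMaskSet:
    """Binary masks of one instance's parts plus the pixel size."""

    instance_id: int
    head: Optional[np.ndarray]
    midpiece: Optional[np.ndarray]
    tail: Optional[np.ndarray]
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        shapes = {m.shape for m in (self.head, self.midpiece, self.tail)
                  if m is not None}
        if len(shapes) > 1:
            raise ValueError("part masks must share a shape")


def _contour_points(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel boundary points of a mask (0.5-level contour)."""
    padded = np.pad(mask.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise DegenerateMaskError("mask has no contour")
    return np.concatenate(contours) - 1.0  # undo the padding offset


def min_area_rect(mask: np.ndarray) -> RectFit:
    """Minimum-area rectangle enclosing the sub-pixel mask contour.

    For an exactly square fit the long-side direction is ambiguous; the
    side with the smaller angle from the column axis is reported, so the
    angle is then always in [0, 90) degrees.
    """
    pts = _contour_points(mask)
    rect = MultiPoint([(c, r) for r, c in pts]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # collinear degenerate contour
        raise DegenerateMaskError("contour degenerates to a line")
    xy = np.asarray(rect.exterior.coords)[:4]  # (x=col, y=row)
    e0 = xy[1] - xy[0]
    e1 = xy[2] - xy[1]
    l0, l1 = np.hypot(*e0), np.hypot(*e1)
    if l0 >= l1:
        length, width, long_vec = l0, l1, e0
    else:
        length, width, long_vec = l1, l0, e1
    if np.isclose(l0, l1):
        # square: pick the side closer to the column axis, deterministically
        a0 = np.arctan2(e0[1], e0[0]) % np.pi
        a1 = np.arctan2(e1[1], e1[0]) % np.pi
        long_vec = e0 if min(a0, np.pi - a0) <= min(a1, np.pi - a1) else e1
    angle = np.arctan2(long_vec[1], long_vec[0]) % np.pi  # from col axis
    center = xy[:4].mean(axis=0)
    return RectFit(center=(float(center[1]), float(center[0])),
                   length_px=float(length), width_px=float(width),
                   angle_rad=float(angle))


def moments_ellipse(mask: np.ndarray) -> EllipseFit:
    """Ellipse with the same second-order moments as the mask."""
    props = skmeasure.regionprops(mask.astype(np.uint8))
    if not props:
        raise DegenerateMaskError("empty mask")
    p = props[0]
    o = p.orientation  # skimage: major-axis direction (cos o, sin o) in (row, col)
    theta = (np.pi / 2 - o) % np.pi
    return EllipseFit(center=tuple(map(float, p.centroid)),
                      major_px=float(p.axis_major_length),
                      minor_px=float(max(p.axis_minor_length, 1e-9)),
                      orientation_rad=float(theta))


def _require(mask: Optional[np.ndarray], part: str) -> np.ndarray:
    if mask is None or np.count_nonzero(mask) < 5:
        raise DegenerateMaskError(f"{part} mask missing or under 5 pixels")
    return np.asarray(mask, dtype=bool)


def fit_head(mask: np.ndarray, pixel_size_um: float,
             ellipticity_mode: str = "ratio") -> tuple[EllipseFit, RectFit, dict]:
    """Head measurements: rectangle length/width, moments-ellipse ellipticity.

    ``ellipticity_mode`` selects the reported shape index: ``"ratio"``
    (major/minor, >= 1) or ``"eccentricity"`` (sqrt(1 - (b/a)^2), in [0, 1)).
    The returned dict also carries ``normal_length`` — whether the length
    falls in the WHO normal band of 3.7-4.7 um.
    """
    mask = _require(mask, "head")
    ellipse = moments_ellipse(mask)
    rect = min_area_rect(mask)
    if ellipticity_mode == "ratio":
        ell = ellipse.major_px / ellipse.minor_px
    elif ellipticity_mode == "eccentricity":
        ell = float(np.sqrt(1.0 - (ellipse.minor_px / ellipse.major_px) ** 2))
    else:
        raise ValueError(f"unknown ellipticity mode {ellipticity_mode!r}")
    length = rect.length_px * pixel_size_um
    fields = {
        "head_length_um": length,
        "head_width_um": rect.width_px * pixel_size_um,
        "head_ellipticity": ell,
        "normal_length": NORMAL_HEAD_LENGTH_UM[0] <= length <= NORMAL_HEAD_LENGTH_UM[1],
    }
    return ellipse, rect, fields


def fit_midpiece(mask: np.ndarray, pixel_size_um: float) -> tuple[RectFit, dict]:
    """Midpiece measurements from its minimum-area rectangle.

    The reported angle is the rectangle's long-side orientation from the
    image column axis, in degrees ([0, 180), folded to [0, 90) for a square
    fit); the head-relative acute angle is composed in
    :func:`measure_instance`.
    """
    mask = _require(mask, "midpiece")
    rect = min_area_rect(mask)
    return rect, {
        "mid_length_um": rect.length_px * pixel_size_um,
        "mid_width_um": rect.width_px * pixel_size_um,
        "mid_angle_deg": float(np.degrees(rect.angle_rad)),
    }


def fit_tail(mask: np.ndarray, pixel_size_um: float,
             width_range_px: tuple[float, float] = (1.0, 6.0)) -> tuple[Centerline, dict]:
    """Tail measurements via Steger centerline tracing on the mask."""
    mask = _require(mask, "tail")
    centerline = steger_centerline(mask, width_range_px=width_range_px)
    return centerline, {
        "tail_length_um": centerline.arc_length * pixel_size_um,
        "tail_width_um": centerline.mean_width * pixel_size_um,
        "tail_angle_deg": centerline.end_chord_angle_deg(),
    }


def measure_instance(parts: PartMaskSet,
                     ellipticity_mode: str = "ratio") -> MorphParams:
    """Compose the three fitters into the nine-parameter record.

    Missing or degenerate parts leave their fields ``None``; an instance
    with no measurable part at all raises, naming the missing parts.  The
    midpiece angle is reported relative to the head's rectangle axis (acute,
    in [0, 90] degrees) when the head is available, otherwise as the
    absolute image-axis angle.
    """
    out = MorphParams()
    head_rect = None
    errors = []
    try:
        _, head_rect, hf = fit_head(parts.head, parts.pixel_size_um, ellipticity_mode)
        out.head_length_um = hf["head_length_um"]
        out.head_width_um = hf["head_width_um"]
        out.head_ellipticity = hf["head_ellipticity"]
    except DegenerateMaskError as e:
        errors.append(str(e))
    try:
        mid_rect, mf = fit_midpiece(parts.midpiece, parts.pixel_size_um)
        out.mid_length_um = mf["mid_length_um"]
        out.mid_width_um = mf["mid_width_um"]
        if head_rect is not None:
            out.mid_angle_deg = acute_angle_deg(mid_rect.angle_rad, head_rect.angle_rad)
        else:
            out.mid_angle_deg = mf["mid_angle_deg"]
    except DegenerateMaskError as e:
        errors.append(str(e))
    try:
        _, tf = fit_tail(parts.tail, parts.pixel_size_um)
        out.tail_length_um = tf["tail_length_um"]
        out.tail_width_um = tf["tail_width_um"]
        out.tail_angle_deg = tf["tail_angle_deg"]
    except (DegenerateMaskError, EmptyCenterlineError) as e:
        errors.append(str(e))
    if len(errors) == 3:
        raise DegenerateMaskError(
            f"instance {parts.instance_id}: no measurable part ({'; '.join(errors)})")
    return out
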
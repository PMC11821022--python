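"""Seeded synthetic sperm scenes and periodic motion signals.

The generator emulates the kind of data the measurement pipeline targets:
stain-free phase microscopy fields of 1200 x 900 px containing 15-30 sperm,
with blurred low-contrast boundaries, plus 2-second / 60 fps time series of a
morphological parameter oscillating at ~3.7 Hz (the helical-rotation
frequency of rapidly progressive sperm) contaminated by noise and outliers.

Every output is bitwise-deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .geometry import (
    HEAD,
    MIDPIECE,
    TAIL,
    MorphParams,
    SpermGeometry,
    chord_angle_deg,
    polyline_length,
)


class ConfigurationError(ValueError):
    """Raised when a generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass
class GeometryRanges:
    """Plausible per-part dimension ranges (um) for sampled sperm.

    Defaults follow normal human sperm morphometry: head 3.7-5.1 um long and
    2.1-3.0 um wide, midpiece ~4 um, tail 20-32 um long and ~0.5 um wide.
    """

    head_length_um: tuple[float, float] = (3.7, 5.1)
    head_width_um: tuple[float, float] = (2.1, 3.0)
    mid_length_um: tuple[float, float] = (3.9, 4.3)
    mid_width_um: tuple[float, float] = (0.5, 0.65)
    mid_angle_deg: tuple[float, float] = (0.0, 15.0)
    tail_length_um: tuple[float, float] = (20.0, 32.0)
    tail_width_um: tuple[float, float] = (0.45, 0.65)

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 <= lo <= hi):
                raise ConfigurationError(f"invalid range {name}={lo, hi}")


@dataclass
class SceneSpec:
    """Configuration of one rendered scene."""

    width: int = 1200
    height: int = 900
    count_range: tuple[int, int] = (15, 30)
    pixel_size_um: float = 0.25
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.02
    overlap_prob: float = 0.0
    seed: Optional[int] = None
    ranges: GeometryRanges = field(default_factory=GeometryRanges)
    #: rendered intensity of head / midpiece / tail on a black background
    part_intensity: tuple[float, float, float] = (1.0, 0.7, 0.45)

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        lo, hi = self.count_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("count range must be non-empty")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel size must be positive")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ConfigurationError("blur sigma and noise sd must be >= 0")
        if not (0.0 <= self.overlap_prob <= 1.0):
            raise ConfigurationError("overlap_prob must lie in [0, 1]")
        self.ranges.validate()


@dataclass
class RenderedScene:
    """A synthetic image with its pixel-exact ground truth."""

    image: np.ndarray  # (H, W) float
    instance_map: np.ndarray  # (H, W) int, 0 = background
    part_map: np.ndarray  # (H, W) int in {0, 1, 2, 3}
    geometries: list[SpermGeometry]

    def check_invariants(self) -> None:
        if (self.part_map > 0).sum() != ((self.part_map > 0) & (self.instance_map > 0)).sum():
            raise AssertionError("part map labels a pixel with no instance id")
        ids = set(np.unique(self.instance_map)) - {0}
        known = {g.instance_id for g in self.geometries}
        if not ids <= known:
            raise AssertionError(f"instance ids {ids - known} missing geometry")


# ---------------------------------------------------------------------------
# Geometry sampling
# ---------------------------------------------------------------------------

def _unit(theta: float) -> np.ndarray:
    return np.array([np.sin(theta), np.cos(theta)])  # (row, col) convention


def _sample_one(
    rng: np.random.Generator, spec: SceneSpec, instance_id: int
) -> tuple[SpermGeometry, MorphParams]:
    r = spec.ranges
    px = spec.pixel_size_um

    head_len = rng.uniform(*r.head_length_um)
    head_wid = rng.uniform(*r.head_width_um)
    mid_len = rng.uniform(*r.mid_length_um)
    mid_wid = rng.uniform(*r.mid_width_um)
    mid_ang = rng.uniform(*r.mid_angle_deg)
    tail_len = rng.uniform(*r.tail_length_um)
    tail_wid = rng.uniform(*r.tail_width_um)

    a = head_len / 2 / px  # semi-major, px
    b = head_wid / 2 / px
    margin = a + (mid_len + tail_len) / px  # worst case: a fully extended tail
    margin = min(margin, 0.45 * min(spec.height, spec.width))
    center = np.array([
        rng.uniform(margin, spec.height - 1 - margin),
        rng.uniform(margin, spec.width - 1 - margin),
    ])
    theta = rng.uniform(0, 2 * np.pi)  # head axis direction (towards tail)

    # Midpiece: straight segment leaving the head boundary at a small angle.
    mid_sign = rng.choice([-1.0, 1.0])
    mid_theta = theta + mid_sign * np.radians(mid_ang)
    mid_start = center + a * _unit(theta)
    n_mid = max(2, int(mid_len / px / 1.5))
    ts = np.linspace(0.0, mid_len / px, n_mid)
    mid_points = mid_start[None, :] + ts[:, None] * _unit(mid_theta)[None, :]

    # Tail: heading meanders sinusoidally around the midpiece direction,
    # emulating flagellar beat shape frozen in one frame.
    step = 1.0  # px
    n_steps = max(2, int(round(tail_len / px / step)))
    amp = rng.uniform(0.15, 0.45)  # heading modulation, rad
    wavelength = rng.uniform(18.0, 28.0) / px  # flagellar wave, um -> px
    phase = rng.uniform(0, 2 * np.pi)
    drift = rng.uniform(-0.004, 0.004)  # gentle overall bend, rad / px
    s = np.arange(n_steps) * step
    headings = mid_theta + amp * np.sin(2 * np.pi * s / wavelength + phase) + drift * s
    deltas = step * np.stack([np.sin(headings), np.cos(headings)], axis=1)
    tail_points = mid_points[-1][None, :] + np.concatenate(
        [np.zeros((1, 2)), np.cumsum(deltas, axis=0)], axis=0
    )
    # rescale so the arc length matches the drawn tail length exactly
    arc = polyline_length(tail_points)
    tail_points = tail_points[0] + (tail_points - tail_points[0]) * (tail_len / px / arc)

    params = MorphParams(
        head_length_um=head_len,
        head_width_um=head_wid,
        head_ellipticity=head_len / head_wid,
        mid_length_um=mid_len,
        mid_width_um=mid_wid,
        mid_angle_deg=mid_ang,
        tail_length_um=polyline_length(tail_points) * px,
        tail_width_um=tail_wid,
        tail_angle_deg=chord_angle_deg(tail_points),
    )
    return SpermGeometry(
        instance_id=instance_id,
        head_center=(float(center[0]), float(center[1])),
        head_semi_major_px=a,
        head_semi_minor_px=b,
        head_orientation_rad=theta,
        midpiece_points=mid_points,
        midpiece_width_px=mid_wid / px,
        tail_points=tail_points,
        tail_width_px=tail_wid / px,
    ), params


def sample_geometries(spec: SceneSpec) -> list[SpermGeometry]:
    """Draw a seeded set of sperm geometries for one scene.

    The instance count is uniform over ``spec.count_range``; per-part
    dimensions are uniform over ``spec.ranges``.  When ``overlap_prob`` is
    low, placements that collide with already-placed instances are
    rejection-resampled (up to a retry cap, after which the colliding
    placement is kept).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.count_range
    n = int(rng.integers(lo, hi + 1))
    geoms: list[SpermGeometry] = []
    placed_pts: list[np.ndarray] = []
    for i in range(1, n + 1):
        for _attempt in range(50):
            geom, params = _sample_one(rng, spec, i)
            geom.params = params
            allow_overlap = rng.random() < spec.overlap_prob
            if allow_overlap or not placed_pts:
                break
            pts = np.concatenate(
                [np.array([geom.head_center]), geom.midpiece_points, geom.tail_points]
            )
            others = np.concatenate(placed_pts)
            d2 = (
                (pts[:, None, 0] - others[None, :, 0]) ** 2
                + (pts[:, None, 1] - others[None, :, 1]) ** 2
            )
            clearance = 2.0 * geom.head_semi_minor_px + 3.0
            if d2.min() > clearance**2:
                break
        geoms.append(geom)
        placed_pts.append(
            np.concatenate(
                [np.array([geom.head_center]), geom.midpiece_points, geom.tail_points]
            )
        )
    return geoms


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _tube_mask(shape: tuple[int, int], points: np.ndarray, width: float) -> np.ndarray:
    """Binary mask of a tube of the given full width around a polyline.

    The polyline is resampled densely, stamped onto the grid, and dilated by
    a Euclidean distance threshold of half the width (computed inside the
    tube's bounding box only).
    """
    points = np.asarray(points, dtype=float)
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seglen.sum()
    n = max(2, int(total / 0.25))
    t = np.concatenate([[0.0], np.cumsum(seglen)])
    ti = np.linspace(0, total, n)
    rr = np.interp(ti, t, points[:, 0])
    cc = np.interp(ti, t, points[:, 1])

    pad = int(np.ceil(width / 2)) + 2
    r0 = max(0, int(np.floor(rr.min())) - pad)
    r1 = min(shape[0], int(np.ceil(rr.max())) + pad + 1)
    c0 = max(0, int(np.floor(cc.min())) - pad)
    c1 = min(shape[1], int(np.ceil(cc.max())) + pad + 1)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    stamp = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    ri = np.clip(np.rint(rr).astype(int) - r0, 0, r1 - r0 - 1)
    ci = np.clip(np.rint(cc).astype(int) - c0, 0, c1 - c0 - 1)
    keep = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
    stamp[ri[keep], ci[keep]] = True
    if stamp.any():
        dist = ndimage.distance_transform_edt(~stamp)
        mask[r0:r1, c0:c1] = dist <= width / 2
    return mask


def _bar_mask(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray,
              width: float) -> np.ndarray:
    """Flat-ended bar of the given full width between two points.

    Used for the midpiece so that its enclosing-rectangle length equals the
    segment length exactly (a round-capped tube would add one width).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    mask = np.zeros(shape, dtype=bool)
    if length == 0:
        return mask
    axis = axis / length
    pad = int(np.ceil(width / 2 + 2))
    r0 = max(0, int(np.floor(min(p0[0], p1[0]))) - pad)
    r1 = min(shape[0], int(np.ceil(max(p0[0], p1[0]))) + pad + 1)
    c0 = max(0, int(np.floor(min(p0[1], p1[1]))) - pad)
    c1 = min(shape[1], int(np.ceil(max(p0[1], p1[1]))) + pad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - p0[0]
    dc = cc - p0[1]
    along = dr * axis[0] + dc * axis[1]
    perp = np.abs(dr * axis[1] - dc * axis[0])
    mask[r0:r1, c0:c1] = (along >= 0) & (along <= length) & (perp <= width / 2)
    return mask


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  a: float, b: float, theta: float) -> np.ndarray:
    """Pixel-centre point-in-ellipse mask (semi-axes a >= b, axis at angle theta)."""
    rot = float(np.arctan2(np.sin(-theta), np.cos(-theta)))  # wrap to (-pi, pi)
    rr, cc = skdraw.ellipse(center[0], center[1], b, a, shape=shape, rotation=rot)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def part_masks(geom: SpermGeometry, shape: tuple[int, int]) -> dict[int, np.ndarray]:
    """Undegraded binary masks for one instance, keyed by part label."""
    return {
        TAIL: _tube_mask(shape, geom.tail_points, geom.tail_width_px),
        MIDPIECE: _bar_mask(shape, geom.midpiece_points[0], geom.midpiece_points[-1],
                            geom.midpiece_width_px),
        HEAD: _ellipse_mask(shape, geom.head_center, geom.head_semi_major_px,
                            geom.head_semi_minor_px, geom.head_orientation_rad),
    }


def render_scene(geometries: list[SpermGeometry], spec: SceneSpec) -> RenderedScene:
    """Rasterize geometries into an intensity image plus ground-truth maps.

    Parts are painted tail, then midpiece, then head so that the head — the
    most measurement-critical part — always wins at part junctions; a later
    instance overwrites an earlier one where instances overlap.  Blur and
    additive Gaussian noise degrade the intensity image only, never the
    ground-truth maps.
    """
    spec.validate()
    shape = (spec.height, spec.width)
    part_map = np.zeros(shape, dtype=np.uint8)
    inst_map = np.zeros(shape, dtype=np.int32)
    for label in (TAIL, MIDPIECE, HEAD):
        for geom in geometries:
            mask = part_masks(geom, shape)[label]
            part_map[mask] = label
            inst_map[mask] = geom.instance_id

    levels = np.array([0.0, *spec.part_intensity])
    image = levels[part_map]
    if spec.blur_sigma_px > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
        image = image + rng.normal(0.0, spec.noise_sd, size=shape)
    scene = RenderedScene(image=image, instance_map=inst_map,
                          part_map=part_map, geometries=list(geometries))
    scene.check_invariants()
    return scene


def make_scene(spec: SceneSpec) -> RenderedScene:
    """Convenience: sample geometries and render them in one call."""
    return render_scene(sample_geometries(spec), spec)


# ---------------------------------------------------------------------------
# Periodic motion signals
# ---------------------------------------------------------------------------

@dataclass
class MotionSignalSpec:
    """Per-frame parameter series of a rotating sperm.

    The noise-free signal is ``baseline + amplitude * g(t)`` where ``g`` is a
    raised-cosine bump train of the given frequency with maximum 1, so the
    true (noise-free) peak value is ``baseline + amplitude``.  Defaults
    emulate a head-width series: 3.7 Hz rotation sampled at 60 fps for 2 s
    (120 frames), noise sd 5% of amplitude, 5% outlier frames at 3x
    amplitude.
    """

    frequency_hz: float = 3.7
    fps: float = 60.0
    duration_s: float = 2.0
    baseline: float = 10.0
    amplitude: float = 2.0
    noise_sd: float = 0.1
    outlier_rate: float = 0.05
    outlier_magnitude: float = 3.0  # in units of amplitude
    seed: Optional[int] = None

    @property
    def n_frames(self) -> int:
        n = self.fps * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("fps * duration must be an integer frame count")
        return int(round(n))

    def validate(self) -> None:
        if self.frequency_hz <= 0:
            raise ConfigurationError("frequency must be positive")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fps and duration must be positive")
        if not (0.0 <= self.outlier_rate < 0.5):
            raise ConfigurationError("outlier rate must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        self.n_frames


@dataclass
class MotionSignal:
    """One generated parameter series with its known true peak value."""

    values: np.ndarray
    timestamps: np.ndarray
    true_max: float
    outlier_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def generate_motion_signal(spec: MotionSignalSpec) -> MotionSignal:
    """Generate one seeded periodic parameter series.

    ``values[i] = baseline + amplitude * 0.5 * (1 - cos(2 pi f t_i)) +
    noise_i``, after which ``floor(rate * n)`` outlier frames receive a
    symmetric +-``magnitude * amplitude`` spike.
    """
    spec.validate()
    n = spec.n_frames
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n) / spec.fps
    bump = 0.5 * (1.0 - np.cos(2 * np.pi * spec.frequency_hz * t))
    values = spec.baseline + spec.amplitude * bump
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=n)
    outlier_mask = np.zeros(n, dtype=bool)
    m = int(spec.outlier_rate * n)
    if m > 0:
        idx = rng.choice(n, size=m, replace=False)
        signs = rng.choice([-1.0, 1.0], size=m)
        values = values.copy()
        values[idx] += signs * spec.outlier_magnitude * spec.amplitude
        outlier_mask[idx] = True
    return MotionSignal(
        values=values,
        timestamps=t,
        true_max=spec.baseline + spec.amplitude,
        outlier_mask=outlier_mask,
    )
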
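"""Measurement-accuracy enhancement for periodic parameter series.

A morphological parameter measured over a 2-s, 60-fps clip (120 frames)
oscillates with the sperm's helical rotation (~3.7 Hz), so its true value is
best represented by the peak of each rotation cycle.  A naive ``max`` over
the raw series is driven by segmentation outliers; this pipeline instead

1. extracts the local-maximum region of each cycle (peak index plus ``k``
   neighbours on each side),
2. removes outliers from the pooled region values with the 1.5-IQR fence,
3. Gaussian-smooths the surviving values within each region, and
4. returns the maximum of the smoothed values.

The stage order (local-maximum extraction, outlier removal, Gaussian
filtering) is fixed; all intermediates are retained for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EnhancementConfig",
    "ParameterSeries",
    "PeakRegionSet",
    "EnhancedEstimate",
    "extract_peak_regions",
    "iqr_filter",
    "gaussian_kernel",
    "gaussian_smooth",
    "robust_max",
    "enhance",
    "relative_error",
    "error_reduction",
    "is_rapidly_progressive",
]

#: WHO velocity threshold (um/s at 37 C) above which a sperm is rapidly progressive.
RAPID_PROGRESSIVE_UM_PER_S = 25.0


@dataclass
class ParameterSeries:
    """Per-frame values of one morphological parameter."""

    parameter: str
    values: np.ndarray
    fps: float = 60.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("series values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EnhancementConfig:
    """Tunables of the enhancement pipeline.

    ``k`` is the peak-region half-size (region length 2k+1); ``s`` and
    ``sigma`` the Gaussian window half-size and standard deviation; the IQR
    multiplier is the conventional 1.5; ``min_separation`` is the minimum
    frame distance between retained peaks, defaulting to one rotation period
    ``round(fps / f)`` at f = 3.7 Hz and 60 fps.

    ``sigma`` defaults to 0.7: the dominance simulation (see
    docs/methods.md) shows it is the strongest smoothing whose attenuation
    of a clean 3.7 Hz peak sampled at 60 fps stays within 2% of the
    oscillation amplitude.
    """

    k: int = 2
    s: int = 2
    sigma: float = 0.7
    iqr_multiplier: float = 1.5
    min_separation: Optional[int] = None  # None -> round(fps / 3.7)
    per_region_iqr: bool = False

    def validate(self) -> None:
        if self.k < 1 or self.s < 1:
            raise ValueError("k and s must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def separation_for(self, fps: float) -> int:
        if self.min_separation is not None:
            return self.min_separation
        return max(1, int(round(fps / 3.7)))


@dataclass
class PeakRegionSet:
    """Local-maximum regions X' extracted from a series."""

    regions: list[np.ndarray]  # per-region value arrays (views into X)
    peak_indices: np.ndarray  # frame index of each region's centre
    k: int

    @property
    def n_cycles(self) -> int:
        return len(self.regions)

    def pooled(self) -> np.ndarray:
        if not self.regions:
            return np.empty(0)
        return np.concatenate(self.regions)


@dataclass
class EnhancedEstimate:
    """Robust maximum Y with the audit trail of every stage."""

    parameter: str
    y: float
    x: np.ndarray  # raw series X
    regions: PeakRegionSet  # X'
    x_filtered: list[np.ndarray] = field(default_factory=list)  # X'' per region
    x_smoothed: list[np.ndarray] = field(default_factory=list)  # X''' per region
    stage_order: tuple[str, ...] = (
        "local_maximum_extraction",
        "outlier_removal",
        "gaussian_filtering",
        "maximum_extraction",
    )


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Strict interior local maxima; a plateau counts once, at its leftmost index."""
    n = len(values)
    peaks = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[i]:
                j += 1
            if j < n - 1 and values[j + 1] < values[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def extract_peak_regions(series: ParameterSeries,
                         cfg: EnhancementConfig | None = None) -> PeakRegionSet:
    """Find one local-maximum region per rotation cycle.

    Peaks closer than the minimum separation are pruned keeping the larger
    value (lower index on ties); each surviving peak is expanded to the
    window of ``k`` neighbours on each side, truncated at the series edges.
    """
    cfg = cfg or EnhancementConfig()
    cfg.validate()
    x = series.values
    if len(x) < 2 * cfg.k + 1:
        raise ValueError("series shorter than one peak region (2k+1)")
    cand = _local_maxima(x)
    if len(cand) == 0:
        warnings.warn("no interior local maxima; falling back to the global maximum")
        return PeakRegionSet(regions=[], peak_indices=np.empty(0, dtype=int), k=cfg.k)
    sep = cfg.separation_for(series.fps)
    order = sorted(cand, key=lambda i: (-x[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= sep for j in kept):
            kept.append(i)
    kept.sort()
    regions = [x[max(0, i - cfg.k): min(len(x), i + cfg.k + 1)].copy() for i in kept]
    return PeakRegionSet(regions=regions, peak_indices=np.asarray(kept), k=cfg.k)


def iqr_filter(values: Sequence[float], multiplier: float = 1.5) -> np.ndarray:
    """Keep values inside the closed fence [Q1 - m*IQR, Q3 + m*IQR].

    Quartiles use the linear-interpolation convention (numpy's default).
    Fewer than 4 values pass through unchanged with a warning; order is
    preserved.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; IQR filter passes data through")
        return values.copy()
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return values[(values >= lo) & (values <= hi)]


def gaussian_kernel(s: int, sigma: float) -> np.ndarray:
    """Normalized Gaussian weights G(j), j = -s..s, summing to 1."""
    j = np.arange(-s, s + 1, dtype=float)
    g = np.exp(-(j**2) / (2.0 * sigma**2))
    return g / g.sum()


def gaussian_smooth(values: Sequence[float], s: int = 2, sigma: float = 1.0) -> np.ndarray:
    """Gaussian-weighted moving average with edge renormalization.

    At positions nearer than ``s`` to a boundary the window is truncated and
    the weights renormalized to sum 1, so a constant input is reproduced
    exactly and the output stays inside [min, max] of the input.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("cannot smooth an empty sequence")
    g = gaussian_kernel(s, sigma)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - s)
        hi = min(n, i + s + 1)
        w = g[lo - i + s: hi - i + s]
        out[i] = np.dot(w, values[lo:hi]) / w.sum()
    return out


def robust_max(smoothed_regions: Sequence[np.ndarray],
               fallback: Optional[np.ndarray] = None) -> float:
    """Y = maximum over all smoothed region values.

    If every region was emptied by filtering, falls back to the maximum of
    ``fallback`` (the pre-smoothing values) with a warning.
    """
    pools = [np.asarray(r) for r in smoothed_regions if np.asarray(r).size > 0]
    if not pools:
        if fallback is not None and np.asarray(fallback).size > 0:
            warnings.warn("all regions empty after filtering; using unsmoothed maximum")
            return float(np.max(fallback))
        raise ValueError("no values available for maximum extraction")
    return float(max(np.max(p) for p in pools))


def enhance(series: ParameterSeries,
            cfg: EnhancementConfig | None = None) -> EnhancedEstimate:
    """Run the full enhancement pipeline on one parameter series.

    Stages run in the fixed order: local-maximum extraction, IQR outlier
    removal (on the pooled region values by default), within-region Gaussian
    smoothing, maximum extraction.  Falls back to the raw global maximum when
    the series has no interior local maxima (e.g. a monotone series).
    """
    cfg = cfg or EnhancementConfig()
    cfg.validate()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        region_set = extract_peak_regions(series, cfg)
    if region_set.n_cycles == 0:
        y = float(np.max(series.values))
        return EnhancedEstimate(parameter=series.parameter, y=y,
                                x=series.values, regions=region_set)

    if cfg.per_region_iqr:
        filtered = [iqr_filter(r, cfg.iqr_multiplier) for r in region_set.regions]
    else:
        pooled = region_set.pooled()
        if pooled.size < 4:
            keep_lo, keep_hi = -np.inf, np.inf
        else:
            q1, q3 = np.percentile(pooled, [25, 75])
            iqr = q3 - q1
            keep_lo = q1 - cfg.iqr_multiplier * iqr
            keep_hi = q3 + cfg.iqr_multiplier * iqr
        filtered = [r[(r >= keep_lo) & (r <= keep_hi)] for r in region_set.regions]

    smoothed = [gaussian_smooth(r, cfg.s, cfg.sigma) if r.size else r.copy()
                for r in filtered]
    y = robust_max(smoothed, fallback=region_set.pooled())
    return EnhancedEstimate(parameter=series.parameter, y=y, x=series.values,
                            regions=region_set, x_filtered=filtered,
                            x_smoothed=smoothed)


# ---------------------------------------------------------------------------
# Error reporting
# ---------------------------------------------------------------------------

def relative_error(measured: float, ground_truth: float) -> float:
    """|V_M - V_GT| / V_GT * 100, in percent."""
    if ground_truth == 0:
        raise ZeroDivisionError("relative error undefined for zero ground truth")
    return abs(measured - ground_truth) / abs(ground_truth) * 100.0


def error_reduction(before_pct: float, after_pct: float) -> float:
    """(before - after) / before * 100, rounded to one decimal for reports."""
    if before_pct <= 0:
        raise ValueError("error reduction requires a positive 'before' error")
    return round((before_pct - after_pct) / before_pct * 100.0, 1)


def is_rapidly_progressive(velocity_um_per_s: float) -> bool:
    """WHO criterion: strictly greater than 25 um/s at 37 C."""
    if velocity_um_per_s < 0:
        raise ValueError("velocity must be non-negative")
    return velocity_um_per_s > RAPID_PROGRESSIVE_UM_PER_S
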
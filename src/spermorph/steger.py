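"""Sub-pixel centerline extraction for curvilinear structures (Steger's method).

The detector treats the image as a differentiable intensity surface: at every
pixel the Hessian of the Gaussian-smoothed image is diagonalized, the
eigenvector of the largest-magnitude eigenvalue giving the direction normal
to the line.  A pixel is a line point when the first directional derivative
along that normal vanishes within half a pixel of the pixel centre; solving
the first-order Taylor expansion gives the sub-pixel position.  Line points
are then linked into an ordered polyline by greedy, orientation-consistent
extension from the strongest response, and a per-point line width is
estimated along the normal.

For binary masks (the usual input here: a tail mask produced by the parsing
network) the Euclidean distance transform of the mask serves as the ridge
image and the local width is twice the interpolated distance-transform
value, which is exact for a tube of constant width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import polyline_length, chord_angle_deg


class EmptyCenterlineError(RuntimeError):
    """No ridge points above threshold were found."""


@dataclass
class Centerline:
    """Ordered sub-pixel line points with per-point width."""

    points: np.ndarray  # (N, 2) float (row, col)
    widths: np.ndarray  # (N,) float, px

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if len(self.points) < 2:
            raise EmptyCenterlineError("a centerline needs at least 2 points")

    @property
    def arc_length(self) -> float:
        return polyline_length(self.points)

    @property
    def mean_width(self) -> float:
        w = self.widths[np.isfinite(self.widths) & (self.widths > 0)]
        return float(np.mean(w)) if w.size else float("nan")

    def end_chord_angle_deg(self, frac: float = 0.15) -> float:
        return chord_angle_deg(self.points, frac)


def _hessian_ridge(image: np.ndarray, sigma: float):
    """Gaussian derivatives, principal normals and ridge response (bright lines)."""
    img = image.astype(float)
    rr = ndimage.gaussian_filter(img, sigma, order=(2, 0), mode="nearest")
    cc = ndimage.gaussian_filter(img, sigma, order=(0, 2), mode="nearest")
    rc = ndimage.gaussian_filter(img, sigma, order=(1, 1), mode="nearest")
    dr = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    dc = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")

    # eigen-decomposition of [[rr, rc], [rc, cc]], analytic for 2x2 symmetric
    half_trace = 0.5 * (rr + cc)
    disc = np.sqrt(np.maximum(0.25 * (rr - cc) ** 2 + rc**2, 0.0))
    lam1 = half_trace + disc
    lam2 = half_trace - disc  # most negative across a bright line
    # eigenvector for lam2: (rc, lam2 - rr), guarded for the diagonal case
    nr = np.where(np.abs(rc) > 1e-12, rc, np.where(rr <= cc, 1.0, 0.0))
    nc = np.where(np.abs(rc) > 1e-12, lam2 - rr, np.where(rr <= cc, 0.0, 1.0))
    norm = np.hypot(nr, nc)
    norm[norm == 0] = 1.0
    nr, nc = nr / norm, nc / norm
    response = -lam2  # large where a bright ridge crosses
    return dr, dc, lam1, lam2, nr, nc, response


def _bilinear(arr: np.ndarray, p: np.ndarray) -> float:
    r = float(np.clip(p[0], 0, arr.shape[0] - 1))
    c = float(np.clip(p[1], 0, arr.shape[1] - 1))
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, arr.shape[0] - 1), min(c0 + 1, arr.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return float(
        arr[r0, c0] * (1 - fr) * (1 - fc)
        + arr[r1, c0] * fr * (1 - fc)
        + arr[r0, c1] * (1 - fr) * fc
        + arr[r1, c1] * fr * fc
    )


def _link_points(cand: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, float]]
                 ) -> list[tuple[int, int]]:
    """Greedy orientation-consistent linking starting from the peak response.

    ``cand`` maps pixel -> (sub-pixel point, unit tangent, response).  From
    the strongest point the chain is extended in both directions; at each
    step the unused 8-neighbour minimizing the orientation change (and not
    doubling back) is chosen.
    """
    seed = max(cand, key=lambda k: cand[k][2])
    used = {seed}

    def grow(direction_sign: float) -> list[tuple[int, int]]:
        chain = []
        cur = seed
        tangent = cand[seed][1] * direction_sign
        while True:
            best, best_cost = None, None
            r, c = cur
            for radius in (1, 2):  # radius 2 bridges single-pixel dropouts
                for drr in range(-radius, radius + 1):
                    for dcc in range(-radius, radius + 1):
                        if max(abs(drr), abs(dcc)) != radius:
                            continue
                        nxt = (r + drr, c + dcc)
                        if nxt == cur or nxt in used or nxt not in cand:
                            continue
                        step = cand[nxt][0] - cand[cur][0]
                        ns = np.linalg.norm(step)
                        if ns == 0:
                            continue
                        step = step / ns
                        if np.dot(step, tangent) < 0.2:  # no doubling back
                            continue
                        t_next = cand[nxt][1]
                        if np.dot(t_next, tangent) < 0:
                            t_next = -t_next
                        cost = 1.0 - np.dot(t_next, tangent)  # smallest turn
                        if best_cost is None or cost < best_cost:
                            best, best_cost, best_t = nxt, cost, t_next
                if best is not None:
                    break
            if best is None:
                return chain
            used.add(best)
            chain.append(best)
            tangent = best_t
            cur = best

    forward = grow(1.0)
    backward = grow(-1.0)
    return list(reversed(backward)) + [seed] + forward


def _width_from_gradient(image: np.ndarray, point: np.ndarray, normal: np.ndarray,
                         sigma: float, w_max: float) -> float:
    """Line width from the gradient-magnitude extrema along the normal."""
    gr = ndimage.gaussian_filter(image.astype(float), sigma, order=(1, 0), mode="nearest")
    gc = ndimage.gaussian_filter(image.astype(float), sigma, order=(0, 1), mode="nearest")
    gm = np.hypot(gr, gc)
    ts = np.arange(0.2, w_max + 2 * sigma, 0.1)
    dists = []
    for sign in (1.0, -1.0):
        prof = np.array([_bilinear(gm, point + sign * t * normal) for t in ts])
        i = int(np.argmax(prof))
        # parabolic sub-sample refinement
        if 0 < i < len(prof) - 1:
            denom = prof[i - 1] - 2 * prof[i] + prof[i + 1]
            shift = 0.5 * (prof[i - 1] - prof[i + 1]) / denom if denom != 0 else 0.0
            dists.append(ts[i] + np.clip(shift, -0.5, 0.5) * 0.1)
        else:
            dists.append(ts[i])
    return float(dists[0] + dists[1])


def steger_centerline(
    image: np.ndarray,
    width_range_px: tuple[float, float] = (2.0, 6.0),
    sigma: float | None = None,
    rel_threshold: float = 0.25,
    extend_to_boundary: bool = True,
) -> Centerline:
    """Extract the sub-pixel centerline of a single curvilinear structure.

    Parameters
    ----------
    image
        Either a float intensity image containing a bright line or a binary
        mask of the structure (detected by dtype); masks are converted to
        their Euclidean distance transform first.
    width_range_px
        Expected (min, max) full line width; sets the derivative scale
        ``sigma >= w/sqrt(3)`` for half-width ``w`` unless ``sigma`` is given.
    rel_threshold
        Ridge points must exceed this fraction of the maximum ridge response.
    extend_to_boundary
        In mask mode, prolong the two chain ends along their tangents while
        still inside the mask, compensating the response fall-off at tips.
    """
    image = np.asarray(image)
    mask_mode = image.dtype == bool or set(np.unique(image)) <= {0, 1}
    if mask_mode:
        mask = image.astype(bool)
        if not mask.any():
            raise EmptyCenterlineError("empty input mask")
        work = ndimage.distance_transform_edt(mask)
    else:
        mask = None
        work = image.astype(float)

    w_half = 0.5 * 0.5 * (width_range_px[0] + width_range_px[1])
    if sigma is None:
        sigma = max(1.0, w_half / np.sqrt(3.0))

    dr, dc, lam1, lam2, nr, nc, response = _hessian_ridge(work, sigma)
    thresh = rel_threshold * response.max()
    if thresh <= 0:
        raise EmptyCenterlineError("no ridge response in input")

    num = dr * nr + dc * nc
    den = lam2  # n^T H n for the unit eigenvector of lam2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.abs(den) > 1e-12, -num / den, np.nan)
        pr = t * nr
        pc = t * nc
    valid = (
        (response > thresh) & np.isfinite(pr) & np.isfinite(pc)
        & (np.abs(pr) <= 0.5) & (np.abs(pc) <= 0.5) & (lam2 < 0)
    )

    rows, cols = np.nonzero(valid)
    if rows.size < 2:
        raise EmptyCenterlineError("no ridge points above threshold")
    cand = {}
    for r, c in zip(rows, cols):
        point = np.array([r + pr[r, c], c + pc[r, c]])
        tangent = np.array([-nc[r, c], nr[r, c]])  # perpendicular to the normal
        cand[(r, c)] = (point, tangent, response[r, c])

    chain = _link_points(cand)
    if len(chain) < 2:
        raise EmptyCenterlineError("could not link ridge points into a line")
    points = np.array([cand[p][0] for p in chain])

    if mask_mode and extend_to_boundary:
        points = _trim_caps(_extend_ends(points, work), work)

    if mask_mode:
        # Background pixel centres sit ~0.5 px beyond the true boundary, so
        # the distance transform overestimates the half-width by ~0.5 px.
        widths = np.array([max(2.0 * _bilinear(work, p) - 1.0, 0.0) for p in points])
    else:
        normals = _chain_normals(points)
        widths = np.array([
            _width_from_gradient(work, p, n, sigma, width_range_px[1])
            for p, n in zip(points, normals)
        ])
    return Centerline(points=points, widths=widths)


def _chain_normals(points: np.ndarray) -> np.ndarray:
    grad = np.gradient(points, axis=0)
    norm = np.linalg.norm(grad, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangents = grad / norm
    return np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)


def _extend_ends(points: np.ndarray, dist: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Prolong both chain ends along their local tangents up to the line tips.

    The ridge response decays near the ends of an open line, so linking stops
    short of the tips.  Each end is extended along its tangent while the
    distance transform stays at the local ridge level; once it drops below
    that level the extension has entered the rounded end cap and stops.
    """
    k = min(4, len(points) - 1)
    ridge_level = float(np.median([_bilinear(dist, p) for p in points]))

    def extend(p_end: np.ndarray, p_prev: np.ndarray) -> list[np.ndarray]:
        d = p_end - p_prev
        n = np.linalg.norm(d)
        if n == 0:
            return []
        d = d / n
        out = []
        cur = p_end.copy()
        for _ in range(400):
            nxt = cur + step * d
            if _bilinear(dist, nxt) < ridge_level - 0.35:
                break
            out.append(nxt)
            cur = nxt
        return out

    head = extend(points[0], points[k])
    tail = extend(points[-1], points[-1 - k])
    return np.concatenate([np.array(head[::-1]).reshape(-1, 2), points,
                           np.array(tail).reshape(-1, 2)])


def _trim_caps(points: np.ndarray, dist: np.ndarray, drop: float = 0.35) -> np.ndarray:
    """Drop chain ends that wandered into the rounded end caps of the tube.

    On the ridge proper the distance transform sits at the local half-width;
    inside an end cap it decays towards the tip.  Points at either end whose
    interpolated distance lies more than ``drop`` below the chain's median
    ridge level are removed, so the chain spans cap centre to cap centre.
    """
    level = float(np.median([_bilinear(dist, p) for p in points]))
    vals = np.array([_bilinear(dist, p) for p in points])
    keep = vals >= level - drop
    lo = 0
    while lo < len(points) and not keep[lo]:
        lo += 1
    hi = len(points)
    while hi > lo and not keep[hi - 1]:
        hi -= 1
    if hi - lo >= 2:
        return points[lo:hi]
    return points
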
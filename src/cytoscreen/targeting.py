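"""Bright-spot nucleus targeting: autofocus, stitching, detection, routing.

The workflow mirrors an automated cytology microscope: sweep the focus to
find the plane where nucleus "microlens" bright spots maximise image
contrast, tile the slide with overlapping frames, stitch them, detect the
spots as local maxima, keep the most isolated candidates, map their pixel
positions to stage coordinates, and order them into a short acquisition
route.

Conventions: pixel coordinates are 0-based ``(row, col)``; stage
coordinates are µm with x right and y up; :class:`AffineMap2D` owns all
sign conventions between the two frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .phantom import ImageTile

__all__ = [
    "VarianceProfile",
    "FocusResult",
    "CandidateSet",
    "AffineMap2D",
    "TargetList",
    "ScanRangeError",
    "variance_metric",
    "autofocus",
    "stitch_grid",
    "detect_bright_spots",
    "select_isolated",
    "order_route",
    "fit_pixel_to_stage",
    "apply_laser_offset",
]


class ScanRangeError(RuntimeError):
    """The focus scan did not bracket the contrast extrema."""


@dataclass
class VarianceProfile:
    """Focus positions paired with the image-contrast metric."""

    z: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.z.shape != self.metric.shape or self.z.ndim != 1:
            raise ValueError("z and metric must be equal-length 1-D arrays")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")


@dataclass(frozen=True)
class FocusResult:
    z_bright_spot: float
    z_focus: float


@dataclass
class CandidateSet:
    """Detected bright-spot candidates in the mosaic pixel frame."""

    points: np.ndarray  # (n, 2) of (row, col)
    score: np.ndarray  # peak intensity per candidate
    isolation: np.ndarray = field(default=None)  # px distance to nearest other

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.score = np.asarray(self.score, dtype=float).reshape(-1)
        if len(self.score) != len(self.points):
            raise ValueError("score length must match points")
        if self.isolation is None:
            self.isolation = _nearest_neighbour_distances(self.points)
        else:
            self.isolation = np.asarray(self.isolation, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class AffineMap2D:
    """Map ``stage = A @ (row, col) + t`` from mosaic pixels to stage µm."""

    linear: np.ndarray  # 2x2, µm/px
    translation: np.ndarray  # 2, µm
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        A = np.asarray(self.linear, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) < 1e-15:
            raise ValueError("affine linear part must be invertible")
        object.__setattr__(self, "linear", A)
        object.__setattr__(self, "translation", t)

    def __call__(self, pixel_pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pixel_pts, dtype=float).reshape(-1, 2)
        return pts @ self.linear.T + self.translation

    def inverse(self, stage_pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(stage_pts, dtype=float).reshape(-1, 2)
        return (pts - self.translation) @ np.linalg.inv(self.linear).T


@dataclass
class TargetList:
    """Ordered stage coordinates queued for acquisition, with provenance."""

    stage_xy: np.ndarray  # (n, 2) µm, in visit order
    pixel_rc: np.ndarray | None = None  # (n, 2) source mosaic pixels
    order: np.ndarray | None = None  # permutation applied to the input points

    def __post_init__(self) -> None:
        self.stage_xy = np.asarray(self.stage_xy, dtype=float).reshape(-1, 2)
        if self.pixel_rc is not None:
            self.pixel_rc = np.asarray(self.pixel_rc, dtype=float).reshape(-1, 2)
        if self.order is not None:
            self.order = np.asarray(self.order, dtype=int).reshape(-1)

    def __len__(self) -> int:
        return len(self.stage_xy)

    def travel_length(self, start: tuple[float, float] | None = None) -> float:
        pts = self.stage_xy
        if len(pts) == 0:
            return 0.0
        total = 0.0
        prev = np.asarray(start, dtype=float) if start is not None else pts[0]
        for p in pts:
            total += float(np.hypot(*(p - prev)))
            prev = p
        return total


# ---------------------------------------------------------------------------
# Autofocus


def variance_metric(img: ImageTile | np.ndarray) -> float:
    """Image contrast as variance over mean, σ²/µ (population σ).

    Spots concentrated above a flat background raise the variance much faster
    than the mean, so this peaks at the bright-spot plane.
    """
    pixels = img.pixels if isinstance(img, ImageTile) else np.asarray(img, dtype=float)
    if pixels.size == 0:
        raise ValueError("empty image")
    mu = float(pixels.mean())
    if mu <= 0:
        raise ValueError(f"variance metric undefined for mean {mu}")
    return float(pixels.var() / mu)


def autofocus(profile: VarianceProfile) -> FocusResult:
    """Locate the bright-spot plane (global contrast maximum) and the focal
    plane (interior contrast minimum nearest the bright-spot plane).

    Ties between equally near minima break toward smaller ``|z|``; a maximum
    on the scan boundary means the scan did not bracket the bright-spot
    plane and raises :class:`ScanRangeError`.
    """
    z, m = profile.z, profile.metric
    if len(z) < 5:
        raise ValueError("autofocus needs at least 5 focus samples")
    order = np.argsort(z)
    z, m = z[order], m[order]

    i_max = int(np.argmax(m))
    if i_max in (0, len(z) - 1):
        raise ScanRangeError(
            f"contrast maximum at scan boundary z={z[i_max]:.2f}; extend the z range"
        )
    z_bright = float(z[i_max])

    interior = np.arange(1, len(z) - 1)
    is_min = (m[interior] <= m[interior - 1]) & (m[interior] <= m[interior + 1])
    # collapse plateau minima to a single representative (plateau midpoint)
    mins = interior[is_min]
    if len(mins) == 0:
        raise ScanRangeError("no interior local minimum of contrast in the scan")
    dist = np.abs(z[mins] - z_bright)
    best = dist == dist.min()
    cand = mins[best]
    if len(cand) > 1:
        cand = cand[np.argsort(np.abs(z[cand]), kind="stable")]
    return FocusResult(z_bright_spot=z_bright, z_focus=float(z[cand[0]]))


# ---------------------------------------------------------------------------
# Stitching


def _grid_layout(tiles: list[ImageTile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive (rows, cols) grid indices from tile stage positions."""
    xs = np.array([t.stage_xy[0] for t in tiles])
    ys = np.array([t.stage_xy[1] for t in tiles])
    tol = 1e-6 + 0.25 * tiles[0].pixel_size * max(tiles[0].pixels.shape)

    def classes(vals: np.ndarray) -> np.ndarray:
        uniq: list[float] = []
        out = np.empty(len(vals), dtype=int)
        for i, v in enumerate(vals):
            for j, u in enumerate(uniq):
                if abs(v - u) <= tol:
                    out[i] = j
                    break
            else:
                uniq.append(v)
                out[i] = len(uniq) - 1
        ranks = np.argsort(np.argsort(uniq))
        return np.array([ranks[c] for c in out])

    gx = classes(xs)  # column index grows with x
    gy_raw = classes(ys)
    gy = gy_raw.max() - gy_raw  # row index grows with decreasing y
    n_expected = (gx.max() + 1) * (gy.max() + 1)
    key = gy * (gx.max() + 1) + gx
    if n_expected != len(tiles) or len(set(key.tolist())) != len(tiles):
        raise ValueError("tile stage positions do not form a full rectangular grid")
    return gy, gx, key


def _phase_peak_ratio(ref: np.ndarray, mov: np.ndarray) -> float:
    """Confidence of the overlap registration: highest phase-correlation peak
    over the highest secondary peak.  Near 1 for featureless or inconsistent
    overlaps; large when the strips share real structure."""
    F1, F2 = np.fft.fft2(ref - ref.mean()), np.fft.fft2(mov - mov.mean())
    cross = F1 * np.conj(F2)
    denom = np.abs(cross)
    denom[denom == 0] = 1.0
    corr = np.abs(np.fft.ifft2(cross / denom))
    peak = float(corr.max())
    pr, pc = np.unravel_index(int(np.argmax(corr)), corr.shape)
    masked = corr.copy()
    masked[max(pr - 2, 0):pr + 3, max(pc - 2, 0):pc + 3] = 0.0
    secondary = float(masked.max())
    return peak / secondary if secondary > 0 else np.inf


def _ncc_shift(ref: np.ndarray, mov: np.ndarray,
               center: tuple[int, int] = (0, 0), search: int = 6) -> np.ndarray:
    """Shift of ``mov`` relative to ``ref`` by normalised cross-correlation
    over a +/-``search`` px window around ``center``, refined to sub-pixel by
    a parabolic fit.

    Direct spatial NCC localises correctly on smooth, band-limited content
    (diffuse bright spots) where spectral phase methods lock onto window
    edges; the strips are already coarsely aligned by the stage geometry, so
    a small search window around the nominal residual shift suffices.
    """
    h, w = ref.shape
    cr0, cc0 = int(round(center[0])), int(round(center[1]))
    sr = min(search, max(1, h // 3))
    sc = min(search, max(1, w // 3))
    rows = range(cr0 - sr, cr0 + sr + 1)
    cols = range(cc0 - sc, cc0 + sc + 1)
    surface = np.full((len(rows), len(cols)), -np.inf)
    for i_r, dr in enumerate(rows):
        for i_c, dc in enumerate(cols):
            a = ref[max(dr, 0):h + min(dr, 0), max(dc, 0):w + min(dc, 0)]
            b = mov[max(-dr, 0):h + min(-dr, 0), max(-dc, 0):w + min(-dc, 0)]
            if a.size < 0.25 * ref.size:
                continue
            da = a - a.mean()
            db = b - b.mean()
            denom = np.sqrt((da * da).sum() * (db * db).sum())
            if denom > 0:
                surface[i_r, i_c] = (da * db).sum() / denom

    pr, pc = np.unravel_index(int(np.argmax(surface)), surface.shape)

    def parabola(vals: np.ndarray, i: int) -> float:
        if i <= 0 or i >= len(vals) - 1 or not np.all(np.isfinite(vals[i - 1:i + 2])):
            return float(i)
        c0, c1, c2 = vals[i - 1], vals[i], vals[i + 1]
        denom = c0 - 2 * c1 + c2
        return float(i) + (0.5 * (c0 - c2) / denom if denom < 0 else 0.0)

    dr = parabola(surface[:, pc], pr) + (cr0 - sr)
    dc = parabola(surface[pr, :], pc) + (cc0 - sc)
    # (dr, dc) place mov's origin at ref's origin + (dr, dc) in mosaic frame
    return np.array([dr, dc])


def stitch_grid(
    tiles: list[ImageTile],
    nominal_overlap: float,
    peak_ratio_min: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stitch a rectangular grid of overlapping tiles into one mosaic.

    Registration is translation-only: initial per-tile offsets come from the
    commanded stage positions, then each adjacent pair is refined by phase
    correlation on its overlap strip.  A refinement whose correlation peak
    ratio falls below ``peak_ratio_min`` (featureless overlap) is discarded
    in favour of the nominal offset.  Overlaps are blended by a feathered
    average.

    Returns ``(mosaic, offsets)`` where ``offsets[i]`` is the (row, col)
    pixel position of tile ``i``'s top-left corner in the mosaic.
    """
    if not tiles:
        raise ValueError("no tiles")
    shape = tiles[0].pixels.shape
    px = tiles[0].pixel_size
    for t in tiles:
        if t.pixels.shape != shape or t.pixel_size != px or t.z != tiles[0].z:
            raise ValueError("tiles must share shape, pixel size and focus")
    if len(tiles) == 1:
        return tiles[0].pixels.copy(), np.zeros((1, 2))

    gy, gx, _ = _grid_layout(tiles)
    n_rows, n_cols = gy.max() + 1, gx.max() + 1
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(gy, gx))}
    H, W = shape

    # nominal offsets from stage positions (row grows with -y, col with +x)
    x0 = min(t.stage_xy[0] for t in tiles)
    y0 = max(t.stage_xy[1] for t in tiles)
    nominal = np.array(
        [[(y0 - t.stage_xy[1]) / px, (t.stage_xy[0] - x0) / px] for t in tiles]
    )

    offsets = np.full((len(tiles), 2), np.nan)
    offsets[index[(0, 0)]] = (0.0, 0.0)
    for r in range(n_rows):
        for c in range(n_cols):
            i = index[(r, c)]
            if not np.any(np.isnan(offsets[i])):
                continue
            if c > 0:
                j = index[(r, c - 1)]
                rel_nom = nominal[i] - nominal[j]
                # strips span the nominally overlapping region (plus margin),
                # which the stage geometry fixes per pair
                ov = int(np.clip(W - np.floor(rel_nom[1]) + 4, 2, W))
                strip_ref = tiles[j].pixels[:, W - ov:]
                strip_mov = tiles[i].pixels[:, :ov]
                rel = _refine_pair(strip_ref, strip_mov, rel_nom,
                                   base=(0.0, float(W - ov)), ratio_min=peak_ratio_min)
            else:
                j = index[(r - 1, c)]
                rel_nom = nominal[i] - nominal[j]
                ov = int(np.clip(H - np.floor(rel_nom[0]) + 4, 2, H))
                strip_ref = tiles[j].pixels[H - ov:, :]
                strip_mov = tiles[i].pixels[:ov, :]
                rel = _refine_pair(strip_ref, strip_mov, rel_nom,
                                   base=(float(H - ov), 0.0), ratio_min=peak_ratio_min)
            offsets[i] = offsets[j] + rel

    offsets -= offsets.min(axis=0)
    out_h = int(np.ceil(offsets[:, 0].max())) + H
    out_w = int(np.ceil(offsets[:, 1].max())) + W
    mosaic = np.zeros((out_h, out_w))
    weight = np.zeros((out_h, out_w))

    feather_r = np.minimum(np.arange(H) + 1, np.arange(H)[::-1] + 1).astype(float)
    feather_c = np.minimum(np.arange(W) + 1, np.arange(W)[::-1] + 1).astype(float)
    w_tile = np.minimum(np.outer(feather_r, np.ones(W)), np.outer(np.ones(H), feather_c))
    for i, t in enumerate(tiles):
        r0 = int(round(offsets[i, 0]))
        c0 = int(round(offsets[i, 1]))
        mosaic[r0:r0 + H, c0:c0 + W] += t.pixels * w_tile
        weight[r0:r0 + H, c0:c0 + W] += w_tile
    mosaic = np.divide(mosaic, weight, out=mosaic, where=weight > 0)
    return mosaic, offsets


def _refine_pair(
    strip_ref: np.ndarray,
    strip_mov: np.ndarray,
    rel_nominal: np.ndarray,
    base: tuple[float, float],
    ratio_min: float,
) -> np.ndarray:
    """Relative tile offset refined on an overlap strip, or the nominal one."""
    if strip_ref.std() == 0 or strip_mov.std() == 0:
        return rel_nominal
    if _phase_peak_ratio(strip_ref, strip_mov) < ratio_min:
        return rel_nominal
    center = np.asarray(rel_nominal) - np.asarray(base)
    refined = np.asarray(base) + _ncc_shift(strip_ref, strip_mov,
                                            center=(center[0], center[1]))
    # trust the refinement only near the nominal geometry (guards against
    # locking onto a periodic feature one spot-spacing away)
    if np.any(np.abs(refined - rel_nominal) > 0.3 * max(strip_ref.shape)):
        return rel_nominal
    return refined


# ---------------------------------------------------------------------------
# Detection, isolation, routing, geometry


def detect_bright_spots(
    mosaic: np.ndarray,
    sigma: float = 4.0,
    min_distance: int = 8,
    prominence: float = 0.25,
) -> CandidateSet:
    """Detect bright-spot candidates as local maxima of the smoothed mosaic.

    After Gaussian smoothing with ``sigma`` px, local maxima that exceed
    ``background + prominence * (max - background)`` (background = median of
    the smoothed image) and are at least ``min_distance`` px apart are kept;
    plateau maxima are reduced to their centroid.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    img = np.asarray(mosaic, dtype=float)
    sm = ndi.gaussian_filter(img, sigma) if sigma > 0 else img
    background = float(np.median(sm))
    peak = float(sm.max())
    noise_sd = 1.4826 * float(np.median(np.abs(sm - background)))
    if peak - background <= max(6.0 * noise_sd, 0.0) or peak <= background:
        # dynamic range indistinguishable from smoothed camera noise: an
        # empty field must not sprout candidates
        return CandidateSet(points=np.empty((0, 2)), score=np.empty(0),
                            isolation=np.empty(0))
    threshold = background + prominence * (peak - background)

    size = 2 * min_distance + 1
    is_max = (sm == ndi.maximum_filter(sm, size=size)) & (sm >= threshold)
    labels, n_lab = ndi.label(is_max)
    if n_lab == 0:
        return CandidateSet(points=np.empty((0, 2)), score=np.empty(0),
                            isolation=np.empty(0))
    centroids = np.asarray(ndi.center_of_mass(is_max, labels, range(1, n_lab + 1)))
    scores = np.asarray(ndi.maximum(sm, labels, range(1, n_lab + 1)), dtype=float)

    # enforce min_distance between surviving candidates, strongest first
    order = np.argsort(-scores, kind="stable")
    kept: list[int] = []
    for i in order:
        if all(np.hypot(*(centroids[i] - centroids[j])) >= min_distance for j in kept):
            kept.append(i)
    kept_arr = np.array(sorted(kept), dtype=int)
    return CandidateSet(points=centroids[kept_arr], score=scores[kept_arr])


def _nearest_neighbour_distances(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < 2:
        return np.full(n, np.inf)
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def select_isolated(cs: CandidateSet, n_keep: int) -> CandidateSet:
    """Keep the ``n_keep`` candidates farthest from their nearest neighbour.

    Clustered cells risk double targeting, so the most isolated candidates
    make the best spectra.  Ties break toward higher score, then lower
    (row, col).
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if len(cs) <= n_keep:
        return CandidateSet(points=cs.points.copy(), score=cs.score.copy())
    iso = _nearest_neighbour_distances(cs.points)
    key = sorted(
        range(len(cs)),
        key=lambda i: (-iso[i], -cs.score[i], cs.points[i, 0], cs.points[i, 1]),
    )
    kept = np.array(sorted(key[:n_keep]), dtype=int)
    return CandidateSet(points=cs.points[kept], score=cs.score[kept])


def order_route(points: np.ndarray, start: tuple[float, float] = (0.0, 0.0)) -> TargetList:
    """Greedy nearest-neighbour route over the points, seeded at ``start``.

    Limits total stage travel (and hence drift and acquisition time); ties go
    to the lowest input index.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("no points to route")
    remaining = list(range(len(pts)))
    current = np.asarray(start, dtype=float)
    order: list[int] = []
    while remaining:
        d = [float(np.hypot(*(pts[i] - current))) for i in remaining]
        j = int(np.argmin(d))  # argmin returns the first (lowest-index) tie
        order.append(remaining.pop(j))
        current = pts[order[-1]]
    order_arr = np.array(order, dtype=int)
    return TargetList(stage_xy=pts[order_arr], order=order_arr)


def fit_pixel_to_stage(pixel_pts: np.ndarray, stage_pts: np.ndarray) -> AffineMap2D:
    """Least-squares affine fit from mosaic pixel (row, col) to stage (x, y) µm.

    Accommodates per-axis scale, flips, rotation and skew.  Requires at least
    three non-collinear correspondences.
    """
    P = np.asarray(pixel_pts, dtype=float).reshape(-1, 2)
    S = np.asarray(stage_pts, dtype=float).reshape(-1, 2)
    if P.shape != S.shape or len(P) < 3:
        raise ValueError("need >= 3 matching pixel/stage correspondences")
    D = np.column_stack([P, np.ones(len(P))])
    if np.linalg.matrix_rank(D, tol=1e-9 * max(1.0, np.abs(D).max())) < 3:
        raise ValueError("correspondences are collinear; the affine map is underdetermined")
    coef, *_ = np.linalg.lstsq(D, S, rcond=None)
    A = coef[:2].T
    t = coef[2]
    resid = D @ coef - S
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineMap2D(linear=A, translation=t, rms_residual=rms)


def apply_laser_offset(tl: TargetList, offset: tuple[float, float]) -> TargetList:
    """Translate every target by the measured laser-spot offset (µm)."""
    off = np.asarray(offset, dtype=float).reshape(2)
    if not np.all(np.isfinite(off)):
        raise ValueError("laser offset must be finite")
    return TargetList(
        stage_xy=tl.stage_xy + off,
        pixel_rc=None if tl.pixel_rc is None else tl.pixel_rc.copy(),
        order=None if tl.order is None else tl.order.copy(),
    )
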
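"""Multi-threshold capillary segmentation with EDT pixel verification.

Each preprocessed level image is binarized (vessels are dark, so
foreground means intensity <= threshold).  For every binary image an
exact Euclidean distance transform supplies, per candidate pixel ``p``,
both the distance to and the coordinates of its nearest background
pixel ``b_p``.  The nearest background pixels ``b_j`` of the 24
neighbors in the 5x5 window around ``p`` then yield three features:

* diameter  ``d = max_j ||b_p - b_j||`` — the span between the two
  sides of the local structure; ``b_max`` is the maximizing pixel;
* angle ``theta`` — the angle at ``p`` in the triangle
  ``(b_p, p, b_max)`` by the cosine rule (opposite side ``d``, cosine
  clamped to [-1, 1]); large when ``b_p`` and ``b_max`` lie on opposite
  sides of a thin curvilinear structure;
* contrast ``C = GL(b_max) / GL(p)`` on the enhanced image — the
  intensity ratio across the structure, from the candidate to the
  opposite background pixel.

A candidate is verified as a capillary centerline pixel iff
``d < P_d`` (excludes large vessels), ``theta > P_theta`` (requires
curvilinear geometry) and ``C > P_C`` (requires real contrast).
Defaults P_d = 13 px, P_theta = 130 deg, P_C = 1.17; at the reference
resolution 13 px corresponds to a vessel diameter of about 20 um.

Verified centerlines are re-inflated to full vessels by stamping a disk
of radius round(d/2) at each verified pixel; the 10 per-level
reconstructions are unioned, holes filled and the result opened.
Per-frame masks are finally combined by voting (a pixel is vessel when
segmented in more than one frame).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .exceptions import NoBackgroundError, ParameterError, ShapeError
from .io import BinaryMask
from .preprocess import LevelSchedule, adjust, clahe, median_smooth

#: candidate pixels keep this margin from the borders so the 5x5
#: neighborhood always fits.
BORDER_MARGIN = 2

_NEIGHBOR_OFFSETS = [(dr, dc) for dr in range(-2, 3) for dc in range(-2, 3)
                     if not (dr == 0 and dc == 0)]


@dataclass(frozen=True)
class VerificationParams:
    """Thresholds of the three-feature pixel verification test."""

    P_d: float = 13.0       # px, maximum local diameter
    P_theta: float = 130.0  # degrees, minimum angle
    P_C: float = 1.17       # minimum background/vessel contrast ratio

    def __post_init__(self):
        if not self.P_d >= 0:
            raise ParameterError("P_d must be non-negative")
        if not 0 < self.P_theta < 180:
            raise ParameterError("P_theta must lie in (0, 180)")
        if not self.P_C > 0:
            raise ParameterError("P_C must be positive")


@dataclass
class EDTResult:
    """Exact Euclidean distance transform with nearest-pixel lookups.

    ``dist[p]`` is the distance from foreground pixel ``p`` to its
    nearest background pixel (0 on background); ``nearest_row/col[p]``
    are that pixel's coordinates, ties broken by smaller row then
    smaller col so lookups are reproducible.  Background pixels map to
    themselves.
    """

    dist: np.ndarray
    nearest_row: np.ndarray
    nearest_col: np.ndarray


@dataclass
class PixelFeatures:
    """The (d, theta, C) feature triple of one candidate pixel."""

    d: float
    theta: float
    C: float
    b_p: tuple[int, int]
    b_max: tuple[int, int]


def binarize(preprocessed: np.ndarray, threshold: float) -> BinaryMask:
    """Foreground (vessel candidate) wherever intensity <= threshold."""
    if not 0 < threshold < 1:
        raise ParameterError("threshold must lie in (0, 1)")
    return BinaryMask(np.asarray(preprocessed) <= threshold)


@lru_cache(maxsize=4096)
def _ring_offsets(r2: int) -> tuple[tuple[int, int], ...]:
    """All integer (dy, dx) with dy^2 + dx^2 == r2, in (dy, dx) lexical
    order — the order that realizes the (row, col) nearest tie-break."""
    out = []
    rmax = int(np.floor(np.sqrt(r2)))
    for dy in range(-rmax, rmax + 1):
        rem = r2 - dy * dy
        dx = int(round(np.sqrt(rem)))
        if dx * dx == rem:
            if dx == 0:
                out.append((dy, 0))
            else:
                out.append((dy, -dx))
                out.append((dy, dx))
    return tuple(sorted(out))


def edt(mask: BinaryMask) -> EDTResult:
    """Exact EDT of a vessel-candidate mask with tie-broken nearest pixels.

    Distances come from an exact Euclidean distance transform of the
    foreground; the nearest background pixel is then re-derived per
    pixel by scanning the integer lattice ring at the known distance in
    (row, col) order, which fixes the tie-break deterministically.
    """
    fg = mask.grid
    bg = ~fg
    if not bg.any():
        raise NoBackgroundError("mask has no background pixel")
    h, w = fg.shape
    dist = ndimage.distance_transform_edt(fg)
    rows, cols = np.indices((h, w))
    nearest_row = rows.copy()
    nearest_col = cols.copy()

    r2_grid = np.rint(dist * dist).astype(np.int64)
    for r2 in np.unique(r2_grid[fg]):
        if r2 == 0:
            continue
        pr, pc = np.nonzero(r2_grid == r2)
        unassigned = np.ones(pr.size, dtype=bool)
        for dy, dx in _ring_offsets(int(r2)):
            if not unassigned.any():
                break
            rr = pr + dy
            cc = pc + dx
            ok = (unassigned & (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w))
            ok[ok] = bg[rr[ok], cc[ok]]
            nearest_row[pr[ok], pc[ok]] = rr[ok]
            nearest_col[pr[ok], pc[ok]] = cc[ok]
            unassigned &= ~ok
    return EDTResult(dist=dist, nearest_row=nearest_row, nearest_col=nearest_col)


def _feature_maps(mask: BinaryMask, edt_result: EDTResult, gray: np.ndarray):
    """Vectorized (d, theta, C) maps over the candidate interior.

    Returns full-frame float arrays (NaN outside candidates) plus the
    candidate mask (foreground pixels >= 2 px from every border).
    """
    fg = mask.grid
    h, w = fg.shape
    if gray.shape != fg.shape:
        raise ShapeError("gray image and mask shapes differ")
    m = BORDER_MARGIN
    core = np.s_[m:h - m, m:w - m]
    cand = np.zeros_like(fg)
    cand[core] = fg[core]

    nr = edt_result.nearest_row.astype(np.float64)
    nc = edt_result.nearest_col.astype(np.float64)
    rows, cols = np.indices((h, w), dtype=np.float64)

    bp_r = nr[core]
    bp_c = nc[core]
    p_r = rows[core]
    p_c = cols[core]
    gl_p = np.asarray(gray, dtype=np.float64)[core]

    gray64 = np.asarray(gray, dtype=np.float64)
    d2_best = np.full(bp_r.shape, -1.0)
    bmax_r = bp_r.copy()
    bmax_c = bp_c.copy()
    for dr, dc in _NEIGHBOR_OFFSETS:
        sl = np.s_[m + dr:h - m + dr, m + dc:w - m + dc]
        bj_r = nr[sl]
        bj_c = nc[sl]
        d2 = (bp_r - bj_r) ** 2 + (bp_c - bj_c) ** 2
        better = d2 > d2_best
        d2_best = np.where(better, d2, d2_best)
        bmax_r = np.where(better, bj_r, bmax_r)
        bmax_c = np.where(better, bj_c, bmax_c)
    d = np.sqrt(np.maximum(d2_best, 0.0))
    # contrast across the vessel: gray level at the opposite background
    # pixel b_max over the gray level at p
    gl_bmax = gray64[bmax_r.astype(int), bmax_c.astype(int)]

    a2 = (p_r - bp_r) ** 2 + (p_c - bp_c) ** 2      # |p - b_p|^2
    b2 = (p_r - bmax_r) ** 2 + (p_c - bmax_c) ** 2  # |p - b_max|^2
    ab = np.sqrt(a2 * b2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_theta = np.where(ab > 0, (a2 + b2 - d2_best) / (2 * ab), 1.0)
        theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
        contrast = np.where(gl_p > 0, gl_bmax / gl_p, np.inf)

    full = lambda arr: _embed(arr, (h, w), m)
    d_map = full(d)
    theta_map = full(theta)
    c_map = full(contrast)
    for a in (d_map, theta_map, c_map):
        a[~cand] = np.nan
    bmax_r_map = full(bmax_r)
    bmax_c_map = full(bmax_c)
    return d_map, theta_map, c_map, cand, bmax_r_map, bmax_c_map


def _embed(core_arr, shape, m):
    out = np.full(shape, np.nan)
    out[m:shape[0] - m, m:shape[1] - m] = core_arr
    return out


def pixel_features(p: tuple[int, int], mask: BinaryMask, edt_result: EDTResult,
                   gray: np.ndarray) -> PixelFeatures:
    """Feature triple of one candidate pixel (see module docstring).

    ``p`` must be foreground and at least 2 px from every border.
    """
    r, c = p
    h, w = mask.grid.shape
    if not (BORDER_MARGIN <= r < h - BORDER_MARGIN
            and BORDER_MARGIN <= c < w - BORDER_MARGIN):
        raise ParameterError(f"pixel {p} is inside the border margin")
    if not mask.grid[r, c]:
        raise ParameterError(f"pixel {p} is not foreground")
    d_map, theta_map, c_map, _, bmr, bmc = _feature_maps(mask, edt_result, gray)
    return PixelFeatures(
        d=float(d_map[r, c]), theta=float(theta_map[r, c]), C=float(c_map[r, c]),
        b_p=(int(edt_result.nearest_row[r, c]), int(edt_result.nearest_col[r, c])),
        b_max=(int(bmr[r, c]), int(bmc[r, c])),
    )


def verify(mask: BinaryMask, edt_result: EDTResult, gray: np.ndarray,
           params: VerificationParams = VerificationParams(),
           *, return_centers: bool = False):
    """Apply the three-feature test; returns (verified mask, d map).

    verified(p) <=> candidate(p) and d < P_d and theta > P_theta and
    C > P_C.  The returned d map holds the local diameter where the
    pixel verified (NaN elsewhere).  With ``return_centers`` the
    (row, col) midpoint grids of (b_p, b_max) are appended, for
    center-anchored reconstruction.
    """
    d_map, theta_map, c_map, cand, bmr, bmc = _feature_maps(mask, edt_result,
                                                            gray)
    with np.errstate(invalid="ignore"):
        ok = cand & (d_map < params.P_d) & (theta_map > params.P_theta) \
            & (c_map > params.P_C)
    d_out = np.where(ok, d_map, np.nan)
    if return_centers:
        centers = ((edt_result.nearest_row + bmr) / 2.0,
                   (edt_result.nearest_col + bmc) / 2.0)
        return BinaryMask(ok), d_out, centers
    return BinaryMask(ok), d_out


@lru_cache(maxsize=64)
def _disk(radius: int) -> np.ndarray:
    """4-connected rasterized disk: pixels with dy^2+dx^2 <= r^2."""
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def reconstruct(verified: BinaryMask, d_map: np.ndarray,
                centers: tuple[np.ndarray, np.ndarray] | None = None
                ) -> BinaryMask:
    """Re-inflate verified pixels to full vessel cross-sections.

    Without ``centers``, each verified pixel stamps a disk of radius
    round(d/2) at itself.  With ``centers`` (row and col arrays of the
    midpoint of b_p and b_max, as produced during verification), the
    disk is stamped at that midpoint — the vessel axis implied by the
    two opposite background pixels — with lumen radius
    round((d - 2) / 2), since d spans the background pixels one step
    outside the vessel on either side.  The midpoint form reproduces
    the true cross-section even for verified pixels that sit off the
    centerline; the output always contains the verified pixels.
    """
    out = verified.grid.copy() if centers is not None \
        else np.zeros_like(verified.grid)
    v = verified.grid
    if not v.any():
        return BinaryMask(out)
    h, w = v.shape
    d_vals = np.nan_to_num(d_map[v], nan=0.0)
    if centers is None:
        radii_v = np.rint(d_vals / 2.0).astype(int)
        pr, pc = np.nonzero(v)
        for r in np.unique(radii_v):
            sel = radii_v == r
            pts = np.zeros_like(v)
            pts[pr[sel], pc[sel]] = True
            if r <= 0:
                out |= pts
            else:
                out |= ndimage.binary_dilation(pts, structure=_disk(int(r)))
        return BinaryMask(out)
    # continuous centers: rasterize each disk about its float center so
    # half-integer midpoints do not smear the cross-section by a pixel
    cr = centers[0][v]
    cc = centers[1][v]
    rad = np.maximum((d_vals - 2.0) / 2.0, 0.0)
    base_r = np.rint(cr).astype(int)
    base_c = np.rint(cc).astype(int)
    R = int(np.ceil(rad.max() + 0.5))
    for dy in range(-R, R + 1):
        for dx in range(-R, R + 1):
            rr = base_r + dy
            ccol = base_c + dx
            hit = ((rr - cr) ** 2 + (ccol - cc) ** 2 <= rad * rad)
            hit &= (rr >= 0) & (rr < h) & (ccol >= 0) & (ccol < w)
            out[rr[hit], ccol[hit]] = True
    return BinaryMask(out)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background holes not 4-connected to the frame border."""
    return ndimage.binary_fill_holes(mask)


def segment_frame(mean_frame: np.ndarray, schedule: LevelSchedule,
                  params: VerificationParams = VerificationParams(),
                  *, return_levels: bool = False):
    """Segment one mean frame across all 10 threshold levels.

    For each level: preprocess -> binarize -> EDT -> verify ->
    reconstruct; the 10 reconstructions are unioned, interior holes
    filled, and the union morphologically opened with a radius-1 disk.
    The contrast feature is evaluated on the enhanced (CLAHE-equalized,
    median-smoothed) image of the level.
    """
    import warnings as _w

    h, w = mean_frame.shape
    union = np.zeros((h, w), dtype=bool)
    per_level = []
    for entry in schedule:
        enhanced = clahe(mean_frame, entry.clahe_tile, entry.clahe_clip)
        smoothed = median_smooth(enhanced, entry.median_kernel)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            pre = adjust(smoothed)
        mask = binarize(pre, entry.threshold_value)
        if mask.grid.all():  # threshold swallowed the frame: nothing verifiable
            level_mask = np.zeros((h, w), dtype=bool)
        else:
            edt_result = edt(mask)
            # contrast is evaluated on the smoothed enhanced image:
            # candidates are the dark tail of the histogram, so
            # unsmoothed CLAHE output would let pure sensor noise pass
            # the ratio test at any tile size
            verified, d_map, centers = verify(mask, edt_result, smoothed,
                                              params, return_centers=True)
            level_mask = reconstruct(verified, d_map, centers).grid
        union |= level_mask
        if return_levels:
            per_level.append(BinaryMask(level_mask))
    filled = fill_holes(union)
    opened = ndimage.binary_opening(filled, structure=_disk(1))
    result = BinaryMask(opened)
    if return_levels:
        return result, per_level
    return result


def combine_frames(per_frame_masks, min_votes: int = 2) -> BinaryMask:
    """Label a pixel vessel when it is foreground in >= min_votes masks.

    The default of 2 implements the "segmented as vessel in more than
    one frame" rule; min_votes=1 degenerates to a plain union.
    """
    masks = [m.grid if isinstance(m, BinaryMask) else np.asarray(m, bool)
             for m in per_frame_masks]
    if len(masks) < 2:
        raise ParameterError("need at least 2 masks to combine")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ShapeError("masks differ in shape")
    if min_votes < 1:
        raise ParameterError("min_votes must be >= 1")
    votes = np.sum(np.stack(masks), axis=0)
    return BinaryMask(votes >= min_votes)
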
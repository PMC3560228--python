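"""Translational video stabilization by control-point block matching.

Handheld SDF probes move relative to the tissue, so raw recordings carry
global translational jitter that would corrupt any temporal analysis.
The stabilizer picks distinctive image features (typically vessel branch
points) as control points, tracks each with zero-mean normalized
cross-correlation between a 25x25 reference patch and a 40x40 search
window in the next frame, and registers frames with the component-wise
median of the seven tracked displacements.

Flat patches cannot be matched reliably ("remarkableness"); control
points are therefore chosen as maxima of a Laplacian applied to the
Gaussian-gradient magnitude, taken over seven areas of the frame so the
estimate is spatially distributed.  Points that drift out of the tracked
interior trigger a full re-seed on the current frame.

The motion model is translation-only with integer shifts; the per-step
search radius is +/-7 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import (
    DegenerateContentError,
    ParameterError,
    RemarkablenessError,
    StabilizationError,
)
from .io import VideoSequence

PATCH = 25           # reference patch side
SEARCH = 40          # search window side
MARGIN = PATCH // 2  # 12: control points keep this distance from borders
MAX_SHIFT = (SEARCH - PATCH) // 2  # 7: per-step search radius
N_POINTS = 7

#: 4-connected 3x3 Laplacian used on the gradient magnitude.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


@dataclass(frozen=True)
class ControlPoint:
    row: int
    col: int
    tile_id: int


@dataclass
class MotionEstimate:
    """Cumulative integer shifts of each frame relative to frame 0.

    ``shifts[t] = (dy, dx)`` is the displacement of frame ``t``'s content
    relative to frame 0; ``valid_roi`` is the rectangle (row_start,
    row_stop, col_start, col_stop) common to all aligned frames.
    """

    shifts: np.ndarray                       # (n, 2) int
    valid_roi: tuple[int, int, int, int]
    reseeded: np.ndarray | None = None       # (n,) bool
    saturated: np.ndarray | None = None      # (n,) bool

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=int)
        n = self.shifts.shape[0]
        if self.reseeded is None:
            self.reseeded = np.zeros(n, dtype=bool)
        if self.saturated is None:
            self.saturated = np.zeros(n, dtype=bool)

    def per_step(self) -> np.ndarray:
        return np.diff(self.shifts, axis=0)


def gaussian_gradient(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Gradient magnitude from first-order Gaussian-derivative filters."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    gy = ndimage.gaussian_filter(frame, sigma, order=(1, 0), mode="nearest")
    gx = ndimage.gaussian_filter(frame, sigma, order=(0, 1), mode="nearest")
    return np.hypot(gy, gx)


def _response(frame: np.ndarray, sigma: float) -> np.ndarray:
    """|Laplacian of the Gaussian-gradient magnitude| — the corner/branch
    saliency map control points are drawn from."""
    g = gaussian_gradient(frame, sigma)
    return np.abs(ndimage.convolve(g, LAPLACIAN_KERNEL, mode="nearest"))


def select_control_points(frame: np.ndarray, sigma: float = 1.5) -> list[ControlPoint]:
    """Pick 7 control points, one from each of the 7 best of 9 tiles.

    The frame is split into a 3x3 grid of tiles; each tile contributes
    its interior saliency maximum, and the seven tiles with the largest
    peaks are kept (spatial spread with exactly seven areas).
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    if h < 75 or w < 75:
        raise ParameterError(f"frame {h}x{w} too small for control points (need 75x75)")
    resp = _response(frame, sigma)
    interior = np.zeros_like(resp, dtype=bool)
    interior[MARGIN:h - MARGIN, MARGIN:w - MARGIN] = True

    candidates = []  # (peak, tile_id, row, col)
    rows = np.linspace(0, h, 4).astype(int)
    cols = np.linspace(0, w, 4).astype(int)
    for ti in range(3):
        for tj in range(3):
            tile_id = ti * 3 + tj
            r0, r1 = rows[ti], rows[ti + 1]
            c0, c1 = cols[tj], cols[tj + 1]
            sub = np.where(interior[r0:r1, c0:c1], resp[r0:r1, c0:c1], -np.inf)
            k = int(np.argmax(sub))
            rr, cc = divmod(k, sub.shape[1])
            peak = sub[rr, cc]
            if np.isfinite(peak) and peak > 0:
                candidates.append((float(peak), tile_id, r0 + rr, c0 + cc))
    if len(candidates) < N_POINTS:
        raise DegenerateContentError(
            f"only {len(candidates)} of 9 tiles have distinctive content")
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return [ControlPoint(row=r, col=c, tile_id=tid)
            for _, tid, r, c in candidates[:N_POINTS]]


def _zncc(ref: np.ndarray, patch: np.ndarray) -> float:
    a = ref - ref.mean()
    b = patch - patch.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom < 1e-12:
        return -np.inf
    return float((a * b).sum() / denom)


def _match_in_frame(ref: np.ndarray, frame: np.ndarray, center: tuple[int, int],
                    max_shift: int = MAX_SHIFT):
    """Best integer offset (dy, dx) in [-max_shift, max_shift]^2 of ``ref``
    around ``center`` in ``frame`` by zero-mean NCC.  Ties go to the
    smallest |dy|+|dx|, then smallest dy, then dx.  Returns
    (dy, dx, score); raises RemarkablenessError on a flat reference."""
    if ref.std() < 1e-12:
        raise RemarkablenessError("reference patch has zero variance")
    h, w = frame.shape
    r, c = center
    half = ref.shape[0] // 2
    best = None
    for dy in range(-max_shift, max_shift + 1):
        r0 = r + dy - half
        if r0 < 0 or r0 + ref.shape[0] > h:
            continue
        for dx in range(-max_shift, max_shift + 1):
            c0 = c + dx - half
            if c0 < 0 or c0 + ref.shape[1] > w:
                continue
            score = _zncc(ref, frame[r0:r0 + ref.shape[0], c0:c0 + ref.shape[1]])
            key = (-score, abs(dy) + abs(dx), dy, dx)
            if best is None or key < best[0]:
                best = (key, dy, dx, score)
    if best is None or not np.isfinite(best[3]):
        raise RemarkablenessError("no valid placement for reference patch")
    return best[1], best[2], best[3]


def match_window(ref: np.ndarray, search: np.ndarray):
    """Match a 25x25 reference inside a 40x40 search window.

    Returns (dy, dx, score) with the offset measured from the centered
    placement, restricted to [-7, 7]^2.
    """
    ref = np.asarray(ref, dtype=np.float64)
    search = np.asarray(search, dtype=np.float64)
    if ref.shape != (PATCH, PATCH) or search.shape != (SEARCH, SEARCH):
        raise ParameterError(
            f"expected {PATCH}x{PATCH} ref and {SEARCH}x{SEARCH} search, "
            f"got {ref.shape} and {search.shape}")
    # center of the search window such that offset (0,0) is the centered
    # 25x25 placement: top-left (7,7) -> center index 7+12 = 19
    return _match_in_frame(ref, search, (19, 19), MAX_SHIFT)


def shift_frame(frame: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Sample ``frame`` at position + shift (i.e. translate content by
    -shift) with edge replication, keeping the original shape."""
    dy, dx = int(shift[0]), int(shift[1])
    h, w = frame.shape
    pad_y = abs(dy)
    pad_x = abs(dx)
    padded = np.pad(frame, ((pad_y, pad_y), (pad_x, pad_x)), mode="edge")
    return padded[pad_y + dy:pad_y + dy + h, pad_x + dx:pad_x + dx + w]


def _valid_roi(shifts: np.ndarray, h: int, w: int) -> tuple[int, int, int, int]:
    dy = shifts[:, 0]
    dx = shifts[:, 1]
    r0 = int(max(0, -dy.min()))
    r1 = int(min(h, h - dy.max()))
    c0 = int(max(0, -dx.min()))
    c1 = int(min(w, w - dx.max()))
    return (r0, max(r0, r1), c0, max(c0, c1))


def stabilize(video: VideoSequence, sigma: float = 1.5):
    """Register all frames to frame 0.

    Returns ``(aligned_video, MotionEstimate)``.  Control points are
    seeded on frame 0, tracked frame to frame, advected by the estimated
    median shift, and fully re-seeded whenever a point leaves the
    trackable interior or loses distinctive content.
    """
    if video.n_frames < 2:
        raise ParameterError("stabilization needs at least 2 frames")
    frames = video.frames
    n, h, w = frames.shape

    try:
        points = select_control_points(frames[0], sigma)
    except DegenerateContentError as exc:
        raise StabilizationError(0, f"cannot seed control points: {exc}") from exc

    shifts = np.zeros((n, 2), dtype=int)
    reseeded = np.zeros(n, dtype=bool)
    saturated = np.zeros(n, dtype=bool)
    cum = np.zeros(2, dtype=int)

    for t in range(n - 1):
        disps = []
        for pt in points:
            r, c = pt.row, pt.col
            ref = frames[t][r - MARGIN:r + MARGIN + 1, c - MARGIN:c + MARGIN + 1]
            try:
                dy, dx, _ = _match_in_frame(ref, frames[t + 1], (r, c))
            except RemarkablenessError:
                continue
            disps.append((dy, dx))
        if not disps:
            raise StabilizationError(t + 1, "all control-point matches failed"
                                            f" between frames {t} and {t + 1}")
        disps = np.array(disps)
        step = np.array([int(np.median(disps[:, 0])), int(np.median(disps[:, 1]))])
        if np.any(np.abs(step) >= MAX_SHIFT):
            saturated[t + 1] = True
        cum = cum + step
        shifts[t + 1] = cum

        # advect and check interior; re-seed on the new frame if needed
        new_points = [ControlPoint(p.row + step[0], p.col + step[1], p.tile_id)
                      for p in points]
        needs_reseed = (
            len(disps) < N_POINTS
            or saturated[t + 1]
            or any(not (MARGIN <= p.row < h - MARGIN and MARGIN <= p.col < w - MARGIN)
                   for p in new_points)
        )
        if needs_reseed:
            try:
                points = select_control_points(frames[t + 1], sigma)
                reseeded[t + 1] = True
            except DegenerateContentError as exc:
                raise StabilizationError(t + 1, str(exc)) from exc
        else:
            points = new_points

    aligned = np.stack([shift_frame(frames[t], tuple(shifts[t])) for t in range(n)])
    est = MotionEstimate(shifts=shifts, valid_roi=_valid_roi(shifts, h, w),
                         reseeded=reseeded, saturated=saturated)
    out = VideoSequence(np.clip(aligned, 0.0, 1.0),
                        pixel_size_um=video.pixel_size_um,
                        source_path=video.source_path)
    return out, est


def motion_to_csv(est: MotionEstimate) -> str:
    """Serialize a MotionEstimate as CSV (frame, dy, dx, reseeded)."""
    lines = ["frame,dy,dx,reseeded"]
    for t, (dy, dx) in enumerate(est.shifts):
        lines.append(f"{t},{dy},{dx},{int(est.reseeded[t])}")
    return "\n".join(lines) + "\n"
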
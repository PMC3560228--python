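"""Post-processing of the combined vessel mask.

Pixel-verified segmentation can leave 1-px gaps, isolated speckles and
short spurs.  Post-processing applies, in order: *bridge* (connect
foreground pixels separated by a single background pixel), *fill*
(remove interior background holes), *spur* removal (iteratively delete
endpoint pixels), and finally orientation-guided region growing, which
extends vessel endpoints along the local vessel direction while the
underlying gray level stays within mean +/- 0.5 sd of the vessel pixels
in the surrounding 35x35 window.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .io import BinaryMask
from .segment import fill_holes

WINDOW = 35          # region-growing analysis window side, px
MIN_VESSEL_PX = 10   # orientation undefined below this support
ISO_TOL = 1e-6       # moment isotropy tolerance
DEFAULT_MAX_STEPS = 10

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class WindowStats:
    """Orientation and gray-level statistics of one analysis window."""

    origin: tuple[int, int]
    orientation: float      # degrees in [0, 180), from +col toward +row
    mean_gray: float
    sd_gray: float
    n_vessel_px: int


@lru_cache(maxsize=1)
def _bridge_lut() -> np.ndarray:
    """256-entry truth table: for each 8-neighbor pattern, should a
    background center pixel be bridged?  Yes iff the set neighbors form
    >= 2 components under 8-connectivity within the 3x3 ring (the
    center itself excluded)."""
    lut = np.zeros(256, dtype=bool)
    coords = _N8
    for code in range(256):
        pts = [coords[i] for i in range(8) if code >> i & 1]
        if len(pts) < 2:
            continue
        # count components among pts with 8-adjacency
        remaining = set(pts)
        n_comp = 0
        while remaining:
            n_comp += 1
            stack = [remaining.pop()]
            while stack:
                y, x = stack.pop()
                for q in list(remaining):
                    if abs(q[0] - y) <= 1 and abs(q[1] - x) <= 1:
                        remaining.discard(q)
                        stack.append(q)
        lut[code] = n_comp >= 2
    return lut


def _neighbor_code(mask: np.ndarray) -> np.ndarray:
    """Per-pixel 8-bit code of the foreground pattern of the 8 neighbors."""
    padded = np.pad(mask, 1, mode="constant")
    code = np.zeros(mask.shape, dtype=np.uint8)
    h, w = mask.shape
    for i, (dy, dx) in enumerate(_N8):
        code |= (padded[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
                 .astype(np.uint8) << i)
    return code


def bridge(mask: np.ndarray) -> np.ndarray:
    """Set background pixels whose neighborhood holds >= 2 mutually
    disconnected foreground pixels."""
    lut = _bridge_lut()
    code = _neighbor_code(mask)
    return mask | (~mask & lut[code])


def _endpoints(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with exactly one 8-connected foreground neighbor."""
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    counts = ndimage.convolve(mask.astype(np.uint8), kernel, mode="constant")
    return mask & (counts == 1)


def remove_spurs(mask: np.ndarray, iterations: int = 3) -> np.ndarray:
    """Iteratively delete endpoint pixels (short spur pruning)."""
    out = mask.copy()
    for _ in range(iterations):
        ep = _endpoints(out)
        if not ep.any():
            break
        out &= ~ep
    return out


def morph_postprocess(mask: BinaryMask) -> BinaryMask:
    """bridge -> fill -> spur (3 iterations)."""
    m = mask.grid
    m = bridge(m)
    m = fill_holes(m)
    m = remove_spurs(m, 3)
    return BinaryMask(m)


def window_orientation(mask_window: np.ndarray, gray_window: np.ndarray | None = None,
                       origin: tuple[int, int] = (0, 0)) -> WindowStats | None:
    """Principal-axis orientation of the vessel pixels in a window.

    Uses second-order central moments of the foreground coordinates;
    returns None when the window holds fewer than 10 vessel pixels or
    the moments are isotropic within tolerance (no defined axis).
    """
    m = np.asarray(mask_window, dtype=bool)
    n = int(m.sum())
    if n < MIN_VESSEL_PX:
        return None
    ys, xs = np.nonzero(m)
    y = ys - ys.mean()
    x = xs - xs.mean()
    mu20 = float((x * x).mean())
    mu02 = float((y * y).mean())
    mu11 = float((x * y).mean())
    if abs(mu20 - mu02) < ISO_TOL and abs(mu11) < ISO_TOL:
        return None
    angle = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02)) % 180.0
    if gray_window is not None:
        g = np.asarray(gray_window, dtype=np.float64)[m]
        mean_gray, sd_gray = float(g.mean()), float(g.std())
    else:
        mean_gray = sd_gray = 0.0
    return WindowStats(origin=origin, orientation=float(angle),
                       mean_gray=mean_gray, sd_gray=sd_gray, n_vessel_px=n)


def grow(mask: BinaryMask, gray: np.ndarray,
         max_steps: int = DEFAULT_MAX_STEPS) -> BinaryMask:
    """Orientation-guided region growing over 35x35 windows.

    For every window with a defined vessel orientation, each endpoint of
    the segmented structure is extended one pixel at a time along both
    senses of the orientation; a pixel is accepted iff its gray level
    lies within [mean - 0.5 sd, mean + 0.5 sd] of the window's vessel
    pixels.  Growth stops at the first rejection or after ``max_steps``.
    The operation is extensive (output is a superset of the input).
    """
    src = mask.grid
    gray = np.asarray(gray, dtype=np.float64)
    h, w = src.shape
    out = src.copy()
    for r0 in range(0, h, WINDOW):
        for c0 in range(0, w, WINDOW):
            r1, c1 = min(r0 + WINDOW, h), min(c0 + WINDOW, w)
            stats = window_orientation(src[r0:r1, c0:c1], gray[r0:r1, c0:c1],
                                       origin=(r0, c0))
            if stats is None:
                continue
            lo = stats.mean_gray - 0.5 * stats.sd_gray
            hi = stats.mean_gray + 0.5 * stats.sd_gray
            theta = np.radians(stats.orientation)
            u = np.array([np.sin(theta), np.cos(theta)])  # (drow, dcol)
            ep_r, ep_c = np.nonzero(_endpoints(src[r0:r1, c0:c1]))
            for er, ec in zip(ep_r + r0, ep_c + c0):
                for sense in (1.0, -1.0):
                    prev = (er, ec)
                    for step in range(1, max_steps + 1):
                        rr = int(round(er + sense * u[0] * step))
                        cc = int(round(ec + sense * u[1] * step))
                        if not (0 <= rr < h and 0 <= cc < w):
                            break
                        if (rr, cc) == prev or src[rr, cc] or out[rr, cc]:
                            prev = (rr, cc)
                            continue
                        if lo <= gray[rr, cc] <= hi:
                            out[rr, cc] = True
                            prev = (rr, cc)
                        else:
                            break
    return BinaryMask(out)
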
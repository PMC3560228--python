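"""Per-level contrast enhancement ahead of multi-threshold binarization.

Each analyzed frame position is first replaced by a weighted mean of the
five consecutive stabilized frames centered on it (middle frame heaviest,
weights 1-2-3-2-1), which improves vessel connectivity without the
"over-averaging" that longer windows cause.  The mean frame is then,
for each of 10 threshold levels, CLAHE-equalized, median-smoothed and
linearly stretched; the per-level parameters trade off which vessels a
level is meant to capture:

* low levels (low thresholds, only wide/clear vessels survive): small
  CLAHE tiles and large median kernels;
* high levels (high thresholds, nearly everything dark is foreground):
  larger CLAHE tiles and small median kernels, to bring out thin vessels
  and let pixel verification prune the noise.

Threshold values themselves come from histogram quantiles of adjusted
reference frames, standing in for a training-video calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .exceptions import DegenerateHistogramError, ParameterError, ShapeError

#: weights for the 5-frame temporal mean (middle frame heaviest).
DEFAULT_WEIGHTS = np.array([1.0, 2.0, 3.0, 2.0, 1.0])

#: quantiles of the pooled adjusted histogram used as the 10 thresholds.
DEFAULT_QUANTILES = np.arange(0.10, 0.56, 0.05)

DEFAULT_TILES = (8, 8, 16, 16, 24, 24, 32, 32, 48, 64)
DEFAULT_KERNELS = (7, 7, 7, 5, 5, 5, 5, 3, 3, 3)
DEFAULT_CLIP = 0.01
N_LEVELS = 10


@dataclass(frozen=True)
class LevelEntry:
    """Parameters of one threshold level."""

    level: int              # 1..10
    threshold_value: float  # in (0, 1), strictly increasing with level
    clahe_tile: int         # CLAHE tile side, px (non-decreasing)
    clahe_clip: float
    median_kernel: int      # odd, px (non-increasing)


@dataclass
class LevelSchedule:
    """The ordered list of 10 threshold-level parameter records."""

    entries: list[LevelEntry]

    def __post_init__(self):
        if len(self.entries) != N_LEVELS:
            raise ParameterError(f"schedule needs {N_LEVELS} entries")
        # Threshold *levels* are ordered by the fraction of their own
        # preprocessed image they binarize; the raw threshold values
        # live in per-level enhancement domains and need not be
        # comparable across levels, so only their range is checked.
        if not all(0 < e.threshold_value < 1 for e in self.entries):
            raise ParameterError("threshold values must lie in (0, 1)")
        tiles = [e.clahe_tile for e in self.entries]
        if not all(b >= a for a, b in zip(tiles, tiles[1:])):
            raise ParameterError("CLAHE tiles must be non-decreasing")
        kernels = [e.median_kernel for e in self.entries]
        if not all(b <= a for a, b in zip(kernels, kernels[1:])):
            raise ParameterError("median kernels must be non-increasing")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def weighted_mean(frames, weights=DEFAULT_WEIGHTS) -> np.ndarray:
    """Weighted per-pixel average of 5 consecutive frames."""
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) != 5:
        raise ParameterError("weighted_mean expects exactly 5 frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ShapeError("frames differ in shape")
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (5,) or np.any(w < 0) or w.sum() <= 0:
        raise ParameterError("weights must be 5 non-negative reals with positive sum")
    out = sum(wi * fi for wi, fi in zip(w, frames)) / w.sum()
    return np.clip(out, 0.0, 1.0)


def clahe(frame: np.ndarray, tile: int, clip: float = DEFAULT_CLIP) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on [0,1] input."""
    frame = np.asarray(frame, dtype=np.float64)
    if tile < 2:
        raise ParameterError("CLAHE tile must be >= 2 px")
    if clip <= 0:
        raise ParameterError("CLAHE clip limit must be positive")
    if tile > min(frame.shape):
        raise ParameterError(f"tile {tile} exceeds frame {frame.shape}")
    if frame.max() == frame.min():
        return frame.copy()
    return exposure.equalize_adapthist(frame, kernel_size=tile, clip_limit=clip)


def median_smooth(frame: np.ndarray, k: int) -> np.ndarray:
    """k x k median filter with edge replication."""
    if k < 1 or k % 2 == 0:
        raise ParameterError("median kernel must be odd and >= 1")
    frame = np.asarray(frame, dtype=np.float64)
    if k == 1:
        return frame.copy()
    return ndimage.median_filter(frame, size=k, mode="nearest")


def adjust(frame: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linear stretch mapping the 1st/99th percentiles to 0/1, clipped."""
    frame = np.asarray(frame, dtype=np.float64)
    lo, hi = np.percentile(frame, (low_pct, high_pct))
    if hi <= lo:
        warnings.warn("adjust: constant frame, returned unchanged")
        return frame.copy()
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)


def build_schedule(reference, quantiles=None, tiles=DEFAULT_TILES,
                   kernels=DEFAULT_KERNELS, clip: float = DEFAULT_CLIP) -> LevelSchedule:
    """Derive the 10-level schedule from one or more reference frames.

    Thresholds are the q = 0.10, 0.15, ..., 0.55 quantiles of the pooled
    intensity histogram of the adjusted reference frames.
    """
    if quantiles is None:
        quantiles = DEFAULT_QUANTILES
    quantiles = np.asarray(quantiles, dtype=np.float64)
    if quantiles.shape != (N_LEVELS,):
        raise ParameterError(f"need {N_LEVELS} quantiles")
    ref = np.asarray(reference, dtype=np.float64)
    frames = ref[None] if ref.ndim == 2 else ref
    if all(f.max() == f.min() for f in frames):
        raise DegenerateHistogramError("all reference frames are constant")
    pooled = np.concatenate([adjust(f).ravel() for f in frames])
    th = np.quantile(pooled, quantiles)
    # enforce strict monotonicity against tied quantiles on spiky histograms
    for i in range(1, N_LEVELS):
        if th[i] <= th[i - 1]:
            th[i] = np.nextafter(th[i - 1], 1.0)
    th = np.clip(th, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    entries = [LevelEntry(level=i + 1, threshold_value=float(th[i]),
                          clahe_tile=int(tiles[i]), clahe_clip=float(clip),
                          median_kernel=int(kernels[i]))
               for i in range(N_LEVELS)]
    return LevelSchedule(entries)


def preprocess_level(mean_frame: np.ndarray, entry: LevelEntry) -> np.ndarray:
    """CLAHE -> median smoothing -> percentile stretch for one level."""
    out = clahe(mean_frame, entry.clahe_tile, entry.clahe_clip)
    out = median_smooth(out, entry.median_kernel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = adjust(out)
    return out


def vessel_fraction_estimate(frames) -> float:
    """Estimate the fraction of the image covered by dark (vessel)
    content from the pooled adjusted histogram, via Otsu's threshold.

    Hemoglobin-dark vessels form the low mode of the intensity
    histogram; the fraction of pixels below the Otsu split is a robust
    proxy for vessel coverage.  Clipped to [0.05, 0.45] so degenerate
    histograms cannot produce useless schedules.
    """
    from skimage.filters import threshold_otsu

    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    usable = [adjust(f).ravel() for f in frames if f.max() > f.min()]
    if not usable:
        raise DegenerateHistogramError("all reference frames are constant")
    pooled = np.concatenate(usable)
    t = threshold_otsu(pooled)
    return float(np.clip((pooled <= t).mean(), 0.05, 0.45))


def adaptive_quantiles(vessel_fraction: float) -> np.ndarray:
    """The 10 threshold quantiles spread around the estimated vessel
    coverage: from 0.3x (only the darkest vessel cores) to 1.5x (all
    vessels plus a margin of background for the verifier to prune)."""
    return np.clip(vessel_fraction * np.linspace(0.3, 1.5, N_LEVELS),
                   0.02, 0.65)


def training_schedule(mean_frames, quantiles=None, tiles=DEFAULT_TILES,
                      kernels=DEFAULT_KERNELS, clip: float = DEFAULT_CLIP,
                      max_frames: int = 3) -> LevelSchedule:
    """Build the level schedule with thresholds measured in each level's
    own *enhancement* domain, the domain binarization actually sees.

    Two calibrations happen here.  First, the quantile grid defaults to
    :func:`adaptive_quantiles` of the estimated vessel coverage —
    thresholds far beyond the dark-content fraction would binarize
    large swaths of background, thickening every vessel's foreground
    and flooding the verifier with noise.  Second, CLAHE approximately
    equalizes the histogram and the per-level tile/kernel reshape it
    differently at every level, so each level's threshold is taken as
    the level's quantile of the pooled histogram of *its own*
    preprocessed training frames; level k then binarizes (about) the
    darkest ``q_k`` fraction of its own image, as the quantile rule
    intends.
    """
    frames_arr = np.asarray(mean_frames, dtype=np.float64)
    if quantiles is None:
        quantiles = adaptive_quantiles(vessel_fraction_estimate(frames_arr))
    quantiles = np.asarray(quantiles, dtype=np.float64)
    if quantiles.shape != (N_LEVELS,):
        raise ParameterError(f"need {N_LEVELS} quantiles")
    frames = np.stack([np.asarray(f, dtype=np.float64) for f in mean_frames]) \
        if not isinstance(mean_frames, np.ndarray) else mean_frames
    if frames.ndim == 2:
        frames = frames[None]
    step = max(1, len(frames) // max_frames)
    train = [f for f in frames[::step][:max_frames] if f.max() > f.min()]
    if not train:
        raise DegenerateHistogramError("all reference frames are constant")

    th = np.empty(N_LEVELS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(N_LEVELS):
            pooled = []
            for f in train:
                e = clahe(f, min(int(tiles[i]), min(f.shape)), clip)
                pooled.append(adjust(median_smooth(e, int(kernels[i]))).ravel())
            th[i] = np.quantile(np.concatenate(pooled), quantiles[i])
    th = np.clip(th, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    entries = [LevelEntry(level=i + 1, threshold_value=float(th[i]),
                          clahe_tile=int(tiles[i]), clahe_clip=float(clip),
                          median_kernel=int(kernels[i]))
               for i in range(N_LEVELS)]
    return LevelSchedule(entries)


def sliding_mean_frames(frames: np.ndarray, n_use: int,
                        weights=DEFAULT_WEIGHTS) -> list[np.ndarray]:
    """One 5-frame weighted mean per analyzed frame position.

    The window is centered on each of the first ``n_use`` frames and
    clamped at the sequence ends (indices repeat at the boundary so the
    window always holds 5 frames).
    """
    n = frames.shape[0]
    n_use = min(n_use, n)
    out = []
    for i in range(n_use):
        idx = [min(max(j, 0), n - 1) for j in range(i - 2, i + 3)]
        out.append(weighted_mean([frames[j] for j in idx], weights))
    return out
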
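"""Video and result I/O.

Sidestream dark field (SDF) devices illuminate tissue with green light
near 550 nm, which hemoglobin absorbs; capillaries therefore appear as
dark curvilinear structures on a bright background.  Colour input is
reduced to the green channel (where that contrast lives) rather than to
luma, and intensities are normalised by the container's full-scale value
so that threshold levels are comparable across frames and recordings.

Internal conventions: frames are float64 arrays in [0, 1], coordinates
are (row, col), 0-based, row 0 at the top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import EmptyInputError, InputFormatError, ShapeError

#: micrometres per pixel implied by a 13 px cap on capillary diameter
#: corresponding to roughly 20 um at the acquisition resolution.
DEFAULT_PIXEL_SIZE_UM = 20.0 / 13.0

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class VideoSequence:
    """An ordered stack of same-sized intensity frames.

    Parameters
    ----------
    frames : ndarray, shape (n, height, width)
        Intensities in [0, 1].
    pixel_size_um : float
        Physical size of one pixel in micrometres (> 0).
    source_path : str
        Provenance string (file path or synthetic tag).
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    source_path: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] == 0:
            raise EmptyInputError("a video needs at least one 2-D frame")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]


@dataclass
class BinaryMask:
    """A boolean vessel mask (True = vessel) aligned with a frame."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ShapeError("mask must be 2-D")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


def to_intensity(arr: np.ndarray, *, channel: str = "green") -> np.ndarray:
    """Convert a raw decoded frame to a [0, 1] float64 grayscale image.

    RGB(A) input is reduced to the requested channel ("green", default,
    or "luma"); integer input is divided by the dtype's full-scale value
    (255, 65535, ...) so the mapping does not depend on frame content.
    Already-grayscale input passes through (idempotent).
    """
    a = np.asarray(arr)
    if a.ndim == 3:
        if a.shape[2] not in (3, 4):
            raise InputFormatError(f"unsupported channel count {a.shape[2]}")
        if channel == "green":
            a = a[:, :, 1]
        elif channel == "luma":
            a = 0.299 * a[:, :, 0] + 0.587 * a[:, :, 1] + 0.114 * a[:, :, 2]
        else:
            raise InputFormatError(f"unknown channel reduction {channel!r}")
    elif a.ndim != 2:
        raise InputFormatError(f"cannot interpret array of ndim {a.ndim} as a frame")
    if np.issubdtype(a.dtype, np.integer):
        full_scale = float(np.iinfo(a.dtype).max)
        a = a.astype(np.float64) / full_scale
    else:
        a = np.clip(a.astype(np.float64), 0.0, 1.0)
    return a


def load_video(
    path,
    max_frames: int | None = None,
    *,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel: str = "green",
) -> VideoSequence:
    """Read a video or multi-page TIFF stack into a :class:`VideoSequence`.

    At most ``max_frames`` frames are returned, in temporal order.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    if max_frames is not None and max_frames <= 0:
        raise EmptyInputError("max_frames must be positive")

    frames: list[np.ndarray] = []
    if path.suffix.lower() in _TIFF_SUFFIXES:
        try:
            with tifffile.TiffFile(str(path)) as tf:
                for page in tf.pages:
                    frames.append(to_intensity(page.asarray(), channel=channel))
                    if max_frames is not None and len(frames) >= max_frames:
                        break
        except (tifffile.TiffFileError, ValueError) as exc:
            raise InputFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    else:
        # AVI / MP4 etc. via whatever imageio plugin the runtime provides.
        import imageio.v3 as iio

        try:
            for frame in iio.imiter(str(path)):
                frames.append(to_intensity(frame, channel=channel))
                if max_frames is not None and len(frames) >= max_frames:
                    break
        except Exception as exc:  # plugin zoo raises many types
            raise InputFormatError(f"cannot decode {path}: {exc}") from exc

    if not frames:
        raise EmptyInputError(f"{path} contains no frames")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ShapeError(f"frames differ in shape: {sorted(shapes)}")
    return VideoSequence(np.stack(frames), pixel_size_um=pixel_size_um,
                         source_path=str(path))


def write_video(path, video: VideoSequence) -> None:
    """Write a sequence as an 8-bit multi-page TIFF stack."""
    data = np.clip(np.rint(video.frames * 255), 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def write_mask(path, mask: BinaryMask) -> None:
    """Save a binary mask as an 8-bit PNG/TIFF with values {0, 255}."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.grid.astype(np.uint8) * 255))


def read_mask(path) -> BinaryMask:
    import imageio.v3 as iio

    return BinaryMask(np.asarray(iio.imread(str(path))) > 0)


def write_outputs(masks, results, out_dir) -> list[Path]:
    """Write per-frame masks plus the FCD result as CSV and JSON.

    Returns the list of files written.  ``results`` is a
    :class:`microcirc.flow.FCDResult`.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputFormatError(f"cannot create {out_dir}: {exc}") from exc
    if not out_dir.is_dir():
        raise InputFormatError(f"not a directory: {out_dir}")

    written: list[Path] = []
    for i, mask in enumerate(masks):
        p = out_dir / f"mask_{i:03d}.png"
        write_mask(p, mask)
        written.append(p)

    record = {
        "fcd_area_percent": float(results.fcd_area_percent),
        "fcd_length_mm_per_mm2": float(results.fcd_length_mm_per_mm2),
        "roi_area_px": int(results.roi_area_px),
        "frames_used": int(results.frames_used),
    }
    jpath = out_dir / "fcd.json"
    jpath.write_text(json.dumps(record, indent=2) + "\n")
    written.append(jpath)
    cpath = out_dir / "fcd.csv"
    keys = list(record)
    cpath.write_text(",".join(keys) + "\n" +
                     ",".join(str(record[k]) for k in keys) + "\n")
    written.append(cpath)
    return written
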
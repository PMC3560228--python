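"""Synthetic SDF-like phantom videos with ground truth.

The generator emulates what a sidestream dark field probe sees on a
mucosal surface: a bright tissue background crossed by dark curvilinear
capillaries, global translational jitter from the handheld probe, and
additive sensor noise.  Hemoglobin is the only absorber at 550 nm, so
vessels are visible exactly where red cells are:

* a *non-perfused* vessel holds a stagnant blood column — a static dark
  tube at ``vessel_level``;
* a *perfused* vessel shows a train of dark cells (``cell_level``)
  advected along the centerline at ``cell_speed`` px/frame with
  ``cell_spacing`` px between cells, over a plasma tube whose baseline
  (``plasma_level``, default the background level) is nearly invisible.
  Its per-frame appearance therefore changes as cells move, which is
  the physical signal the temporal flow classifier keys on.

Ground truth (full vessel and perfused-vessel masks, per-frame jitter,
per-vessel centerlines/widths/flags) is rendered before jitter is
applied, so every pipeline stage can be scored without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .flow import Rect
from .io import DEFAULT_PIXEL_SIZE_UM, BinaryMask, VideoSequence


@dataclass
class VesselRecord:
    centerline: np.ndarray  # (n, 2) float (row, col) polyline, ~1 px steps
    width: float            # px
    perfused: bool


@dataclass
class PhantomSpec:
    """Generation parameters of one phantom recording.

    Defaults describe the reference condition: 480x640 frames, ~12% of
    the frame covered by perfused capillaries of width 3-9 px (all
    under the 13 px diameter cap), background 0.8, stagnant blood 0.55,
    cells 0.35, noise sd 0.02, 24 frames.
    """

    height: int = 480
    width: int = 640
    n_vessels: int = 28
    width_range: tuple[float, float] = (3.0, 9.0)
    perfused_fraction: float = 0.75
    background_level: float = 0.8
    vessel_level: float = 0.55
    cell_level: float = 0.35
    plasma_level: float | None = None  # None -> background (plasma invisible)
    cell_radius: float = 3.0
    cell_speed: float = 3.0            # px/frame (~0.18 mm/s at 1.54 um/px)
    cell_spacing: float = 30.0         # px between cell-train centers
    noise_sd: float = 0.02
    jitter: object = 0                 # amplitude (int) or list of (dy, dx)
    n_frames: int = 24
    seed: int = 0

    def __post_init__(self):
        if not self.vessel_level < self.background_level:
            raise ValueError("vessel_level must be darker than background_level")
        if not self.cell_level <= self.vessel_level:
            raise ValueError("cell_level must be at most vessel_level")
        if not (2.0 <= self.width_range[0] <= self.width_range[1] <= 30.0):
            raise ValueError("width_range must lie within [2, 30]")
        if not 0.0 <= self.perfused_fraction <= 1.0:
            raise ValueError("perfused_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    vessel_mask: BinaryMask
    perfused_mask: BinaryMask
    shifts: np.ndarray          # (n_frames, 2) int, applied jitter
    vessels: list[VesselRecord] = field(default_factory=list)


def _jitter_shifts(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(spec.jitter):
        amp = int(spec.jitter)
        shifts = np.zeros((spec.n_frames, 2), dtype=int)
        if amp > 0:
            shifts[1:] = rng.integers(-amp, amp + 1, size=(spec.n_frames - 1, 2))
        return shifts
    shifts = np.asarray(spec.jitter, dtype=int)
    if shifts.shape != (spec.n_frames, 2):
        raise ValueError(f"jitter list must have shape ({spec.n_frames}, 2)")
    return shifts.copy()


def _smooth_centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """One curvature-limited smooth curve through random control points,
    resampled to ~1 px steps (piecewise quadratic smoothing of a random
    heading walk)."""
    h, w = spec.height, spec.width
    margin = 20
    # random entry point on a border region, heading roughly across the frame
    start = np.array([rng.uniform(margin, h - margin),
                      rng.uniform(margin, w - margin)])
    heading = rng.uniform(0, 2 * np.pi)
    n_steps = int(0.55 * max(h, w))
    max_turn = np.radians(4.0)  # per-px curvature limit
    steer_zone = 2.0 * margin   # start turning back near the borders
    pts = [start.copy()]
    pos = start.copy()
    center = np.array([h / 2.0, w / 2.0])
    for _ in range(n_steps):
        heading += rng.uniform(-max_turn, max_turn)
        # steer gently back toward the interior when close to a border,
        # so curves keep a realistic length at any frame size
        edge_dist = min(pos[0], h - pos[0], pos[1], w - pos[1])
        if edge_dist < steer_zone:
            to_center = np.arctan2(*(center - pos))
            delta = (to_center - heading + np.pi) % (2 * np.pi) - np.pi
            heading += np.clip(delta, -max_turn, max_turn) \
                * (1.0 - edge_dist / steer_zone) * 2.0
        pos = pos + np.array([np.sin(heading), np.cos(heading)])
        if not (margin / 2 <= pos[0] < h - margin / 2
                and margin / 2 <= pos[1] < w - margin / 2):
            break
        pts.append(pos.copy())
    poly = np.array(pts)
    if len(poly) >= 7:  # quadratic smoothing of the sampled walk
        kernel = np.array([1, 2, 3, 2, 1], dtype=float)
        kernel /= kernel.sum()
        sm = poly.copy()
        for axis in range(2):
            sm[2:-2, axis] = np.convolve(poly[:, axis], kernel, mode="valid")
        poly = sm
    return poly


def _stamp_disks(mask: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Set all pixels within ``radius`` of any of the points."""
    h, w = mask.shape
    r_int = int(np.ceil(radius))
    yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    disk = (yy * yy + xx * xx) <= radius * radius
    for pr, pc in np.rint(points).astype(int):
        r0, r1 = pr - r_int, pr + r_int + 1
        c0, c1 = pc - r_int, pc + r_int + 1
        dr0, dc0 = max(0, -r0), max(0, -c0)
        dr1 = disk.shape[0] - max(0, r1 - h)
        dc1 = disk.shape[1] - max(0, c1 - w)
        if dr0 >= dr1 or dc0 >= dc1:
            continue
        mask[max(0, r0):min(h, r1), max(0, c0):min(w, c1)] |= \
            disk[dr0:dr1, dc0:dc1]


def _tube_mask(shape, centerline: np.ndarray, width: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    _stamp_disks(mask, centerline, width / 2.0)
    return mask


def make_vessel_network(spec: PhantomSpec, rng: np.random.Generator
                        ) -> list[VesselRecord]:
    """Sample ``n_vessels`` smooth non-overlapping curves with widths and
    perfusion flags.  ceil(perfused_fraction * n) vessels are perfused.
    Placement uses rejection sampling against a dilated occupancy mask
    so vessels stay separated (mirrors 2-D projections of capillary
    beds, and keeps per-vessel scoring unambiguous)."""
    vessels: list[VesselRecord] = []
    if spec.n_vessels == 0:
        return vessels
    occupancy = np.zeros((spec.height, spec.width), dtype=bool)
    attempts = 0
    while len(vessels) < spec.n_vessels and attempts < 80 * spec.n_vessels:
        attempts += 1
        centerline = _smooth_centerline(spec, rng)
        if len(centerline) < 30:
            continue
        width = float(rng.uniform(*spec.width_range))
        tube = _tube_mask(occupancy.shape, centerline, width)
        halo = ndimage.binary_dilation(tube, iterations=3)
        if (halo & occupancy).any():
            continue
        occupancy |= halo
        vessels.append(VesselRecord(centerline=centerline, width=width,
                                    perfused=False))
    # flags apply to the vessels actually placed, so the perfused
    # fraction holds even when rejection sampling falls short
    n_perfused = int(np.ceil(spec.perfused_fraction * len(vessels)))
    for i in range(n_perfused):
        vessels[i].perfused = True
    return vessels


def _arclength(poly: np.ndarray) -> np.ndarray:
    seg = np.sqrt(((np.diff(poly, axis=0)) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def _cell_centers(poly: np.ndarray, s_cum: np.ndarray, offset: float,
                  spacing: float) -> np.ndarray:
    """Points on the polyline at arclengths (offset + k*spacing) mod L."""
    total = s_cum[-1]
    if total <= 0 or spacing <= 0:
        return np.empty((0, 2))
    ss = (offset + np.arange(0, total, spacing)) % total
    out = np.empty((len(ss), 2))
    out[:, 0] = np.interp(ss, s_cum, poly[:, 0])
    out[:, 1] = np.interp(ss, s_cum, poly[:, 1])
    return out


def render_sequence(spec: PhantomSpec) -> tuple[VideoSequence, GroundTruth]:
    """Render the phantom video and its ground truth.

    Frames are drawn un-jittered (vessels, cells, noise), ground-truth
    masks are taken from that geometry, and each frame is then
    translated by its per-frame jitter with edge replication.
    """
    rng = np.random.default_rng(spec.seed)
    vessels = make_vessel_network(spec, rng)
    shifts = _jitter_shifts(spec, rng)
    h, w = spec.height, spec.width

    vessel_mask = np.zeros((h, w), dtype=bool)
    perfused_mask = np.zeros((h, w), dtype=bool)
    static_canvas = np.full((h, w), spec.background_level)
    plasma = (spec.background_level if spec.plasma_level is None
              else spec.plasma_level)
    tubes = []
    for v in vessels:
        tube = _tube_mask((h, w), v.centerline, v.width)
        tubes.append(tube)
        vessel_mask |= tube
        if v.perfused:
            perfused_mask |= tube
            static_canvas[tube] = plasma
        else:
            static_canvas[tube] = spec.vessel_level

    cell_phase = [float(np.random.default_rng(spec.seed + 1000 + i).uniform(
        0, spec.cell_spacing)) for i in range(len(vessels))]

    frames = np.empty((spec.n_frames, h, w))
    for t in range(spec.n_frames):
        frame = static_canvas.copy()
        for i, v in enumerate(vessels):
            if not v.perfused:
                continue
            s_cum = _arclength(v.centerline)
            centers = _cell_centers(v.centerline, s_cum,
                                    cell_phase[i] + spec.cell_speed * t,
                                    spec.cell_spacing)
            cell_mask = np.zeros((h, w), dtype=bool)
            radius = min(spec.cell_radius, max(1.0, v.width / 2.0))
            _stamp_disks(cell_mask, centers, radius)
            cell_mask &= tubes[i]  # cells stay inside the vessel lumen
            frame[cell_mask] = spec.cell_level
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=(h, w))
        frame = np.clip(frame, 0.0, 1.0)
        dy, dx = shifts[t]
        if dy or dx:
            frame = _translate(frame, dy, dx)
        frames[t] = frame

    video = VideoSequence(frames, pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
                          source_path=f"phantom(seed={spec.seed})")
    gt = GroundTruth(vessel_mask=BinaryMask(vessel_mask),
                     perfused_mask=BinaryMask(perfused_mask),
                     shifts=shifts, vessels=vessels)
    return video, gt


def _translate(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Move content by (+dy, +dx) with edge replication."""
    h, w = frame.shape
    pad = np.pad(frame, ((abs(dy),) * 2, (abs(dx),) * 2), mode="edge")
    return pad[abs(dy) - dy:abs(dy) - dy + h, abs(dx) - dx:abs(dx) - dx + w]


def true_fcd(gt: GroundTruth, roi: Rect,
             pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> tuple[float, float]:
    """Ground-truth FCD (area %, length mm/mm^2) from the phantom masks.

    Area uses the perfused mask directly; length uses the analytic
    centerline polylines clipped to the ROI, with the same unit
    conventions as the pipeline's measure.
    """
    r0, r1, c0, c1 = roi
    sub = gt.perfused_mask.grid[r0:r1, c0:c1]
    area_pct = 100.0 * float(sub.sum()) / sub.size

    length_px = 0.0
    for v in gt.vessels:
        if not v.perfused:
            continue
        pts = v.centerline
        inside = ((pts[:, 0] >= r0) & (pts[:, 0] < r1)
                  & (pts[:, 1] >= c0) & (pts[:, 1] < c1))
        seg = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
        length_px += float(seg[inside[:-1] & inside[1:]].sum())
    px_mm = pixel_size_um * 1e-3
    area_mm2 = (r1 - r0) * px_mm * (c1 - c0) * px_mm
    length_density = length_px * px_mm / area_mm2 if area_mm2 > 0 else 0.0
    return area_pct, length_density


def baseline_spec(**overrides) -> PhantomSpec:
    """The reference (healthy baseline) phantom condition."""
    return PhantomSpec(**overrides)


def hemorrhage_spec(**overrides) -> PhantomSpec:
    """Same network statistics with the perfused fraction halved,
    mirroring a baseline-vs-hemorrhage contrast."""
    base = PhantomSpec(**overrides)
    return replace(base, perfused_fraction=base.perfused_fraction / 2.0)


def scaled_spec(height: int, width: int, **overrides) -> PhantomSpec:
    """A spec at reduced frame size with the perfused *area fraction*
    kept in the reference regime (~12%).

    A vessel's area scales like its length (proportional to the larger
    frame dimension) times its width (unchanged), so the vessel count
    scales with frame_area / max_dimension rather than with area.
    """
    ref = PhantomSpec()
    ref_density = ref.n_vessels / (ref.height * ref.width / max(ref.height,
                                                                ref.width))
    n = max(4, int(round(ref_density * height * width / max(height, width))))
    overrides.setdefault("n_vessels", n)
    return PhantomSpec(height=height, width=width, **overrides)


def render_static_jittered(spec: PhantomSpec,
                           shifts=None) -> tuple[VideoSequence, GroundTruth]:
    """A single rendered frame (texture, vessels and noise frozen)
    replayed under per-frame integer shifts.

    This isolates pure camera translation: the scene does not evolve,
    so motion estimates can be checked against the injected shifts
    exactly.  ``shifts`` defaults to the spec's jitter.
    """
    frozen = replace(spec, n_frames=1, jitter=0)
    video1, gt = render_sequence(frozen)
    base = video1.frames[0]
    if shifts is None:
        shifts = _jitter_shifts(replace(spec, jitter=spec.jitter),
                                np.random.default_rng(spec.seed + 77))
    shifts = np.asarray(shifts, dtype=int)
    frames = np.stack([_translate(base, int(dy), int(dx))
                       for dy, dx in shifts])
    video = VideoSequence(frames, pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
                          source_path=f"phantom-static(seed={spec.seed})")
    gt = GroundTruth(vessel_mask=gt.vessel_mask, perfused_mask=gt.perfused_mask,
                     shifts=shifts, vessels=gt.vessels)
    return video, gt
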
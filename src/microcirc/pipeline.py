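"""End-to-end orchestration: video in, FCD out.

``analyze_video`` composes the stages in their canonical order:

    load -> stabilize -> per-frame 5-frame weighted mean
         -> multi-threshold segmentation with pixel verification
         -> per-frame mask voting -> bridge/fill/spur -> region growing
         -> temporal flow classification -> area- and length-based FCD

Twenty frame positions are analyzed per recording by default.  The
region of interest is the rectangle common to all aligned frames minus
the 2-px candidate border margin, so neither stabilization padding nor
unverifiable border pixels contribute to density.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import flow, preprocess, refine, segment, stabilize
from .exceptions import (DegenerateHistogramError, MicrocircError,
                         StabilizationError)
from .io import DEFAULT_PIXEL_SIZE_UM, BinaryMask, VideoSequence, load_video

log = logging.getLogger("microcirc")


@dataclass
class PipelineConfig:
    """All tunables of one analysis run (defaults are the reference
    operating point of each stage)."""

    frames_to_use: int = 20
    stabilize: bool = True
    allow_unstable: bool = False
    sigma: float = 1.5
    weights: tuple = (1.0, 2.0, 3.0, 2.0, 1.0)
    quantiles: tuple | None = None      # None -> 0.10 .. 0.55 step 0.05
    P_d: float = 13.0
    P_theta: float = 130.0
    P_C: float = 1.17
    min_votes: int = 2
    region_grow: bool = True
    max_grow_steps: int = 10
    t_flow: int = 2
    component_vote: bool = True
    vote_frac: float = 0.5
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def verification_params(self) -> segment.VerificationParams:
        return segment.VerificationParams(self.P_d, self.P_theta, self.P_C)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineArtifacts:
    """Intermediate products of one run, for inspection and resumption."""

    motion: stabilize.MotionEstimate | None
    per_frame_masks: list[BinaryMask]
    combined: BinaryMask
    refined: BinaryMask
    activity: flow.ActivityMap
    schedule: preprocess.LevelSchedule
    roi: flow.Rect
    timings: dict = field(default_factory=dict)


def _stage(timings: dict, name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            timings[name] = timings.get(name, 0.0) + dt
            log.info("stage %-14s %.2fs", name, dt)
    return _T()


def _empty_result(video, config, roi, timings):
    h, w = video.height, video.width
    empty = BinaryMask(np.zeros((h, w), dtype=bool))
    n = min(config.frames_to_use, video.n_frames)
    masks = [BinaryMask(np.zeros((h, w), dtype=bool)) for _ in range(max(n, 2))]
    act = flow.activity_map([m.grid for m in masks])
    r0, r1, c0, c1 = roi
    result = flow.FCDResult(
        fcd_area_percent=0.0, fcd_length_mm_per_mm2=0.0, roi=roi,
        roi_area_px=(r1 - r0) * (c1 - c0), pixel_size_um=config.pixel_size_um,
        frames_used=len(masks), active_mask=empty)
    artifacts = PipelineArtifacts(
        motion=None, per_frame_masks=masks, combined=empty, refined=empty,
        activity=act, schedule=None, roi=roi, timings=timings)
    return result, artifacts


def analyze_video(video, config: PipelineConfig | None = None
                  ) -> tuple[flow.FCDResult, PipelineArtifacts]:
    """Run the full analysis on a path or :class:`VideoSequence`.

    Returns ``(FCDResult, PipelineArtifacts)``.
    """
    config = config or PipelineConfig()
    timings: dict = {}

    if not isinstance(video, VideoSequence):
        with _stage(timings, "load"):
            video = load_video(video, max_frames=config.frames_to_use + 4,
                               pixel_size_um=config.pixel_size_um)

    motion = None
    h, w = video.height, video.width
    roi_rect = (0, h, 0, w)
    if config.stabilize and video.n_frames >= 2:
        with _stage(timings, "stabilize"):
            try:
                video, motion = stabilize.stabilize(video, config.sigma)
                roi_rect = motion.valid_roi
            except StabilizationError:
                if not config.allow_unstable:
                    raise
                log.warning("stabilization failed; continuing unstabilized")

    # shrink ROI by the verification border margin
    m = segment.BORDER_MARGIN
    r0, r1, c0, c1 = roi_rect
    roi = (min(r0 + m, r1), max(r1 - m, r0 + m),
           min(c0 + m, c1), max(c1 - m, c0 + m))

    with _stage(timings, "mean_frames"):
        mean_frames = preprocess.sliding_mean_frames(
            video.frames, config.frames_to_use, np.asarray(config.weights))

    with _stage(timings, "schedule"):
        try:
            schedule = preprocess.training_schedule(
                np.stack(mean_frames),
                quantiles=None if config.quantiles is None
                else np.asarray(config.quantiles))
        except DegenerateHistogramError:
            # featureless (blank) video: no vessels, zero density
            log.warning("degenerate histogram; reporting zero FCD")
            return _empty_result(video, config, roi, timings)

    params = config.verification_params()
    per_frame_masks: list[BinaryMask] = []
    with _stage(timings, "segment"):
        for i, mf in enumerate(mean_frames):
            mask = segment.segment_frame(mf, schedule, params)
            per_frame_masks.append(mask)
            log.debug("frame %d: %d vessel px", i, int(mask.grid.sum()))

    with _stage(timings, "combine"):
        combined = segment.combine_frames(per_frame_masks, config.min_votes)

    with _stage(timings, "refine"):
        refined = refine.morph_postprocess(combined)
        if config.region_grow:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                gray = preprocess.adjust(np.mean(mean_frames, axis=0))
            refined = refine.grow(refined, gray, config.max_grow_steps)

    with _stage(timings, "flow_fcd"):
        result = flow.compute_fcd(
            refined, [m.grid for m in per_frame_masks], roi,
            pixel_size_um=config.pixel_size_um, t_flow=config.t_flow,
            component_vote=config.component_vote, vote_frac=config.vote_frac)
        act = flow.activity_map([m.grid for m in per_frame_masks])

    artifacts = PipelineArtifacts(
        motion=motion, per_frame_masks=per_frame_masks, combined=combined,
        refined=refined, activity=act, schedule=schedule, roi=roi,
        timings=timings)
    return result, artifacts


__all__ = ["PipelineConfig", "PipelineArtifacts", "analyze_video",
           "MicrocircError"]
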
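"""Recover injected camera jitter from a static textured scene.

A single rendered frame is replayed under known integer translations
(handheld-probe motion); the block-matching stabilizer must recover
every shift exactly and re-stabilizing the aligned video must yield
all-zero motion.
"""

import numpy as np

from microcirc import stabilize
from microcirc.phantom import render_static_jittered, scaled_spec

shifts = np.cumsum([(0, 0), (2, 0), (-3, 1), (5, -4), (0, 6)], axis=0)
video, truth = render_static_jittered(scaled_spec(192, 256, seed=3), shifts)

aligned, motion = stabilize(video, sigma=1.5)
print("injected shifts :", truth.shifts.tolist())
print("recovered shifts:", motion.shifts.tolist())
print("exact recovery  :", bool((motion.shifts == truth.shifts).all()))

_, motion2 = stabilize(aligned, sigma=1.5)
print("residual motion after re-stabilization:",
      int(np.abs(motion2.shifts).max()), "px")
# Exact recovery and zero residual confirm the translation-only motion
# model is solved to the pixel on pure camera motion.
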
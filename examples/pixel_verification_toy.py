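"""The three-feature pixel verification on a printable toy image.

A 9x9 frame holds a vertical dark band of width 3 (a capillary seen in
cross-section).  For the center pixel the local diameter d, the angle
theta between the two opposite background pixels, and the contrast
ratio C are computed from the Euclidean distance transform, then tested
against the defaults P_d = 13 px, P_theta = 130 deg, P_C = 1.17.
"""

import numpy as np

from microcirc import VerificationParams, binarize, edt, pixel_features, verify

img = np.full((9, 9), 0.8)
img[:, 3:6] = 0.4  # dark band, width 3

mask = binarize(img, threshold=0.5)
dt = edt(mask)
pf = pixel_features((4, 4), mask, dt, img)

print(f"d     = {pf.d:.3f} px   (must be < 13 to exclude large vessels)")
print(f"theta = {pf.theta:.1f} deg  (must be > 130: curvilinear geometry)")
print(f"C     = {pf.C:.2f}       (must be > 1.17: real contrast)")

verified, _ = verify(mask, dt, img, VerificationParams())
print("center pixel verified as capillary:", bool(verified.grid[4, 4]))

wide = np.full((40, 60), 0.8)
wide[:, 15:35] = 0.4  # width 20 -> a large vessel, excluded
vmask = binarize(wide, 0.5)
v, _ = verify(vmask, edt(vmask), wide, VerificationParams())
print("verified pixels on a width-20 band:", int(v.grid.sum()),
      "(large-vessel exclusion)")
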
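"""Render a synthetic SDF phantom and run the full analysis pipeline.

Builds a small baseline recording (bright tissue, dark capillaries,
moving cells in the perfused vessels), runs stabilization-free analysis
and compares the measured functional capillary density (FCD) with the
phantom's ground truth.
"""

from microcirc import PipelineConfig, analyze_video, scaled_spec, true_fcd
from microcirc.phantom import render_sequence

spec = scaled_spec(192, 256, seed=0)
video, truth = render_sequence(spec)
print(f"phantom: {video.n_frames} frames of {video.height}x{video.width}, "
      f"{sum(v.perfused for v in truth.vessels)} perfused / "
      f"{len(truth.vessels)} vessels")

result, artifacts = analyze_video(video, PipelineConfig(stabilize=False))
true_area, true_length = true_fcd(truth, artifacts.roi)

print(f"measured FCD (area)  : {result.fcd_area_percent:.2f} % of ROI")
print(f"ground-truth FCD     : {true_area:.2f} %")
print(f"measured FCD (length): {result.fcd_length_mm_per_mm2:.2f} mm/mm^2")
print(f"ground-truth length  : {true_length:.2f} mm/mm^2")
# The area measure counts every pixel of actively perfused capillaries
# inside the region of interest; agreement with ground truth within a
# few tens of percent relative is the expected operating accuracy.
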
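"""Zoom estimation with the scale pyramid.

The log-polar sampling absorbs scale differences up to roughly a factor
of two.  For larger, unknown zoom the pipeline compares five resize
scenarios — A vs B, A vs 0.5B, 0.5A vs B, A vs 0.25B, 0.25A vs B — and
keeps the one with the most raw candidate matches.  Here image B is A
shrunk by a factor of four, so shrinking A by 0.25 equalizes the scales.
"""

from skimage.transform import rescale

from lpm import Image, PipelineConfig, make_texture, run_pipeline

img_a = make_texture(384, "blobs", seed=5)
img_b = Image(
    rescale(img_a.pixels, 0.25, order=3, anti_aliasing=True, preserve_range=True)
)

config = PipelineConfig(
    detector="hessian", max_features=200, harris_radius=24.0, use_scale_pyramid=True
)
result = run_pipeline(img_a, img_b, config)

print(f"winning scenario : {result.report['scenario']}")
print(f"candidates       : {result.report['candidates']}")
print(f"inliers          : {result.report['inliers']}")
if result.report["success"]:
    H = result.report["homography"]
    print(f"estimated scale  : {H[0][0]:.3f} (ground truth 0.25)")
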
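"""Using externally detected features.

The descriptor only needs a center and radius, so keypoints from any
detector can be used.  External detectors report an internal scale value
rather than a pixel radius; a feature scaling coefficient converts one to
the other (14 for difference-of-Gaussian scales, 9 for Hessian-type
scales).  Here external detections are simulated as (x, y, scale)
triples, adapted, described, and matched.
"""

from lpm import (
    PipelineConfig,
    adapt_external,
    make_texture,
    run_pipeline,
)

img = make_texture(256, "blobs", seed=8)

# simulated output of a difference-of-Gaussian detector: (x, y, scale)
external = [
    (100.0, 100.0, 2.0),
    (150.0, 120.0, 2.5),
    (80.0, 160.0, 1.8),
    (190.0, 70.0, 2.2),
    (120.0, 190.0, 2.0),
]

feats = adapt_external(external, sigma=14.0)  # SIFT-type coefficient
for (x, y, s), f in zip(external, feats):
    print(f"scale {s:.1f} -> radius {f.radius:.1f} px at ({x:.0f}, {y:.0f})")

config = PipelineConfig(detector="external")
result = run_pipeline(img, img, config, features_a=feats, features_b=feats)
print(
    f"\nself-match: {result.report['candidates']} candidates from "
    f"{result.report['features_a']} described features "
    f"(border features are dropped before description)"
)
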
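"""Evaluating descriptor matches against ground truth.

With a known homography between two images, feature pairs whose discs
overlap sufficiently (overlap error < 0.4) form the ground-truth match
set.  Descriptor matches are scored against it: the matching score is
correct matches over the smaller co-visible feature count, and the
inlier ratio is verified matches over all candidates.
"""

from lpm import (
    Feature,
    PipelineConfig,
    ground_truth_matches,
    inlier_ratio,
    make_pair,
    make_texture,
    matching_score,
    overlap_error,
    run_pipeline,
)

# overlap error of two equal discs as their centers separate
print("overlap error vs center distance (radius 30, identity map):")
import numpy as np

I3 = np.eye(3)
for d in (0, 10, 20, 30, 40, 60):
    res = overlap_error(Feature(0, 0, 30), Feature(d, 0, 30), I3)
    tag = "match" if res.is_match else "no match"
    print(f"  d = {d:2d}: error = {res.error:.3f}  ({tag})")

# end-to-end scoring on a synthetic pair
base = make_texture(256, "blobs", seed=3)
pair = make_pair(base, rotation_deg=30.0, noise_sigma=1.0, seed=3)
result = run_pipeline(pair.img_a, pair.img_b, PipelineConfig(detector="hessian", seed=1))

feats_a = [d.feature for d in result.desc_a]
feats_b = [d.feature for d in result.desc_b]
gt = ground_truth_matches(feats_a, feats_b, pair.H.matrix)
got = {(m.index_a, m.index_b) for m in result.candidates}
correct = len(got & gt)

print(f"\nground-truth pairs : {len(gt)}")
print(f"candidate matches  : {len(got)} ({correct} correct)")
print(f"matching score     : {matching_score(correct, len(feats_a), len(feats_b)):.3f}")
print(f"inlier ratio       : {inlier_ratio(result.report['inliers'], len(got)):.3f}")
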
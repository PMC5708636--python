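# lpm — Log-Polar Magnitude feature descriptor

A compact local feature descriptor for image matching, built from the
magnitude spectrum of a log-polar resampling of each feature's
neighborhood, together with the full matching pipeline around it:
feature detection, descriptor extraction, thresholded nearest-neighbor
matching with the Lowe ratio test, RANSAC homography verification,
ground-truth evaluation metrics, and a scale pyramid for large zoom
differences.

## The method in brief

Each feature is a circular image region (center + radius). Its disc is
resampled onto an `N x N` grid of `N` logarithmically spaced rings times
`N` uniform angles — the log-polar transform (LPT). In this domain a
rotation of the image becomes a circular shift of the columns, and the
magnitude of the 2-D discrete Fourier transform is blind to circular
shifts, so taking FFT magnitudes yields rotation invariance without
estimating an orientation. A fixed low-frequency mask then selects a
small set of spectral magnitudes:

* the DC term is excluded — invariance to additive intensity offsets;
* the zero-angular-frequency line is excluded — those bins are dominated
  by the artificial top/bottom discontinuity of the LPT image;
* one half of the centrally symmetric spectrum is excluded — for real
  inputs it is redundant;
* the final vector is normalized to unit length — invariance to
  multiplicative intensity changes.

The default masks give **48 values for 16×16 sampling and 56 values for
32×32**, far shorter than classical 128-dimensional descriptors. The
logarithmic ring spacing concentrates samples near the feature center,
which also makes the descriptor tolerant to a misestimated feature size
(up to roughly a factor of two); beyond that, a five-scenario scale
pyramid (A vs B, A vs 0.5B, 0.5A vs B, A vs 0.25B, 0.25A vs B) picks the
resize with the most raw matches.

Matching is exhaustive SSD between unit vectors with an absolute
threshold expressed as a percentage of the maximum possible SSD
(`D_max = 2`), making the threshold independent of descriptor length,
plus the Lowe ratio condition (`d1 < 0.6 * d2`). Matches are verified by
RANSAC homography fitting (normalized DLT, MSAC scoring, symmetric
transfer error, local re-estimation to a fixed point).

## Worked example

```python
from lpm import PipelineConfig, make_pair, make_texture, run_pipeline

base = make_texture(256, "blobs", seed=3)              # synthetic blob field
pair = make_pair(base, rotation_deg=30.0, noise_sigma=1.0, seed=3)

result = run_pipeline(pair.img_a, pair.img_b,
                      PipelineConfig(detector="hessian", seed=1))
print(result.report)
```

prints (exactly reproducible):

```
{'features_a': 62, 'features_b': 61, 'candidates': 45, 'inliers': 45,
 'inlier_ratio': 1.0, 'success': True, 'scenario': 'A vs B', 'seed': 1, ...}
```

The recovered homography deviates from the ground-truth 30° rotation by
at most **0.80 px** at the four image corners (per-corner errors
`[0.43, 0.35, 0.16, 0.80]`). Rotating a feature
analytically changes its descriptor by an SSD of about **1e-6**, an
affine intensity remap by about **1e-31**, while descriptors of
*different* features on a textured image differ by a median SSD of
**0.41** — the invariances sit many orders of magnitude below the
distinctiveness floor.

The same pipeline is available from the command line:

```
lpm synth --kind blobs --theta 30 --seed 3 -o pairdir/
lpm pipeline pairdir/img_a.png pairdir/img_b.png --seed 1 -o report.json
```

See `examples/` for narrative scripts covering descriptor invariances,
synthetic-pair matching, external (SIFT/SURF-style) features, the scale
pyramid and the evaluation metrics, and `docs/methods.md` for the
methods note.

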
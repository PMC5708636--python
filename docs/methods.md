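# Methods note

This note records the model implemented by the package, every default
parameter with its rationale, the numerical choices that required
judgment, and the known limitations.

## 1. Model

### 1.1 Features

A feature is a circular region: center `(x, y)` in pixel coordinates
(x right, y down) and a radius `R > 0` in pixels. Features come from
three sources:

* **Harris corners** — response `det(M) − k·trace(M)²` with `k = 0.04`,
  gradients by central differences, structure tensor integrated with a
  Gaussian of σ = 2. Corners carry no scale, so every feature receives a
  fixed radius (default 32 px).
* **Determinant-of-Hessian blobs** — `Ixx·Iyy − Ixy²` from Gaussian
  second derivatives at σ = 2; same fixed radius.
* **External detectors** — consumed as `(x, y, scale)` triples; the
  scale is converted to a radius by a feature scaling coefficient:
  14 for difference-of-Gaussian (SIFT-type) scales, 9 for Hessian-type
  (SURF-type) scales.

Both built-in detectors apply 5×5 non-maximum suppression and keep
maxima above 1% of the strongest response, strongest first. All
description runs on images pre-smoothed by a Gaussian of σ = 1
(reflect boundary), which suppresses pixel noise before interpolation.

### 1.2 Log-polar transform

The disc of radius `R` is resampled on `N` rings × `N` angles
(default `N = 32`). Ring radii are geometric with both endpoints
pinned, `ρ_i = R^(i/(N−1))`, running from 1 to `R`; angles are uniform,
`θ_j = 2πj/N`. The outermost ring is stored as row 0. Sub-pixel values
are read through a 5×5 Gaussian-weighted interpolation (σ = 1) centered
on the nearest pixel, weights normalized to sum 1. Features whose
sampling disc plus the 2-px interpolation margin would leave the image
are dropped before description (this changes evaluation denominators
and is logged).

### 1.3 Descriptor

2-D FFT of the LPT image → elementwise magnitude → values at a fixed
set of DC-centered coordinates `(u, v)` (`u` radial, `v` angular
frequency) → unit normalization. Default mask:
`{1 ≤ |u| ≤ r_e, 1 ≤ v ≤ 4}` with radial extent `r_e = 6` for N=16 and
`7` for N=32 → vector lengths **48** and **56**. More radial than
angular frequencies are kept because intensity variation from the
center outward is the more discriminative direction. Flat patches whose
selected magnitudes vanish are flagged degenerate and dropped.

### 1.4 Matching

Exhaustive SSD between unit vectors (`SSD = 2 − 2⟨a,b⟩`). A candidate
must satisfy (a) nearest-neighbor status for its query, (b) absolute
threshold `SSD < (threshold_pct/100) · 2` with `threshold_pct = 1`
(length-independent because `D_max = 2` for any unit non-negative
vectors), and (c) the Lowe condition `d1 < 0.6 · d2`. Each query
matches at most one reference; several queries may share a reference
(legitimate under large scale differences).

### 1.5 Verification

RANSAC over 4-point minimal samples with normalized DLT, MSAC scoring
(truncated quadratic, tolerance 3 px on the symmetric transfer error),
adaptive stopping at confidence 0.999 (disable by setting confidence to
1.0), followed by iterated least-squares re-estimation on the inlier
set to a fixed point. Hypothesis generation is vectorized in batches;
runs are deterministic given the seed and invariant to input match
order (matches are canonically sorted first).

### 1.6 Evaluation

Ground truth comes from a known homography: a feature pair is a true
correspondence when the overlap error — 1 minus intersection-over-union
of the A-disc and the B-disc mapped into A's frame — is below
`ε₀ = 0.4`. Areas are measured by counting pixels on a 1-px raster; the
closed-form circle-lens area serves as a test oracle for the identity
case (agreement within 0.003). Matching score = correct matches over
the smaller co-visible feature count; inlier ratio = verified matches
over all candidates.

### 1.7 Scale pyramid

Five scenarios (A vs B, A vs 0.5B, 0.5A vs B, A vs 0.25B, 0.25A vs B;
bicubic resizing) are each run through detect–describe–match; the one
with the most raw candidates wins, ties breaking toward no resize, then
the milder resize. Coordinates are mapped back to the original frames
by the pixel-center-aligned inverse `orig = (coord + 0.5)/f − 0.5`.
With no scale difference the pyramid provably returns the plain
pipeline's result (the A-vs-B scenario wins ties).

## 2. Parameter summary

| parameter | default | rationale |
|---|---|---|
| N (LPT resolution) | 32 | descriptor length 56; 16 → 48 also supported |
| radial / angular mask extent | 7 (6 for N=16) / 4 | lengths 48/56; radial bias is more discriminative |
| pre-smoothing σ | 1.0 | noise suppression before interpolation |
| interpolation | 5×5 Gaussian, σ=1 | sub-pixel reads; margin 2 px |
| fixed detector radius | 32 px | scale-less built-in detectors |
| scaling coefficient σ_SIFT / σ_SURF | 14 / 9 | converts detector scales to radii |
| match threshold | 1% of D_max=2 | length-independent absolute cutoff |
| Lowe ratio τ_L | 0.6 | ambiguity rejection |
| overlap threshold ε₀ | 0.4 | ground-truth match criterion |
| RANSAC tolerance | 3 px | symmetric transfer error |
| RANSAC confidence / cap | 0.999 / 10⁴ | adaptive stop; raise cap for low inlier rates |

## 3. Numerical notes

* **Interpolation bias.** The nearest-pixel-centered 5×5 Gaussian
  interpolation has a sub-pixel-dependent effective kernel; on
  band-limited fixtures the LPT column-shift identity under rotation
  holds only to ~1e-2 (worst at the innermost rings). The error is
  incoherent across samples and the descriptor-level rotation SSD is
  ~1e-6 — four orders below the matching threshold — so the bias is
  documented rather than corrected.
* **Scale-tolerance vs threshold.** At a factor-1.5–2 feature-size
  error the descriptor SSD grows to ~0.03–0.2, still far below the
  inter-feature median (~0.4) but above the default 1% absolute cutoff
  (0.02). Matching across a deliberate scale change therefore needs
  either a raised threshold (2–3%) or the scale pyramid.
* **RANSAC at very low inlier rates.** With only a handful of absolute
  inliers, spurious consensus sets (4 exactly-fit outliers plus an
  accidental capture) can outscore the true model regardless of the
  iteration budget. The stress regime exercised in the tests uses a 5%
  inlier *rate* with 15 absolute inliers of 300 matches, cap 2·10⁶,
  adaptive stop disabled: recovery there is 15/15 with no extras.
* **Projective extrapolation.** Fitting the full 8-dof homography to
  similarity-generated data amplifies ~0.6 px inlier noise to a few px
  at image corners outside the inlier hull; corner-error bounds in the
  tests account for this estimator variance.
* **Determinism.** All randomness flows through explicit
  `numpy.random.default_rng(seed)` instances; pipeline runs, synthetic
  pairs and RANSAC results are bit-reproducible per seed.

## 4. Problem sizes

Designed and tested at desk scale: images 64–512 px square, tens to
hundreds of features, descriptor extraction ~0.3 ms (N=16) to ~2.4 ms
(N=32/64) per feature in pure numpy, full pipeline on a 256² pair well
under 10 s, the RANSAC stress run ~50 s.

## 5. Scope and limitations

* Synthetic ground truth uses similarity transforms only; full
  projective viewpoint change is fit by verification but not generated,
  since circular features degrade under strong viewpoint distortion.
* The evaluation module reproduces the overlap-error protocol, not any
  external benchmark harness or dataset downloads.
* Descriptors are compared by SSD only; no approximate nearest-neighbor
  indexing is provided (exhaustive matching is exact and fast at these
  sizes).
* The scale pyramid covers zoom factors up to 4 in either direction via
  the five fixed scenarios; it does not estimate continuous zoom.
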
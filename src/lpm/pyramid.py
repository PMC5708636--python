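"""Scale pyramid: zoom estimation by comparing five resize scenarios.

When the zoom difference between two images exceeds what the log-polar
sampling absorbs (about a factor of 2) and no detector scale information
is available, the pipeline can compare five scenarios — A vs B, A vs
0.5B, A vs 0.25B, 0.5A vs B, 0.25A vs B — and keep the one producing the
most raw candidate matches (false matches included; verification happens
afterwards).  Feature coordinates from a resized scenario are scaled back
to the original image frames so homography fitting and display are
unaffected.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import rescale

from .descriptor import describe_all
from .image_io import Image, presmooth
from .matching import match

__all__ = ["SCENARIOS", "pyramid_match"]

#: (name, factor applied to A, factor applied to B); listed in
#: tie-breaking priority order: no resize first, then the milder resizes
SCENARIOS: tuple[tuple[str, float, float], ...] = (
    ("A vs B", 1.0, 1.0),
    ("A vs 0.5B", 1.0, 0.5),
    ("0.5A vs B", 0.5, 1.0),
    ("A vs 0.25B", 1.0, 0.25),
    ("0.25A vs B", 0.25, 1.0),
)


def _resize(img: Image, factor: float) -> Image:
    if factor == 1.0:
        return img
    px = rescale(
        img.pixels, factor, order=3, anti_aliasing=factor < 1.0, preserve_range=True
    )
    return Image(px)


def pyramid_match(img_a: Image, img_b: Image, config):
    """Run detect-describe-match under all five scenarios; keep the best.

    Returns ``(scenario_name, candidates, desc_a, desc_b, coords_a,
    coords_b)`` with coordinates in the *original* image frames.  Ties
    break toward no resize, then toward the milder resize.  A scenario
    where either image has no describable features scores zero.
    """
    from .pipeline import _detect

    best = None
    for name, fa, fb in SCENARIOS:
        try:
            ra, rb = _resize(img_a, fa), _resize(img_b, fb)
        except ValueError:  # image shrunk below the minimum size
            continue
        sm_a, sm_b = presmooth(ra), presmooth(rb)
        feats_a = _detect(sm_a, config)
        feats_b = _detect(sm_b, config)
        desc_a = describe_all(sm_a, feats_a, config.N, config.get_mask())
        desc_b = describe_all(sm_b, feats_b, config.N, config.get_mask())
        candidates = (
            match(desc_a, desc_b, config.threshold_pct, config.tau_L)
            if desc_a and desc_b
            else []
        )
        entry = (name, fa, fb, candidates, desc_a, desc_b)
        if best is None or len(candidates) > len(best[3]):
            best = entry

    if best is None:
        raise ValueError("no scenario could be evaluated")
    name, fa, fb, candidates, desc_a, desc_b = best

    def back(coord: float, f: float) -> float:
        # pixel-center-aligned inverse of rescale: resized pixel i covers
        # original (i + 0.5) / f - 0.5
        return coord if f == 1.0 else (coord + 0.5) / f - 0.5

    coords_a = np.array(
        [[back(d.feature.x, fa), back(d.feature.y, fa)] for d in desc_a]
    ).reshape(-1, 2)
    coords_b = np.array(
        [[back(d.feature.x, fb), back(d.feature.y, fb)] for d in desc_b]
    ).reshape(-1, 2)
    return name, candidates, desc_a, desc_b, coords_a, coords_b
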
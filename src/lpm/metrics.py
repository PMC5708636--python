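"""Evaluation metrics: overlap error, ground-truth matches, matching
score and inlier ratio.

Ground truth for descriptor evaluation comes from a known homography
between the two images: a feature pair is a true correspondence when the
discs, brought into a common frame through the homography, overlap
sufficiently.  The overlap error is one minus intersection-over-union of
the two regions, with areas measured by counting pixels on a common 1-px
raster; a pair counts as a match when the error is below a threshold
(0.4 by default — larger values tolerate more accidental overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detect import Feature
from .homography import Homography

__all__ = [
    "OverlapResult",
    "overlap_error",
    "ground_truth_matches",
    "matching_score",
    "inlier_ratio",
    "visible_features",
]

DEFAULT_EPSILON0 = 0.4


@dataclass(frozen=True)
class OverlapResult:
    error: float
    is_match: bool


def _as_matrix(H) -> Homography:
    return H if isinstance(H, Homography) else Homography(np.asarray(H))


def overlap_error(
    feat_a: Feature,
    feat_b: Feature,
    H,
    epsilon0: float = DEFAULT_EPSILON0,
) -> OverlapResult:
    """Overlap error between a disc in image A and a disc in image B
    mapped into A's frame through the homography ``H`` (A -> B).

    A pixel of A's frame belongs to the mapped B disc iff its image under
    ``H`` lies inside ``feat_b``'s disc; intersection and union are
    counted in pixels on a raster covering both regions.  ``is_match`` is
    true when the error is below ``epsilon0``.
    """
    H = _as_matrix(H)
    Hinv = H.inverse()
    # bounding box: disc A plus the mapped outline of disc B
    angles = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    circle_b = np.stack(
        [
            feat_b.x + feat_b.radius * np.cos(angles),
            feat_b.y + feat_b.radius * np.sin(angles),
        ],
        axis=1,
    )
    mapped_b = Hinv.apply(circle_b)
    x_lo = min(feat_a.x - feat_a.radius, mapped_b[:, 0].min()) - 1
    x_hi = max(feat_a.x + feat_a.radius, mapped_b[:, 0].max()) + 1
    y_lo = min(feat_a.y - feat_a.radius, mapped_b[:, 1].min()) - 1
    y_hi = max(feat_a.y + feat_a.radius, mapped_b[:, 1].max()) + 1
    xs = np.arange(np.floor(x_lo), np.ceil(x_hi) + 1)
    ys = np.arange(np.floor(y_lo), np.ceil(y_hi) + 1)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)

    in_a = (pts[:, 0] - feat_a.x) ** 2 + (pts[:, 1] - feat_a.y) ** 2 <= feat_a.radius**2
    fwd = H.apply(pts)
    in_b = (fwd[:, 0] - feat_b.x) ** 2 + (fwd[:, 1] - feat_b.y) ** 2 <= feat_b.radius**2

    union = int(np.sum(in_a | in_b))
    if union == 0:
        return OverlapResult(error=1.0, is_match=False)
    inter = int(np.sum(in_a & in_b))
    err = 1.0 - inter / union
    return OverlapResult(error=err, is_match=err < epsilon0)


def _disc_in_frame(f: Feature, shape: tuple[int, int]) -> bool:
    h, w = shape
    return (
        f.x - f.radius >= 0
        and f.y - f.radius >= 0
        and f.x + f.radius <= w - 1
        and f.y + f.radius <= h - 1
    )


def _mapped_box_in_frame(f: Feature, H: Homography, shape: tuple[int, int]) -> bool:
    angles = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    outline = np.stack(
        [f.x + f.radius * np.cos(angles), f.y + f.radius * np.sin(angles)], axis=1
    )
    mapped = H.apply(outline)
    h, w = shape
    return (
        mapped[:, 0].min() >= 0
        and mapped[:, 1].min() >= 0
        and mapped[:, 0].max() <= w - 1
        and mapped[:, 1].max() <= h - 1
    )


def visible_features(
    feats: Sequence[Feature],
    H,
    shape_own: tuple[int, int],
    shape_other: tuple[int, int],
) -> list[int]:
    """Indices of features fully visible in both frames: the disc fits in
    its own frame and its mapped outline's bounding box fits in the other
    frame (``H`` maps own coordinates to the other frame)."""
    H = _as_matrix(H)
    return [
        i
        for i, f in enumerate(feats)
        if _disc_in_frame(f, shape_own) and _mapped_box_in_frame(f, H, shape_other)
    ]


def ground_truth_matches(
    feats_a: Sequence[Feature],
    feats_b: Sequence[Feature],
    H,
    epsilon0: float = DEFAULT_EPSILON0,
    shape_a: tuple[int, int] | None = None,
    shape_b: tuple[int, int] | None = None,
) -> set[tuple[int, int]]:
    """All index pairs ``(i, j)`` whose overlap error is below ``epsilon0``.

    ``H`` maps A coordinates to B coordinates.  When the image shapes are
    given, pairs are restricted to features fully visible in both frames.
    """
    H = _as_matrix(H)
    idx_a = range(len(feats_a))
    idx_b = range(len(feats_b))
    if shape_a is not None and shape_b is not None:
        idx_a = visible_features(feats_a, H, shape_a, shape_b)
        idx_b = visible_features(feats_b, H.inverse(), shape_b, shape_a)
    pairs = set()
    for i in idx_a:
        for j in idx_b:
            if overlap_error(feats_a[i], feats_b[j], H, epsilon0).is_match:
                pairs.add((i, j))
    return pairs


def matching_score(correct: int, n_visible_a: int, n_visible_b: int) -> float:
    """Correct matches over the smaller count of co-visible features."""
    if correct < 0 or n_visible_a < 0 or n_visible_b < 0:
        raise ValueError("counts must be non-negative")
    denom = min(n_visible_a, n_visible_b)
    if denom == 0:
        raise ZeroDivisionError("no co-visible features: matching score undefined")
    return correct / denom


def inlier_ratio(n_inliers: int, n_matches: int) -> float:
    """Verified matches over all candidate matches (0 when no candidates)."""
    if n_inliers < 0 or n_matches < 0:
        raise ValueError("counts must be non-negative")
    if n_inliers > n_matches:
        raise ValueError(f"inliers ({n_inliers}) exceed matches ({n_matches})")
    if n_matches == 0:
        return 0.0
    return n_inliers / n_matches
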
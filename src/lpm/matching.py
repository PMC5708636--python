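"""Candidate matching: exhaustive thresholded search with the Lowe ratio test.

Distances are sums of squared differences (SSD) between unit-length
descriptor vectors, computed exhaustively so no potential match is missed.
The absolute distance threshold is expressed as a percentage of the
maximum achievable SSD between two unit-length non-negative vectors
(``D_max = 2``, attained by orthogonal vectors), which makes the threshold
independent of descriptor length — descriptors of different lengths can be
compared under the same setting.  On top of the threshold, the Lowe
condition rejects ambiguous matches: a query is kept only when its second
nearest neighbor is substantially farther than the nearest
(``d1 / d2 < tau_L``, default 0.6).

Each query (a vector of the second, transformed image) matches at most its
single nearest neighbor in the reference set, but several queries may
match the same reference vector — such one-to-many matches are legitimate
under large scale differences, where one coarse-scale feature covers
several fine-scale ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .descriptor import FeatureVector

__all__ = ["MatchCandidate", "match", "MAX_UNIT_SSD"]

#: maximum SSD between two unit-length vectors with non-negative components
MAX_UNIT_SSD = 2.0


@dataclass(frozen=True)
class MatchCandidate:
    """One candidate correspondence: positions in the two descriptor lists,
    their SSD, and the second-to-first neighbor distance ratio (``inf``
    when the nearest neighbor is unique or exact)."""

    index_a: int
    index_b: int
    distance: float
    ratio: float


def match(
    desc_a: Sequence[FeatureVector],
    desc_b: Sequence[FeatureVector],
    threshold_pct: float = 1.0,
    tau_L: float = 0.6,
) -> list[MatchCandidate]:
    """Match descriptors of image B (queries) into image A (reference).

    A pair ``(a, b)`` is emitted iff ``a`` is ``b``'s nearest neighbor,
    ``SSD(a, b) < threshold_pct / 100 * 2``, and the Lowe condition
    ``d1 < tau_L * d2`` holds (``d1`` nearest, ``d2`` second-nearest SSD).
    An exact nearest match (``d1 = 0``) with a distinct second neighbor is
    always accepted.  Nearest-neighbor ties break toward the lowest
    reference index, for determinism.
    """
    if len(desc_a) == 0 or len(desc_b) == 0:
        return []
    A = np.stack([d.values for d in desc_a])
    B = np.stack([d.values for d in desc_b])
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"descriptor length mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    cutoff = threshold_pct / 100.0 * MAX_UNIT_SSD
    # SSD between unit vectors: 2 - 2 <a, b>; clip the tiny negatives from rounding
    d2mat = np.maximum(2.0 - 2.0 * (B @ A.T), 0.0)

    out: list[MatchCandidate] = []
    for j in range(len(desc_b)):
        row = d2mat[j]
        i1 = int(np.argmin(row))  # argmin takes the lowest index on ties
        d1 = float(row[i1])
        if len(row) > 1:
            rest = np.delete(row, i1)
            d2 = float(rest.min())
        else:
            d2 = np.inf
        ratio = np.inf if d1 == 0.0 else d2 / d1
        lowe_ok = (d1 == 0.0 and d2 > 0.0) or (np.isinf(d2)) or (d1 < tau_L * d2)
        if d1 < cutoff and lowe_ok:
            out.append(MatchCandidate(index_a=i1, index_b=j, distance=d1, ratio=ratio))
    return out
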
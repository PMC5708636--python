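"""The Log-Polar Magnitude feature vector.

The descriptor of a feature is built in three steps: 2-D FFT of the
feature's log-polar image, elementwise magnitude, and selection of a fixed
set of low-frequency coordinates (the frequency mask).  The magnitude
spectrum is invariant to circular shifts of the input, so rotations of the
underlying image patch — which the log-polar transform turns into column
shifts — leave the descriptor unchanged without any orientation
normalization.  Dropping the DC component makes it invariant to additive
intensity offsets, and the final unit-length normalization removes
multiplicative intensity changes.

Frequency coordinates are DC-centered: ``u`` indexes radial frequency
(variation from ring to ring, i.e. along image rows), ``v`` angular
frequency (variation along each ring).  The default mask is a pair of
rectangles mirrored across the angular axis::

    {(u, v) : 1 <= |u| <= radial_extent, 1 <= v <= angular_extent}

with radial extent 6 for 16 x 16 sampling and 7 for 32 x 32, angular
extent 4 for both — 48 and 56 selected magnitudes respectively.  The mask
excludes:

* the DC component (average intensity — illumination invariance);
* the entire ``v = 0`` line: those "primarily horizontal" frequencies are
  dominated by the artificial top-vs-bottom row discontinuity of the LPT
  image (the FFT treats the signal as periodic, and the innermost and
  outermost rings generally differ sharply);
* one half-plane of the centrally symmetric spectrum of a real image,
  which carries no extra information.

Giving more radial than angular indices prioritizes intensity changes
from the feature center outwards over changes along the rings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .detect import Feature, remove_border_features
from .image_io import Image
from .lpt import LPTImage, sample_patch

__all__ = [
    "FrequencyMask",
    "FeatureVector",
    "build_default_mask",
    "compute_descriptor",
    "describe_all",
    "load_mask",
    "save_mask",
]

DEGENERATE_NORM = 1e-12


@dataclass(frozen=True)
class FrequencyMask:
    """An ordered set of DC-centered DFT coordinates forming the descriptor.

    ``selected`` lists ``(u, v)`` pairs: ``u`` radial (row) frequency, ``v``
    angular (column) frequency.  The DC term must be excluded and no
    coordinate may appear together with its point reflection ``(-u, -v)``
    (the spectrum of a real image is centrally symmetric, so that pair is
    redundant).
    """

    N: int
    selected: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        sel = tuple((int(u), int(v)) for u, v in self.selected)
        half = self.N // 2
        seen = set()
        for u, v in sel:
            if (u, v) == (0, 0):
                raise ValueError("mask must exclude the DC component")
            if not (-half <= u <= half - 1 and -half <= v <= half - 1):
                raise ValueError(f"frequency ({u}, {v}) out of range for N={self.N}")
            if (u, v) in seen:
                raise ValueError(f"duplicate frequency ({u}, {v})")
            if (-u, -v) in seen:
                raise ValueError(f"redundant symmetric pair ({u}, {v}) / ({-u}, {-v})")
            seen.add((u, v))
        object.__setattr__(self, "selected", sel)

    def __len__(self) -> int:
        return len(self.selected)


@dataclass(frozen=True)
class FeatureVector:
    """Unit-length vector of selected FFT magnitudes for one feature."""

    values: np.ndarray
    feature: Feature
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if not self.degenerate:
            n = np.linalg.norm(v)
            if abs(n - 1.0) > 1e-9:
                raise ValueError(f"feature vector norm {n} != 1")
            if np.any(v < 0):
                raise ValueError("magnitudes must be non-negative")


def build_default_mask(N: int, radial_extent: int | None = None, angular_extent: int = 4) -> FrequencyMask:
    """The default double-rectangle mask for a given sampling resolution.

    Radial extent defaults to 6 for N=16 and 7 for N=32, giving vector
    lengths 48 and 56.  Coordinates are ordered ``v`` ascending then ``u``
    ascending, which fixes the layout of every feature vector.
    """
    if radial_extent is None:
        if N == 16:
            radial_extent = 6
        elif N == 32:
            radial_extent = 7
        else:
            raise ValueError(
                f"no default radial extent for N={N}; pass radial_extent explicitly"
            )
    if N < 2 * radial_extent + 1 or N < 2 * angular_extent + 1:
        raise ValueError(
            f"N={N} too small for extents ({radial_extent}, {angular_extent})"
        )
    selected = [
        (u, v)
        for v in range(1, angular_extent + 1)
        for u in range(-radial_extent, radial_extent + 1)
        if u != 0
    ]
    return FrequencyMask(N=N, selected=tuple(selected))


def compute_descriptor(lpt: LPTImage, mask: FrequencyMask) -> FeatureVector:
    """FFT magnitude of the LPT image, read at the mask, unit-normalized.

    A flat patch has energy only in the DC bin; its selected magnitudes
    are all (numerically) zero and the vector is flagged degenerate — the
    pipeline drops such features rather than emit a zero vector that would
    spuriously match every other flat patch.
    """
    N = lpt.N
    if mask.N != N:
        raise ValueError(f"mask is for N={mask.N}, LPT image is {N}x{N}")
    spectrum = np.abs(np.fft.fft2(lpt.values))
    u = np.array([c[0] for c in mask.selected]) % N
    v = np.array([c[1] for c in mask.selected]) % N
    vals = spectrum[u, v]
    norm = np.linalg.norm(vals)
    if norm < DEGENERATE_NORM:
        return FeatureVector(values=np.zeros(len(mask)), feature=lpt.feature, degenerate=True)
    return FeatureVector(values=vals / norm, feature=lpt.feature)


def describe_all(
    img: Image,
    features: Sequence[Feature],
    N: int = 32,
    mask: FrequencyMask | None = None,
) -> list[FeatureVector]:
    """Describe every feature of a (pre-smoothed) image.

    Border features whose sampling neighborhood would leave the image are
    removed first; degenerate (flat-patch) vectors are dropped.  Output
    order follows input feature order.
    """
    if mask is None:
        mask = build_default_mask(N)
    out = []
    for f in remove_border_features(features, img):
        fv = compute_descriptor(sample_patch(img, f, N), mask)
        if not fv.degenerate:
            out.append(fv)
    return out


def write_descriptors(path: str | Path, descriptors: Sequence[FeatureVector]) -> None:
    """Write descriptors as CSV ``x,y,radius,v0,...,v{L-1}``."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if descriptors:
            L = len(descriptors[0].values)
            w.writerow(["x", "y", "radius"] + [f"v{i}" for i in range(L)])
            for d in descriptors:
                w.writerow(
                    [f"{d.feature.x:.6f}", f"{d.feature.y:.6f}", f"{d.feature.radius:.6f}"]
                    + [f"{v:.12g}" for v in d.values]
                )
        else:
            w.writerow(["x", "y", "radius"])


def read_descriptors(path: str | Path) -> list[FeatureVector]:
    import csv

    out: list[FeatureVector] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty descriptor file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x, y, r = (float(c) for c in row[:3])
                vals = np.array([float(c) for c in row[3:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row") from exc
            feat = Feature(x=x, y=y, radius=r, source="external")
            n = np.linalg.norm(vals)
            out.append(FeatureVector(values=vals / n if n > 0 else vals, feature=feat))
    return out


def save_mask(path: str | Path, mask: FrequencyMask) -> None:
    Path(path).write_text(
        json.dumps({"N": mask.N, "selected": [list(c) for c in mask.selected]}) + "\n"
    )


def load_mask(path: str | Path) -> FrequencyMask:
    data = json.loads(Path(path).read_text())
    return FrequencyMask(N=int(data["N"]), selected=tuple((u, v) for u, v in data["selected"]))
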
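"""Image and feature-file input/output plus pre-smoothing.

Conventions used throughout the package:

* coordinates are 0-based with ``x`` = column and ``y`` = row; pixel
  centers sit at integer coordinates;
* intensities are floats on an arbitrary scale — the descriptor is
  invariant to affine intensity maps, so no rescaling happens on load;
* every image is smoothed exactly once (Gaussian, sigma = 1) before both
  detection and description.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Image",
    "load_image",
    "presmooth",
    "write_features",
    "read_features",
    "write_matches",
    "read_matches",
    "write_homography",
    "read_homography",
]


@dataclass(frozen=True)
class Image:
    """A 2-D grayscale image with float intensities on an arbitrary scale."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image too small: {px.shape} (need at least 8x8)")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | Path) -> Image:
    """Read a PNG or TIFF image as grayscale floats.

    RGB(A) images are collapsed to grayscale by the unweighted mean of the
    color channels (alpha, if present, is ignored).  Integer sample values
    are cast to float without rescaling: a 16-bit pixel of 40000 stays
    40000.0.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw, dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return Image(arr)


def save_image(path: str | Path, img: Image) -> None:
    """Write an image as 8-bit PNG (intensities min-max scaled) or as
    float TIFF (kept verbatim), chosen by the file extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        iio.imwrite(path, img.pixels.astype(np.float32))
    else:
        px = img.pixels
        lo, hi = px.min(), px.max()
        scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo) * 255.0
        iio.imwrite(path, np.round(scaled).astype(np.uint8))


def presmooth(img: Image, sigma: float = 1.0) -> Image:
    """Gaussian pre-smoothing of the input image (variance 1 by default).

    This is the only pre-computation of the whole method; the smoothed
    image feeds both detection and descriptor sampling.  The kernel is
    truncated at 4 sigma and borders are handled by reflection, so constant
    images and the total intensity of interior-dominated images are
    preserved.
    """
    return Image(gaussian_filter(img.pixels, sigma=sigma, mode="reflect", truncate=4.0))


# ---------------------------------------------------------------------------
# feature / match / homography files (plain-text interchange formats)

def write_features(path: str | Path, features) -> None:
    """Write features as CSV with header ``x,y,radius`` (6-decimal fixed)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "radius"])
        for f in features:
            w.writerow([f"{f.x:.6f}", f"{f.y:.6f}", f"{f.radius:.6f}"])


def read_features(path: str | Path):
    """Read a feature CSV written by :func:`write_features`.

    Malformed rows raise ``ValueError`` carrying the 1-based line number.
    """
    from .detect import Feature

    feats = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["x", "y", "radius"]:
            raise ValueError(f"{path}: line 1: expected header 'x,y,radius'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x, y, r = (float(c) for c in row[:3])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row {row!r}") from exc
            try:
                feats.append(Feature(x=x, y=y, radius=r, source="external"))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return feats


def write_matches(path: str | Path, rows) -> None:
    """Write matches as CSV ``x1,y1,x2,y2,distance,is_inlier``.

    ``rows`` yields tuples in that order; ``is_inlier`` is written 0/1.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x1", "y1", "x2", "y2", "distance", "is_inlier"])
        for x1, y1, x2, y2, d, inl in rows:
            w.writerow(
                [f"{x1:.6f}", f"{y1:.6f}", f"{x2:.6f}", f"{y2:.6f}", f"{d:.9g}", int(inl)]
            )


def read_matches(path: str | Path):
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty matches file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x1, y1, x2, y2, d = (float(c) for c in row[:5])
                inl = bool(int(row[5]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row {row!r}") from exc
            out.append((x1, y1, x2, y2, d, inl))
    return out


def write_homography(path: str | Path, H: np.ndarray) -> None:
    """Write a 3x3 homography as 9 whitespace-separated numbers, row-major."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape != (3, 3):
        raise ValueError(f"homography must be 3x3, got {H.shape}")
    Path(path).write_text(" ".join(f"{v:.17g}" for v in H.ravel()) + "\n")


def read_homography(path: str | Path) -> np.ndarray:
    vals = Path(path).read_text().split()
    if len(vals) != 9:
        raise ValueError(f"{path}: expected 9 numbers, got {len(vals)}")
    return np.array([float(v) for v in vals], dtype=np.float64).reshape(3, 3)
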
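"""End-to-end matching pipeline: smooth, detect, describe, match, verify.

This is the glue the command-line interface and the examples run: a
single configuration object carrying every default of the method, and one
function taking two images to a verified match set plus a JSON-ready
report of per-stage counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .descriptor import FeatureVector, FrequencyMask, build_default_mask, describe_all
from .detect import Feature, detect_harris, detect_hessian
from .homography import VerifiedMatchSet, verify
from .image_io import Image, presmooth
from .matching import MatchCandidate, match
from .metrics import inlier_ratio

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_report"]


@dataclass
class PipelineConfig:
    """All tunables of the matching pipeline, with the method's defaults.

    ``sigma_sift`` / ``sigma_surf`` convert external detector scales to
    pixel radii; ``harris_radius`` is the fixed radius of the scale-less
    built-in detectors.
    """

    detector: str = "harris"  # harris | hessian | external
    max_features: int = 500
    harris_radius: float = 32.0
    N: int = 32
    mask: FrequencyMask | None = None
    threshold_pct: float = 1.0
    tau_L: float = 0.6
    epsilon0: float = 0.4
    sigma_sift: float = 14.0
    sigma_surf: float = 9.0
    ransac_tol: float = 3.0
    seed: int = 0
    use_scale_pyramid: bool = False

    def get_mask(self) -> FrequencyMask:
        return self.mask if self.mask is not None else build_default_mask(self.N)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    """Pipeline output: descriptors of both images, candidate matches,
    the verified set, and a flat JSON-ready report."""

    desc_a: list[FeatureVector]
    desc_b: list[FeatureVector]
    candidates: list[MatchCandidate]
    verified: VerifiedMatchSet | None
    report: dict
    scenario: str = "A vs B"


def _detect(img: Image, config: PipelineConfig) -> list[Feature]:
    if config.detector == "harris":
        return detect_harris(img, config.max_features, config.harris_radius)
    if config.detector == "hessian":
        return detect_hessian(img, config.max_features, config.harris_radius)
    raise ValueError(f"unknown detector {config.detector!r} (external features must be passed in)")


def run_pipeline(
    img_a: Image,
    img_b: Image,
    config: PipelineConfig | None = None,
    features_a: Sequence[Feature] | None = None,
    features_b: Sequence[Feature] | None = None,
) -> PipelineResult:
    """Run the full matching pipeline on an image pair.

    Externally detected features may be passed in; otherwise the
    configured built-in detector runs on the pre-smoothed images.  With
    ``use_scale_pyramid`` the five resize scenarios are compared first and
    matching proceeds from the best one (coordinates reported in the
    original frames).  Verification failure (too few candidates, or no
    consensus) is reported with ``success: false``, not raised.
    """
    config = config or PipelineConfig()
    mask = config.get_mask()
    scenario = "A vs B"

    if config.use_scale_pyramid and features_a is None and features_b is None:
        from .pyramid import pyramid_match

        scenario, candidates, desc_a, desc_b, coords_a, coords_b = pyramid_match(
            img_a, img_b, config
        )
    else:
        sm_a, sm_b = presmooth(img_a), presmooth(img_b)
        feats_a = list(features_a) if features_a is not None else _detect(sm_a, config)
        feats_b = list(features_b) if features_b is not None else _detect(sm_b, config)
        desc_a = describe_all(sm_a, feats_a, config.N, mask)
        desc_b = describe_all(sm_b, feats_b, config.N, mask)
        candidates = match(desc_a, desc_b, config.threshold_pct, config.tau_L)
        coords_a = np.array([[d.feature.x, d.feature.y] for d in desc_a]).reshape(-1, 2)
        coords_b = np.array([[d.feature.x, d.feature.y] for d in desc_b]).reshape(-1, 2)

    verified = None
    if len(candidates) >= 4:
        verified = verify(
            candidates, coords_a, coords_b, pixel_tol=config.ransac_tol, seed=config.seed
        )
    n_inl = len(verified.inliers) if verified is not None and verified.success else 0
    report = {
        "features_a": len(desc_a),
        "features_b": len(desc_b),
        "candidates": len(candidates),
        "inliers": n_inl,
        "inlier_ratio": inlier_ratio(n_inl, len(candidates)),
        "success": bool(verified is not None and verified.success),
        "scenario": scenario,
        "seed": config.seed,
        "homography": (
            verified.homography.matrix.tolist()
            if verified is not None and verified.success
            else None
        ),
    }
    return PipelineResult(
        desc_a=list(desc_a),
        desc_b=list(desc_b),
        candidates=list(candidates),
        verified=verified,
        report=report,
        scenario=scenario,
    )


#: minimal schema of the pipeline report (field name -> allowed types)
REPORT_SCHEMA: dict[str, tuple] = {
    "features_a": (int,),
    "features_b": (int,),
    "candidates": (int,),
    "inliers": (int,),
    "inlier_ratio": (int, float),
    "success": (bool,),
    "scenario": (str,),
    "seed": (int,),
    "homography": (list, type(None)),
}


def validate_report(report: dict) -> None:
    """Raise ``ValueError`` unless ``report`` conforms to REPORT_SCHEMA."""
    for key, types in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing field {key!r}")
        if not isinstance(report[key], types):
            raise ValueError(f"report field {key!r} has type {type(report[key]).__name__}")
    if report["homography"] is not None:
        H = report["homography"]
        if len(H) != 3 or any(len(row) != 3 for row in H):
            raise ValueError("homography must be a 3x3 nested list")
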
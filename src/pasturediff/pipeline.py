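"""End-to-end orchestration: difference -> threshold -> polygons -> metrics."""

from __future__ import annotations

from dataclasses import dataclass

from .detect import (
    DetectionPolygon,
    SpatialThreshold,
    SpectralThreshold,
    extract_polygons,
    filter_by_area,
    suggest_threshold,
    threshold_mask,
)
from .errors import ThresholdError
from .evaluate import (
    EvaluationResult,
    MatchResult,
    TruthSet,
    compute_metrics,
    match_detections,
)
from .pca import DifferenceImage, PCAResult, difference_pc1
from .raster import MultibandImage


@dataclass
class PipelineResult:
    diff: DifferenceImage
    pca_t1: PCAResult
    pca_t2: PCAResult
    threshold: SpectralThreshold
    polygons: list[DetectionPolygon]  # after the area filter
    n_candidates: int  # components before the area filter
    match: MatchResult | None
    evaluation: EvaluationResult | None


def run_pipeline(
    t1: MultibandImage,
    t2: MultibandImage,
    truth: TruthSet | None = None,
    threshold: SpectralThreshold | None = None,
    percentile: float = 0.05,
    spatial: SpatialThreshold = SpatialThreshold(),
    connectivity: int = 8,
    r_match: float = 1.0,
    match_mode: str = "both",
    label: str = "",
) -> PipelineResult:
    """Run the full differencing pipeline on one acquisition pair.

    The spectral threshold is either supplied (``threshold``) or derived
    from the truth set (:func:`~pasturediff.detect.suggest_threshold` at
    ``percentile``); evaluation against the truth set is performed when
    truth is given.
    """
    diff, p1, p2 = difference_pc1(t1, t2)
    if threshold is None:
        if truth is None:
            raise ThresholdError(
                "either an explicit spectral threshold or a truth set "
                "(to derive one from) is required"
            )
        threshold = suggest_threshold(diff, truth, percentile=percentile)
    mask = threshold_mask(diff, threshold)
    candidates = extract_polygons(mask, diff.transform, connectivity=connectivity)
    polygons = filter_by_area(candidates, spatial)
    match = evaluation = None
    if truth is not None:
        match = match_detections(polygons, truth, r_match=r_match, mode=match_mode)
        evaluation = compute_metrics(match, truth.known_count, label=label)
    return PipelineResult(
        diff=diff,
        pca_t1=p1,
        pca_t2=p2,
        threshold=threshold,
        polygons=polygons,
        n_candidates=len(candidates),
        match=match,
        evaluation=evaluation,
    )
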
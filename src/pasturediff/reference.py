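"""Published validation data from the original eight-pasture field campaign.

The technique was validated on eight fenced pastures of cattle and horses
in northern Utah, imaged twice on one day with concurrent ground counts.
The per-pasture detection/accuracy tallies and the residual
mis-registration assessment below are the published record of that
campaign; the raw flight imagery itself was never deposited, so these
counts are the only quantities that can be recomputed exactly.
"""

from __future__ import annotations

from .evaluate import EvaluationResult, metrics_from_counts

#: Per-pasture accuracy tallies: (pasture, known animals, mapped polygons,
#: correctly mapped polygons, polygons representing 2 animals, missed
#: animals, incorrectly mapped polygons).
PASTURE_COUNTS: tuple[tuple[int, int, int, int, int, int, int], ...] = (
    (1, 18, 15, 9, 0, 9, 6),
    (2, 38, 26, 22, 3, 13, 4),
    (3, 4, 10, 3, 0, 1, 7),
    (4, 29, 33, 22, 1, 6, 11),
    (5, 13, 71, 12, 0, 1, 59),
    (6, 15, 136, 14, 0, 1, 122),
    (7, 38, 35, 35, 2, 1, 0),
    (8, 3, 59, 3, 0, 0, 56),
)

#: Campaign-mean residual image-to-image mis-registration, meters
#: (absolute offsets of five check features per pasture, averaged).
MEAN_MISREGISTRATION_X_M = 0.58
MEAN_MISREGISTRATION_Y_M = 1.06

#: Campaign-mean tie-point registration RMSE, pixels.
MEAN_REGISTRATION_RMSE_PIXELS = 1.9

#: Known animal counts per pasture, a convenient suite recipe.
KNOWN_ANIMALS_PER_PASTURE: tuple[int, ...] = tuple(row[1] for row in PASTURE_COUNTS)


def pasture_results() -> list[EvaluationResult]:
    """The eight campaign rows as EvaluationResult objects (percentages
    recomputed from the count columns, not copied)."""
    return [
        metrics_from_counts(
            known=known,
            mapped=mapped,
            correct_polygons=correct,
            dual_polygons=dual,
            missed=missed,
            incorrect=incorrect,
            label=str(pasture),
        )
        for pasture, known, mapped, correct, dual, missed, incorrect in PASTURE_COUNTS
    ]
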
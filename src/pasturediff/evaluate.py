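"""Accuracy evaluation against known animal locations, and count correction.

Each detection polygon is matched to the known per-animal positions at the
two acquisition times. A polygon is eligible for an animal if it contains,
or lies within ``r_match`` of, either the T1 or the T2 position (default
1 m, about half an adult cow body length). Eligible pairs are assigned
greedily in order of increasing polygon-animal distance; an animal is
credited to at most one polygon and a polygon may absorb at most two
animals (two individuals standing close enough to difference as one blob).

The resulting counts follow the standard census-accuracy vocabulary:

* mapped — all polygons the pipeline called animals;
* correctly mapped — polygons credited with at least one animal;
* incorrectly mapped — polygons coincident with no animal (commission);
* missed — animals credited to no polygon (omission);

with percentages::

    P_correct  = 100 * (correctly mapped + dual polygons) / known
    P_omiss    = 100 * missed / known
    P_commiss  = 100 * incorrectly mapped / mapped

P_correct counts credited ANIMALS, so a dual polygon contributes two; the
polygon-counting variant is exposed as ``p_correct_polygon_form``. A raw
survey count is corrected by dividing by the detection probability
(:func:`adjust_count`).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from .errors import EvaluationError


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class Animal:
    """One known individual with its mapped position at each acquisition."""

    id: str
    pos_t1: tuple[float, float]
    pos_t2: tuple[float, float]


@dataclass
class TruthSet:
    """Known animal locations for one pasture; the ground-count surrogate."""

    animals: list[Animal]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise EvaluationError("animal ids must be unique")

    @property
    def known_count(self) -> int:
        return len(self.animals)

    @classmethod
    def from_csv(cls, path) -> "TruthSet":
        """Read columns id, x_t1, y_t1, x_t2, y_t2 (map meters)."""
        animals = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                animals.append(
                    Animal(
                        id=str(rec["id"]),
                        pos_t1=(float(rec["x_t1"]), float(rec["y_t1"])),
                        pos_t2=(float(rec["x_t2"]), float(rec["y_t2"])),
                    )
                )
        return cls(animals=animals)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x_t1", "y_t1", "x_t2", "y_t2"])
            for a in self.animals:
                w.writerow([a.id, *a.pos_t1, *a.pos_t2])

    @classmethod
    def from_geojson(cls, path) -> "TruthSet":
        """Read a FeatureCollection of points with properties id, time
        ("t1"/"t2"); the two features of an id form one animal record."""
        with open(path) as fh:
            fc = json.load(fh)
        pos: dict[str, dict[str, tuple[float, float]]] = {}
        for feat in fc.get("features", []):
            props = feat.get("properties", {})
            aid = str(props["id"])
            when = str(props["time"]).lower()
            x, y = feat["geometry"]["coordinates"][:2]
            pos.setdefault(aid, {})[when] = (float(x), float(y))
        animals = []
        for aid, d in pos.items():
            if "t1" not in d or "t2" not in d:
                raise EvaluationError(f"animal {aid}: needs both t1 and t2 positions")
            animals.append(Animal(id=aid, pos_t1=d["t1"], pos_t2=d["t2"]))
        animals.sort(key=lambda a: a.id)
        return cls(animals=animals)

    def to_geojson(self, path) -> None:
        features = []
        for a in self.animals:
            for when, p in (("t1", a.pos_t1), ("t2", a.pos_t2)):
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "Point", "coordinates": list(p)},
                        "properties": {"id": a.id, "time": when},
                    }
                )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)


@dataclass
class MatchResult:
    """Polygon-animal assignment: per-polygon labels and credited animal
    ids, per-animal detected/missed status, and the dual-polygon count."""

    polygon_labels: list[str]  # "correct" | "incorrect", parallel to input polys
    polygon_animals: list[list[str]]  # credited animal ids per polygon (0-2)
    animal_status: dict[str, str]  # id -> "detected" | "missed"
    dual_polygons: int

    @property
    def mapped(self) -> int:
        return len(self.polygon_labels)

    @property
    def correct_polygons(self) -> int:
        return sum(1 for lab in self.polygon_labels if lab == "correct")

    @property
    def incorrect(self) -> int:
        return sum(1 for lab in self.polygon_labels if lab == "incorrect")

    @property
    def missed(self) -> int:
        return sum(1 for s in self.animal_status.values() if s == "missed")


def match_detections(
    polys,
    truth: TruthSet,
    r_match: float = 1.0,
    mode: str = "both",
    max_animals_per_polygon: int = 2,
) -> MatchResult:
    """Greedily assign detection polygons to known animals.

    ``mode`` selects which truth positions a polygon may coincide with:
    ``"both"`` (default), ``"t1"``, or ``"t2"``. Assignment order is
    increasing polygon-animal distance (distance to the nearer eligible
    position; 0 if contained), ties broken by animal id then polygon
    order, so results are deterministic.
    """
    if r_match <= 0:
        raise EvaluationError(f"r_match must be > 0, got {r_match}")
    if mode not in ("both", "t1", "t2"):
        raise EvaluationError(f"mode must be 'both', 't1' or 't2', got {mode!r}")

    candidates = []  # (distance, animal_id, poly_index)
    for j, animal in enumerate(truth.animals):
        positions = {
            "both": (animal.pos_t1, animal.pos_t2),
            "t1": (animal.pos_t1,),
            "t2": (animal.pos_t2,),
        }[mode]
        pts = [Point(*p) for p in positions]
        for i, poly in enumerate(polys):
            d = min(poly.geometry.distance(pt) for pt in pts)
            if d <= r_match:
                candidates.append((d, animal.id, i))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    credited: dict[int, list[str]] = {i: [] for i in range(len(polys))}
    animal_done: set[str] = set()
    for d, aid, i in candidates:
        if aid in animal_done or len(credited[i]) >= max_animals_per_polygon:
            continue
        credited[i].append(aid)
        animal_done.add(aid)

    labels = ["correct" if credited[i] else "incorrect" for i in range(len(polys))]
    status = {
        a.id: ("detected" if a.id in animal_done else "missed") for a in truth.animals
    }
    dual = sum(1 for ids in credited.values() if len(ids) == 2)
    return MatchResult(
        polygon_labels=labels,
        polygon_animals=[credited[i] for i in range(len(polys))],
        animal_status=status,
        dual_polygons=dual,
    )


@dataclass
class EvaluationResult:
    """One pasture's accuracy row: counts plus the three percentages.

    Percentages are stored unrounded; the ``*_rounded`` properties apply
    nearest-integer rounding (half away from zero) for display. Partition
    identities (mapped = correct + incorrect; known = credited animals +
    missed) are validated at construction.
    """

    known: int
    mapped: int
    correct_polygons: int
    dual_polygons: int
    missed: int
    incorrect: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("known", "mapped", "correct_polygons", "dual_polygons", "missed", "incorrect"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be >= 0")
        if self.mapped != self.correct_polygons + self.incorrect:
            raise EvaluationError(
                f"mapped ({self.mapped}) != correct ({self.correct_polygons}) "
                f"+ incorrect ({self.incorrect})"
            )
        if self.known != self.animals_credited + self.missed:
            raise EvaluationError(
                f"known ({self.known}) != credited animals ({self.animals_credited}) "
                f"+ missed ({self.missed})"
            )
        if self.known == 0 and self.animals_credited > 0:
            raise EvaluationError("known = 0 but animals were credited")

    @property
    def animals_credited(self) -> int:
        # a dual polygon carries two animals: one from the polygon count
        # plus one extra per dual
        return self.correct_polygons + self.dual_polygons

    @property
    def p_correct(self) -> float:
        return 100.0 * self.animals_credited / self.known if self.known else 0.0

    @property
    def p_omiss(self) -> float:
        return 100.0 * self.missed / self.known if self.known else 0.0

    @property
    def p_commiss(self) -> float:
        return 100.0 * self.incorrect / self.mapped if self.mapped else 0.0

    @property
    def p_correct_polygon_form(self) -> float:
        """Literal polygon-count variant, 100 * correct_polygons / known."""
        return 100.0 * self.correct_polygons / self.known if self.known else 0.0

    @property
    def p_correct_rounded(self) -> int:
        return round_half_away(self.p_correct)

    @property
    def p_omiss_rounded(self) -> int:
        return round_half_away(self.p_omiss)

    @property
    def p_commiss_rounded(self) -> int:
        return round_half_away(self.p_commiss)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "known": self.known,
            "mapped": self.mapped,
            "correct_polygons": self.correct_polygons,
            "dual_polygons": self.dual_polygons,
            "missed": self.missed,
            "incorrect": self.incorrect,
            "p_correct": self.p_correct,
            "p_omiss": self.p_omiss,
            "p_commiss": self.p_commiss,
            "p_correct_rounded": self.p_correct_rounded,
            "p_omiss_rounded": self.p_omiss_rounded,
            "p_commiss_rounded": self.p_commiss_rounded,
        }


def compute_metrics(mr: MatchResult, known: int, label: str = "") -> EvaluationResult:
    """Build the accuracy row from a match result and the known count."""
    return EvaluationResult(
        known=known,
        mapped=mr.mapped,
        correct_polygons=mr.correct_polygons,
        dual_polygons=mr.dual_polygons,
        missed=mr.missed,
        incorrect=mr.incorrect,
        label=label,
    )


def metrics_from_counts(
    known: int,
    mapped: int,
    correct_polygons: int,
    dual_polygons: int,
    missed: int,
    incorrect: int,
    label: str = "",
) -> EvaluationResult:
    """Accuracy row directly from published or externally tallied counts."""
    return EvaluationResult(
        known=known,
        mapped=mapped,
        correct_polygons=correct_polygons,
        dual_polygons=dual_polygons,
        missed=missed,
        incorrect=incorrect,
        label=label,
    )


@dataclass
class Summary:
    """Multi-pasture aggregate: column sums of the counts; mean and sample
    SD (n-1) of the UNROUNDED percentages, rounded only for display. SDs
    are absent for a single pasture."""

    n: int
    sums: dict
    mean_p_correct: float
    mean_p_omiss: float
    mean_p_commiss: float
    std_p_correct: float | None
    std_p_omiss: float | None
    std_p_commiss: float | None

    def rounded(self) -> dict:
        out = {
            "mean_p_correct": round_half_away(self.mean_p_correct),
            "mean_p_omiss": round_half_away(self.mean_p_omiss),
            "mean_p_commiss": round_half_away(self.mean_p_commiss),
        }
        for key in ("std_p_correct", "std_p_omiss", "std_p_commiss"):
            v = getattr(self, key)
            out[key] = None if v is None else round_half_away(v)
        return out


def summarize(results: list[EvaluationResult]) -> Summary:
    if not results:
        raise EvaluationError("cannot summarize an empty result list")
    n = len(results)
    sums = {
        key: sum(getattr(r, key) for r in results)
        for key in ("known", "mapped", "correct_polygons", "dual_polygons", "missed", "incorrect")
    }
    pc = np.array([r.p_correct for r in results])
    po = np.array([r.p_omiss for r in results])
    pk = np.array([r.p_commiss for r in results])
    return Summary(
        n=n,
        sums=sums,
        mean_p_correct=float(pc.mean()),
        mean_p_omiss=float(po.mean()),
        mean_p_commiss=float(pk.mean()),
        std_p_correct=float(pc.std(ddof=1)) if n > 1 else None,
        std_p_omiss=float(po.std(ddof=1)) if n > 1 else None,
        std_p_commiss=float(pk.std(ddof=1)) if n > 1 else None,
    )


def results_to_csv(results: list[EvaluationResult], path, summary: Summary | None = None) -> None:
    """Write per-pasture rows (and optional Sum/Mean/STD rows) as CSV."""
    cols = [
        "label", "known", "mapped", "correct_polygons", "dual_polygons",
        "missed", "incorrect", "p_correct", "p_omiss", "p_commiss",
        "p_correct_rounded", "p_omiss_rounded", "p_commiss_rounded",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for r in results:
            w.writerow(r.to_dict())
        if summary is not None:
            rd = summary.rounded()
            w.writerow({"label": "Sum", **summary.sums})
            w.writerow(
                {
                    "label": "Mean",
                    "p_correct": summary.mean_p_correct,
                    "p_omiss": summary.mean_p_omiss,
                    "p_commiss": summary.mean_p_commiss,
                    "p_correct_rounded": rd["mean_p_correct"],
                    "p_omiss_rounded": rd["mean_p_omiss"],
                    "p_commiss_rounded": rd["mean_p_commiss"],
                }
            )
            w.writerow(
                {
                    "label": "STD",
                    "p_correct": summary.std_p_correct,
                    "p_omiss": summary.std_p_omiss,
                    "p_commiss": summary.std_p_commiss,
                    "p_correct_rounded": rd["std_p_correct"],
                    "p_omiss_rounded": rd["std_p_omiss"],
                    "p_commiss_rounded": rd["std_p_commiss"],
                }
            )


def detection_probability(observed: int, available: int) -> float:
    """Fraction of available (e.g. marked) animals seen during a survey."""
    if available <= 0:
        raise EvaluationError(f"available must be > 0, got {available}")
    if not 0 <= observed <= available:
        raise EvaluationError(
            f"observed must be in [0, available], got {observed}/{available}"
        )
    return observed / available


def adjust_count(count: float, detection_prob: float) -> float:
    """Correct a raw survey count by the detection probability: count / p."""
    if not 0 < detection_prob <= 1:
        raise EvaluationError(
            f"detection probability must be in (0, 1], got {detection_prob}"
        )
    return count / detection_prob
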
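"""Analytic Hierarchy Process scoring for conservation prioritisation.

Criterion weights come either directly from a configured scheme or from a
Saaty 1-9 pairwise-comparison judgment matrix, whose normalized principal
eigenvector gives the weights (power iteration; the geometric-mean / row
product method is available as an independent cross-check). Consistency is
the standard companion check: lambda_max gives CI = (lambda_max - n)/(n - 1)
and CR = CI / RI with Saaty's random indices; CR < 0.1 is acceptable.

A species' composite score is

    S = sum_i w_i * (p_i / p_i_max)

where p_i is the points the species earns on criterion i and p_i_max is
that criterion's maximum level. Each criterion therefore contributes its
full weight at its top level; S = sum(w) when every criterion is maximal.
An alternative global normalization (points / 9) can be selected; every
report records which convention produced it. Composite scores map to three
priority classes: class 1 for S >= 0.60, class 2 for 0.40 <= S < 0.60,
class 3 for S < 0.40.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Saaty's random consistency index for matrix sizes 1..9.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

#: Class boundaries: S >= 0.60 -> class 1; 0.40 <= S < 0.60 -> class 2.
DEFAULT_THRESHOLDS = (0.60, 0.40)


@dataclass(frozen=True)
class ConsistencyResult:
    lambda_max: float
    n: int
    CI: float
    RI: float
    CR: float

    @property
    def acceptable(self) -> bool:
        return self.CR < 0.1


@dataclass(frozen=True)
class Criterion:
    """One scored criterion: identifier, label, weight, ordered score levels."""

    id: str
    label: str
    weight: float
    levels: tuple[tuple[str, int], ...]  # (level label, points), best first

    @property
    def max_points(self) -> int:
        return max(p for _, p in self.levels)

    @property
    def min_points(self) -> int:
        return min(p for _, p in self.levels)

    @property
    def points(self) -> tuple[int, ...]:
        return tuple(p for _, p in self.levels)


@dataclass
class CriterionScheme:
    """An ordered set of criteria whose weights sum to 1 (tolerance 1e-3)."""

    criteria: list[Criterion]
    normalization: str = "per_criterion_max"  # or "global_nine"

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.criteria)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"criterion weights sum to {total}, expected 1 within 1e-3")
        if any(c.weight <= 0 for c in self.criteria):
            raise ValueError("criterion weights must be positive")
        if self.normalization not in ("per_criterion_max", "global_nine"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def __iter__(self):
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.criteria]

    def by_id(self, cid: str) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def min_score(self) -> float:
        """Composite score when every criterion sits at its minimum level."""
        if self.normalization == "per_criterion_max":
            return sum(c.weight * c.min_points / c.max_points for c in self.criteria)
        return sum(c.weight * c.min_points / 9.0 for c in self.criteria)


@dataclass
class SpeciesScoreCard:
    species: str
    family: str
    points: dict[str, int]
    score: float
    priority_class: int


def default_scheme() -> CriterionScheme:
    """The 13-criterion conservation-priority scheme with expert weights.

    Thirteen indicators (endangerment category, feasibility of artificial
    propagation, conservation status, threat persistence, population impacts
    at home and abroad, trade pressure, community role, growth form,
    endemism, taxonomic isolation, relict status, economic value, genetic
    value) with weights elicited from expert pairwise comparison.
    """
    spec = [
        ("D1", "Endangered category", 0.3938,
         (("Extinct", 9), ("Critically Endangered", 7), ("Endangered", 5),
          ("Vulnerable or Near Threatened", 3), ("Least Concern", 1))),
        ("D2", "Artificial planting", 0.0438,
         (("Unable to artificially breed", 5),
          ("Artificial populations cannot form under natural conditions", 3),
          ("Artificial populations can form under natural conditions", 1))),
        ("D3", "Conservation status", 0.0127,
         (("Not conserved", 7), ("Not effectively regulated", 5),
          ("Conserved in situ, translocated, or isolated", 3),
          ("Restoration of populations", 1))),
        ("D4", "Threat persistence", 0.0410,
         (("Persistent threatening factors", 5), ("Transient threatening factors", 3),
          ("Non-threatening factors", 1))),
        ("D5", "Domestic and international population impacts", 0.0029,
         (("Breeding from abroad", 5), ("No effect within populations", 3),
          ("No population decline at home or abroad", 1))),
        ("D6", "Species trade impacts", 0.0059,
         (("Over-utilization", 3), ("No over-utilization", 1))),
        ("D7", "Community status", 0.0041,
         (("Dominant species", 7), ("Subdominant species", 5), ("Companion species", 3),
          ("No effect on other species in the community", 1))),
        ("D8", "Organism type", 0.0289,
         (("Tree", 7), ("Shrub", 5), ("Perennial herb", 3), ("Annual herb", 1))),
        ("D9", "Endemic species", 0.0545,
         (("Provincial endemic", 7), ("Regional endemic", 5), ("Chinese endemic", 3),
          ("Non-Chinese endemic", 1))),
        ("D10", "Species status", 0.0060,
         (("Monotypic family", 9), ("Oligocene species", 7), ("Monotypic genus", 5),
          ("Oligotypic genus", 3), ("Polyphyletic genus", 1))),
        ("D11", "Relict status", 0.0140,
         (("Glacial relict", 3), ("Non-glacial relict", 1))),
        ("D12", "Economic values", 0.0655,
         (("Valuable for development and utilization", 3),
          ("No development or utilization value", 1))),
        ("D13", "Hereditary value", 0.3270,
         (("Unique utilization value", 5), ("Certain utilization value", 3),
          ("No utilization value", 1))),
    ]
    return CriterionScheme(
        criteria=[Criterion(id=i, label=l, weight=w, levels=lv) for i, l, w, lv in spec]
    )


def _validate_judgment(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("judgment matrix must be square")
    if (matrix <= 0).any():
        raise ValueError("judgment matrix entries must be positive")
    if not np.allclose(np.diag(matrix), 1.0):
        raise ValueError("judgment matrix diagonal must be 1")
    if not np.allclose(matrix * matrix.T, 1.0, rtol=1e-6):
        raise ValueError("judgment matrix must be reciprocal: a_ij = 1/a_ji")
    return matrix


def derive_weights(matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> tuple[np.ndarray, ConsistencyResult]:
    """Weights as the normalized principal eigenvector, plus consistency.

    Power iteration on the positive reciprocal matrix converges to the
    Perron eigenvector; lambda_max is estimated from the final iterate.
    """
    matrix = _validate_judgment(matrix)
    n = matrix.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        v = matrix @ w
        w_new = v / v.sum()
        if np.max(np.abs(w_new - w)) < tol * np.max(np.abs(w_new)):
            w = w_new
            break
        w = w_new
    lambda_max = float(np.mean((matrix @ w) / w))
    CI = (lambda_max - n) / (n - 1) if n > 1 else 0.0
    CI = max(CI, 0.0)  # guard tiny negative round-off
    RI = RANDOM_INDEX.get(n)
    if RI is None:
        raise ValueError(f"no random consistency index for n={n}")
    CR = CI / RI if RI > 0 else 0.0
    return w, ConsistencyResult(lambda_max=lambda_max, n=n, CI=CI, RI=RI, CR=CR)


def geometric_mean_weights(matrix: np.ndarray) -> np.ndarray:
    """Row geometric-mean weights (the logarithmic least-squares solution)."""
    matrix = _validate_judgment(matrix)
    g = np.exp(np.log(matrix).mean(axis=1))
    return g / g.sum()


def composite_score(points: dict[str, int], scheme: CriterionScheme) -> float:
    """Weighted normalized score S for one species."""
    missing = [c.id for c in scheme if c.id not in points]
    if missing:
        raise KeyError(f"missing criterion scores: {missing}")
    total = 0.0
    for crit in scheme:
        p = points[crit.id]
        if p not in crit.points:
            raise ValueError(
                f"criterion {crit.id}: points {p} not among declared levels {crit.points}"
            )
        denom = crit.max_points if scheme.normalization == "per_criterion_max" else 9.0
        total += crit.weight * p / denom
    return total


def classify(score: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> int:
    """Map a composite score to priority class 1 (highest), 2 or 3."""
    upper, lower = thresholds
    if score >= upper:
        return 1
    if score >= lower:
        return 2
    return 3


def score_table(
    points_table: pd.DataFrame,
    scheme: CriterionScheme,
    taxonomy: pd.DataFrame | None = None,
) -> list[SpeciesScoreCard]:
    """Score every row of a (species, D1..Dn points) table."""
    family_of = {}
    if taxonomy is not None:
        family_of = taxonomy.drop_duplicates("species").set_index("species")["family"].to_dict()
    cards = []
    for _, row in points_table.iterrows():
        pts = {cid: int(row[cid]) for cid in scheme.ids}
        s = composite_score(pts, scheme)
        cards.append(
            SpeciesScoreCard(
                species=row["species"],
                family=row.get("family", family_of.get(row["species"], "")),
                points=pts,
                score=s,
                priority_class=classify(s),
            )
        )
    return cards


def rank_species(cards: list[SpeciesScoreCard]) -> dict:
    """Ranked table (descending score, ties alphabetical) with class tallies."""
    if not cards:
        raise ValueError("no score cards to rank")
    ordered = sorted(cards, key=lambda c: (-c.score, c.species))
    table = pd.DataFrame(
        [
            {
                "rank": k + 1,
                "species": c.species,
                "family": c.family,
                "score": c.score,
                "priority_class": c.priority_class,
            }
            for k, c in enumerate(ordered)
        ]
    )
    tallies = table["priority_class"].value_counts().sort_index().to_dict()
    class1 = table[table["priority_class"] == 1]
    family_breakdown = class1["family"].value_counts().sort_index().to_dict()
    return {
        "table": table,
        "class_tallies": {int(k): int(v) for k, v in tallies.items()},
        "class1_family_breakdown": {str(k): int(v) for k, v in family_breakdown.items()},
    }
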
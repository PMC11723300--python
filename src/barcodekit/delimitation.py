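"""Distance-based MOTU delimitation.

Two methods operating on a pairwise distance matrix:

* :func:`abgd_partition` — automatic barcode gap discovery: for each prior
  intraspecific divergence P, locate the first sufficiently wide gap in the
  ranked pairwise distances at or above P, cut the graph there, and recurse
  into the resulting groups.
* :func:`asap_partition` — a partition ranker in the spirit of ASAP:
  single-linkage agglomeration proposes one candidate partition per merge
  height, and candidates are ranked by a composite of the gap width to the
  next merge height and the within/between separation they achieve. The
  published ASAP probability model (panmixia p-values) is not reproduced;
  the scorer is a rank-based analogue, which every report records.

Both return :class:`Partition` objects whose MOTU ids are contiguous from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from barcodekit.distmat import DistanceMatrix


@dataclass
class AbgdConfig:
    """ABGD settings; defaults mirror the public web server."""

    p_min: float = 0.001
    p_max: float = 0.1
    steps: int = 10
    X: float = 1.5  # relative gap width multiplier

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min <= self.p_max < 1.0):
            raise ValueError("require 0 < p_min <= p_max < 1")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.X <= 0:
            raise ValueError("X must be positive")

    def priors(self) -> np.ndarray:
        if self.steps == 1:
            return np.array([self.p_min])
        return np.logspace(np.log10(self.p_min), np.log10(self.p_max), self.steps)


@dataclass
class Partition:
    """Assignment of every sample to exactly one MOTU (ids 1..n_motus)."""

    assignment: dict[str, int]
    method: str
    parameter: float | None = None
    score: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        motus = sorted(set(self.assignment.values()))
        if motus != list(range(1, len(motus) + 1)):
            # renumber to contiguous ids starting at 1, preserving order
            remap = {m: k + 1 for k, m in enumerate(motus)}
            self.assignment = {s: remap[m] for s, m in self.assignment.items()}

    @property
    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sample, motu in self.assignment.items():
            out.setdefault(motu, []).append(sample)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s,
                    "motu_id": m,
                    "method": self.method,
                    "parameter": self.parameter,
                }
                for s, m in self.assignment.items()
            ]
        )


def _find_gap(sorted_dists: np.ndarray, prior: float, X: float) -> float | None:
    """Lower edge of the first qualifying gap reaching at or above ``prior``.

    A gap between consecutive ranked distances qualifies when it is not
    entirely below the prior (distances below P are presumed intraspecific,
    so only a jump crossing or above P can be the barcode gap) and its width
    exceeds X times the running mean of the distances at and below its lower
    edge.
    """
    for i in range(len(sorted_dists) - 1):
        lower, upper = sorted_dists[i], sorted_dists[i + 1]
        if upper <= prior:
            continue
        width = upper - lower
        if width <= 0:
            continue
        running_mean = float(np.mean(sorted_dists[: i + 1]))
        if width > X * running_mean:
            return float(lower)
    return None


def _connected_components(ids: list[str], sub: np.ndarray, threshold: float) -> list[list[str]]:
    """Groups linked by any pairwise distance <= threshold (single linkage)."""
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            d = sub[i, j]
            if not np.isnan(d) and d <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(ids[i])
    return list(comps.values())


def _abgd_split(ids: list[str], sub: np.ndarray, prior: float, X: float) -> list[list[str]]:
    """One recursion level: cut at the first qualifying gap, then recurse."""
    if len(ids) < 3:
        return [ids]
    dists = sub[np.triu_indices(len(ids), k=1)]
    dists = np.sort(dists[~np.isnan(dists)])
    if len(dists) == 0:
        return [ids]
    edge = _find_gap(dists, prior, X)
    if edge is None:
        return [ids]
    groups = _connected_components(ids, sub, edge)
    if len(groups) == 1:
        return groups
    out: list[list[str]] = []
    index = {s: k for k, s in enumerate(ids)}
    for group in groups:
        idx = [index[s] for s in group]
        out.extend(_abgd_split(group, sub[np.ix_(idx, idx)], prior, X))
    return out


def abgd_partition(matrix: DistanceMatrix, config: AbgdConfig | None = None) -> list[Partition]:
    """One partition per prior P; no qualifying gap means a single MOTU."""
    config = config or AbgdConfig()
    if len(matrix) < 2:
        raise ValueError("ABGD requires >= 2 samples")
    partitions = []
    for prior in config.priors():
        groups = _abgd_split(matrix.ids, matrix.values, float(prior), config.X)
        assignment = {
            s: k + 1 for k, group in enumerate(sorted(groups)) for s in group
        }
        partitions.append(
            Partition(assignment=assignment, method="abgd", parameter=float(prior))
        )
    return partitions


def choose_abgd_partition(partitions: list[Partition]) -> Partition:
    """Partition with the modal MOTU count over priors; ties go to fewer MOTUs."""
    if not partitions:
        raise ValueError("no partitions to choose from")
    counts = pd.Series([p.n_motus for p in partitions])
    freq = counts.value_counts()
    best_count = min(freq[freq == freq.max()].index)
    for p in partitions:
        if p.n_motus == best_count:
            return p
    raise AssertionError("unreachable")


def asap_partition(matrix: DistanceMatrix) -> list[Partition]:
    """Ranked candidate partitions from single-linkage merge heights.

    Each merge height proposes the partition obtained by applying every
    merge at or below it. Candidates are scored by the mean of two ranks:
    the width of the gap to the next merge height (larger is better) and the
    separation statistic mean(inter) - mean(intra) of the partition (larger
    is better). Best score first; ties go to fewer MOTUs.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("ASAP requires >= 2 samples")
    vals = matrix.values
    if np.isnan(vals).any():
        raise ValueError("ASAP requires a fully applicable distance matrix")
    condensed = squareform(vals, checks=False)
    flags: list[str] = []
    if np.allclose(condensed, 0.0):
        flags.append("degenerate: all distances zero")
        return [
            Partition(
                assignment={s: 1 for s in matrix.ids},
                method="asap",
                parameter=0.0,
                score=float("nan"),
                flags=flags,
            )
        ]
    Z = linkage(condensed, method="single")
    heights = Z[:, 2]
    distinct = sorted(set(np.round(heights, 12)))
    candidates = []
    for k, h in enumerate(distinct):
        next_h = distinct[k + 1] if k + 1 < len(distinct) else None
        gap_width = (next_h - h) if next_h is not None else 0.0
        labels = fcluster(Z, t=h + (gap_width / 2 if next_h else 1e-12), criterion="distance")
        assignment = dict(zip(matrix.ids, (int(c) for c in labels)))
        part = Partition(assignment=assignment, method="asap", parameter=float(h))
        candidates.append((part, gap_width, _separation(part, vals, matrix.ids)))
    gap_ranks = rankdata([c[1] for c in candidates])
    sep_ranks = rankdata([c[2] for c in candidates])
    for (part, _, _), gr, sr in zip(candidates, gap_ranks, sep_ranks):
        part.score = float((gr + sr) / 2.0)
    ranked = sorted(
        (c[0] for c in candidates), key=lambda p: (-p.score, p.n_motus)
    )
    return ranked


def _separation(partition: Partition, values: np.ndarray, ids: list[str]) -> float:
    """mean inter-MOTU distance minus mean intra-MOTU distance (empty -> 0)."""
    label = np.array([partition.assignment[s] for s in ids])
    iu = np.triu_indices(len(ids), k=1)
    same = label[iu[0]] == label[iu[1]]
    d = values[iu]
    intra = d[same]
    inter = d[~same]
    mean_intra = float(intra.mean()) if intra.size else 0.0
    mean_inter = float(inter.mean()) if inter.size else 0.0
    return mean_inter - mean_intra


def match_partition(partition: Partition, taxonomy: pd.DataFrame) -> dict:
    """Score a partition against morphological species labels.

    A species succeeds iff all of its samples fall in a single MOTU and
    that MOTU contains no other species (exact one-to-one match). The
    discrimination rate is the percentage of species that succeed.
    """
    species = taxonomy.set_index("sample_id")["species"]
    missing = [s for s in partition.assignment if s not in species.index]
    if missing:
        raise KeyError(f"samples missing from taxonomy: {missing}")
    motu_of: dict[str, set[int]] = {}
    species_in_motu: dict[int, set[str]] = {}
    for sample, motu in partition.assignment.items():
        sp = species[sample]
        motu_of.setdefault(sp, set()).add(motu)
        species_in_motu.setdefault(motu, set()).add(sp)
    successes = 0
    for sp, motus in motu_of.items():
        if len(motus) == 1 and species_in_motu[next(iter(motus))] == {sp}:
            successes += 1
    n_species = len(motu_of)
    return {
        "method": partition.method,
        "n_motus": partition.n_motus,
        "n_species": n_species,
        "successes": successes,
        "rate": 100.0 * successes / n_species,
        "match_rule": "exact one-to-one",
    }
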
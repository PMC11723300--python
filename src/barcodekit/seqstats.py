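"""Per-marker sequence characteristics.

Length range, GC content, alignment site classes (conserved, variable,
parsimony-informative, singleton) and nucleotide diversity pi computed as
the mean pairwise p-distance with pairwise deletion of gapped/ambiguous
sites.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from barcodekit.seqio import CANONICAL_BASES, MarkerDataset


@dataclass
class AlignmentStats:
    """Summary row for one marker (or marker combination)."""

    marker: str
    n_sequences: int
    length_min: int
    length_max: int
    length_mean: float
    gc_min: float
    gc_max: float
    gc_mean: float
    aligned_length: int | None = None
    variable_sites: int | None = None
    parsimony_informative_sites: int | None = None
    singleton_sites: int | None = None
    conserved_sites: int | None = None
    excluded_sites: int | None = None
    pi: float | None = None

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("length_mean", "gc_min", "gc_max", "gc_mean"):
            d[key] = round(d[key], 2)
        if d["pi"] is not None:
            d["pi"] = round(d["pi"], 4)
        if d["variable_sites"] is not None and d["aligned_length"]:
            d["variable_sites_pct"] = round(
                100.0 * d["variable_sites"] / d["aligned_length"], 2
            )
            d["conserved_sites_pct"] = round(
                100.0 * d["conserved_sites"] / d["aligned_length"], 2
            )
        return d


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases; gaps/ambiguity codes excluded."""
    counts = Counter(sequence.upper())
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return 100.0 * (counts["G"] + counts["C"]) / total


def _column_states(column: str) -> list[str]:
    """Unambiguous bases in one alignment column (gapped rows dropped)."""
    return [b for b in column if b in CANONICAL_BASES]


def site_classes(dataset: MarkerDataset) -> dict[str, int]:
    """Classify every alignment column.

    Per column, rows carrying a gap or ambiguity code are dropped for that
    column. Columns retaining fewer than two unambiguous bases are excluded
    from all classes. A retained column is conserved when a single state
    remains, otherwise variable; a variable column is parsimony-informative
    when at least two states each occur at least twice, else a singleton
    site.
    """
    if not dataset.aligned:
        raise ValueError("site classification requires an aligned dataset")
    if len(dataset) < 2:
        raise ValueError("site classification requires >= 2 sequences")
    seqs = [r.sequence for r in dataset]
    length = len(seqs[0])
    conserved = variable = informative = singleton = excluded = 0
    for j in range(length):
        states = _column_states("".join(s[j] for s in seqs))
        if len(states) < 2:
            excluded += 1
            continue
        tally = Counter(states)
        if len(tally) == 1:
            conserved += 1
        else:
            variable += 1
            if sum(1 for c in tally.values() if c >= 2) >= 2:
                informative += 1
            else:
                singleton += 1
    return {
        "aligned_length": length,
        "conserved_sites": conserved,
        "variable_sites": variable,
        "parsimony_informative_sites": informative,
        "singleton_sites": singleton,
        "excluded_sites": excluded,
    }


def nucleotide_diversity(dataset: MarkerDataset) -> float:
    """Mean pairwise p-distance (pi) with pairwise deletion."""
    from barcodekit.distmat import p_distance

    if len(dataset) < 2:
        raise ValueError("nucleotide diversity requires >= 2 sequences")
    if not dataset.aligned:
        raise ValueError("nucleotide diversity requires an aligned dataset")
    seqs = [(r.sample_id, r.sequence) for r in dataset]
    dists = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = p_distance(seqs[i][1], seqs[j][1])
            if d is None:
                raise ValueError(
                    f"no comparable sites between {seqs[i][0]!r} and {seqs[j][0]!r}"
                )
            dists.append(d)
    return float(np.mean(dists))


def summarize_marker(dataset: MarkerDataset) -> AlignmentStats:
    """All per-marker characteristics in one row.

    For a single-sequence dataset the alignment-level fields (site classes,
    pi) are left unset.
    """
    if len(dataset) == 0:
        raise ValueError("cannot summarize an empty dataset")
    lengths = [len(r.ungapped) for r in dataset]
    gcs = [gc_content(r.ungapped) for r in dataset]
    stats = AlignmentStats(
        marker=dataset.marker,
        n_sequences=len(dataset),
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=float(np.mean(lengths)),
        gc_min=min(gcs),
        gc_max=max(gcs),
        gc_mean=float(np.mean(gcs)),
    )
    if len(dataset) >= 2 and dataset.aligned:
        sites = site_classes(dataset)
        stats.aligned_length = sites["aligned_length"]
        stats.variable_sites = sites["variable_sites"]
        stats.parsimony_informative_sites = sites["parsimony_informative_sites"]
        stats.singleton_sites = sites["singleton_sites"]
        stats.conserved_sites = sites["conserved_sites"]
        stats.excluded_sites = sites["excluded_sites"]
        stats.pi = nucleotide_diversity(dataset)
    return stats
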
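"""Reference-library best-hit identification.

A local stand-in for querying a public nucleotide database: every query is
globally aligned to every reference of the same marker, the best hit is the
reference with the highest percent identity (ties: higher coverage, then
lexicographic reference id), and identification verdicts compare the best
hit's taxonomy to the query's at species, genus and family rank.

Percent identity is computed over aligned comparable positions (gap columns
excluded); coverage is the fraction of the query's ungapped length that was
aligned against a base. The default evaluation is leave-one-out
(``exclude_self=True``), emulating a query against independent records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from barcodekit.seqio import BarcodeRecord, MarkerDataset

RANKS = ("species", "genus", "family")


@dataclass
class ReferenceLibrary:
    """Reference records with complete taxonomy for one marker."""

    marker: str
    records: list[BarcodeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference library must be nonempty")
        for rec in self.records:
            if rec.marker != self.marker:
                raise ValueError(
                    f"record {rec.sample_id!r} marker {rec.marker!r} != {self.marker!r}"
                )
            if not (rec.species and rec.genus and rec.family):
                raise ValueError(f"record {rec.sample_id!r} has incomplete taxonomy")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_dataset(cls, dataset: MarkerDataset) -> "ReferenceLibrary":
        return cls(marker=dataset.marker, records=list(dataset.records))


@dataclass
class HitReport:
    """Best-hit outcome for one query."""

    query_id: str
    best_hit_id: str | None
    percent_identity: float
    coverage: float
    species_match: bool
    genus_match: bool
    family_match: bool
    no_hit: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity(aligner: Align.PairwiseAligner, query: str, ref: str) -> tuple[float, float]:
    """(percent identity over comparable positions, query coverage)."""
    alignment = aligner.align(query, ref)[0]
    counts = alignment.counts()
    comparable = counts.identities + counts.mismatches
    if comparable == 0:
        return 0.0, 0.0
    return 100.0 * counts.identities / comparable, comparable / len(query)


def best_hit(
    query: BarcodeRecord,
    library: ReferenceLibrary,
    min_identity: float = 0.0,
    exclude_self: bool = True,
) -> HitReport:
    """Best reference hit for one query, with rank-level verdicts.

    Hits below ``min_identity`` percent are discarded; an empty surviving
    hit set yields a flagged no-hit report with all verdicts false.
    """
    if query.marker != library.marker:
        raise ValueError("query and library marker differ")
    aligner = _aligner()
    qseq = query.ungapped
    hits = []
    for ref in library.records:
        if exclude_self and ref.sample_id == query.sample_id:
            continue
        pid, cov = _identity(aligner, qseq, ref.ungapped)
        if pid < min_identity:
            continue
        hits.append((pid, cov, ref))
    if not hits:
        return HitReport(
            query_id=query.sample_id,
            best_hit_id=None,
            percent_identity=0.0,
            coverage=0.0,
            species_match=False,
            genus_match=False,
            family_match=False,
            no_hit=True,
        )
    pid, cov, ref = min(hits, key=lambda h: (-h[0], -h[1], h[2].sample_id))
    species_ok = ref.species == query.species
    genus_ok = ref.genus == query.genus
    family_ok = ref.family == query.family
    # taxonomy is hierarchical: a conspecific hit is by construction
    # congeneric and confamilial
    if species_ok:
        genus_ok = True
    if genus_ok:
        family_ok = True
    return HitReport(
        query_id=query.sample_id,
        best_hit_id=ref.sample_id,
        percent_identity=pid,
        coverage=cov,
        species_match=species_ok,
        genus_match=genus_ok,
        family_match=family_ok,
    )


def identify_all(
    queries: MarkerDataset,
    library: ReferenceLibrary,
    min_identity: float = 0.0,
    exclude_self: bool = True,
) -> list[HitReport]:
    """Best-hit reports for every query in a dataset."""
    return [
        best_hit(q, library, min_identity=min_identity, exclude_self=exclude_self)
        for q in queries
    ]


def success_rates(reports: list[HitReport]) -> dict:
    """Identification success percentage at each taxonomic rank."""
    if not reports:
        raise ValueError("no hit reports to summarize")
    n = len(reports)
    rates = {
        "n_queries": n,
        "species": 100.0 * sum(r.species_match for r in reports) / n,
        "genus": 100.0 * sum(r.genus_match for r in reports) / n,
        "family": 100.0 * sum(r.family_match for r in reports) / n,
    }
    return rates


def reports_to_frame(reports: list[HitReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
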
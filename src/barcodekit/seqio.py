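"""Readers and writers for the formats the pipeline touches.

Sequences arrive as FASTA, taxonomy as a delimited table keyed by
``sample_id``, trees as Newick with numeric internal-node labels read as
branch support on a 0-100 scale. The first whitespace-delimited token of a
FASTA header is the sample id; sequences are upper-cased and RNA ``U`` is
mapped to ``T`` on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TAXONOMY_COLUMNS = ("sample_id", "species", "genus", "family")

#: IUPAC codes that count as unambiguous DNA bases.
CANONICAL_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence bound to its specimen and taxonomy."""

    sample_id: str
    species: str
    genus: str
    family: str
    marker: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"empty sequence for sample {self.sample_id!r}")
        if self.species and not (self.genus and self.family):
            raise ValueError(
                f"sample {self.sample_id!r}: species given without genus/family"
            )

    @property
    def ungapped(self) -> str:
        """Sequence with alignment gaps removed."""
        return self.sequence.replace("-", "")


@dataclass
class MarkerDataset:
    """An ordered set of records for one marker, optionally aligned."""

    marker: str
    records: list[BarcodeRecord] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.marker != self.marker:
                raise ValueError(
                    f"record {rec.sample_id!r} carries marker {rec.marker!r}, "
                    f"dataset is {self.marker!r}"
                )
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample_id {rec.sample_id!r}")
            seen.add(rec.sample_id)
        if self.aligned and len({len(r.sequence) for r in self.records}) > 1:
            raise ValueError("aligned dataset has sequences of unequal length")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def alignment_length(self) -> int:
        if not self.aligned:
            raise ValueError("dataset is not aligned")
        return len(self.records[0].sequence) if self.records else 0

    def subset(self, sample_ids: Iterable[str]) -> "MarkerDataset":
        """Records restricted to ``sample_ids``, original order preserved."""
        wanted = set(sample_ids)
        return MarkerDataset(
            marker=self.marker,
            records=[r for r in self.records if r.sample_id in wanted],
            aligned=self.aligned,
        )

    def taxonomy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.species, r.genus, r.family) for r in self.records],
            columns=list(TAXONOMY_COLUMNS),
        )


def _clean_sequence(raw: str) -> str:
    return str(raw).upper().replace("U", "T")


def read_taxonomy(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a taxonomy table (sample_id, species, genus, family).

    The delimiter is sniffed from the extension (``.csv`` -> comma, else tab)
    unless given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in TAXONOMY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"taxonomy table {path} lacks columns: {missing}")
    dupes = table["sample_id"][table["sample_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate sample_id in taxonomy: {sorted(set(dupes))}")
    return table


def read_fasta(
    path: str | Path,
    taxonomy: pd.DataFrame,
    marker: str,
    aligned: bool | None = None,
) -> MarkerDataset:
    """Read a FASTA file and join each entry to its taxonomy row.

    Parameters
    ----------
    path : FASTA file.
    taxonomy : table with columns sample_id, species, genus, family.
    marker : marker name to stamp on every record.
    aligned : force the aligned flag; by default the dataset is marked
        aligned when every sequence has the same length and there are >= 2.
    """
    by_id = taxonomy.set_index("sample_id")
    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        sample_id = entry.id.split()[0]
        if sample_id in seen:
            raise ValueError(f"duplicate FASTA header {sample_id!r} in {path}")
        seen.add(sample_id)
        if sample_id not in by_id.index:
            raise KeyError(
                f"FASTA entry {sample_id!r} has no row in the taxonomy table"
            )
        row = by_id.loc[sample_id]
        records.append(
            BarcodeRecord(
                sample_id=sample_id,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                marker=marker,
                sequence=_clean_sequence(entry.seq),
            )
        )
    if aligned is None:
        aligned = len(records) >= 2 and len({len(r.sequence) for r in records}) == 1
    return MarkerDataset(marker=marker, records=records, aligned=aligned)


def write_fasta(dataset: MarkerDataset, path: str | Path) -> None:
    """Write a dataset back to FASTA, one entry per record."""
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.sample_id, description="")
        for rec in dataset
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a Newick tree; numeric internal-node labels become supports.

    Accepts either a path or a literal Newick string. Support values are
    stored on ``node.support`` (float, conventionally 0-100) for internal
    nodes whose label parses as a number.
    """
    source = str(path_or_string)
    if source.lstrip().startswith("(") or source.rstrip().endswith(";"):
        kwargs = {"data": source}
    else:
        kwargs = {"path": source}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            **kwargs,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick input: {exc}") from exc
    for node in tree.preorder_node_iter():
        support = None
        if not node.is_leaf() and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        node.support = support
    return tree


def write_table(rows: pd.DataFrame | Sequence[dict], path: str | Path, sep: str = "\t") -> None:
    """Write tabular results as delimited text with a header row."""
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    frame.to_csv(path, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=sep)


def is_missing(value: object) -> bool:
    """True for the sentinels used to flag unavailable statistics."""
    if value is None:
        return True
    return isinstance(value, float) and math.isnan(value)
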
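"""Intra- vs inter-specific distance pools and the barcoding-gap test.

Every off-diagonal distance is pooled as intraspecific (both specimens
share a species) or interspecific. A species shows a barcoding gap when
its maximum intraspecific distance is strictly less than its minimum
distance to any other species. Species represented by a single specimen
have no intraspecific variation; they are judged on ``min_inter`` alone,
reported with ``singleton=True`` and ``max_intra=0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcodekit.distmat import DistanceMatrix
from barcodekit.seqio import MarkerDataset


@dataclass
class DistancePools:
    """Distances split into intra- and inter-specific pools."""

    label: str
    intra: pd.DataFrame  # columns: id_a, id_b, species, distance
    inter: pd.DataFrame  # columns: id_a, id_b, species_a, species_b, distance
    n_inapplicable: int = 0


@dataclass
class GapReport:
    """Per-species barcoding-gap verdicts plus pooled summaries."""

    label: str
    per_species: pd.DataFrame  # species, n_samples, max_intra, min_inter, gap_present, singleton
    pooled: dict = field(default_factory=dict)
    overlap_fraction: float = 0.0


def pool_distances(matrix: DistanceMatrix, taxonomy: pd.DataFrame, label: str | None = None) -> DistancePools:
    """Split a distance matrix into intra/inter-specific pools."""
    species = taxonomy.set_index("sample_id")["species"]
    missing = [i for i in matrix.ids if i not in species.index]
    if missing:
        raise KeyError(f"samples missing from taxonomy: {missing}")
    intra_rows, inter_rows = [], []
    n_na = 0
    ids = matrix.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = matrix.values[i, j]
            if np.isnan(d):
                n_na += 1
                continue
            sp_a, sp_b = species[ids[i]], species[ids[j]]
            if sp_a == sp_b:
                intra_rows.append(
                    {"id_a": ids[i], "id_b": ids[j], "species": sp_a, "distance": d}
                )
            else:
                inter_rows.append(
                    {
                        "id_a": ids[i],
                        "id_b": ids[j],
                        "species_a": sp_a,
                        "species_b": sp_b,
                        "distance": d,
                    }
                )
    return DistancePools(
        label=label or matrix.model,
        intra=pd.DataFrame(intra_rows, columns=["id_a", "id_b", "species", "distance"]),
        inter=pd.DataFrame(
            inter_rows, columns=["id_a", "id_b", "species_a", "species_b", "distance"]
        ),
        n_inapplicable=n_na,
    )


def _pool_summary(values: pd.Series) -> dict:
    if values.empty:
        return {"min": float("nan"), "max": float("nan"), "mean": float("nan"), "n": 0}
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "n": int(len(values)),
    }


def summarize_pools(pools: DistancePools) -> dict:
    """Min/max/mean of each pool (NaN-flagged when a pool is empty)."""
    return {
        "label": pools.label,
        "intra": _pool_summary(pools.intra["distance"]),
        "inter": _pool_summary(pools.inter["distance"]),
        "n_inapplicable": pools.n_inapplicable,
    }


def barcode_gap(pools: DistancePools) -> GapReport:
    """Per-species gap verdicts: gap present iff max_intra < min_inter (strict)."""
    intra, inter = pools.intra, pools.inter
    species_names = sorted(
        set(intra["species"]) | set(inter["species_a"]) | set(inter["species_b"])
    )
    if len(species_names) < 2:
        raise ValueError("barcode-gap analysis requires >= 2 species")
    sample_counts: dict[str, set] = {s: set() for s in species_names}
    for _, row in intra.iterrows():
        sample_counts[row["species"]].update([row["id_a"], row["id_b"]])
    for _, row in inter.iterrows():
        sample_counts[row["species_a"]].add(row["id_a"])
        sample_counts[row["species_b"]].add(row["id_b"])
    rows = []
    for sp in species_names:
        own_intra = intra.loc[intra["species"] == sp, "distance"]
        own_inter = inter.loc[
            (inter["species_a"] == sp) | (inter["species_b"] == sp), "distance"
        ]
        singleton = own_intra.empty
        max_intra = 0.0 if singleton else float(own_intra.max())
        min_inter = float(own_inter.min()) if not own_inter.empty else float("nan")
        gap = bool(max_intra < min_inter) if not np.isnan(min_inter) else False
        rows.append(
            {
                "species": sp,
                "n_samples": len(sample_counts[sp]),
                "max_intra": max_intra,
                "min_inter": min_inter,
                "gap_present": gap,
                "singleton": singleton,
            }
        )
    per_species = pd.DataFrame(rows)
    overlap = float((~per_species["gap_present"]).mean())
    return GapReport(
        label=pools.label,
        per_species=per_species,
        pooled=summarize_pools(pools),
        overlap_fraction=overlap,
    )


def gap_histogram(pools: DistancePools, bin_width: float) -> pd.DataFrame:
    """Left-closed right-open histogram of both pools from 0, shared bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = pd.concat([pools.intra["distance"], pools.inter["distance"]])
    if values.empty:
        return pd.DataFrame(columns=["bin_left", "bin_right", "intra", "inter"])
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(0, (n_bins + 1)) * bin_width
    intra_counts, _ = np.histogram(pools.intra["distance"], bins=edges)
    inter_counts, _ = np.histogram(pools.inter["distance"], bins=edges)
    # np.histogram closes the last bin on the right; values at the final
    # edge cannot occur because the edge lies strictly above the max.
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "intra": intra_counts,
            "inter": inter_counts,
        }
    )


def concatenate_markers(datasets: list[MarkerDataset]) -> MarkerDataset:
    """Concatenate aligned markers over the samples present in all of them.

    The combined marker name joins the component names with ``+``. Distances
    downstream are recomputed on the concatenated alignment rather than
    averaged across markers.
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 marker datasets to concatenate")
    for ds in datasets:
        if not ds.aligned:
            raise ValueError(f"marker {ds.marker!r} is not aligned")
    shared = set(datasets[0].sample_ids)
    for ds in datasets[1:]:
        shared &= set(ds.sample_ids)
    if not shared:
        raise ValueError("no samples shared across all requested markers")
    order = [s for s in datasets[0].sample_ids if s in shared]
    name = "+".join(ds.marker for ds in datasets)
    by_id = [{r.sample_id: r for r in ds} for ds in datasets]
    from barcodekit.seqio import BarcodeRecord

    records = []
    for sid in order:
        first = by_id[0][sid]
        seq = "".join(d[sid].sequence for d in by_id)
        records.append(
            BarcodeRecord(
                sample_id=sid,
                species=first.species,
                genus=first.genus,
                family=first.family,
                marker=name,
                sequence=seq,
            )
        )
    return MarkerDataset(marker=name, records=records, aligned=True)
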
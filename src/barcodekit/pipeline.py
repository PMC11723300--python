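"""End-to-end orchestration: every analysis stage over every marker.

:func:`run_all` takes in-memory inputs (per-marker datasets, taxonomy,
optional trees and AHP tables), runs sequence statistics, distances,
barcoding-gap analysis, MOTU delimitation, reference-library
identification and monophyly scoring for each marker and each requested
concatenated combination, and returns a bundle of data frames. When an
output directory is given every table is also written as TSV together with
a JSON manifest recording the seed and every tunable setting.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from barcodekit import __version__
from barcodekit.ahp import CriterionScheme, default_scheme, rank_species, score_table
from barcodekit.delimitation import (
    AbgdConfig,
    abgd_partition,
    asap_partition,
    choose_abgd_partition,
    match_partition,
)
from barcodekit.distmat import distance_matrix
from barcodekit.gap_analysis import barcode_gap, concatenate_markers, pool_distances
from barcodekit.identification import ReferenceLibrary, identify_all, success_rates
from barcodekit.phylo import nj_tree, species_monophyly
from barcodekit.seqio import MarkerDataset, write_table
from barcodekit.seqstats import summarize_marker

logger = logging.getLogger("barcodekit.pipeline")


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    combinations: list[list[str]] = field(default_factory=list)
    model: str = "k2p"
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    min_identity: float = 0.0
    support_threshold: float = 0.0
    include_singletons_in_monophyly: bool = False
    seed: int = 0

    def manifest(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "model": self.model,
            "abgd": asdict(self.abgd),
            "min_identity": self.min_identity,
            "support_threshold": self.support_threshold,
            "include_singletons_in_monophyly": self.include_singletons_in_monophyly,
            "combinations": ["+".join(c) for c in self.combinations],
            "gap_rule": "strict max_intra < min_inter; singletons flagged",
            "discrimination_rule": "exact one-to-one MOTU/species match",
            "asap_scorer": "rank-based analogue (gap width + separation ranks)",
            "identification": "local library best-hit, leave-one-out",
        }


def default_combinations(markers: list[str]) -> list[list[str]]:
    """All pairwise combinations plus the full concatenation."""
    combos = [
        [markers[i], markers[j]]
        for i in range(len(markers))
        for j in range(i + 1, len(markers))
    ]
    if len(markers) > 2:
        combos.append(list(markers))
    return combos


def run_all(
    datasets: dict[str, MarkerDataset],
    taxonomy: pd.DataFrame,
    config: RunConfig | None = None,
    trees: dict | None = None,
    libraries: dict[str, ReferenceLibrary] | None = None,
    ahp_points: pd.DataFrame | None = None,
    scheme: CriterionScheme | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage for every marker and combination.

    Returns a bundle: per-marker statistics, distance-pool summaries and
    gap reports, MOTU discrimination rates, identification success rates,
    monophyly rates, the AHP ranking (when score inputs are given), and the
    manifest. Optional stages (trees, AHP) are skipped when their inputs
    are absent.
    """
    config = config or RunConfig(combinations=default_combinations(sorted(datasets)))
    analyses: dict[str, MarkerDataset] = dict(datasets)
    for combo in config.combinations:
        missing = [m for m in combo if m not in datasets]
        if missing:
            raise KeyError(f"combination {combo} references unknown markers {missing}")
        ds = concatenate_markers([datasets[m] for m in combo])
        analyses[ds.marker] = ds

    bundle: dict = {"manifest": config.manifest()}
    stats_rows, gap_rows, motu_rows, ident_rows, mono_rows = [], [], [], [], []
    per_species_gap = {}

    for name, ds in analyses.items():
        t0 = time.perf_counter()
        stats_rows.append(summarize_marker(ds).as_dict())
        matrix = distance_matrix(ds, model=config.model)
        pools = pool_distances(matrix, taxonomy, label=name)
        report = barcode_gap(pools)
        per_species_gap[name] = report.per_species
        gap_rows.append(
            {
                "marker": name,
                "model": config.model,
                "intra_mean": report.pooled["intra"]["mean"],
                "intra_max": report.pooled["intra"]["max"],
                "inter_mean": report.pooled["inter"]["mean"],
                "inter_min": report.pooled["inter"]["min"],
                "overlap_fraction": report.overlap_fraction,
                "n_inapplicable": report.pooled["n_inapplicable"],
            }
        )
        abgd_parts = abgd_partition(matrix, config.abgd)
        abgd_best = choose_abgd_partition(abgd_parts)
        asap_best = asap_partition(matrix)[0]
        for part in (abgd_best, asap_best):
            row = match_partition(part, taxonomy)
            row["marker"] = name
            motu_rows.append(row)
        if name in datasets:  # identification runs on single markers only
            library = (libraries or {}).get(name) or ReferenceLibrary.from_dataset(ds)
            reports = identify_all(
                ds, library, min_identity=config.min_identity, exclude_self=True
            )
            rates = success_rates(reports)
            rates["marker"] = name
            ident_rows.append(rates)
        tree = (trees or {}).get(name)
        threshold = config.support_threshold
        if tree is None and len(ds) >= 3:
            tree = nj_tree(matrix)
            threshold = 0.0  # NJ plumbing trees carry no supports
        if tree is not None:
            mono = species_monophyly(
                tree,
                taxonomy,
                support_threshold=threshold,
                include_singletons=config.include_singletons_in_monophyly,
            )
            mono_rows.append(
                {
                    "marker": name,
                    "rate": mono.rate,
                    "n_singletons": mono.n_singletons,
                    "support_threshold": threshold,
                }
            )
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    bundle["stats"] = pd.DataFrame(stats_rows)
    bundle["gap_summary"] = pd.DataFrame(gap_rows)
    bundle["per_species_gap"] = per_species_gap
    bundle["discrimination"] = pd.DataFrame(motu_rows)
    bundle["identification"] = pd.DataFrame(ident_rows)
    bundle["monophyly"] = pd.DataFrame(mono_rows)

    if ahp_points is not None:
        scheme = scheme or default_scheme()
        cards = score_table(ahp_points, scheme, taxonomy=taxonomy)
        ranking = rank_species(cards)
        bundle["ahp_ranking"] = ranking["table"]
        bundle["ahp_class_tallies"] = ranking["class_tallies"]
        bundle["manifest"]["ahp_normalization"] = scheme.normalization

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("stats", "gap_summary", "discrimination", "identification", "monophyly"):
            write_table(bundle[key], out / f"{key}.tsv")
        for name, frame in per_species_gap.items():
            write_table(frame, out / f"gap_{name.replace('+', '_')}.tsv")
        if "ahp_ranking" in bundle:
            write_table(bundle["ahp_ranking"], out / "ahp_ranking.tsv")
        (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    return bundle
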
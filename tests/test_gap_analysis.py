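import math

import numpy as np
import pandas as pd
import pytest

from barcodekit.distmat import distance_matrix
from barcodekit.gap_analysis import (
    DistancePools,
    barcode_gap,
    concatenate_markers,
    gap_histogram,
    pool_distances,
    summarize_pools,
)
from barcodekit.synthetic_data import simulate_sequences

from conftest import TWO_SPECIES_TAX, make_dataset, taxonomy_frame


def _pools(intra, inter, label="toy"):
    return DistancePools(
        label=label,
        intra=pd.DataFrame(
            [{"id_a": f"x{i}", "id_b": f"y{i}", "species": "sp_a", "distance": d}
             for i, d in enumerate(intra)],
            columns=["id_a", "id_b", "species", "distance"],
        ),
        inter=pd.DataFrame(
            [{"id_a": f"u{i}", "id_b": f"v{i}", "species_a": "sp_a",
              "species_b": "sp_b", "distance": d}
             for i, d in enumerate(inter)],
            columns=["id_a", "id_b", "species_a", "species_b", "distance"],
        ),
    )


class TestPoolDistances:
    def test_two_species_two_samples(self, two_species_dataset):
        ds, tax = two_species_dataset
        pools = pool_distances(distance_matrix(ds, model="p"), tax)
        # C(4,2)=6 pairs: 2 intra (a1a2, b1b2) + 4 inter
        assert len(pools.intra) == 2
        assert len(pools.inter) == 4

    def test_all_conspecific_gives_empty_inter(self):
        tax = {k: ("sp", "g", "f") for k in ("s1", "s2", "s3")}
        ds = make_dataset({"s1": "AAAA", "s2": "AAAT", "s3": "AATT"}, tax)
        pools = pool_distances(distance_matrix(ds, model="p"), taxonomy_frame(tax))
        assert pools.inter.empty and len(pools.intra) == 3

    def test_pool_size_conservation(self, gap_config):
        datasets, tax = simulate_sequences(gap_config)
        m = distance_matrix(datasets["ITS"], model="p")
        pools = pool_distances(m, tax)
        n = len(m.ids)
        assert len(pools.intra) + len(pools.inter) + pools.n_inapplicable == n * (n - 1) // 2

    def test_missing_taxonomy_raises(self, two_species_dataset):
        ds, tax = two_species_dataset
        with pytest.raises(KeyError):
            pool_distances(distance_matrix(ds, model="p"), tax.iloc[:2])


class TestSummarizePools:
    def test_hand_means(self):
        out = summarize_pools(_pools([0.00, 0.02], [0.10, 0.20]))
        assert out["intra"]["mean"] == pytest.approx(0.01)
        assert out["inter"]["mean"] == pytest.approx(0.15)

    def test_empty_intra_flagged(self):
        out = summarize_pools(_pools([], [0.1]))
        assert math.isnan(out["intra"]["mean"]) and out["intra"]["n"] == 0
        assert out["inter"]["min"] == out["inter"]["max"] == out["inter"]["mean"] == 0.1


class TestBarcodeGap:
    def test_strict_inequality_at_boundary(self):
        report = barcode_gap(_pools([0.05], [0.05]))
        row = report.per_species.set_index("species").loc["sp_a"]
        assert not row["gap_present"]

    def test_clear_gap(self):
        report = barcode_gap(_pools([0.01], [0.05]))
        row = report.per_species.set_index("species").loc["sp_a"]
        assert row["gap_present"] and not row["singleton"]

    def test_singleton_species_flagged(self, gap_config):
        datasets, tax = simulate_sequences(gap_config)
        ds = datasets["ITS"]
        # drop all but one voucher of the first species to force a singleton
        first = tax["species"].iloc[0]
        keep = [r.sample_id for r in ds
                if r.species != first or r.sample_id.endswith("_v1")]
        pools = pool_distances(distance_matrix(ds.subset(keep), model="p"), tax)
        report = barcode_gap(pools)
        row = report.per_species.set_index("species").loc[first]
        assert row["singleton"] and row["max_intra"] == 0.0

    def test_one_species_rejected(self):
        with pytest.raises(ValueError, match="2 species"):
            barcode_gap(_pools([0.01], []))

    def test_synthetic_gap_no_overlap(self, gap_config):
        datasets, tax = simulate_sequences(gap_config)
        pools = pool_distances(distance_matrix(datasets["ITS"], model="p"), tax)
        report = barcode_gap(pools)
        assert report.overlap_fraction == 0.0
        assert report.per_species["gap_present"].all()

    def test_verdicts_invariant_under_species_rename(self, gap_config):
        datasets, tax = simulate_sequences(gap_config)
        pools = pool_distances(distance_matrix(datasets["ITS"], model="p"), tax)
        renamed = tax.copy()
        renamed["species"] = "Z_" + renamed["species"]
        pools2 = pool_distances(distance_matrix(datasets["ITS"], model="p"), renamed)
        a = barcode_gap(pools).per_species
        b = barcode_gap(pools2).per_species
        assert list(a["gap_present"]) == list(b["gap_present"])


class TestGapHistogram:
    def test_direct_binning(self):
        hist = gap_histogram(_pools([0.005, 0.015], [0.1]), bin_width=0.01)
        assert list(hist["intra"][:2]) == [1, 1]
        assert hist["inter"].sum() == 1

    def test_counts_conserve_pool_sizes(self, gap_config):
        datasets, tax = simulate_sequences(gap_config)
        pools = pool_distances(distance_matrix(datasets["ITS"], model="p"), tax)
        hist = gap_histogram(pools, bin_width=0.013)
        assert hist["intra"].sum() == len(pools.intra)
        assert hist["inter"].sum() == len(pools.inter)

    def test_empty_pools(self):
        assert gap_histogram(_pools([], []), bin_width=0.01).empty

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            gap_histogram(_pools([0.1], []), bin_width=0.0)


class TestConcatenateMarkers:
    def test_length_is_sum_over_shared_samples(self, gap_config):
        datasets, _ = simulate_sequences(gap_config)
        from dataclasses import replace
        from barcodekit.synthetic_data import MarkerProfile, SimConfig

        cfg2 = replace(
            gap_config,
            markers=(
                gap_config.markers[0],
                MarkerProfile(name="rbcL", length=400, gc=0.44,
                              intra_divergence=0.005, inter_divergence=0.06),
            ),
        )
        ds, _ = simulate_sequences(cfg2)
        combo = concatenate_markers([ds["ITS"], ds["rbcL"]])
        assert combo.marker == "ITS+rbcL"
        assert combo.alignment_length == 800 + 400
        assert set(combo.sample_ids) == set(ds["ITS"].sample_ids) & set(ds["rbcL"].sample_ids)

    def test_disjoint_samples_rejected(self):
        a = make_dataset({"x1": "AAAA"}, {"x1": ("sp", "g", "f")}, marker="A", aligned=True)
        b = make_dataset({"y1": "TTTT"}, {"y1": ("sp", "g", "f")}, marker="B", aligned=True)
        with pytest.raises(ValueError, match="shared"):
            concatenate_markers([a, b])

    def test_combined_distance_matches_sitewise_bruteforce(self, two_species_dataset):
        ds, _ = two_species_dataset
        other = make_dataset(
            {sid: "ACGTACGTACGT" if sid.startswith("a") else "ACGAACGAACGA"
             for sid in TWO_SPECIES_TAX},
            TWO_SPECIES_TAX,
            marker="rbcL",
        )
        combo = concatenate_markers([ds, other])
        m = distance_matrix(combo, model="p")
        seqs = {r.sample_id: r.sequence for r in combo}
        for a in seqs:
            for b in seqs:
                if a < b:
                    expected = np.mean(
                        [x != y for x, y in zip(seqs[a], seqs[b])]
                    )
                    assert m.get(a, b) == pytest.approx(expected)
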
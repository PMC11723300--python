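import numpy as np
import pytest

from barcodekit.delimitation import (
    AbgdConfig,
    Partition,
    abgd_partition,
    asap_partition,
    choose_abgd_partition,
    match_partition,
)
from barcodekit.distmat import DistanceMatrix, distance_matrix
from barcodekit.synthetic_data import simulate_sequences

from conftest import taxonomy_frame


def matrix_from(values: np.ndarray, ids: list[str]) -> DistanceMatrix:
    sites = np.full_like(values, 100, dtype=int)
    return DistanceMatrix(ids=ids, model="p", values=values, comparable_sites=sites)


def two_cluster_matrix() -> DistanceMatrix:
    ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
    v = np.full((6, 6), 0.25)
    v[:3, :3] = 0.01
    v[3:, 3:] = 0.01
    np.fill_diagonal(v, 0.0)
    return matrix_from(v, ids)


def brute_force_components(matrix: DistanceMatrix, threshold: float) -> int:
    """Independent oracle: count connected components at a link threshold."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    for i, a in enumerate(matrix.ids):
        for j in range(i + 1, len(matrix.ids)):
            if matrix.values[i, j] <= threshold:
                g.add_edge(a, matrix.ids[j])
    return nx.number_connected_components(g)


class TestAbgd:
    def test_two_separated_clusters(self):
        m = two_cluster_matrix()
        parts = abgd_partition(m, AbgdConfig(p_min=0.05, p_max=0.05, steps=1))
        assert parts[0].n_motus == 2 == brute_force_components(m, 0.05)
        groups = sorted(sorted(g) for g in parts[0].groups().values())
        assert groups == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]

    def test_all_zero_distances_single_motu(self):
        v = np.zeros((4, 4))
        m = matrix_from(v, ["s1", "s2", "s3", "s4"])
        for part in abgd_partition(m):
            assert part.n_motus == 1

    def test_uniform_ladder_does_not_split(self):
        # consecutive gaps all equal; none exceeds 1.5x the running mean
        ids = ["s1", "s2", "s3", "s4"]
        v = np.array(
            [
                [0.0, 0.10, 0.20, 0.30],
                [0.10, 0.0, 0.12, 0.22],
                [0.20, 0.12, 0.0, 0.14],
                [0.30, 0.22, 0.14, 0.0],
            ]
        )
        m = matrix_from(v, ids)
        parts = abgd_partition(m, AbgdConfig(p_min=0.01, p_max=0.05, steps=3))
        assert all(p.n_motus == 1 for p in parts)

    def test_prior_monotonicity(self, gap_config):
        datasets, _ = simulate_sequences(gap_config)
        m = distance_matrix(datasets["ITS"], model="p")
        counts = [p.n_motus for p in abgd_partition(m)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            AbgdConfig(p_min=0.5, p_max=0.1)
        with pytest.raises(ValueError):
            AbgdConfig(X=0.0)

    def test_partition_covers_all_samples_once(self, gap_config):
        datasets, _ = simulate_sequences(gap_config)
        m = distance_matrix(datasets["ITS"], model="p")
        for part in abgd_partition(m):
            assert sorted(part.assignment) == sorted(m.ids)
            motus = sorted(set(part.assignment.values()))
            assert motus == list(range(1, len(motus) + 1))


class TestChooseAbgd:
    def _part(self, n):
        return Partition(
            assignment={f"s{i}": (i % n) + 1 for i in range(10)}, method="abgd"
        )

    def test_modal_count_wins(self):
        parts = [self._part(2), self._part(2), self._part(2), self._part(5)]
        assert choose_abgd_partition(parts).n_motus == 2

    def test_tie_broken_toward_fewer(self):
        parts = [self._part(2), self._part(5)]
        assert choose_abgd_partition(parts).n_motus == 2

    def test_single_partition(self):
        parts = [self._part(3)]
        assert choose_abgd_partition(parts) is parts[0]


class TestAsap:
    def test_three_separated_clusters_top_ranked(self):
        ids = [f"{c}{i}" for c in "abc" for i in (1, 2)]
        v = np.full((6, 6), 0.25)
        for k in range(3):
            v[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = 0.005
        np.fill_diagonal(v, 0.0)
        ranked = asap_partition(matrix_from(v, ids))
        assert ranked[0].n_motus == 3

    def test_two_samples_single_candidate(self):
        v = np.array([[0.0, 0.1], [0.1, 0.0]])
        ranked = asap_partition(matrix_from(v, ["s1", "s2"]))
        assert len(ranked) == 1

    def test_degenerate_all_zero_flagged(self):
        v = np.zeros((3, 3))
        ranked = asap_partition(matrix_from(v, ["s1", "s2", "s3"]))
        assert len(ranked) == 1 and ranked[0].flags

    def test_agreement_with_abgd_on_separable_data(self):
        m = two_cluster_matrix()
        abgd_best = choose_abgd_partition(abgd_partition(m))
        asap_best = asap_partition(m)[0]
        assert abgd_best.n_motus == asap_best.n_motus == 2
        assert sorted(map(sorted, abgd_best.groups().values())) == sorted(
            map(sorted, asap_best.groups().values())
        )


class TestMatchPartition:
    TAX = {
        "a1": ("sp_a", "g", "f"),
        "a2": ("sp_a", "g", "f"),
        "b1": ("sp_b", "g", "f"),
        "c1": ("sp_c", "g", "f"),
        "c2": ("sp_c", "g", "f"),
    }

    def test_identity_partition_scores_100(self):
        part = Partition(
            assignment={"a1": 1, "a2": 1, "b1": 2, "c1": 3, "c2": 3}, method="abgd"
        )
        out = match_partition(part, taxonomy_frame(self.TAX))
        assert out["rate"] == 100.0 and out["successes"] == 3

    def test_total_lumping_scores_0(self):
        part = Partition(assignment={k: 1 for k in self.TAX}, method="abgd")
        assert match_partition(part, taxonomy_frame(self.TAX))["rate"] == 0.0

    def test_one_species_split_into_two_motus(self):
        part = Partition(
            assignment={"a1": 1, "a2": 2, "b1": 3, "c1": 4, "c2": 4}, method="asap"
        )
        out = match_partition(part, taxonomy_frame(self.TAX))
        assert out["rate"] == pytest.approx(200.0 / 3.0)

    def test_invariant_under_motu_relabeling(self):
        base = {"a1": 1, "a2": 1, "b1": 2, "c1": 3, "c2": 3}
        relabeled = {k: {1: 3, 2: 1, 3: 2}[v] for k, v in base.items()}
        a = match_partition(Partition(assignment=base, method="abgd"),
                            taxonomy_frame(self.TAX))
        b = match_partition(Partition(assignment=relabeled, method="abgd"),
                            taxonomy_frame(self.TAX))
        assert a["rate"] == b["rate"] and a["successes"] == b["successes"]


class TestParameterRecovery:
    def test_both_methods_recover_species_count(self, gap_config):
        """Smoke-scale recovery on separable data (10 seeds)."""
        from dataclasses import replace

        hits_abgd = hits_asap = 0
        for seed in range(10):
            cfg = replace(gap_config, seed=seed)
            datasets, tax = simulate_sequences(cfg)
            m = distance_matrix(datasets["ITS"], model="p")
            k = tax["species"].nunique()
            abgd_best = choose_abgd_partition(abgd_partition(m))
            asap_best = asap_partition(m)[0]
            hits_abgd += abgd_best.n_motus == k
            hits_asap += asap_best.n_motus == k
            if abgd_best.n_motus == k:
                assert match_partition(abgd_best, tax)["rate"] == 100.0
        assert hits_abgd >= 9 and hits_asap >= 9
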
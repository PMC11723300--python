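import numpy as np
import pandas as pd
import pytest

from barcodekit.ahp import (
    Criterion,
    CriterionScheme,
    classify,
    composite_score,
    default_scheme,
    derive_weights,
    geometric_mean_weights,
    rank_species,
    score_table,
)
from barcodekit.datasets import class1_priority_table


def consistent_matrix(weights: np.ndarray) -> np.ndarray:
    return np.outer(weights, 1.0 / weights)


from barcodekit.synthetic_data import simulate_judgment_matrix as random_reciprocal  # noqa: E402


class TestDeriveWeights:
    def test_consistent_3x3_recovers_weights(self):
        w = np.array([0.6, 0.3, 0.1])
        weights, cons = derive_weights(consistent_matrix(w))
        assert np.allclose(weights, w, atol=1e-8)
        assert cons.CR == pytest.approx(0.0, abs=1e-10)
        assert cons.lambda_max == pytest.approx(3.0, abs=1e-8)

    def test_all_ones_matrix_gives_equal_weights(self):
        weights, cons = derive_weights(np.ones((4, 4)))
        assert np.allclose(weights, 0.25)
        assert cons.CR == 0.0

    @pytest.mark.parametrize("n", range(3, 10))
    def test_consistent_matrices_all_sizes(self, n):
        rng = np.random.default_rng(n)
        w = rng.dirichlet(np.ones(n)) + 0.01
        w = w / w.sum()
        weights, cons = derive_weights(consistent_matrix(w))
        assert np.max(np.abs(weights - w)) <= 1e-8
        assert cons.CR == pytest.approx(0.0, abs=1e-9)

    def test_eigenvector_agrees_with_geometric_mean(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = random_reciprocal(4, rng)
            w_eig, _ = derive_weights(m)
            w_geo = geometric_mean_weights(m)
            assert np.max(np.abs(w_eig - w_geo)) < 0.02

    def test_scale_invariance_of_generating_weights(self):
        w = np.array([0.5, 0.3, 0.2])
        a, _ = derive_weights(consistent_matrix(w))
        b, _ = derive_weights(consistent_matrix(w * 7.3))
        assert np.allclose(a, b, atol=1e-10)

    def test_non_reciprocal_rejected(self):
        m = np.array([[1.0, 2.0], [0.4, 1.0]])
        with pytest.raises(ValueError, match="reciprocal"):
            derive_weights(m)

    def test_nonpositive_rejected(self):
        m = np.array([[1.0, -2.0], [-0.5, 1.0]])
        with pytest.raises(ValueError, match="positive"):
            derive_weights(m)


class TestCompositeScore:
    def test_all_criteria_at_maximum_sums_the_weights(self):
        scheme = default_scheme()
        points = {c.id: c.max_points for c in scheme}
        total_weight = sum(c.weight for c in scheme)
        assert composite_score(points, scheme) == pytest.approx(total_weight)
        assert total_weight == pytest.approx(1.0001)

    def test_all_criteria_at_minimum(self):
        scheme = default_scheme()
        points = {c.id: c.min_points for c in scheme}
        expected = sum(c.weight * c.min_points / c.max_points for c in scheme)
        assert composite_score(points, scheme) == pytest.approx(expected)
        assert expected == pytest.approx(0.170, abs=0.0005)

    def test_single_criterion_scheme(self):
        scheme = CriterionScheme(
            criteria=[Criterion(id="C", label="only", weight=1.0,
                                levels=(("hi", 5), ("mid", 3), ("lo", 1)))]
        )
        assert composite_score({"C": 3}, scheme) == pytest.approx(0.6)

    def test_missing_criterion_named(self):
        scheme = default_scheme()
        points = {c.id: c.min_points for c in scheme}
        del points["D7"]
        with pytest.raises(KeyError, match="D7"):
            composite_score(points, scheme)

    def test_undeclared_level_rejected(self):
        scheme = default_scheme()
        points = {c.id: c.min_points for c in scheme}
        points["D1"] = 4  # not a declared level for D1
        with pytest.raises(ValueError, match="D1"):
            composite_score(points, scheme)

    def test_monotone_in_every_criterion(self):
        scheme = default_scheme()
        base = {c.id: c.min_points for c in scheme}
        s0 = composite_score(base, scheme)
        for crit in scheme:
            for p in crit.points:
                bumped = dict(base)
                bumped[crit.id] = p
                assert composite_score(bumped, scheme) >= s0

    def test_global_nine_normalization_alternative(self):
        scheme = default_scheme()
        scheme.normalization = "global_nine"
        points = {c.id: c.max_points for c in scheme}
        expected = sum(c.weight * c.max_points / 9.0 for c in scheme)
        assert composite_score(points, scheme) == pytest.approx(expected)


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.65, 1), (0.60, 1), (0.69, 1), (0.59, 2), (0.40, 2), (0.39, 3), (0.28, 3)],
    )
    def test_published_boundaries(self, score, expected):
        assert classify(score) == expected


class TestRankSpecies:
    def test_bundled_class1_table_classification(self):
        table = class1_priority_table()
        classes = table["score"].map(classify)
        assert (classes == 1).all()
        assert len(table) == 23
        fam_counts = table["family"].value_counts()
        assert fam_counts["Asteraceae"] == 4
        assert table["score"].max() == pytest.approx(0.69)

    def test_ties_ranked_alphabetically(self):
        scheme = _passthrough_scheme()
        pts = pd.DataFrame(
            {"species": ["zebra", "aster"], "family": ["F", "F"], "S1": [3, 3]}
        )
        ranking = rank_species(score_table(pts, scheme))
        assert list(ranking["table"]["species"]) == ["aster", "zebra"]

    def test_single_card(self):
        scheme = _passthrough_scheme()
        pts = pd.DataFrame({"species": ["only"], "family": ["F"], "S1": [5]})
        ranking = rank_species(score_table(pts, scheme))
        assert ranking["class_tallies"] == {1: 1}
        assert ranking["table"]["rank"].iloc[0] == 1


def _passthrough_scheme() -> CriterionScheme:
    return CriterionScheme(
        criteria=[Criterion(id="S1", label="single", weight=1.0,
                            levels=(("hi", 5), ("mid", 3), ("lo", 1)))]
    )


class TestSchemeValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CriterionScheme(
                criteria=[
                    Criterion(id="A", label="a", weight=0.5, levels=(("x", 1),)),
                    Criterion(id="B", label="b", weight=0.2, levels=(("x", 1),)),
                ]
            )

    def test_default_scheme_weight_sum_within_tolerance(self):
        scheme = default_scheme()
        assert abs(sum(c.weight for c in scheme) - 1.0) <= 1e-3
        assert len(scheme) == 13
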
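import math

import numpy as np
import pytest

from irappa.rsvm import build_pairs, rank_by_projection, swapped_pair_fraction, train
from irappa.synthetic import SyntheticSpec, generate

from .oracles import qp_reference_objective


class TestBuildPairs:
    def test_cross_category_count_one_complex(self, decoyset_factory):
        dset = decoyset_factory(np.zeros((3, 2)), "hii")
        pairs = build_pairs([dset])
        assert pairs.n_pairs == 2  # 1 high x 2 incorrect
        for _, better, worse in pairs.pairs:
            assert dset.labels[better] > dset.labels[worse]

    def test_three_distinct_categories(self, decoyset_factory):
        dset = decoyset_factory(np.zeros((3, 1)), "hmi")
        assert build_pairs([dset]).n_pairs == 3

    def test_no_pairs_span_complexes(self, decoyset_factory):
        a = decoyset_factory(np.zeros((2, 1)), "ai", complex_id="cx1")
        b = decoyset_factory(np.zeros((2, 1)), "ai", complex_id="cx2")
        pairs = build_pairs([a, b])
        assert pairs.n_pairs == 2
        assert {cid for cid, _, _ in pairs.pairs} == {"cx1", "cx2"}

    def test_single_category_complex_contributes_nothing(self, decoyset_factory):
        dset = decoyset_factory(np.zeros((4, 1)), "iiii")
        assert build_pairs([dset]).n_pairs == 0

    def test_difference_vectors(self, decoyset_factory):
        dset = decoyset_factory([[1.0, 0.0], [4.0, 2.0]], "ia")
        pairs = build_pairs([dset])
        np.testing.assert_array_equal(pairs.diffs, [[3.0, 2.0]])  # better minus worse


class TestTrain:
    def test_separable_one_dimensional_sign_recovery(self, decoyset_factory):
        dset = decoyset_factory([[2.0], [1.0], [0.0]], "hai")
        pairs = build_pairs([dset])
        model = train(pairs, c=100.0, tolerance=1e-8)
        assert model.weights[0] > 0
        # all margins satisfied: slack sum ~ 0
        slacks = np.maximum(0.0, 1.0 - pairs.diffs @ model.weights)
        assert slacks.sum() == pytest.approx(0.0, abs=1e-6)

    def test_single_pair_closed_form(self, decoyset_factory):
        # one constraint w.(2, 0) >= 1: minimum-norm solution w = (0.5, 0)
        dset = decoyset_factory([[2.0, 5.0], [0.0, 5.0]], "ai")
        model = train(build_pairs([dset]), c=1000.0, tolerance=1e-10)
        np.testing.assert_allclose(model.weights, [0.5, 0.0], atol=1e-6)
        assert model.objective_value == pytest.approx(0.125, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("c", [0.1, 1.0, 10.0])
    def test_objective_matches_dense_qp_oracle(self, seed, c):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(size=(rng.integers(3, 15), 2))
        from irappa.rsvm import PairConstraintSet

        pairs = PairConstraintSet(
            pairs=[("cx", 0, i + 1) for i in range(len(diffs))], diffs=diffs
        )
        model = train(pairs, c=c, tolerance=1e-8)
        oracle = qp_reference_objective(diffs, c)
        assert model.objective_value == pytest.approx(oracle, abs=1e-4, rel=1e-4)

    def test_agrees_with_independent_svm_library(self, decoyset_factory):
        """Cross-check against LinearSVC on the +/- difference-vector trick."""
        sklearn = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(3)
        diffs = rng.normal(size=(40, 5)) + 0.5
        from irappa.rsvm import PairConstraintSet

        pairs = PairConstraintSet(pairs=[("cx", 0, i) for i in range(40)], diffs=diffs)
        c = 0.5
        model = train(pairs, c=c, tolerance=1e-9)
        # duplicate +x/-x halves the per-sample hinge weight
        clf = sklearn.LinearSVC(
            loss="hinge", C=c / 2.0, fit_intercept=False, tol=1e-10, max_iter=200000
        )
        clf.fit(np.vstack([diffs, -diffs]), [1] * 40 + [-1] * 40)
        np.testing.assert_allclose(model.weights, clf.coef_.ravel(), atol=1e-3)

    def test_invalid_inputs(self, decoyset_factory):
        dset = decoyset_factory(np.zeros((2, 1)), "ai")
        with pytest.raises(ValueError):
            train(build_pairs([dset]), c=-1.0)
        empty = build_pairs([decoyset_factory(np.zeros((2, 1)), "ii")])
        with pytest.raises(ValueError):
            train(empty, c=1.0)


class TestRankByProjection:
    def test_orders_by_projection(self, decoyset_factory):
        dset = decoyset_factory([[2.0, 9.0], [1.0, 9.0], [3.0, 9.0]], "iii")
        from irappa.rsvm import RankingModel

        model = RankingModel(weights=np.array([1.0, 0.0]), c=1.0)
        np.testing.assert_array_equal(rank_by_projection(model, dset), [2, 0, 1])

    def test_zero_weights_fall_back_to_initial_ranks(self, decoyset_factory):
        dset = decoyset_factory(np.zeros((4, 2)), "iiii", initial_ranks=[3, 1, 4, 2])
        from irappa.rsvm import RankingModel

        model = RankingModel(weights=np.zeros(2), c=1.0)
        np.testing.assert_array_equal(rank_by_projection(model, dset), [1, 3, 0, 2])

    def test_matches_sort_oracle(self, decoyset_factory):
        rng = np.random.default_rng(11)
        feats = rng.normal(size=(10, 4))
        dset = decoyset_factory(feats, "i" * 10)
        from irappa.rsvm import RankingModel

        w = rng.normal(size=4)
        model = RankingModel(weights=w, c=1.0)
        got = rank_by_projection(model, dset)
        expected = sorted(range(10), key=lambda i: -float(feats[i] @ w))
        assert got.tolist() == expected

    def test_dimension_mismatch(self, decoyset_factory):
        from irappa.rsvm import RankingModel

        dset = decoyset_factory(np.zeros((2, 3)), "ii")
        with pytest.raises(ValueError):
            rank_by_projection(RankingModel(weights=np.zeros(2), c=1.0), dset)


class TestSwappedPairFraction:
    def test_perfect_ranking_scores_zero(self):
        from irappa.decoyset_io import CapriCategory as C

        labels = [C.HIGH, C.MEDIUM, C.ACCEPTABLE, C.INCORRECT]
        assert swapped_pair_fraction([0, 1, 2, 3], labels) == 0.0

    def test_reversed_ranking_scores_one(self):
        from irappa.decoyset_io import CapriCategory as C

        labels = [C.HIGH, C.MEDIUM, C.ACCEPTABLE, C.INCORRECT]
        assert swapped_pair_fraction([3, 2, 1, 0], labels) == 1.0

    def test_single_misplacement_fraction(self):
        from irappa.decoyset_io import CapriCategory as C

        # 2 acceptable + 2 incorrect -> 4 cross pairs; one incorrect above one acceptable
        labels = [C.ACCEPTABLE, C.ACCEPTABLE, C.INCORRECT, C.INCORRECT]
        assert swapped_pair_fraction([0, 2, 1, 3], labels) == pytest.approx(0.25)

    def test_undefined_without_cross_pairs(self):
        from irappa.decoyset_io import CapriCategory as C

        assert math.isnan(swapped_pair_fraction([0, 1], [C.INCORRECT, C.INCORRECT]))


class TestScaleInvariance:
    def test_feature_scaling_scales_weights_inversely(self, decoyset_factory):
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(8, 3))
        labels = "aaii" + "mmhh"
        dset = decoyset_factory(feats, labels)
        scaled = decoyset_factory(feats * 4.0, labels)
        m1 = train(build_pairs([dset]), c=1.0, tolerance=1e-9)
        m2 = train(build_pairs([scaled]), c=1.0, tolerance=1e-9)
        np.testing.assert_allclose(m2.weights, m1.weights / 4.0, atol=1e-5)
        r1 = rank_by_projection(m1, dset)
        r2 = rank_by_projection(m2, scaled)
        # any disagreement must come from numerically tied projections
        proj = feats @ m1.weights
        for a, b in zip(r1, r2):
            if a != b:
                assert abs(proj[a] - proj[b]) < 1e-5


class TestParameterRecovery:
    def test_planted_direction_recovered_at_low_noise(self):
        """Raw-feature training approximately recovers the planted weights."""
        spec = SyntheticSpec(
            n_complexes=6, decoys_per_complex=80, noise_sigma=0.01, seed=17
        )
        sets = generate(spec)
        rng = np.random.default_rng(17)
        u = rng.normal(size=spec.n_features)
        u /= np.linalg.norm(u)
        model = train(build_pairs(sets), c=0.01, tolerance=1e-6)
        w = model.weights / np.linalg.norm(model.weights)
        assert float(w @ u) >= 0.9

    def test_separable_training_reaches_zero_swaps(self):
        spec = SyntheticSpec(n_complexes=3, decoys_per_complex=50, noise_sigma=0.0, seed=23)
        sets = generate(spec)
        model = train(build_pairs(sets), c=100.0, tolerance=1e-8)
        for dset in sets:
            frac = swapped_pair_fraction(rank_by_projection(model, dset), dset.labels)
            assert frac == 0.0
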
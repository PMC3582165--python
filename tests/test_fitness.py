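import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edasvm.cv import build_cv_plan
from edasvm.dataset import ExpressionDataset
from edasvm.fitness import (
    FitnessEvaluator,
    accuracy,
    evaluate_individual,
    feature_preweights,
    train_linear_svm,
)
from edasvm.simulate import PlantedDesign, generate

from qp_oracle import solve_svm_dual, decision_values


class TestAccuracy:
    def test_identity_and_partial(self):
        v = np.array([1, -1, 1, -1, 1, 1, -1, -1])
        assert accuracy(v, v) == 1.0
        assert accuracy(np.array([1, 1, -1, -1]),
                        np.array([1, -1, -1, 1])) == 0.5
        assert accuracy(np.array([1, 1, 1, -1]),
                        np.array([1, 1, 1, 1])) == 0.75

    @settings(deadline=None, max_examples=25, derandomize=True,
              database=None)
    @given(st.lists(st.sampled_from([1, -1]), min_size=1, max_size=100),
           st.randoms(use_true_random=False))
    def test_matches_brute_force_count(self, truth, rnd):
        pred = [rnd.choice([1, -1]) for _ in truth]
        expected = sum(1 for p, t in zip(pred, truth) if p == t) / len(truth)
        assert accuracy(np.array(pred), np.array(truth)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            accuracy(np.array([1, 1]), np.array([1]))


class TestTrainLinearSVM:
    def test_separable_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(3, 0.3, (10, 2)),
                       rng.normal(-3, 0.3, (10, 2))])
        y = np.array([1] * 10 + [-1] * 10)
        model = train_linear_svm(X, y)
        assert accuracy(model.predict(X), y) == 1.0

    def test_xor_is_linearly_inseparable(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([1, 1, -1, -1])
        model = train_linear_svm(X, y, cost=100.0)
        assert accuracy(model.predict(X), y) <= 0.75

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_linear_svm(np.eye(3), np.array([1, 1, 1]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_decision_values_match_dual_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(1.0, 1.0, (5, 2)),
                       rng.normal(-1.0, 1.0, (5, 2))])
        y = np.array([1] * 5 + [-1] * 5)
        model = train_linear_svm(X, y, cost=1.0)
        _a, w, b = solve_svm_dual(X, y, C=1.0)
        Xt = rng.normal(0, 1.5, (8, 2))
        np.testing.assert_allclose(model.decision_function(Xt),
                                   decision_values(Xt, w, b), atol=1e-6)


class TestFeaturePreweights:
    def test_zero_exactly_at_excluded_positions(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(1, 1, (6, 2)), rng.normal(-1, 1, (6, 2))])
        y = np.array([1] * 6 + [-1] * 6)
        model = train_linear_svm(X, y)
        mask = np.array([0, 1, 0, 1, 0])
        pw = feature_preweights(model, mask)
        assert pw.shape == (5,)
        assert (pw[mask == 0] == 0).all()
        assert (pw >= 0).all()

    def test_single_feature_weight_matches_dual_solution(self):
        # 4 hand-picked 1-d points; weight must equal (sum a_h y_h x_h)^2
        X = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        y = np.array([1, 1, -1, -1])
        model = train_linear_svm(X, y, cost=1.0)
        a, w, _b = solve_svm_dual(X, y, C=1.0)
        pw = feature_preweights(model, np.array([1]))
        assert pw[0] == pytest.approx(float(w[0]) ** 2, abs=1e-6)
        assert pw[0] == pytest.approx(float((a * y) @ X.ravel()) ** 2, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        X = np.array([[1.0, 0.0], [2.0, 1.0], [-1.0, 0.5], [-2.0, 1.5]])
        y = np.array([1, 1, -1, -1])
        model = train_linear_svm(X, y)
        with pytest.raises(ValueError, match="mask"):
            feature_preweights(model, np.array([1, 1, 1]))

    def test_preweight_grows_with_feature_scale(self):
        rng = np.random.default_rng(4)
        base = np.vstack([rng.normal(0.8, 1, (10, 2)),
                          rng.normal(-0.8, 1, (10, 2))])
        y = np.array([1] * 10 + [-1] * 10)
        pw0 = [feature_preweights(train_linear_svm(base * [c, 1.0], y),
                                  np.array([1, 1]))[0]
               for c in (0.5, 1.0, 2.0, 5.0)]
        # empirical sign of the effect: inflating a feature's scale shrinks
        # its squared primal weight (w compensates to keep w.x of order 1)
        assert pw0 == sorted(pw0, reverse=True)


class TestEvaluateIndividual:
    def test_oracle_equivalence_on_tiny_instances(self):
        """Accuracy and pre-weights agree with the brute-force dual QP."""
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(1.2, 1, (6, 3)), rng.normal(-1.2, 1, (6, 3))])
        ds = ExpressionDataset(X, ("a", "b", "c"),
                               tuple(f"s{i}" for i in range(12)),
                               labels=np.array([1] * 6 + [-1] * 6))
        plan = build_cv_plan(ds.labels, 3, seed=5)
        ev = FitnessEvaluator(ds, plan, cost=1.0, standardize=False)
        mask = np.array([1, 0, 1])
        res = ev.evaluate(mask)
        accs, pws = [], []
        for learn, test in plan.pairs:
            Xl = X[np.ix_(learn, [0, 2])]
            a, w, b = solve_svm_dual(Xl, ds.labels[learn].astype(float), C=1.0)
            pred = np.where(decision_values(X[np.ix_(test, [0, 2])], w, b) >= 0,
                            1, -1)
            accs.append(np.mean(pred == ds.labels[test]))
            pws.append(w ** 2)
        assert res.fitness == pytest.approx(np.mean(accs), abs=1e-5)
        np.testing.assert_allclose(res.weights[[0, 2]],
                                   np.mean(pws, axis=0), atol=1e-5)
        assert res.weights[1] == 0.0

    def test_fitness_is_mean_of_pair_accuracies(self, planted_small):
        ds, planted = planted_small
        plan = build_cv_plan(ds.labels, 5, seed=1)
        mask = np.isin(np.array(ds.gene_ids), sorted(planted)).astype(int)
        res = evaluate_individual(ds, mask, plan)
        assert res.fitness == pytest.approx(np.mean(res.per_pair_accuracy))
        assert len(res.per_pair_accuracy) == 25
        assert 0.0 <= res.fitness <= 1.0
        assert (res.weights >= 0).all()
        assert (res.weights[mask == 0] == 0).all()

    def test_planted_mask_reaches_high_fitness(self, planted_small):
        ds, planted = planted_small
        plan = build_cv_plan(ds.labels, 5, seed=2)
        mask = np.isin(np.array(ds.gene_ids), sorted(planted)).astype(int)
        res = evaluate_individual(ds, mask, plan)
        assert res.fitness >= 0.95

    def test_empty_mask_degenerate_convention(self, planted_small):
        ds, _ = planted_small
        plan = build_cv_plan(ds.labels, 5, seed=3)
        res = evaluate_individual(ds, np.zeros(ds.n_genes, int), plan)
        assert res.fitness == 0.0
        assert (res.weights == 0).all()

    def test_deterministic_given_plan(self, planted_small):
        ds, _ = planted_small
        plan = build_cv_plan(ds.labels, 5, seed=4)
        mask = np.zeros(ds.n_genes, int)
        mask[:10] = 1
        r1 = evaluate_individual(ds, mask, plan)
        r2 = evaluate_individual(ds, mask, plan)
        assert r1.fitness == r2.fitness
        np.testing.assert_array_equal(r1.weights, r2.weights)

    def test_location_shift_invariance_under_standardization(self, planted_small):
        ds, _ = planted_small
        plan = build_cv_plan(ds.labels, 5, seed=6)
        mask = np.zeros(ds.n_genes, int)
        mask[:8] = 1
        shifted = ExpressionDataset(ds.matrix + np.array([100.0] * 8 + [0.0] *
                                                         (ds.n_genes - 8)),
                                    ds.gene_ids, ds.sample_ids, ds.labels)
        r1 = evaluate_individual(ds, mask, plan, standardize=True)
        r2 = evaluate_individual(shifted, mask, plan, standardize=True)
        assert r1.per_pair_accuracy == pytest.approx(r2.per_pair_accuracy)

    def test_null_mask_on_permuted_labels_near_chance(self):
        ds, planted = generate(PlantedDesign(n_samples_per_class=(15, 15),
                                             n_genes=40, n_informative=3,
                                             effect_size=3.0, seed=21))
        rng = np.random.default_rng(0)
        fits = []
        noise_mask = (~np.isin(np.array(ds.gene_ids),
                               sorted(planted))).astype(int)
        for seed in range(8):
            perm = rng.permutation(ds.labels)
            dsp = ExpressionDataset(ds.matrix, ds.gene_ids, ds.sample_ids, perm)
            plan = build_cv_plan(perm, 5, seed=seed)
            fits.append(evaluate_individual(dsp, noise_mask, plan).fitness)
        se = np.std(fits, ddof=1) / np.sqrt(len(fits))
        assert abs(np.mean(fits) - 0.5) <= 3 * max(se, 0.02)
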
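"""ANFIS core: fuzzification, rule firing, hybrid learning, persistence."""

import json
import math

import hypothesis.strategies as st
import numpy as np
import pytest
from hypothesis import given, settings

from infarctgrowth.anfis import (
    ANFISModel,
    GaussianMF,
    Rule,
    backprop_premises,
    decision_surface,
    fire_rules,
    lse_consequents,
    load_model,
    membership,
    predict,
    predict_igr3,
    premise_gradients,
    save_model,
    train,
)
from infarctgrowth.errors import (
    InvalidParameterError,
    OutOfSupportError,
    UnderdeterminedError,
)
from conftest import PLANTED_CONSEQUENTS, planted_truth_from


def two_input_model(consequents=None, widths=(2.0, 4.0)) -> ANFISModel:
    """Small diagonal-rule model with MF centers at 0/5/10 and 0/10/20."""
    cons = consequents or [np.zeros(3)] * 3
    return ANFISModel(
        ("IGR1", "IGR2"),
        [
            [GaussianMF(c, widths[0]) for c in (0.0, 5.0, 10.0)],
            [GaussianMF(c, widths[1]) for c in (0.0, 10.0, 20.0)],
        ],
        [Rule((k, k), np.asarray(c, dtype=float)) for k, c in enumerate(cons)],
    )


class TestMembership:
    @pytest.mark.parametrize(
        "offset,expected",
        [(0.0, 1.0), (1.0, math.exp(-0.5)), (2.0, math.exp(-2.0))],
    )
    def test_gaussian_values(self, offset, expected):
        mf = GaussianMF(center=3.0, width=1.5)
        assert membership(3.0 + offset * 1.5, mf) == pytest.approx(expected)

    def test_symmetry(self):
        mf = GaussianMF(center=-2.0, width=0.7)
        assert membership(-2.0 + 1.3, mf) == pytest.approx(
            membership(-2.0 - 1.3, mf)
        )

    def test_invalid_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            GaussianMF(0.0, 0.0)
        with pytest.raises(InvalidParameterError):
            GaussianMF(0.0, -1.0)


class TestRuleFiring:
    def test_unit_firing_at_both_centers(self):
        m = two_input_model()
        w = fire_rules(5.0, 10.0, m)  # centers of rule 1's antecedents
        assert w[1] == pytest.approx(1.0)

    def test_product_tnorm(self):
        # place the input where each membership is exactly 0.5
        m = two_input_model()
        x1 = 0.0 + 2.0 * math.sqrt(2.0 * math.log(2.0))
        x2 = 0.0 + 4.0 * math.sqrt(2.0 * math.log(2.0))
        w = fire_rules(x1, x2, m)
        assert w[0] == pytest.approx(0.25, rel=1e-12)

    def test_zero_membership_kills_rule(self):
        m = two_input_model(widths=(1e-3, 1e-3))
        w = fire_rules(5.0, 10.0, m)  # far from rules 0 and 2 in MF units
        assert w[1] == pytest.approx(1.0)
        assert w[0] == 0.0 and w[2] == 0.0

    @given(
        x1=st.floats(-2.0, 12.0),
        x2=st.floats(-2.0, 22.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalized_firing_sums_to_one(self, x1, x2):
        m = two_input_model()
        w = fire_rules(x1, x2, m)
        assert w.sum() > 0
        assert (w / w.sum()).sum() == pytest.approx(1.0, rel=1e-12)


class TestPrediction:
    def test_single_firing_rule_returns_its_consequent(self):
        m = two_input_model(
            consequents=[(0.0, 0.0, 7.0), (0.0, 0.0, -3.0), (0.0, 0.0, 9.0)],
            widths=(1e-3, 1e-3),
        )
        assert predict_igr3(m, 5.0, 10.0) == pytest.approx(-3.0)

    def test_weighted_average_of_rule_outputs(self):
        # one-input model engineered so mu = (0.2, 0.6): out = 2.5
        width = 1.0
        x = 2.0
        c0 = x - width * math.sqrt(2.0 * math.log(1.0 / 0.2))
        c1 = x - width * math.sqrt(2.0 * math.log(1.0 / 0.6))
        m = ANFISModel(
            ("x",),
            [[GaussianMF(c0, width), GaussianMF(c1, width)]],
            [
                Rule((0,), np.array([0.0, 1.0])),
                Rule((1,), np.array([0.0, 3.0])),
            ],
        )
        assert predict(m, [[x]])[0] == pytest.approx(
            (0.2 * 1.0 + 0.6 * 3.0) / 0.8, rel=1e-9
        )

    def test_out_of_support_raises(self):
        m = two_input_model(widths=(0.1, 0.1))
        with pytest.raises(OutOfSupportError):
            predict_igr3(m, 1e6, 1e6)

    @given(
        x1=st.floats(-2.0, 12.0),
        x2=st.floats(-2.0, 22.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_output_is_convex_combination_of_rule_outputs(self, x1, x2):
        """The defuzzified value never leaves the span of the rule outputs
        (the 'stretched sheet' bound of the fuzzy surface)."""
        rng = np.random.default_rng(5)
        m = two_input_model(consequents=list(rng.normal(size=(3, 3))))
        f = np.array([r.consequent[:2] @ [x1, x2] + r.consequent[2] for r in m.rules])
        out = predict_igr3(m, x1, x2)
        assert f.min() - 1e-9 <= out <= f.max() + 1e-9

    def test_planted_model_value_at_training_point(self, planted_rates):
        """Hybrid-trained model agrees with the planted generator at a
        training point to within the (zero) noise floor."""
        X, y, _ = planted_rates
        m = ANFISModel.from_data_range(X)
        train(m, X, y)
        i = 17
        assert predict_igr3(m, X[i, 0], X[i, 1]) == pytest.approx(y[i], abs=1e-3)


class TestLeastSquaresConsequents:
    def test_matches_normal_equations_oracle(self):
        """Consequents equal the direct normal-equations solution computed
        from an explicitly built design matrix."""
        rng = np.random.default_rng(8)
        X = np.column_stack([rng.uniform(0, 10, 60), rng.uniform(0, 20, 60)])
        y = rng.normal(size=60)
        m = two_input_model()
        lse_consequents(m, X, y)
        # independent oracle: loop-built design, normal equations
        A = np.zeros((60, 9))
        for n in range(60):
            w = np.array(
                [
                    math.exp(-0.5 * ((X[n, 0] - c1) / 2.0) ** 2)
                    * math.exp(-0.5 * ((X[n, 1] - c2) / 4.0) ** 2)
                    for c1, c2 in ((0, 0), (5, 10), (10, 20))
                ]
            )
            wn = w / w.sum()
            for r in range(3):
                A[n, 3 * r : 3 * r + 3] = wn[r] * np.array([X[n, 0], X[n, 1], 1.0])
        theta = np.linalg.solve(A.T @ A, A.T @ y)
        got = np.concatenate([r.consequent for r in m.rules])
        assert got == pytest.approx(theta, rel=1e-8, abs=1e-8)

    def test_exact_recovery_of_generating_consequents(self, planted_rates):
        X, y, truth = planted_rates
        m = ANFISModel(
            truth.input_names,
            [[GaussianMF(mf.center, mf.width) for mf in per] for per in truth.mfs],
            [Rule(r.antecedent, np.zeros(3)) for r in truth.rules],
        )
        lse_consequents(m, X, y)
        for fitted, expected in zip(m.rules, PLANTED_CONSEQUENTS):
            assert fitted.consequent == pytest.approx(
                np.array(expected), rel=1e-8
            )

    def test_never_firing_rule_warns_and_zeroes(self):
        m = two_input_model()
        m.mfs[0][2] = GaussianMF(1e6, 0.1)  # rule 2 cannot fire on any datum
        m.mfs[1][2] = GaussianMF(1e6, 0.1)
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.uniform(0, 10, 50), rng.uniform(0, 20, 50)])
        y = rng.normal(size=50)
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            lse_consequents(m, X, y)
        assert np.max(np.abs(m.rules[2].consequent)) < 1e-6

    def test_constant_targets_give_constant_intercepts(self):
        m = two_input_model()
        m.order = 0
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.uniform(0, 10, 30), rng.uniform(0, 20, 30)])
        lse_consequents(m, X, np.full(30, 4.2))
        for rule in m.rules:
            assert rule.consequent[-1] == pytest.approx(4.2, rel=1e-9)
            assert rule.consequent[:2] == pytest.approx(np.zeros(2))

    def test_underdetermined_raises(self):
        m = two_input_model()
        with pytest.raises(UnderdeterminedError):
            lse_consequents(m, np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([1.0, 2.0]))


class TestPremiseGradients:
    def test_zero_step_is_bitwise_noop(self):
        m = two_input_model(consequents=[(0.1, 0.2, 0.3)] * 3)
        before = json.dumps(m.to_dict())
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.uniform(0, 10, 20), rng.uniform(0, 20, 20)])
        backprop_premises(m, X, rng.normal(size=20), step_size=0.0)
        assert json.dumps(m.to_dict()) == before

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([rng.uniform(0, 10, 25), rng.uniform(0, 20, 25)])
        y = rng.normal(size=25)
        m = two_input_model(consequents=list(rng.normal(size=(3, 3))))

        def sse(model):
            r = predict(model, X) - y
            return float(r @ r)

        dC, dW = premise_gradients(m, X, y)
        h = 1e-6
        for j in range(2):
            for a in range(3):
                for attr, grads in (("center", dC), ("width", dW)):
                    orig = getattr(m.mfs[j][a], attr)
                    setattr(m.mfs[j][a], attr, orig + h)
                    up = sse(m)
                    setattr(m.mfs[j][a], attr, orig - h)
                    down = sse(m)
                    setattr(m.mfs[j][a], attr, orig)
                    fd = (up - down) / (2 * h)
                    assert grads[j][a] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_hybrid_epoch_beats_lse_only(self, planted_rates):
        """On imperfectly initialized premises, one gradient step plus a
        consequent refit cannot do worse than the consequent fit alone."""
        X, y, _ = planted_rates
        rng = np.random.default_rng(12)
        y_noisy = y + rng.normal(0, 0.5, size=y.size)
        m_lse = ANFISModel.from_data_range(X)
        _, trace_lse = train(m_lse, X, y_noisy, epochs=1, step_size=0.0)
        m_hyb = ANFISModel.from_data_range(X)
        _, trace_hyb = train(m_hyb, X, y_noisy, epochs=2, step_size=0.01)
        assert trace_hyb[-1] <= trace_lse[-1] + 1e-12


class TestTraining:
    def test_single_epoch_zero_step_is_pure_least_squares(self, planted_rates):
        X, y, _ = planted_rates
        m_a = ANFISModel.from_data_range(X)
        train(m_a, X, y, epochs=1, step_size=0.0)
        m_b = ANFISModel.from_data_range(X)
        lse_consequents(m_b, X, y)
        for ra, rb in zip(m_a.rules, m_b.rules):
            assert ra.consequent == pytest.approx(rb.consequent, rel=1e-12)

    def test_noiseless_planted_recovery_under_defaults(self, planted_rates):
        X, y, _ = planted_rates
        m = ANFISModel.from_data_range(X)
        _, trace = train(m, X, y)
        assert trace[-1] < 1e-3
        assert np.all(np.isfinite(trace))

    def test_metadata_recorded(self, planted_rates):
        X, y, _ = planted_rates
        m = ANFISModel.from_data_range(X)
        train(m, X, y, epochs=5)
        meta = m.training_meta
        assert meta["epochs_run"] == len(meta["rmse_trace"])
        assert meta["final_rmse"] == meta["rmse_trace"][-1]
        assert len(meta["step_trace"]) == len(meta["rmse_trace"])


class TestDecisionSurface:
    def test_singleton_grid_equals_point_prediction(self):
        m = two_input_model(consequents=[(0.5, 0.2, 1.0)] * 3)
        Z = decision_surface(m, [3.0], [7.0])
        assert Z.shape == (1, 1)
        assert Z[0, 0] == pytest.approx(predict_igr3(m, 3.0, 7.0))

    def test_finite_over_training_range(self):
        m = two_input_model(consequents=[(0.5, 0.2, 1.0)] * 3)
        Z = decision_surface(m, np.linspace(0, 10, 21), np.linspace(0, 20, 21))
        assert np.all(np.isfinite(Z))

    def test_symmetric_model_gives_symmetric_surface(self):
        """Identical MFs on both inputs and input-swap-symmetric consequents
        make the surface symmetric under exchanging IGR1 and IGR2."""
        mfs = [GaussianMF(c, 3.0) for c in (0.0, 5.0, 10.0)]
        m = ANFISModel(
            ("IGR1", "IGR2"),
            [[GaussianMF(mf.center, mf.width) for mf in mfs] for _ in range(2)],
            [
                Rule((k, k), np.array([0.3, 0.3, b]))
                for k, b in enumerate((1.0, -2.0, 0.5))
            ],
        )
        grid = np.linspace(0.0, 10.0, 15)
        Z = decision_surface(m, grid, grid)
        assert Z == pytest.approx(Z.T, rel=1e-12)


class TestPersistence:
    def test_round_trip_is_bit_identical(self, tmp_path, planted_rates):
        X, y, _ = planted_rates
        m = ANFISModel.from_data_range(X)
        train(m, X, y, epochs=5)
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        assert m2.to_dict() == m.to_dict()
        q = np.column_stack([np.linspace(1, 11, 7), np.linspace(1, 24, 7)])
        assert np.array_equal(predict(m, q), predict(m2, q))

    def test_version_guard(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"format_version": 99}))
        with pytest.raises(InvalidParameterError):
            load_model(path)


class TestParameterRecovery:
    def test_consequents_within_three_standard_errors(self):
        """With premises fixed at truth, fitted consequents on noisy data lie
        within 3 SEs of the generating coefficients (n = 200)."""
        rng = np.random.default_rng(21)
        X = np.column_stack([rng.uniform(0.5, 12, 200), rng.uniform(0.5, 25, 200)])
        truth = planted_truth_from(X)
        noise_sd = 0.5
        y = predict(truth, X) + rng.normal(0, noise_sd, 200)
        m = ANFISModel(
            truth.input_names,
            [[GaussianMF(mf.center, mf.width) for mf in per] for per in truth.mfs],
            [Rule(r.antecedent, np.zeros(3)) for r in truth.rules],
        )
        lse_consequents(m, X, y)
        # SEs from the LSE covariance noise_sd^2 (A^T A)^-1
        from infarctgrowth.anfis import _design_matrix

        A = _design_matrix(m, X)
        cov = noise_sd**2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        got = np.concatenate([r.consequent for r in m.rules])
        want = np.concatenate([np.array(c) for c in PLANTED_CONSEQUENTS])
        assert np.all(np.abs(got - want) <= 3.0 * se)


class TestModelValidation:
    def test_rule_base_options(self):
        X = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 20, 20)])
        assert ANFISModel.from_data_range(X, rule_base="diagonal").n_rules == 3
        assert ANFISModel.from_data_range(X, rule_base="grid").n_rules == 9

    def test_invalid_rule_index_rejected(self):
        with pytest.raises(InvalidParameterError):
            ANFISModel(
                ("a", "b"),
                [[GaussianMF(0, 1)], [GaussianMF(0, 1)]],
                [Rule((0, 5), np.zeros(3))],
            )

    def test_needs_at_least_one_rule(self):
        with pytest.raises(InvalidParameterError):
            ANFISModel(("a",), [[GaussianMF(0, 1)]], [])
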
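"""ANFIS layer algebra and hybrid-training tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epoadl import anfis


def tiny_model():
    """Hand-built 2-input, 2-MF model with fixed premises and consequents."""
    m = anfis.ANFISModel(
        n_inputs=2,
        n_mf=2,
        a=np.array([[1.0, 1.0], [2.0, 2.0]]),
        b=np.array([[1.0, 2.0], [1.0, 3.0]]),
        c=np.array([[0.0, 2.0], [-1.0, 3.0]]),
        rule_index=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
        consequents=np.array(
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 2.0], [1.0, 1.0, 1.0]]
        ),
    )
    return m


class TestBellMembership:
    def test_center_gives_one(self):
        assert anfis.bell_membership(3.0, anfis.BellMF(2.0, 5.0, 3.0)) == 1.0

    @pytest.mark.parametrize("sign", [-1, 1])
    @pytest.mark.parametrize("b", [0.5, 1.0, 4.0])
    def test_half_width_gives_half_for_any_slope(self, sign, b):
        mf = anfis.BellMF(1.5, b, 2.0)
        assert anfis.bell_membership(2.0 + sign * 1.5, mf) == pytest.approx(0.5)

    def test_two_widths_out(self):
        assert anfis.bell_membership(3.0, anfis.BellMF(1.0, 1.0, 1.0)) == pytest.approx(0.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            anfis.BellMF(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            anfis.BellMF(1.0, -1.0, 0.0)

    @given(st.floats(-5, 5), st.floats(0.1, 3), st.floats(0.2, 4))
    @settings(deadline=None, max_examples=100)
    def test_symmetric_about_center_and_bounded(self, d, a, b):
        mf = anfis.BellMF(a, b, 1.0)
        left, right = anfis.bell_membership(1.0 - d, mf), anfis.bell_membership(1.0 + d, mf)
        assert left == pytest.approx(right, rel=1e-9)
        assert 0.0 < left <= 1.0


class TestLayers:
    def test_fuzzify_at_centers_is_one(self):
        m = tiny_model()
        grid = anfis.fuzzify(np.array([0.0, -1.0]), m)
        assert grid.shape == (2, 2)
        assert grid[0, 0] == 1.0 and grid[1, 0] == 1.0

    def test_fuzzify_decays_away_from_center(self):
        m = tiny_model()
        vals = [anfis.fuzzify(np.array([x, -1.0]), m)[0, 0] for x in (0.0, 1.0, 3.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_firing_strength_is_product(self):
        m = tiny_model()
        mem = np.array([[0.8, 0.3], [0.5, 0.9]])
        w = anfis.firing_strengths(mem, m)
        assert w[0] == pytest.approx(0.8 * 0.5)
        assert w[3] == pytest.approx(0.3 * 0.9)

    def test_firing_zero_and_one_cases(self):
        m = tiny_model()
        assert anfis.firing_strengths(np.array([[0.0, 1.0], [1.0, 1.0]]), m)[0] == 0.0
        assert np.all(anfis.firing_strengths(np.ones((2, 2)), m) == 1.0)

    def test_normalize_basic_and_uniform_fallback(self):
        assert anfis.normalize_firing(np.array([1.0, 3.0])) == pytest.approx([0.25, 0.75])
        assert anfis.normalize_firing(np.array([0.0, 0.0])) == pytest.approx([0.5, 0.5])
        assert anfis.normalize_firing(np.full(4, 0.7)).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            anfis.normalize_firing(np.array([-0.1, 1.0]))

    def test_rule_outputs_linear_consequents(self):
        m = tiny_model()
        f = anfis.rule_outputs(np.array([2.0, 5.0]), m)
        assert f[0] == pytest.approx(2.0)  # p=(1,0), r=0
        assert f[2] == pytest.approx(2.0)  # constant rule
        assert f[3] == pytest.approx(8.0)  # 2+5+1

    def test_forward_matches_hand_computed_trace(self):
        """Layer-by-layer manual evaluation of the tiny model at one point."""
        m = tiny_model()
        x = np.array([1.0, 0.0])
        mu_a = [1 / (1 + abs(1.0 / 1.0) ** 2), 1 / (1 + abs(-1.0 / 1.0) ** 4)]
        mu_b = [1 / (1 + abs(1.0 / 2.0) ** 2), 1 / (1 + abs(-3.0 / 2.0) ** 6)]
        w = [mu_a[0] * mu_b[0], mu_a[0] * mu_b[1], mu_a[1] * mu_b[0], mu_a[1] * mu_b[1]]
        f = [1.0, 0.0, 2.0, 2.0]
        expected = sum(wi * fi for wi, fi in zip(w, f)) / sum(w)
        assert anfis.forward(x, m) == pytest.approx(expected, rel=1e-12)

    def test_forward_constant_consequents_give_constant(self):
        m = tiny_model()
        m.consequents = np.array([[0.0, 0.0, 7.0]] * 4)
        assert anfis.forward(np.array([0.3, 1.8]), m) == pytest.approx(7.0)

    @given(st.floats(-6, 6), st.floats(-6, 6))
    @settings(deadline=None, max_examples=100)
    def test_output_is_convex_combination_of_rule_outputs(self, x1, x2):
        m = tiny_model()
        x = np.array([x1, x2])
        f = anfis.rule_outputs(x, m)
        out = anfis.forward(x, m)
        assert f.min() - 1e-9 <= out <= f.max() + 1e-9


class TestTraining:
    def test_threshold_separable_1d(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.uniform(0, 0.4, (30, 1)), rng.uniform(0.6, 1.0, (30, 1))])
        y = np.array([0] * 30 + [1] * 30)
        m = anfis.ANFISModel.from_grid(X, 2)
        anfis.fit(m, X, y.astype(float), anfis.ANFISTrainConfig(epochs=15))
        assert (anfis.predict(m, X) == y).mean() == 1.0
        assert len(m.loss_trace) == 15

    def test_frozen_premise_loss_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(float)
        m = anfis.ANFISModel.from_grid(X, 2)
        anfis.fit(m, X, y, anfis.ANFISTrainConfig(epochs=6, premise_lr=0.0))
        assert np.all(np.diff(m.loss_trace) <= 1e-12)

    def test_xor_blobs(self):
        rng = np.random.default_rng(1)
        centers = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)]
        X = np.vstack([rng.normal([cx, cy], 0.15, (40, 2)) for cx, cy, _ in centers])
        y = np.concatenate([np.full(40, lab) for _, _, lab in centers])
        m = anfis.ANFISModel.from_grid(X, 2)
        anfis.fit(m, X, y.astype(float), anfis.ANFISTrainConfig(epochs=30, seed=0))
        assert (anfis.predict(m, X) == y).mean() >= 0.95

    def test_lse_step_matches_normal_equations_oracle(self):
        """Frozen premises: the consequents must solve the ridge problem, as
        checked against an explicitly assembled normal-equations solution."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        lam = 1e-6
        m = anfis.ANFISModel.from_grid(X, 2)
        anfis.fit(m, X, y, anfis.ANFISTrainConfig(epochs=1, premise_lr=0.0, l2_ridge=lam))
        # oracle: loops only
        rows = []
        for x in X:
            mem = [[anfis.bell_membership(x[j], anfis.BellMF(m.a[j, k], m.b[j, k], m.c[j, k]))
                    for k in range(m.n_mf)] for j in range(m.n_inputs)]
            w = [mem[0][r0] * mem[1][r1] for r0, r1 in m.rule_index]
            s = sum(w)
            row = []
            for wi in w:
                row.extend([wi / s * x[0], wi / s * x[1], wi / s])
            rows.append(row)
        phi = np.array(rows)
        theta = np.linalg.solve(phi.T @ phi + lam * np.eye(phi.shape[1]), phi.T @ y)
        assert np.abs(theta.reshape(m.consequents.shape) - m.consequents).max() < 1e-8

    def test_rule_blowup_guard(self):
        X = np.random.default_rng(0).normal(size=(5, 11))
        with pytest.raises(ValueError, match="rule"):
            anfis.ANFISModel.from_grid(X, 2)  # 2^11 = 2048 rules

    def test_predict_threshold_convention(self):
        # single-rule model: the normalised weight is exactly 1, so the
        # output equals the constant consequent with no rounding
        def one_rule(r):
            return anfis.ANFISModel(
                n_inputs=1,
                n_mf=1,
                a=np.array([[1.0]]),
                b=np.array([[1.0]]),
                c=np.array([[0.0]]),
                rule_index=np.array([[0]]),
                consequents=np.array([[0.0, r]]),
            )

        X = np.array([[0.0], [2.0]])
        assert np.all(anfis.predict(one_rule(0.5), X) == 1)  # boundary -> positive
        assert np.all(anfis.predict(one_rule(0.2), X) == 0)
        assert np.all(anfis.predict(one_rule(0.9), X) == 1)

    def test_predict_consistent_with_training_accuracy(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 1))
        y = (X[:, 0] > 0).astype(int)
        m = anfis.ANFISModel.from_grid(X, 3)
        anfis.fit(m, X, y.astype(float), anfis.ANFISTrainConfig(epochs=5))
        acc1 = (anfis.predict(m, X) == y).mean()
        acc2 = (anfis.predict(m, X) == y).mean()
        assert acc1 == acc2


class TestSerialization:
    def test_json_round_trip_is_exact(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        y = (X.sum(axis=1) > 0).astype(float)
        m = anfis.ANFISModel.from_grid(X, 2)
        anfis.fit(m, X, y, anfis.ANFISTrainConfig(epochs=3))
        m2 = anfis.model_from_json(anfis.model_to_json(m))
        for attr in ("a", "b", "c", "consequents"):
            assert np.array_equal(getattr(m, attr), getattr(m2, attr))
        assert np.array_equal(m.rule_index, m2.rule_index)
        x = np.array([0.3, -0.7])
        assert anfis.forward(x, m) == anfis.forward(x, m2)
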
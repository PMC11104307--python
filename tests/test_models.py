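import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from conftest import identity_basis, run_steps, random_sequences
from fearsim import (
    ModelParams,
    attention_weights,
    build_basis,
    familiarity_rate,
    predict,
    run,
    step,
)
from fearsim.models import LearnerState, salience_update


def state_with(basis, w=None, n=None, eta=None):
    s = LearnerState.zeros(basis)
    if w is not None:
        s.w = np.asarray(w, dtype=float)
    if n is not None:
        s.n = np.asarray(n, dtype=np.int64)
    if eta is not None:
        s.eta = np.asarray(eta, dtype=float)
    return s


class TestPredict:
    @pytest.mark.parametrize(
        "w, f, rectify, expected",
        [
            ((0.8, -0.5), (1, 1), True, pytest.approx(0.3)),
            ((0.8, -0.5), (0, 1), True, 0.0),
            ((0.0, 0.0), (1, 1), True, 0.0),
            ((-0.5, 0.0), (1, 0), False, pytest.approx(-0.5)),
        ],
    )
    def test_rectified_and_linear_sums(self, w, f, rectify, expected):
        basis = identity_basis(2)
        s = state_with(basis, w=w)
        p = ModelParams(variant="basic", rectify=rectify)
        assert predict(s, np.asarray(f, float), p) == expected

    def test_compact_prediction_uses_attention(self):
        basis = identity_basis(2)
        s = state_with(basis, w=(0.5, 0.5), eta=(1.0, 1.0))
        p = ModelParams.defaults("compact")
        # equal saliences, both present, m=8: a_i = 2^(-1/8) each
        a = 2.0 ** (-1.0 / 8.0)
        assert predict(s, np.ones(2), p) == pytest.approx(a * 1.0, abs=1e-12)


class TestAttention:
    def test_equal_saliences_m8_closed_form(self):
        g, a, g_norm = attention_weights(np.ones(2), np.ones(2), m=8.0)
        assert g_norm == pytest.approx(2 ** (1 / 8), abs=1e-5)
        assert a == pytest.approx([0.91700, 0.91700], abs=1e-5)

    def test_single_present_feature_gets_full_attention(self):
        _, a, _ = attention_weights(np.array([7.0, 3.0]), np.array([0.0, 1.0]), m=8.0)
        assert a.tolist() == [0.0, 1.0]

    def test_m1_is_l1_normalization(self):
        _, a, _ = attention_weights(np.array([3.0, 1.0]), np.ones(2), m=1.0)
        assert a == pytest.approx([0.75, 0.25])

    def test_norm_is_unit_over_present_features(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            eta = rng.uniform(0.1, 3.0, size=4)
            f = (rng.random(4) < 0.7).astype(float)
            if not f.any():
                continue
            m = float(rng.uniform(1.0, 10.0))
            _, a, _ = attention_weights(eta, f, m)
            assert np.sum(np.abs(a) ** m) ** (1 / m) == pytest.approx(1.0)

    def test_undefined_when_nothing_present(self):
        with pytest.raises(ValueError):
            attention_weights(np.ones(2), np.zeros(2), m=8.0)


class TestFamiliarityRate:
    def test_first_observation_closed_form(self):
        assert familiarity_rate(1, 0.1, 1.5) == pytest.approx(
            0.1 + 0.5 * 2 ** (-1.5), abs=1e-12
        )

    def test_fig6_parameterisation(self):
        assert familiarity_rate(3, 0.15, 0.5) == pytest.approx(0.4, abs=1e-12)

    def test_strictly_decreasing_to_minimum(self):
        n = np.arange(0, 2000)
        lam = familiarity_rate(n, 0.1, 1.5)
        assert (np.diff(lam) < 0).all()
        assert lam[-1] == pytest.approx(0.1, abs=1e-3)
        assert lam.max() <= 0.1 + 0.5


class TestSalienceGradient:
    def numerical_gradient(self, eta, w, f, y, m, i, h=1e-7):
        """Finite-difference d/d eta_i of squared prediction error."""

        def loss(eta_vec):
            g = eta_vec * f
            g_norm = np.sum(np.abs(g) ** m) ** (1 / m)
            a = g / g_norm
            y_hat = max(float(np.dot(a * f, w)), 0.0)
            return (y - y_hat) ** 2

        e1, e2 = eta.copy(), eta.copy()
        e1[i] += h
        e2[i] -= h
        return (loss(e1) - loss(e2)) / (2 * h)

    @pytest.mark.parametrize("m", [2.0, 8.0])
    def test_update_matches_finite_difference(self, m):
        rng = np.random.default_rng(11)
        p = ModelParams.defaults("compact", m=m)
        checked = 0
        while checked < 25:
            k = int(rng.integers(2, 5))
            eta = rng.uniform(0.3, 2.0, size=k)
            w = rng.uniform(-1, 1, size=k)
            f = (rng.random(k) < 0.8).astype(float)
            y = float(rng.integers(0, 2))
            if not f.any():
                continue
            g, a, g_norm = attention_weights(eta, f, m)
            y_hat = max(float(np.dot(a * f, w)), 0.0)
            if y_hat <= 1e-3:  # rectifier kink: analytic form only valid inside
                continue
            new_eta = salience_update(eta, w, f, a, g_norm, y_hat, y, p)
            if np.any(new_eta <= p.eta_floor):
                continue  # floor clip fired: no longer a pure gradient step
            analytic = (new_eta - eta) / p.mu
            for i in range(k):
                num = -0.5 * self.numerical_gradient(eta, w, f, y, m, i)
                assert analytic[i] == pytest.approx(num, abs=1e-6)
            checked += 1

    def test_zero_error_leaves_salience_unchanged(self):
        basis = identity_basis(2)
        s = state_with(basis, w=(0.5, 0.5), eta=(1.0, 2.0))
        p = ModelParams.defaults("compact")
        f = np.ones(2)
        _, a, g_norm = attention_weights(s.eta, f, p.m)
        y_hat = float(np.dot(a * f, s.w))
        new_eta = salience_update(s.eta, s.w, f, a, g_norm, y_hat, y_hat, p)
        assert np.array_equal(new_eta, s.eta)

    def test_absent_features_keep_their_salience(self):
        basis = identity_basis(2)
        s = state_with(basis, w=(0.5, 0.5), eta=(1.0, 2.0))
        p = ModelParams.defaults("compact")
        f = np.array([1.0, 0.0])
        g, a, g_norm = attention_weights(s.eta, f, p.m)
        new_eta = salience_update(s.eta, s.w, f, a, g_norm, 0.2, 1.0, p)
        assert new_eta[1] == 2.0


class TestStep:
    def test_first_conditioning_trial_basic(self):
        basis = identity_basis(2)
        s = LearnerState.zeros(basis)
        p = ModelParams.defaults("basic")  # lam = 0.3
        rec, s2 = step(s, np.array([1, 1]), 1.0, basis, p)
        assert rec.y_hat == 0.0 and rec.prediction_error == 1.0
        assert s2.w == pytest.approx([0.3, 0.3])

    def test_decay_acts_on_absent_negative_weights(self):
        basis = identity_basis(2)
        s = state_with(basis, w=(0.4, -0.5))
        p = ModelParams.defaults("decay")  # rho = 0.002
        rec, s2 = step(s, np.zeros(2), 0.0, basis, p)
        assert s2.w[0] == 0.4  # positive weight untouched
        assert s2.w[1] == pytest.approx(-0.499)

    def test_zero_weight_is_not_decayed(self):
        basis = identity_basis(2)
        s = state_with(basis, w=(0.0, 0.0))
        p = ModelParams.defaults("decay")
        _, s2 = step(s, np.zeros(2), 0.0, basis, p)
        assert np.array_equal(s2.w, np.zeros(2))

    def test_zero_error_fixed_point(self):
        basis = identity_basis(2)
        s = state_with(basis, w=(0.7, 0.3))
        p = ModelParams.defaults("basic")
        rec, s2 = step(s, np.ones(2), 1.0, basis, p)
        assert rec.prediction_error == 0.0
        assert np.array_equal(s2.w, s.w)

    def test_lone_inhibitor_is_protected_by_rectification(self):
        basis = identity_basis(2)
        p_on = ModelParams.defaults("basic")
        p_off = ModelParams.defaults("basic", rectify=False)
        s = state_with(basis, w=(-0.5, 0.0))
        x = np.array([1.0, 0.0])
        rec, s2 = step(s, x, 0.0, basis, p_on)
        assert rec.y_hat == 0.0 and s2.w[0] == -0.5
        rec, s2 = step(state_with(basis, w=(-0.5, 0.0)), x, 0.0, basis, p_off)
        assert rec.y_hat == -0.5 and s2.w[0] > -0.5

    def test_nan_state_fails_fast(self):
        basis = identity_basis(2)
        s = state_with(basis, w=(np.nan, 0.0))
        with pytest.raises(FloatingPointError):
            step(s, np.ones(2), 1.0, basis, ModelParams.defaults("basic"))

    def test_familiarity_counts_only_present_features(self):
        basis = identity_basis(3)
        s = LearnerState.zeros(basis)
        p = ModelParams.defaults("familiarity")
        _, s2 = step(s, np.array([1, 0, 1]), 1.0, basis, p)
        assert s2.n.tolist() == [1, 0, 1]


@pytest.mark.parametrize("variant", ["basic", "configural", "decay", "familiarity", "compact"])
def test_step_matches_naive_pseudocode_transcription(variant):
    """Vectorized steps reproduce the scalar-loop oracle to 1e-12."""
    rng = np.random.default_rng(2024)
    params = ModelParams.defaults(variant)
    for f_seq, y_seq in random_sequences(rng, 25):
        ours = run_steps(f_seq, y_seq, params)
        ref = oracle.run_variant(variant, f_seq, y_seq, params)
        np.testing.assert_allclose(ours["y_hat"], ref["y_hat"], atol=1e-12, rtol=0)
        np.testing.assert_allclose(ours["w"], ref["w"], atol=1e-12, rtol=0)


@settings(max_examples=60, deadline=None)
@given(
    variant=st.sampled_from(["basic", "configural", "decay", "familiarity", "compact"]),
    data=st.data(),
)
def test_rectified_prediction_is_never_negative(variant, data):
    k = data.draw(st.integers(2, 4))
    steps = data.draw(
        st.lists(
            st.tuples(
                st.lists(st.integers(0, 1), min_size=k, max_size=k),
                st.integers(0, 1),
            ),
            min_size=1,
            max_size=15,
        )
    )
    f_seq = [f for f, _ in steps]
    y_seq = [y for _, y in steps]
    out = run_steps(f_seq, y_seq, ModelParams.defaults(variant))
    assert (out["y_hat"] >= 0).all()


class TestRun:
    def test_conditioning_approaches_asymptote(self, simple_design):
        tr = run(simple_design, "main", ModelParams.defaults("basic"))
        assert tr.trial_y_hat(stage="conditioning")[-1] > 0.9

    def test_run_is_deterministic(self, simple_design):
        p = ModelParams.defaults("compact")
        a = run(simple_design, "main", p)
        b = run(simple_design, "main", p)
        assert np.array_equal(a.y_hat, b.y_hat)
        assert np.array_equal(a.w, b.w)
        assert np.array_equal(a.eta, b.eta)

    def test_configural_variant_gets_configural_basis(self, simple_design):
        tr = run(simple_design, "main", ModelParams.defaults("configural"))
        assert "CS*A" in tr.basis.ids

    def test_trajectory_long_export(self, simple_design, tmp_path):
        tr = run(simple_design, "main", ModelParams.defaults("basic"))
        df = tr.to_frame()
        assert len(df) == len(tr) * tr.basis.n_features
        for col in ("step", "stage", "y_hat", "feature", "w", "eta", "lambda_i"):
            assert col in df.columns
        tr.to_csv(tmp_path / "traj.csv")
        assert (tmp_path / "traj.csv").exists()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ModelParams.defaults("basic", alpha=0.5)

    def test_invalid_parameter_ranges_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(variant="basic", lam=1.5).validated()
        with pytest.raises(ValueError):
            ModelParams(variant="compact", m=0.5).validated()
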
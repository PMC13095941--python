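import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatiguedyn.models import (
    FatigueParams,
    get_model,
    model_family,
    predict_effort,
    resolve_baseline,
    trajectory,
    update_recoverable,
    update_unrecoverable,
)
from fatiguedyn.task import rest_time


class TestSingleTrialUpdates:
    def test_recoverable_work_trial(self):
        # RF 1.0, E 3, work rest time: 1.0 + 0.1*3 - 0.2*2.5 = 0.8
        assert update_recoverable(1.0, 3, 2.5, alpha=0.1, delta=0.2) == pytest.approx(0.8)

    def test_recoverable_clamped_at_zero(self):
        assert update_recoverable(0.1, 0, 7.5, alpha=0.0, delta=0.2) == 0.0

    def test_recoverable_identity(self):
        assert update_recoverable(0.7, 5, 7.5, alpha=0.0, delta=0.0) == 0.7

    def test_unrecoverable_accumulates(self):
        assert update_unrecoverable(0.0, 3, theta=0.05) == pytest.approx(0.15)
        assert update_unrecoverable(0.4, 0, theta=0.05) == 0.4  # rest: unchanged
        assert update_unrecoverable(0.4, 9, theta=0.0) == 0.4  # null limit


class TestPredictEffort:
    def test_rest_is_zero(self):
        assert predict_effort(1.5, 99.0, 0.0, "rest") == 0.0

    def test_multiplicative(self):
        assert predict_effort(1.5, 2.0, 3, "work", "multiplicative") == pytest.approx(10.5)

    def test_additive(self):
        assert predict_effort(1.5, 2.0, 3, "work", "additive") == pytest.approx(6.5)


class TestResolveBaseline:
    @pytest.mark.parametrize("raw,expected", [(37, 37.0), (0, 0.01), (None, 0.01)])
    def test_rule(self, raw, expected):
        assert resolve_baseline(raw) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            resolve_baseline(-1)


class TestTrajectory:
    def test_hand_computed_three_trials(self):
        """Full model, alpha=.1, delta=.2, theta=.05, F_start=10.

        trial 1 work E=3:  RF=max(0, .3-.5)=0,       UF=.15, F=10.15
        trial 2 rest E=0:  RF=max(0, 0-1.5)=0,       UF=.15, F=10.15
        trial 3 work E=10: RF=max(0, 0+1.0-.5)=.5,   UF=.65, F=11.15
        """
        m = get_model("full", "fatigue")
        p = FatigueParams(alpha=0.1, delta=0.2, theta=0.05)
        tr = trajectory(m, p, [3, 0, 10], [2.5, 7.5, 2.5], [True, False, True], 10.0)
        np.testing.assert_allclose(tr.rf, [0.0, 0.0, 0.5], atol=1e-12)
        np.testing.assert_allclose(tr.uf, [0.15, 0.15, 0.65], atol=1e-12)
        np.testing.assert_allclose(tr.f, [10.15, 10.15, 11.15], atol=1e-12)
        np.testing.assert_allclose(tr.predicted, tr.f, atol=1e-12)

    def test_static_limit(self):
        m = get_model("full", "fatigue")
        tr = trajectory(m, FatigueParams(), [5, 0, 5], [2.5, 7.5, 2.5],
                        [True, False, True], 12.0)
        np.testing.assert_array_equal(tr.predicted, [12.0, 12.0, 12.0])

    def test_null_effort_model(self):
        # F stays at F_start = 0.01 (no baseline collected), so the static
        # effort model predicts (gamma + 0.01) * E on work, 0 on rest.
        m = get_model("null", "effort")
        tr = trajectory(m, FatigueParams(gamma=2.0), [3, 0, 10],
                        [2.5, 7.5, 2.5], [True, False, True], 0.01)
        np.testing.assert_allclose(tr.predicted, [2.01 * 3, 0.0, 2.01 * 10])

    def test_matches_scalar_update_oracle(self, rng):
        """The vectorised trajectory equals a literal per-trial loop over the
        scalar update rules, for random parameters and sequences."""
        for _ in range(25):
            n = 40
            is_work = rng.random(n) < 0.75
            E = np.where(is_work, rng.uniform(1, 10, n), 0.0)
            t_rest = np.where(is_work, 2.5, 7.5)
            p = FatigueParams(*rng.uniform(0, 0.5, size=3), gamma=rng.uniform(0, 2))
            f_start = rng.uniform(0.01, 30)
            for readout in ("fatigue", "effort"):
                for timing in ("post", "pre"):
                    combos = ("multiplicative", "additive") if readout == "effort" else ("multiplicative",)
                    for combi in combos:
                        mid = "full" + ("_add" if combi == "additive" else "")
                        m = get_model(mid if readout == "effort" else "full", readout)
                        tr = trajectory(m, p, E, t_rest, is_work, f_start, timing)
                        rf = uf = 0.0
                        for t in range(n):
                            f_pre = f_start + rf + uf
                            uf = update_unrecoverable(uf, E[t], p.theta)
                            rf = update_recoverable(rf, E[t], t_rest[t], p.alpha, p.delta)
                            f = f_start + rf + uf
                            f_used = f if timing == "post" else f_pre
                            if readout == "fatigue":
                                expect = f_used
                            else:
                                expect = predict_effort(
                                    p.gamma, f_used, E[t],
                                    "work" if is_work[t] else "rest", combi)
                            assert tr.predicted[t] == pytest.approx(expect, abs=1e-10)
                            assert tr.rf[t] == pytest.approx(rf, abs=1e-10)
                            assert tr.uf[t] == pytest.approx(uf, abs=1e-10)

    def test_rest_only_sequence(self):
        m = get_model("full", "fatigue")
        p = FatigueParams(alpha=0.3, delta=0.1, theta=0.2)
        n = 10
        tr = trajectory(m, p, np.zeros(n), np.full(n, 7.5), np.zeros(n, bool), 5.0)
        assert np.all(tr.uf == 0.0)
        assert np.all(np.diff(tr.rf) <= 0) and tr.rf[-1] == 0.0

    def test_nested_models_coincide(self, rng):
        """Restricting the full model reproduces each nested model exactly."""
        n = 30
        is_work = rng.random(n) < 0.75
        E = np.where(is_work, rng.uniform(1, 10, n), 0.0)
        t_rest = np.where(is_work, 2.5, 7.5)
        args = (E, t_rest, is_work, 8.0)
        full = get_model("full", "fatigue")
        a, d, th = 0.3, 0.45, 0.07
        pairs = [
            (FatigueParams(alpha=0, delta=0, theta=th), get_model("uf", "fatigue"),
             FatigueParams(theta=th)),
            (FatigueParams(alpha=a, delta=d, theta=0), get_model("rf", "fatigue"),
             FatigueParams(alpha=a, delta=d)),
            (FatigueParams(alpha=a, delta=a, theta=0), get_model("rf1", "fatigue"),
             FatigueParams(alpha=a)),
        ]
        for full_params, nested, nested_params in pairs:
            t_full = trajectory(full, full_params, *args)
            t_nested = trajectory(nested, nested_params, *args)
            np.testing.assert_allclose(t_full.predicted, t_nested.predicted, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        params=st.tuples(*[st.floats(0, 2) for _ in range(3)]),
        f_start=st.floats(0.01, 50),
        seed=st.integers(0, 10_000),
    )
    def test_structural_invariants(self, params, f_start, seed):
        """F = F_start + RF + UF; UF non-decreasing; RF >= 0; PE 0 at rest."""
        rng = np.random.default_rng(seed)
        n = 24
        is_work = rng.random(n) < 0.75
        E = np.where(is_work, rng.uniform(0.5, 10, n), 0.0)
        t_rest = np.where(is_work, 2.5, 7.5)
        p = FatigueParams(*params)
        m = get_model("full", "fatigue")
        tr = trajectory(m, p, E, t_rest, is_work, f_start)
        np.testing.assert_allclose(tr.f - f_start - tr.rf - tr.uf, 0, atol=1e-9)
        assert np.all(np.diff(tr.uf) >= 0)
        assert np.all(tr.rf >= 0)
        pe = trajectory(get_model("full", "effort"),
                        FatigueParams(*params, gamma=1.0), E, t_rest, is_work,
                        f_start).predicted
        assert np.all(pe[~is_work] == 0.0)


class TestModelFamily:
    def test_family_sizes(self):
        assert len(model_family("effort")) == 6
        assert len(model_family("effort", "additive")) == 6
        assert len(model_family("fatigue")) == 5

    @pytest.mark.parametrize(
        "mid,readout,free",
        [
            ("null", "effort", ("gamma",)),
            ("uf", "effort", ("theta", "gamma")),
            ("rf", "effort", ("alpha", "delta", "gamma")),
            ("rf1", "effort", ("alpha", "gamma")),
            ("uf_rf1", "fatigue", ("theta", "alpha")),
            ("full", "fatigue", ("alpha", "delta", "theta")),
        ],
    )
    def test_free_parameters(self, mid, readout, free):
        assert get_model(mid, readout).free_params == free

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            get_model("null", "fatigue")  # null is effort-only
        with pytest.raises(ValueError):
            get_model("full_add", "fatigue")  # additive is effort-only
        with pytest.raises(ValueError):
            get_model("bogus", "effort")

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            FatigueParams(alpha=-0.1)
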
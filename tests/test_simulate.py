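import numpy as np
import pandas as pd
import pytest

from fatiguedyn.data import read_trial_table, write_trial_table
from fatiguedyn.fitting import fit_participant
from fatiguedyn.force import compute_auc, judge_success
from fatiguedyn.models import FatigueParams
from fatiguedyn.simulate import (
    SimulationConfig,
    recovery_config,
    recovery_report,
    simulate_cohort,
    simulate_force_trace,
    simulate_ratings,
    truth_frame,
)
from fatiguedyn.task import EFFORT_FRACTIONS, TrialSpec, TrialType


def work_spec(level=4, reward=6, shown=True, index=1):
    return TrialSpec(index=index, trial_type=TrialType.WORK, effort_level=level,
                     effort_fraction=EFFORT_FRACTIONS[level], reward=reward,
                     reward_shown_before=shown)


REST_SPEC = TrialSpec(index=1, trial_type=TrialType.REST, effort_level=0,
                      effort_fraction=0.0, reward=6)


class TestForceSimulation:
    def test_rest_trace_is_zero_and_successful(self, rng):
        cfg = SimulationConfig()
        trace = simulate_force_trace(REST_SPEC, 300.0, cfg, rng)
        assert compute_auc(trace) == 0.0
        assert judge_success(trace, 0.0)

    def test_clean_work_trial_matches_template_area(self, rng):
        # no noise, no shortfall: AUC = hold level x (5 - ramp/2)
        cfg = SimulationConfig(force_noise_sd=0.0, success_shortfall_prob=0.0,
                               reward_vigour_gain=0.0)
        spec = work_spec(level=4)
        trace = simulate_force_trace(spec, 300.0, cfg, rng)
        level = 0.48 * 1.08
        assert judge_success(trace, 0.48)
        assert compute_auc(trace) == pytest.approx(level * 4.75, rel=0.02)

    def test_shortfall_fails_success_criterion(self, rng):
        cfg = SimulationConfig(force_noise_sd=0.0, success_shortfall_prob=1.0)
        trace = simulate_force_trace(work_spec(), 300.0, cfg, rng)
        assert not judge_success(trace, 0.48)

    def test_reward_vigour_raises_force(self):
        cfg = SimulationConfig(reward_vigour_gain=0.01)
        rng = np.random.default_rng(0)
        auc6 = np.mean([compute_auc(simulate_force_trace(work_spec(reward=6), 300, cfg, rng))
                        for _ in range(100)])
        auc10 = np.mean([compute_auc(simulate_force_trace(work_spec(reward=10), 300, cfg, rng))
                         for _ in range(100)])
        assert auc10 > auc6

    def test_hidden_reward_has_no_vigour_effect(self):
        cfg = SimulationConfig(reward_vigour_gain=0.01, force_noise_sd=0.0,
                               success_shortfall_prob=0.0)
        rng = np.random.default_rng(0)
        a = compute_auc(simulate_force_trace(work_spec(reward=10, shown=False), 300, cfg, rng))
        b = compute_auc(simulate_force_trace(work_spec(reward=6, shown=False), 300, cfg, rng))
        assert a == pytest.approx(b, rel=1e-6)


class TestRatingSimulation:
    def _args(self, n=5):
        E = np.array([6.0, 0, 8, 10, 0])[:n]
        t = np.where(E > 0, 2.5, 7.5)
        return E, t, E > 0

    def test_static_noiseless_limit(self, rng):
        E, t, w = self._args()
        r = simulate_ratings("full", FatigueParams(), E, t, w, 12, 0.0, 100, rng)
        np.testing.assert_array_equal(r, np.full(E.size, 12.0))

    def test_quantization_rounds(self, rng):
        E, t, w = self._args(1)
        # theta chosen so prediction = 10 + 0.4*... -> 10.4
        r = simulate_ratings("uf", FatigueParams(theta=0.4 / 6.0), E, t, w,
                             10, 0.0, 100, rng)
        assert r[0] == 10.0  # round(10.4)

    def test_ceiling_censoring(self, rng):
        E, t, w = self._args()
        r = simulate_ratings("uf", FatigueParams(theta=10.0), E, t, w,
                             50, 0.0, 100, rng)
        assert r.max() == 100.0

    def test_quantize_off_is_exact(self, rng):
        E, t, w = self._args()
        p = FatigueParams(alpha=0.2, delta=0.3, theta=0.05)
        r = simulate_ratings("full", p, E, t, w, 10, 0.0, 100, rng,
                             quantize=False, censor=False)
        from fatiguedyn.models import get_model, trajectory
        tr = trajectory(get_model("full", "fatigue"), p, E, t, w, 10.0)
        np.testing.assert_array_equal(r, tr.predicted)


class TestCohortSimulation:
    def test_deterministic_from_seed(self, tmp_path):
        cfg = SimulationConfig(n_participants=2, n_trials=24, seed=5)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trial_table(a, pa)
        write_trial_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_cardinality_and_truth(self):
        cfg = SimulationConfig(n_participants=4, n_trials=36, seed=2)
        cohort = simulate_cohort(cfg)
        assert len(cohort) == 4
        assert all(len(ds) == 36 for ds in cohort)
        truths = truth_frame(cohort)
        assert len(truths) == 4 and truths["participant"].is_unique

    def test_ratings_respect_scale(self):
        cfg = SimulationConfig(n_participants=3, n_trials=24, seed=3, noise_sd=30.0)
        for ds in simulate_cohort(cfg):
            r = ds.ratings
            assert np.all(r >= 0) and np.all(r <= ds.scale_max)
            assert np.all(r == np.round(r))

    def test_trial_table_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_participants=2, n_trials=24, seed=7)
        cohort = simulate_cohort(cfg)
        path = tmp_path / "trials.csv"
        write_trial_table(cohort, path)
        loaded = read_trial_table(path)
        assert len(loaded) == 2
        np.testing.assert_allclose(loaded[0].exertion, cohort[0].exertion)
        np.testing.assert_allclose(loaded[0].ratings, cohort[0].ratings)
        assert loaded[0].baseline_rating == cohort[0].baseline_rating

    def test_missing_column_rejected(self, tmp_path):
        cfg = SimulationConfig(n_participants=1, n_trials=12, seed=7)
        frame = simulate_cohort(cfg)[0].to_frame().drop(columns=["rating"])
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="rating"):
            read_trial_table(path)


class TestRecovery:
    def test_noiseless_generating_model_fit_is_exact(self):
        cfg = recovery_config(n_participants=2, seed=11, noise_sd=0.0,
                              quantize=False, censor=False)
        for ds in simulate_cohort(cfg):
            fr = fit_participant("full", ds, readout="fatigue",
                                 xatol=1e-8, fatol=1e-12, maxiter_factor=400,
                                 n_polish=2)
            assert fr.rss < 1e-6

    def test_noise_degrades_recovery(self):
        """Parameter-recovery correlations fall as rating noise rises."""
        corr = {}
        for noise in (0.5, 25.0):
            cfg = recovery_config(n_participants=8, seed=13, noise_sd=noise)
            cohort = simulate_cohort(cfg)
            rows = [(ds.truth["params"], fit_participant("full", ds).params)
                    for ds in cohort]
            rs = []
            for name in ("alpha", "delta", "theta"):
                t = [getattr(a, name) for a, _ in rows]
                f = [getattr(b, name) for _, b in rows]
                rs.append(np.corrcoef(t, f)[0, 1])
            corr[noise] = np.mean(rs)
        assert corr[0.5] > corr[25.0]

    def test_recovery_report_fields(self):
        cfg = recovery_config(n_participants=3, seed=17)
        cohort = simulate_cohort(cfg)
        fits = pd.DataFrame([fit_participant("full", ds).to_row() for ds in cohort])
        report = recovery_report(cohort, fits)
        assert report.generating_model == "full"
        assert set(report.parameter_stats["parameter"]) == {"alpha", "delta", "theta"}
        d = report.to_dict()
        assert "alpha" in d["parameters"]

    def test_recovery_report_requires_complete_fits(self):
        cfg = recovery_config(n_participants=3, seed=19)
        cohort = simulate_cohort(cfg)
        fits = pd.DataFrame([fit_participant("full", cohort[0]).to_row()])
        with pytest.raises(ValueError, match="missing"):
            recovery_report(cohort, fits)
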
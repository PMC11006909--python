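"""Crossed-random-effects REML: design coding, estimation, BLUP features."""

import numpy as np
import pandas as pd
import pytest

from lexcat import GenerativeConfig
from lexcat.lmm import (ModelSpec, build_design, extract_participant_features,
                        factorial_terms, fit_lmm, group_training_analysis,
                        participant_metadata, predict_participant_blups,
                        winning_model_spec)
from lexcat.preprocess import filter_trials, participant_outcomes
from lexcat.simulate import simulate_study


def _toy_trials(n_part=6, n_trials=50, sd_int=0.4, sd_resid=0.5, seed=0,
                beta=(2.0, 0.7)):
    rng = np.random.default_rng(seed)
    rows = []
    b = rng.normal(0, sd_int, n_part)
    for i in range(n_part):
        x = rng.normal(0, 1, n_trials)
        y = beta[0] + beta[1] * x + b[i] + rng.normal(0, sd_resid, n_trials)
        for j in range(n_trials):
            rows.append({"participant_id": f"P{i:02d}", "stimulus": f"S{j}",
                         "x": x[j], "y": y[j]})
    return pd.DataFrame(rows)


@pytest.fixture(autouse=True)
def _register_toy_predictor(monkeypatch):
    import lexcat.lmm as lmm
    monkeypatch.setattr(lmm, "CONTINUOUS_VARS", lmm.CONTINUOUS_VARS + ("x",))


class TestBuildDesign:
    def test_standardization_and_interactions(self, small_study):
        trials = filter_trials(small_study.trials)
        spec = ModelSpec(
            fixed_terms=tuple(factorial_terms("lcm_uncertainty", "old20",
                                              "log_seq_index")),
            participant_slope_terms=(("lcm_uncertainty",),))
        d = build_design(trials, spec)
        i_u = d.xnames.index("lcm_uncertainty")
        col = d.X[:, i_u]
        assert abs(col.mean()) < 1e-10 and col.std() == pytest.approx(1.0)
        i_3 = d.xnames.index("lcm_uncertainty:old20:log_seq_index")
        prod = (d.X[:, d.xnames.index("lcm_uncertainty")]
                * d.X[:, d.xnames.index("old20")]
                * d.X[:, d.xnames.index("log_seq_index")])
        assert np.allclose(d.X[:, i_3], prod)
        assert d.X.shape[0] == len(trials)

    def test_constant_predictor_dropped(self):
        t = _toy_trials()
        t["const"] = 1.5
        spec = ModelSpec(fixed_terms=(("x",), ("const",)),
                         include_stimulus_intercept=False)
        with pytest.warns(UserWarning, match="constant"):
            d = build_design(t, spec, response="y")
        assert "const" not in d.xnames

    def test_missing_column_raises(self):
        t = _toy_trials()
        spec = ModelSpec(fixed_terms=(("nope",),))
        with pytest.raises(KeyError):
            build_design(t, spec, response="y")


class TestFitLmm:
    def test_noise_free_equals_ols_with_zero_blups(self):
        t = _toy_trials(sd_int=0.0, sd_resid=0.0)
        spec = ModelSpec(fixed_terms=(("x",),),
                         participant_slope_terms=(("x",),),
                         include_stimulus_intercept=False)
        d = build_design(t, spec, response="y")
        fit = fit_lmm(d)
        X = d.X
        ols = np.linalg.lstsq(X, d.y, rcond=None)[0]
        assert fit.beta["intercept"] == pytest.approx(ols[0], abs=1e-6)
        assert fit.beta["x"] == pytest.approx(ols[1], abs=1e-6)
        for blups in fit.participant_blups.values():
            for v in blups.values():
                assert abs(v) < 1e-6

    def test_matches_statsmodels_random_intercept(self):
        sm = pytest.importorskip("statsmodels.formula.api")
        t = _toy_trials(seed=42)
        spec = ModelSpec(fixed_terms=(("x",),),
                         include_stimulus_intercept=False)
        d = build_design(t, spec, response="y")
        fit = fit_lmm(d)
        xz = (t["x"] - t["x"].mean()) / t["x"].std(ddof=0)
        m = sm.mixedlm("y ~ xz", t.assign(xz=xz),
                       groups=t["participant_id"]).fit(reml=True)
        assert fit.beta["intercept"] == pytest.approx(m.params["Intercept"],
                                                      abs=1e-4)
        assert fit.beta["x"] == pytest.approx(m.params["xz"], abs=1e-4)
        assert fit.variance_components["participant:intercept"] == \
            pytest.approx(float(m.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.variance_components["residual"] == \
            pytest.approx(m.scale, rel=1e-3)

    def test_variance_component_matches_moments_oracle(self):
        # balanced one-way layout: ANOVA estimator of the intercept variance
        t = _toy_trials(n_part=20, n_trials=100, sd_int=0.5, sd_resid=0.4,
                        seed=7, beta=(1.0, 0.0))
        spec = ModelSpec(fixed_terms=(("x",),),
                         include_stimulus_intercept=False)
        fit = fit_lmm(build_design(t, spec, response="y"))
        g = t.groupby("participant_id")["y"]
        n_per = 100
        msb = n_per * g.mean().var(ddof=1)
        msw = g.var(ddof=1).mean()
        oracle = (msb - msw) / n_per
        assert fit.variance_components["participant:intercept"] == \
            pytest.approx(oracle, rel=0.10)

    def test_reorder_invariance(self, small_study):
        trials = filter_trials(small_study.trials)
        spec = ModelSpec(fixed_terms=(("lcm_uncertainty",), ("old20",)),
                         participant_slope_terms=(("lcm_uncertainty",),))
        f1 = fit_lmm(build_design(trials, spec))
        shuffled = trials.sample(frac=1.0, random_state=3)
        f2 = fit_lmm(build_design(shuffled, spec))
        for k in f1.beta:
            assert f1.beta[k] == pytest.approx(f2.beta[k], abs=1e-6)

    def test_objective_history_monotone(self):
        t = _toy_trials(seed=11)
        spec = ModelSpec(fixed_terms=(("x",),),
                         participant_slope_terms=(("x",),),
                         include_stimulus_intercept=False)
        fit = fit_lmm(build_design(t, spec, response="y"))
        h = fit.objective_history
        assert all(h[i + 1] <= h[i] + 1e-8 for i in range(len(h) - 1))


class TestBlupFeatures:
    def test_shrinkage_vs_per_participant_ols(self, small_study):
        trials = filter_trials(small_study.trials)
        spec = ModelSpec(fixed_terms=(("lcm_uncertainty",),),
                         participant_slope_terms=(("lcm_uncertainty",),))
        fit = fit_lmm(build_design(trials, spec))
        blups = np.array([v["lcm_uncertainty"]
                          for v in fit.participant_blups.values()])
        ols_slopes = []
        for _, g in trials.groupby("participant_id"):
            z = (g["lcm_uncertainty"] - g["lcm_uncertainty"].mean())
            z = z / max(z.std(), 1e-12)
            ols_slopes.append(
                np.polyfit(z, np.log(g["rt_ms"]), 1)[0])
        assert blups.var() <= np.var(ols_slopes) + 1e-12

    def test_blups_recover_true_slopes(self):
        cfg = GenerativeConfig(
            n_participants=24, n_trials_per_session=320, lexicon_size=500,
            seed=314)
        study = simulate_study(cfg, sessions=1)
        trials = filter_trials(study.trials)
        spec = ModelSpec(
            fixed_terms=(("lcm_uncertainty",), ("old20",),
                         ("log_seq_index",), ("lexicality",), ("log_freq",),
                         ("error",)),
            participant_slope_terms=(("lcm_uncertainty",),))
        fit = fit_lmm(build_design(trials, spec))
        truth = study.participants.set_index("id")["true_lcm_slope"]
        b = pd.Series({k: v["lcm_uncertainty"]
                       for k, v in fit.participant_blups.items()})
        assert np.corrcoef(truth[b.index], b)[0, 1] >= 0.6

    def test_blups_sum_to_zero(self, small_study):
        trials = filter_trials(small_study.trials)
        spec = ModelSpec(fixed_terms=(("lcm_uncertainty",),),
                         participant_slope_terms=(("lcm_uncertainty",),))
        fit = fit_lmm(build_design(trials, spec))
        for term in ("intercept", "lcm_uncertainty"):
            s = sum(v[term] for v in fit.participant_blups.values())
            assert abs(s) < 0.05   # REML centering, small-sample tolerance

    def test_feature_extraction_shape(self, small_study):
        trials = filter_trials(small_study.trials)
        parts = participant_outcomes(small_study.participants)
        spec = ModelSpec(fixed_terms=(("lcm_uncertainty",), ("old20",)),
                         participant_slope_terms=(("lcm_uncertainty",),))
        fit = fit_lmm(build_design(trials, spec))
        meta = participant_metadata(trials, parts)
        feats = extract_participant_features(fit, meta)
        assert len(feats) == 12
        # intercept + 1 slope BLUP, plus week/sls/error-count metadata
        assert feats.shape[1] == 2 + 3
        assert not feats.isna().any().any()

    def test_held_out_participant_conditional_modes(self, small_study):
        trials = filter_trials(small_study.trials)
        pids = sorted(trials["participant_id"].unique())
        held = pids[-1]
        spec = ModelSpec(fixed_terms=(("lcm_uncertainty",), ("old20",)),
                         participant_slope_terms=(("lcm_uncertainty",),))
        train = trials[trials["participant_id"] != held]
        fit = fit_lmm(build_design(train, spec))
        pred = predict_participant_blups(
            fit, trials[trials["participant_id"] == held])
        assert set(pred) == {"intercept", "lcm_uncertainty"}
        # full-data fit as reference: held-out mode should be close
        full = fit_lmm(build_design(trials, spec))
        ref = full.participant_blups[held]
        assert pred["intercept"] == pytest.approx(ref["intercept"], abs=0.1)


class TestGroupAnalysis:
    def test_recovers_effect_signs(self, two_session_study):
        tab = group_training_analysis(
            filter_trials(two_session_study.trials)).set_index("term")
        assert tab.loc["lcm_uncertainty", "t"] > 2
        assert tab.loc["session", "t"] < -2

    def test_phonics_arm_shows_no_uncertainty_effect(self):
        cfg = GenerativeConfig(n_participants=16, n_trials_per_session=240,
                               n_sessions=2, lexicon_size=500,
                               condition="phonics", seed=88)
        study = simulate_study(cfg)
        tab = group_training_analysis(
            filter_trials(study.trials)).set_index("term")
        assert abs(tab.loc["lcm_uncertainty", "t"]) < 2
        assert tab.loc["session", "t"] < -2

    def test_single_session_rejected(self, small_study):
        with pytest.raises(ValueError):
            group_training_analysis(small_study.trials)
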
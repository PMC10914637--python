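"""Mixed-effects behavioral models: estimates, df, diagnostics, fallbacks."""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import replace

import numpy as np
import pytest
import scipy.stats as st

from conftest import simulate_linear_choice_sessions
from socialcue.behavior import (
    _frame,
    check_model_diagnostics,
    fit_accuracy_congruency_model,
    fit_choice_model,
    fit_tus_accuracy_model,
    fit_tus_choice_model,
    likelihood_ratio_test,
)
from socialcue.task import (
    AgentParams,
    ParameterError,
    make_session_schedule,
    simulate_agent_choices,
)


def _mixture_sessions(q, n_sessions, n_trials=50, seed=0, prefix="S", tus_site="sham", q_sd=0.0, condition="Face"):
    rng = np.random.default_rng(seed)
    trials = []
    for s in range(n_sessions):
        qs = float(np.clip(q + rng.normal(0, q_sd), 0, 1)) if q_sd else q
        sched = make_session_schedule(
            condition, n_trials, seed=seed + 10 + s, session_id=f"{prefix}{s:02d}", tus_site=tus_site
        )
        trials += simulate_agent_choices(
            sched, AgentParams(follow_face_prob=qs, p_no_response=0, p_slow=0), seed=seed + 500 + s
        )
    return trials


class TestChoiceModel:
    def test_perfect_face_predictor_recovers_unit_slope_exactly(self):
        """Choices identical to the face cue give slope 1, others 0, exactly."""
        trials = _mixture_sessions(q=1.0, n_sessions=4, seed=1)
        res = fit_choice_model(trials, "Face")
        assert res.fixed_effects["face"].estimate == pytest.approx(1.0, abs=1e-10)
        assert res.fixed_effects["object"].estimate == pytest.approx(0.0, abs=1e-10)
        assert res.fixed_effects["face:object"].estimate == pytest.approx(0.0, abs=1e-10)

    def test_generative_weights_recovered_within_ci(self):
        """Linear-probability agent slopes fall inside their 95% CIs."""
        trials = simulate_linear_choice_sessions(
            20, 50, beta_face=0.5, beta_object=0.2, sd_face=0.1, sd_object=0.05,
            sd_intercept=0.05, seed=11,
        )
        res = fit_choice_model(trials, "Face")
        for term, truth in (("face", 0.5), ("object", 0.2)):
            fe = res.fixed_effects[term]
            assert abs(fe.estimate - truth) < fe.ci95_halfwidth * 1.5

    def test_estimates_invariant_to_session_order(self):
        trials = simulate_linear_choice_sessions(6, 40, 0.4, 0.2, sd_face=0.1, seed=3)
        res_a = fit_choice_model(trials, "Face")
        res_b = fit_choice_model(trials[::-1], "Face")
        for term in res_a.fixed_effects:
            assert res_a.fixed_effects[term].estimate == pytest.approx(
                res_b.fixed_effects[term].estimate, abs=1e-6
            )

    def test_mirror_relabelling_flips_slope_signs_only(self):
        """A global left/right swap flips slopes but keeps magnitudes."""
        flip = {"left": "right", "right": "left"}
        trials = simulate_linear_choice_sessions(6, 40, 0.4, 0.2, sd_face=0.1, seed=4)
        mirrored = []
        for t in trials:
            m = replace(
                t,
                face_direction=flip[t.face_direction],
                better_object_side=flip[t.better_object_side],
                rewarded_side=flip[t.rewarded_side],
                choice=flip[t.choice],
            )
            mirrored.append(m)
        res_a = fit_choice_model(trials, "Face")
        res_b = fit_choice_model(mirrored, "Face")
        # cue slopes are invariant; intercept and interaction flip sign
        # (the response flips while the f*o product does not)
        for term in ("face", "object"):
            assert res_a.fixed_effects[term].estimate == pytest.approx(
                res_b.fixed_effects[term].estimate, abs=1e-6
            )
        for term in ("intercept", "face:object"):
            assert res_a.fixed_effects[term].estimate == pytest.approx(
                -res_b.fixed_effects[term].estimate, abs=1e-6
            )

    def test_single_session_falls_back_with_warning(self):
        trials = _mixture_sessions(q=0.8, n_sessions=1, seed=5)
        with pytest.warns(UserWarning, match="single session"):
            res = fit_choice_model(trials, "Face")
        assert res.fell_back_to_fixed and not res.hessian_pd

    def test_logistic_link_available(self):
        trials = simulate_linear_choice_sessions(6, 50, 0.3, 0.15, seed=6)
        res = fit_choice_model(trials, "Face", link="logistic")
        assert res.link == "logistic"
        assert res.fixed_effects["face"].estimate > 0

    def test_logistic_separation_falls_back_to_linear(self):
        trials = _mixture_sessions(q=1.0, n_sessions=3, seed=7)
        with pytest.warns(UserWarning, match="linear link"):
            res = fit_choice_model(trials, "Face", link="logistic")
        assert res.link == "linear"


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLmerTest:
    """Independent oracle: same data, same model, fitted by lmerTest."""

    def test_estimates_df_and_loglik_match_lmer(self, tmp_path):
        trials = simulate_linear_choice_sessions(
            12, 50, 0.5, 0.2, sd_face=0.12, sd_object=0.06, sd_intercept=0.06, seed=21
        )
        res = fit_choice_model(trials, "Face")
        df = _frame(trials)
        df["fo"] = df.face * df.object
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv('{csv}')
        m <- lmer(choice ~ face + object + fo + (1 + face + object + fo || session),
                  data = d, REML = FALSE)
        co <- summary(m)$coefficients
        cat(co[,'Estimate'], co[,'df'], logLik(m), sep='\\n')
        """
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        est_r, df_r, ll_r = vals[0:4], vals[4:8], vals[8]
        terms = ["intercept", "face", "object", "face:object"]
        for term, e in zip(terms, est_r):
            assert res.fixed_effects[term].estimate == pytest.approx(e, abs=2e-4)
        for term, d in zip(terms, df_r):
            assert res.fixed_effects[term].df[1] == pytest.approx(d, rel=0.05)
        assert res.loglik == pytest.approx(ll_r, abs=1e-3)


class TestAccuracyCongruencyModel:
    def test_mixture_agent_gives_analytic_incongruency_effect(self):
        """Follow-reliable probability q implies an incongruency beta of q - 1."""
        trials = _mixture_sessions(q=0.8, n_sessions=20, seed=31, q_sd=0.04)
        res = fit_accuracy_congruency_model(trials)
        assert res.fixed_effects["incongruent"].estimate == pytest.approx(-0.2, abs=0.05)

    def test_perfect_agent_gives_exactly_zero_effect(self):
        trials = _mixture_sessions(q=1.0, n_sessions=4, seed=32)
        res = fit_accuracy_congruency_model(trials)
        assert res.fixed_effects["incongruent"].estimate == pytest.approx(0.0, abs=1e-12)

    def test_constant_congruency_rejected(self):
        trials = [t for t in _mixture_sessions(q=0.9, n_sessions=3, seed=33) if t.congruent]
        with pytest.raises(ParameterError, match="constant"):
            fit_accuracy_congruency_model(trials)


class TestTusModels:
    def _tus_dataset(self, q_sham, q_active, seed, n_sessions=8):
        trials = _mixture_sessions(q_sham, n_sessions, seed=seed, prefix="sh", tus_site="sham")
        trials += _mixture_sessions(
            q_active, n_sessions, seed=seed + 1, prefix="ac", tus_site="dmFPC"
        )
        return trials

    def test_null_stimulation_effect_is_small(self):
        trials = self._tus_dataset(0.85, 0.85, seed=41)
        res = fit_tus_accuracy_model(trials, "dmFPC", trial_subset="incongruent")
        fe = res.fixed_effects["roi"]
        assert abs(fe.estimate) < 2 * fe.ci95_halfwidth

    def test_known_accuracy_difference_recovered(self):
        """sham q=0.9 vs active q=0.8 gives a -0.1 stimulation effect."""
        trials = self._tus_dataset(0.9, 0.8, seed=42)
        res = fit_tus_accuracy_model(trials, "dmFPC", trial_subset="incongruent")
        fe = res.fixed_effects["roi"]
        assert fe.estimate == pytest.approx(-0.1, abs=0.06)

    def test_interaction_form_detects_incongruent_specific_deficit(self):
        trials = self._tus_dataset(0.9, 0.75, seed=43)
        res = fit_tus_accuracy_model(trials, "dmFPC", with_interaction=True)
        assert res.fixed_effects["roi:incongruent"].estimate < 0

    def test_choice_model_interaction_tracks_cue_downweighting(self):
        trials = self._tus_dataset(0.9, 0.7, seed=44)
        res = fit_tus_choice_model(trials, "dmFPC", cue="face")
        assert res.fixed_effects["face:roi"].estimate < -0.05

    def test_missing_sham_rejected(self):
        trials = _mixture_sessions(0.9, 4, seed=45, prefix="ac", tus_site="dmFPC")
        with pytest.raises(ParameterError, match="sham"):
            fit_tus_accuracy_model(trials, "dmFPC")


class TestDiagnostics:
    def test_ks_calibrated_on_normal_residuals(self):
        """KS rejects about 5% of truly normal residual draws."""
        rng = np.random.default_rng(51)
        trials = _mixture_sessions(q=0.8, n_sessions=3, seed=51)
        res = fit_accuracy_congruency_model(trials)
        rejections = 0
        n_draws = 400
        for _ in range(n_draws):
            r = rng.normal(0, 1.3, 250)
            rejections += check_model_diagnostics(res, r).ks_p < 0.05
        assert 0.02 <= rejections / n_draws <= 0.09

    def test_forced_fallback_sets_flag(self):
        """Degenerate (zero) residual variance forces the fixed-effects refit."""
        trials = _mixture_sessions(q=1.0, n_sessions=6, seed=52)
        res = fit_accuracy_congruency_model(trials)  # accuracy is constant 1
        assert res.fell_back_to_fixed and not res.hessian_pd

    def test_full_model_never_below_reduced_loglik(self):
        trials = simulate_linear_choice_sessions(8, 40, 0.4, 0.2, sd_face=0.1, seed=53)
        full = fit_choice_model(trials, "Face")
        reduced = fit_choice_model(trials, "Face", terms=["face"])
        stat, df, p = likelihood_ratio_test(full, reduced)
        assert stat >= -1e-6
        assert df == full.n_params - reduced.n_params
        assert 0 <= p <= 1

    def test_lr_statistic_roughly_chi2_under_reduced_truth(self):
        """Data generated without the extra terms give chi2-scale LR stats."""
        stats = []
        df_expected = None
        for rep in range(25):
            trials = simulate_linear_choice_sessions(6, 30, 0.4, 0.0, seed=600 + rep)
            full = fit_choice_model(trials, "Face")
            reduced = fit_choice_model(trials, "Face", terms=["face"])
            try:
                stat, df, _ = likelihood_ratio_test(full, reduced)
            except ParameterError:
                continue  # mixed/fixed structures differed for this draw
            stats.append(stat)
            df_expected = df
        # mean of a chi-square equals its df; allow generous Monte-Carlo slack
        assert len(stats) >= 15
        assert np.mean(stats) == pytest.approx(df_expected, rel=0.6)

    def test_non_nested_models_rejected(self):
        trials = simulate_linear_choice_sessions(6, 30, 0.4, 0.2, seed=54)
        a = fit_choice_model(trials, "Face", terms=["face"])
        b = fit_choice_model(trials, "Face", terms=["object"])
        with pytest.raises(ParameterError, match="nested"):
            likelihood_ratio_test(a, b)
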
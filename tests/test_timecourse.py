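"""Per-timepoint regression, PPI and permutation inference."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from socialcue.bold import GroundTruthEffects, ROITimeSeries, UPSAMPLE, simulate_roi_bold
from socialcue.task import AgentParams, ParameterError, make_session_schedule, simulate_agent_choices
from socialcue.timecourse import (
    EpochMatrix,
    SessionEpochData,
    UpsampledSeries,
    beta_timecourse,
    extract_epochs,
    fdr_bh,
    holm_across_rois,
    permutation_inference,
    ppi_timecourse,
    preprocess_timecourse,
)

TR = 1.48


def _epochs(data, dt=TR / UPSAMPLE, session="s"):
    data = np.atleast_2d(data)
    return EpochMatrix(data, np.arange(data.shape[1]) * dt, dt, session_id=session)


class TestPreprocess:
    def test_series_explained_by_confounds_leaves_zero_residual(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(200, 3))
        y = C @ np.array([1.0, -2.0, 0.5]) + 4.0
        s = ROITimeSeries(y, TR, "dmFPC", C, "s1")
        up = preprocess_timecourse(s)
        assert np.allclose(up.values, 0.0, atol=1e-9)

    def test_linear_ramp_upsamples_onto_the_line(self):
        """Interpolated fine-grid values of a ramp lie exactly on the line."""
        n = 100
        t_coarse = (np.arange(n) + 0.5) * TR
        y = 0.7 * t_coarse
        s = ROITimeSeries(y, TR, "mSTS", np.zeros((n, 0)), "s2")
        up = preprocess_timecourse(s)
        t_fine = np.arange(n * UPSAMPLE) * up.dt
        resid_line = y - np.polyval(np.polyfit(t_coarse, y, 1), t_coarse)  # ~0
        inside = (t_fine >= t_coarse[0]) & (t_fine <= t_coarse[-1])
        # residualization removes only the intercept here (no confounds)
        expected = 0.7 * t_fine[inside] - np.mean(y)
        assert np.allclose(up.values[inside], expected, atol=1e-9)

    def test_output_has_ten_samples_per_tr(self):
        n = 50
        s = ROITimeSeries(np.zeros(n), TR, "EVC", np.zeros((n, 2)), "s3")
        up = preprocess_timecourse(s)
        assert len(up.values) == n * 10
        assert up.dt == pytest.approx(TR / 10)


class TestExtractEpochs:
    def test_seven_second_window_gives_48_columns(self):
        up = UpsampledSeries(np.zeros(2000), TR / 10, "s")
        ep, kept = extract_epochs(up, [10.0, 50.0], window=7.0)
        assert ep.data.shape == (2, 48)
        assert kept.all()

    def test_constant_series_gives_constant_rows(self):
        up = UpsampledSeries(np.full(2000, 3.3), TR / 10, "s")
        ep, _ = extract_epochs(up, [5.0, 80.0])
        assert np.allclose(ep.data, 3.3)

    def test_out_of_range_onset_excluded_with_warning(self):
        up = UpsampledSeries(np.zeros(500), TR / 10, "s")
        with pytest.warns(UserWarning, match="excluded"):
            ep, kept = extract_epochs(up, [10.0, 73.0])
        assert ep.data.shape[0] == 1 and kept.tolist() == [True, False]


class TestBetaTimecourse:
    def test_exact_recovery_without_noise(self):
        labels = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        base = np.linspace(0, 1, 30)
        data = 2.0 + np.outer(labels, base * 1.5)
        bt = beta_timecourse(_epochs(data), labels)
        assert np.allclose(bt.series("trialtype"), base * 1.5, atol=1e-10)
        assert np.allclose(bt.series("intercept"), 2.0, atol=1e-10)

    def test_matches_generic_least_squares_oracle(self):
        """Vectorized fit equals per-timepoint lstsq on random data."""
        rng = np.random.default_rng(5)
        data = rng.normal(size=(40, 25))
        labels = rng.integers(0, 2, 40).astype(float)
        rt = rng.normal(size=40)
        bt = beta_timecourse(_epochs(data), labels, rt)
        X = np.column_stack([np.ones(40), labels, rt])
        for j in range(25):
            oracle = np.linalg.lstsq(X, data[:, j], rcond=None)[0]
            assert np.max(np.abs(bt.betas[:, j] - oracle)) < 1e-10

    def test_unbiased_for_injected_amplitude(self):
        rng = np.random.default_rng(6)
        est = []
        for _ in range(300)         :
            labels = np.tile([0.0, 1.0], 20)
            rt = rng.normal(size=40)
            data = np.outer(labels, np.ones(5)) * 0.4 + rng.normal(0, 1, (40, 5))
            bt = beta_timecourse(_epochs(data), labels, rt)
            est.append(bt.series("trialtype").mean())
        assert np.mean(est) == pytest.approx(0.4, abs=0.03)

    def test_constant_labels_rejected(self):
        with pytest.raises(ParameterError, match="trialtype"):
            beta_timecourse(_epochs(np.zeros((4, 10))), np.ones(4))


class TestPPI:
    def _make(self, n_trials=500, coupling=0.5, seed=7):
        rng = np.random.default_rng(seed)
        T = 30
        inc = rng.integers(0, 2, n_trials).astype(float)
        physio = rng.normal(size=(n_trials, T))
        target = coupling * physio * inc[:, None] + rng.normal(0, 0.5, (n_trials, T))
        return _epochs(target), inc, _epochs(physio)

    def test_injected_coupling_recovered(self):
        target, inc, physio = self._make()
        bt = ppi_timecourse(target, inc, physio)
        assert np.mean(bt.series("incongruency:physio")) == pytest.approx(0.5, abs=0.05)

    def test_independent_target_gives_zero_coupling(self):
        target, inc, physio = self._make(coupling=0.0)
        bt = ppi_timecourse(target, inc, physio)
        assert np.mean(bt.series("incongruency:physio")) == pytest.approx(0.0, abs=0.05)

    def test_rescaling_physio_scales_beta_not_inference(self):
        """physio * c divides the coupling beta by c; permutation p unchanged."""
        target, inc, physio = self._make(n_trials=80)
        c = 3.7
        scaled = _epochs(physio.data * c)
        b1 = ppi_timecourse(target, inc, physio).series("incongruency:physio")
        b2 = ppi_timecourse(target, inc, scaled).series("incongruency:physio")
        assert np.allclose(b1, b2 * c, atol=1e-8)
        s1 = [SessionEpochData(target, inc, physio=physio, session_id="a")]
        s2 = [SessionEpochData(target, inc, physio=scaled, session_id="a")]
        r1 = permutation_inference(s1, n_perm=100, seed=3, model="ppi")
        r2 = permutation_inference(s2, n_perm=100, seed=3, model="ppi")
        assert np.array_equal(r1.p_raw, r2.p_raw)

    def test_constant_incongruency_rejected(self):
        target, inc, physio = self._make(n_trials=20)
        with pytest.raises(ParameterError):
            ppi_timecourse(target, np.ones(20), physio)


class TestPermutation:
    def _null_sessions(self, n_sessions=3, n_trials=30, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for s in range(n_sessions):
            data = rng.normal(size=(n_trials, 25))
            labels = np.r_[np.zeros(n_trials // 2), np.ones(n_trials - n_trials // 2)]
            out.append(SessionEpochData(_epochs(data, session=f"s{s}"), labels, session_id=f"s{s}"))
        return out

    def test_minimum_p_is_the_add_one_floor(self):
        """A huge consistent effect bottoms out at 1/(n_perm + 1)."""
        rng = np.random.default_rng(9)
        sessions = []
        for s in range(3):
            labels = np.tile([0.0, 1.0], 15)
            data = np.outer(labels, np.ones(25)) * 50 + rng.normal(0, 0.1, (30, 25))
            sessions.append(SessionEpochData(_epochs(data, session=f"s{s}"), labels, session_id=f"s{s}"))
        res = permutation_inference(sessions, n_perm=200, seed=4)
        assert np.min(res.p_raw) == pytest.approx(1 / 201)
        assert np.all(res.p_raw >= 1 / 201)

    def test_bit_reproducible_and_session_order_invariant(self):
        sessions = self._null_sessions(seed=10)
        a = permutation_inference(sessions, n_perm=120, seed=5)
        b = permutation_inference(sessions, n_perm=120, seed=5)
        assert np.array_equal(a.null_distribution, b.null_distribution)
        c = permutation_inference(sessions[::-1], n_perm=120, seed=5)
        assert np.allclose(a.observed, c.observed, atol=1e-12)

    def test_fdr_never_below_raw_in_window(self):
        sessions = self._null_sessions(seed=11)
        res = permutation_inference(sessions, n_perm=150, seed=6)
        w = res.time_axis <= res.test_window
        assert np.all(res.p_fdr[w] >= res.p_raw[w] - 1e-12)
        assert np.all(np.isnan(res.p_fdr[~w]))

    def test_small_sessions_excluded_with_warning(self):
        sessions = self._null_sessions(seed=12)
        bad = SessionEpochData(_epochs(np.zeros((3, 25)), session="tiny"), np.array([0.0, 1.0, 1.0]), session_id="tiny")
        with pytest.warns(UserWarning, match="excluded"):
            res = permutation_inference(sessions + [bad], n_perm=100, seed=7)
        assert res.observed.shape == (25,)

    def test_low_n_perm_rejected(self):
        with pytest.raises(ParameterError):
            permutation_inference(self._null_sessions(), n_perm=50, seed=8)


def brute_force_bh(p):
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def brute_force_holm(p):
    """Holm step-down adjusted p-values straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_max = 0.0
    for rank, i in enumerate(order):
        running_max = max(running_max, (m - rank) * p[i])
        adj[i] = min(1.0, running_max)
    return adj


class TestCorrections:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40))
    def test_fdr_matches_brute_force_definition(self, p):
        assert np.allclose(fdr_bh(np.array(p)), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10))
    def test_holm_matches_brute_force_definition(self, p):
        named = {f"roi{i}": v for i, v in enumerate(p)}
        out = holm_across_rois(named)
        oracle = brute_force_holm(p)
        assert np.allclose([out[f"roi{i}"] for i in range(len(p))], oracle, atol=1e-12)

    def test_worked_three_roi_example(self):
        out = holm_across_rois({"A": 0.01, "B": 0.04, "C": 0.2})
        assert out == pytest.approx({"A": 0.03, "B": 0.08, "C": 0.2})

    def test_single_roi_unchanged(self):
        assert holm_across_rois({"mSTS": 0.33}) == pytest.approx({"mSTS": 0.33})

    def test_empty_map_rejected(self):
        with pytest.raises(ParameterError):
            holm_across_rois({})


class TestRepetitionSuppressionSignal:
    def test_direction_novelty_effect_positive_at_response_peak(self):
        """Injected novelty response shows up as positive trial-type betas."""
        rng = np.random.default_rng(42)
        from socialcue.task import make_exp1_schedule

        sessions = []
        for s in range(4):
            trials = [t for t in make_exp1_schedule(80, seed=60 + s) if t.valid and t.correct]
            labels = np.array([0.0 if t.direction_repeat else 1.0 for t in trials])
            # dissimilar-direction trials respond more strongly around 2-3 s
            T = 48
            taxis = np.arange(T) * TR / 10
            bump = np.exp(-0.5 * ((taxis - 2.5) / 0.8) ** 2)
            data = np.outer(0.3 + 0.4 * labels, bump) + rng.normal(0, 0.3, (len(trials), T))
            sessions.append(SessionEpochData(_epochs(data, session=f"e{s}"), labels,
                                             rt=rng.normal(size=len(trials)), session_id=f"e{s}"))
        res = permutation_inference(sessions, n_perm=300, seed=13)
        peak = (res.time_axis > 1.5) & (res.time_axis < 3.5)
        assert res.observed[peak].mean() > 0
        assert np.nanmin(res.p_fdr[peak]) < 0.05
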
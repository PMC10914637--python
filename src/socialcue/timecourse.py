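"""ROI activity time-course inference.

Procedure: residualize each session's ROI series against its motion
confounds, up-sample to 10 samples per TR, cut trial epochs from each
event onset to 7 s after it, fit a linear regression at every epoch
timepoint (activity model: intercept + trial-type + RT; coupling model:
intercept + incongruency + physiological series + their interaction), and
average the coefficient of interest across sessions.  Significance per
timepoint comes from a permutation null built by shuffling trial labels
within session (1,000 shuffles by default), with two-sided add-one
p-values over the window from onset to the hemodynamic peak (3 s),
Benjamini-Hochberg FDR across timepoints in that window, and a Holm
step-down correction across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._rng import derived_rng
from .bold import UPSAMPLE, ROITimeSeries, tr_sample_times
from .task import ParameterError

DEFAULT_WINDOW = 7.0  # s of epoch extracted after each onset
DEFAULT_TEST_WINDOW = 3.0  # s over which p-values are computed (to HRF peak)
DEFAULT_N_PERM = 1000


@dataclass
class UpsampledSeries:
    """Confound-residualized series on the fine grid (dt = tr/10)."""

    values: np.ndarray
    dt: float
    session_id: str


@dataclass
class EpochMatrix:
    """trials x timepoints window, time-locked to an alignment event."""

    data: np.ndarray
    time_axis: np.ndarray
    dt: float
    alignment_event: str = "decision"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.data.shape[1] != len(self.time_axis):
            raise ParameterError("epoch columns must match the time axis")
        if len(self.time_axis) and abs(self.time_axis[0]) > 1e-9:
            raise ParameterError("time axis must start at 0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class BetaTimecourse:
    betas: np.ndarray  # predictors x timepoints
    predictor_names: list[str]
    time_axis: np.ndarray
    session_id: str = ""

    def series(self, predictor: str) -> np.ndarray:
        return self.betas[self.predictor_names.index(predictor)]


@dataclass
class PermutationResult:
    observed: np.ndarray
    null_distribution: np.ndarray  # n_perm x timepoints
    p_raw: np.ndarray
    p_fdr: np.ndarray
    time_axis: np.ndarray
    test_window: float
    n_perm: int


# ---------------------------------------------------------------------------
# preprocessing and epoching


def preprocess_timecourse(series: ROITimeSeries) -> UpsampledSeries:
    """Residualize against confounds + intercept, then up-sample 10x.

    Constant confound columns (collinear with the intercept) are dropped.
    The fine grid is linear interpolation between TR midpoints.
    """
    y = series.values
    C = series.confounds
    keep = [k for k in range(C.shape[1]) if np.std(C[:, k]) > 0]
    if len(keep) < C.shape[1]:
        import warnings

        warnings.warn("constant confound columns dropped before residualization")
    X = np.column_stack([np.ones(len(y))] + [C[:, k] for k in keep])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dt = series.tr / UPSAMPLE
    t_fine = np.arange(len(y) * UPSAMPLE) * dt
    up = np.interp(t_fine, tr_sample_times(len(y), series.tr), resid)
    return UpsampledSeries(values=up, dt=dt, session_id=series.session_id)


def extract_epochs(
    series_up: UpsampledSeries,
    onsets: Sequence[float],
    window: float = DEFAULT_WINDOW,
    alignment_event: str = "decision",
) -> tuple[EpochMatrix, np.ndarray]:
    """Cut per-trial windows [onset, onset + window] from the fine grid.

    Onsets snap to the nearest grid point.  Trials whose window runs off
    the series are excluded; the boolean mask of retained trials is
    returned so the caller can subset its labels identically.
    """
    dt = series_up.dt
    n_cols = int(np.floor(window / dt)) + 1
    rows, kept = [], []
    for on in onsets:
        i0 = int(round(on / dt))
        if i0 < 0 or i0 + n_cols > len(series_up.values):
            import warnings

            warnings.warn(f"onset {on:.2f}s outside the series; trial excluded")
            kept.append(False)
            continue
        rows.append(series_up.values[i0 : i0 + n_cols])
        kept.append(True)
    if not rows:
        raise ParameterError("no trial fits inside the series")
    return (
        EpochMatrix(
            data=np.vstack(rows),
            time_axis=np.arange(n_cols) * dt,
            dt=dt,
            alignment_event=alignment_event,
            session_id=series_up.session_id,
        ),
        np.asarray(kept),
    )


# ---------------------------------------------------------------------------
# per-timepoint regressions


def _check_labels(labels: np.ndarray, name: str) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if np.unique(labels).size < 2:
        raise ParameterError(f"column {name!r} is constant; effect inestimable")
    return labels


def beta_timecourse(
    epochs: EpochMatrix, trialtype: np.ndarray, rt: np.ndarray | None = None
) -> BetaTimecourse:
    """Per-timepoint regression of activity on trial type (and RT).

    ``trialtype`` is 0/1 (similar/dissimilar, or congruent/incongruent);
    the trial-type coefficient series is the quantity of interest.
    """
    labels = _check_labels(trialtype, "trialtype")
    if len(labels) != epochs.n_trials:
        raise ParameterError("trialtype length must match the epoch rows")
    cols = [np.ones(epochs.n_trials), labels]
    names = ["intercept", "trialtype"]
    if rt is not None:
        rt = np.asarray(rt, dtype=float)
        if len(rt) != epochs.n_trials:
            raise ParameterError("rt length must match the epoch rows")
        cols.append(rt)
        names.append("rt")
    X = np.column_stack(cols)
    betas = np.linalg.solve(X.T @ X, X.T @ epochs.data)
    return BetaTimecourse(betas, names, epochs.time_axis, epochs.session_id)


def ppi_timecourse(
    target_epochs: EpochMatrix,
    incongruency: np.ndarray,
    physio_epochs: EpochMatrix,
) -> BetaTimecourse:
    """Per-timepoint psychophysiological-interaction regression.

    At each timepoint the target ROI is regressed on the incongruency
    indicator, the physiological (source ROI) signal at that timepoint,
    and their product; the interaction coefficient series measures how
    inter-areal coupling changes on incongruent trials.
    """
    inc = _check_labels(incongruency, "incongruency")
    if target_epochs.data.shape != physio_epochs.data.shape:
        raise ParameterError("target and physio epochs must share trials and time axis")
    if len(inc) != target_epochs.n_trials:
        raise ParameterError("incongruency length must match the epoch rows")
    n_t = len(target_epochs.time_axis)
    betas = np.empty((4, n_t))
    ones = np.ones(target_epochs.n_trials)
    for j in range(n_t):
        phys = physio_epochs.data[:, j]
        X = np.column_stack([ones, inc, phys, inc * phys])
        betas[:, j], _, _, _ = np.linalg.lstsq(X, target_epochs.data[:, j], rcond=None)
    return BetaTimecourse(
        betas,
        ["intercept", "incongruency", "physio", "incongruency:physio"],
        target_epochs.time_axis,
        target_epochs.session_id,
    )


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class SessionEpochData:
    """One session's ingredients for the permutation test."""

    epochs: EpochMatrix
    labels: np.ndarray
    rt: np.ndarray | None = None
    physio: EpochMatrix | None = None
    session_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.labels) != self.epochs.n_trials:
            raise ParameterError("labels must match the epoch rows")


def _session_beta(sess: SessionEpochData, labels: np.ndarray, model: str) -> np.ndarray:
    if model == "ppi":
        assert sess.physio is not None
        tc = ppi_timecourse(sess.epochs, labels, sess.physio)
        return tc.series("incongruency:physio")
    tc = beta_timecourse(sess.epochs, labels, sess.rt)
    return tc.series("trialtype")


def permutation_inference(
    sessions: Sequence[SessionEpochData],
    n_perm: int = DEFAULT_N_PERM,
    window: float = DEFAULT_TEST_WINDOW,
    seed: int = 0,
    model: str = "activity",
    shuffle: str = "labels",
) -> PermutationResult:
    """Session-averaged coefficient time course with a permutation null.

    Labels are shuffled within session (RT and physio stay paired to their
    trials under the default ``shuffle='labels'``; ``shuffle='rows'``
    permutes whole trial rows instead), the coefficient series is refit per
    session and averaged.  Two-sided add-one p-values and
    Benjamini-Hochberg FDR are reported over timepoints in [0, window].
    """
    if n_perm < 100:
        raise ParameterError(f"n_perm must be >= 100, got {n_perm}")
    if model == "ppi" and any(s.physio is None for s in sessions):
        raise ParameterError("every session needs physio epochs for the coupling model")
    usable = []
    for s in sessions:
        vals, counts = np.unique(s.labels, return_counts=True)
        if len(vals) < 2 or counts.min() < 2:
            import warnings

            warnings.warn(f"session {s.session_id!r} lacks 2 trials per label; excluded")
            continue
        usable.append(s)
    if not usable:
        raise ParameterError("no usable sessions")

    time_axis = usable[0].epochs.time_axis
    observed = np.mean([_session_beta(s, s.labels, model) for s in usable], axis=0)

    rng = derived_rng(seed, "permutation", model, n_perm)
    null = np.empty((n_perm, len(time_axis)))
    for b in range(n_perm):
        acc = np.zeros(len(time_axis))
        for s in usable:
            perm = rng.permutation(s.epochs.n_trials)
            if shuffle == "labels":
                acc += _session_beta(s, s.labels[perm], model)
            else:
                shuffled = SessionEpochData(
                    epochs=EpochMatrix(
                        s.epochs.data[perm],
                        s.epochs.time_axis,
                        s.epochs.dt,
                        s.epochs.alignment_event,
                        s.epochs.session_id,
                    ),
                    labels=s.labels,
                    rt=s.rt,
                    physio=s.physio,
                    session_id=s.session_id,
                )
                acc += _session_beta(shuffled, s.labels, model)
        null[b] = acc / len(usable)

    p_raw = (1.0 + np.sum(np.abs(null) >= np.abs(observed)[None, :], axis=0)) / (1.0 + n_perm)
    in_window = time_axis <= window + 1e-9
    p_fdr = np.full_like(p_raw, np.nan)
    p_fdr[in_window] = fdr_bh(p_raw[in_window])
    return PermutationResult(
        observed=observed,
        null_distribution=null,
        p_raw=p_raw,
        p_fdr=p_fdr,
        time_axis=time_axis,
        test_window=window,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# multiple-comparison corrections


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value vector")
    return multipletests(p, method="fdr_bh")[1]


def holm_across_rois(p_per_roi: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment of one p-value per ROI."""
    if not p_per_roi:
        raise ParameterError("empty ROI p-value map")
    names = list(p_per_roi)
    adj = multipletests([p_per_roi[n] for n in names], method="holm")[1]
    return {n: float(a) for n, a in zip(names, adj)}
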
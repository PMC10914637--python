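"""Event-related GLM design matrices, high-pass filtering and session GLMs.

Three regressor sets are supported:

* ``GLM1`` — repetition-suppression analysis of face *direction*: 13 task
  regressors (first-face onset, dissimilar/similar-direction decision
  onsets, z-scored RT, left/right responses, outcome main effect and
  reward indicator, three unconvolved movement regressors, and the two
  invalid-trial onset regressors).  Convolved boxcars last 500 ms.
* ``GLM2`` — identical but the similarity regressors encode face
  *identity* repetition.
* ``GLM3`` — the cue-arbitration task: decision-locked main effects for
  incongruent-object-followed, incongruent-face-followed and congruent
  trials, no-response trials, valid/invalid RT modulators, response sides,
  three reward indicators split the same way at outcome, and three
  unconvolved movement regressors.  Decision boxcars last 1 s, outcome
  boxcars 2 s.

Unconvolved regressors last one TR.  Motion-confound columns are appended
unconvolved.  Sessions are summarized by a one-sample random-effects test
on per-session contrast values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats as st

from .bold import (
    UPSAMPLE,
    ROITimeSeries,
    convolve_events,
    decimate_to_tr,
    hrf_kernel,
    tr_sample_times,
)
from .task import Exp1Trial, ParameterError, TrialRecord

logger = logging.getLogger(__name__)

GLM_SPECS = ("GLM1", "GLM2", "GLM3")

#: per-animal invalid-response thresholds (seconds); animal T is slower
INVALID_RT_THRESHOLDS = {"T": 2.5, "V": 1.5, "W": 1.5, "default": 1.5}


@dataclass
class EventRegressor:
    """One named regressor: its events and whether it is HRF-convolved."""

    name: str
    onsets: np.ndarray
    durations: np.ndarray
    amplitudes: np.ndarray
    convolve: bool = True

    def __post_init__(self) -> None:
        self.onsets = np.atleast_1d(np.asarray(self.onsets, dtype=float))
        self.durations = np.atleast_1d(np.asarray(self.durations, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if np.any(self.onsets < 0):
            raise ParameterError(f"regressor {self.name!r} has a negative onset")
        if np.any(self.durations <= 0):
            raise ParameterError(f"regressor {self.name!r} has a non-positive duration")

    @property
    def empty(self) -> bool:
        # all-zero amplitudes (e.g. a single z-scored RT) carry no signal
        return self.onsets.size == 0 or not np.any(self.amplitudes)


EventTable = list[EventRegressor]


@dataclass
class DesignMatrix:
    X: np.ndarray
    column_names: list[str]
    convolved_mask: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        if len(set(self.column_names)) != len(self.column_names):
            raise ParameterError("duplicated column names in design")
        if self.X.shape[1] != len(self.column_names):
            raise ParameterError("column names do not match design width")

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.column_names.index(name)]


@dataclass
class GLMFit:
    betas: np.ndarray
    column_names: list[str]
    residuals: np.ndarray
    sigma2: float
    dof: int

    def beta(self, name: str) -> float:
        return float(self.betas[self.column_names.index(name)])


# ---------------------------------------------------------------------------
# event tables


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def exp1_event_table(
    trials: Sequence[Exp1Trial],
    spec: str = "GLM1",
    tr: float = 1.48,
    boxcar: float = 0.5,
    invalid_rt_threshold: float | None = None,
) -> EventTable:
    """Regressors of the repetition-suppression GLMs for one session.

    ``invalid_rt_threshold`` additionally marks slower responses invalid
    (the per-animal cutoff: 1.5 s, or 2.5 s for the slow animal).
    """
    def is_valid(t: Exp1Trial) -> bool:
        if invalid_rt_threshold is not None and t.rt > invalid_rt_threshold:
            return False
        return t.valid

    valid = [t for t in trials if is_valid(t)]
    invalid = [t for t in trials if not is_valid(t)]
    if spec == "GLM1":
        repeat = lambda t: t.direction_repeat
        sim_name, dsim_name = "simFace", "dsimFace"
    else:
        repeat = lambda t: t.identity_repeat
        sim_name, dsim_name = "simIdentity", "dsimIdentity"

    def ev(name, ts, amps=None, dur=boxcar, convolve=True):
        ts = np.asarray(ts, dtype=float)
        amps = np.ones_like(ts) if amps is None else np.asarray(amps, dtype=float)
        return EventRegressor(name, ts, np.full_like(ts, dur), amps, convolve)

    dec = [t.onset_decision for t in valid]
    out = [t.onset_outcome for t in valid]
    # response regressors model the hand movement itself, so they sit at
    # the moment of movement (decision onset + RT)
    move = lambda t: t.onset_decision + t.rt
    table = [
        ev("face", [t.onset_first for t in valid]),
        ev(dsim_name, [t.onset_decision for t in valid if not repeat(t)]),
        ev(sim_name, [t.onset_decision for t in valid if repeat(t)]),
        ev("RT", dec, _zscore(np.array([t.rt for t in valid]))),
        ev("leftResp", [move(t) for t in valid if t.response == "left"]),
        ev("rightResp", [move(t) for t in valid if t.response == "right"]),
        ev("outcome", out),
        ev("binOutcome", out, [float(t.rewarded) for t in valid]),
        ev("leftUnconv", [move(t) for t in valid if t.response == "left"], dur=tr, convolve=False),
        ev("rightUnconv", [move(t) for t in valid if t.response == "right"], dur=tr, convolve=False),
        ev("juice", [t.onset_outcome for t in valid if t.rewarded], dur=tr, convolve=False),
        ev("fchInvalid", [t.onset_first for t in invalid]),
        ev("schInvalid", [t.onset_decision for t in invalid]),
    ]
    return table


def exp2_event_table(trials: Sequence[TrialRecord], tr: float = 1.48) -> EventTable:
    """Regressors of the cue-arbitration GLM for one session.

    Incongruent trials are split by which cue the animal followed; the
    reward indicator at outcome is split the same way.
    """
    responded = [t for t in trials if t.choice not in (None, "none")]
    valid = [t for t in responded if t.valid]
    invalid = [t for t in responded if not t.valid]
    noresp = [t for t in trials if t.choice in (None, "none")]

    inc_obj = [t for t in valid if not t.congruent and t.choice == t.better_object_side]
    inc_face = [t for t in valid if not t.congruent and t.choice == t.face_direction]
    cong = [t for t in valid if t.congruent]

    def ev(name, ts, amps=None, dur=1.0, convolve=True):
        ts = np.asarray(ts, dtype=float)
        amps = np.ones_like(ts) if amps is None else np.asarray(amps, dtype=float)
        return EventRegressor(name, ts, np.full_like(ts, dur), amps, convolve)

    rewarded = lambda t: float(t.choice == t.rewarded_side)
    # response regressors model the hand movement itself, so they sit at
    # the moment of movement (decision onset + RT)
    move = lambda t: t.onset_decision + (t.rt or 0.0)
    table = [
        ev("object", [t.onset_decision for t in inc_obj]),
        ev("face", [t.onset_decision for t in inc_face]),
        ev("congruent", [t.onset_decision for t in cong]),
        ev("noResp", [t.onset_decision for t in noresp]),
        ev("RTvalid", [t.onset_decision for t in valid], _zscore(np.array([t.rt for t in valid]))),
        ev("RTinvalid", [t.onset_decision for t in invalid], _zscore(np.array([t.rt for t in invalid]))),
        ev("leftResp", [move(t) for t in responded if t.choice == "left"]),
        ev("rightResp", [move(t) for t in responded if t.choice == "right"]),
        ev("binOutcomeObject", [t.onset_outcome for t in inc_obj], [rewarded(t) for t in inc_obj], dur=2.0),
        ev("binOutcomeFace", [t.onset_outcome for t in inc_face], [rewarded(t) for t in inc_face], dur=2.0),
        ev("binOutcomeCong", [t.onset_outcome for t in cong], [rewarded(t) for t in cong], dur=2.0),
        ev("leftUnconv", [move(t) for t in responded if t.choice == "left"], dur=tr, convolve=False),
        ev("rightUnconv", [move(t) for t in responded if t.choice == "right"], dur=tr, convolve=False),
        ev("juice", [t.onset_outcome for t in valid if rewarded(t)], dur=tr, convolve=False),
    ]
    return table


def build_design(
    trials: Sequence[TrialRecord] | Sequence[Exp1Trial],
    spec: str,
    confounds: np.ndarray | None = None,
    tr: float = 1.48,
    n_timepoints: int | None = None,
    invalid_rt_threshold: float | None = None,
) -> DesignMatrix:
    """Time x regressor matrix for one session at the TR grid.

    Convolved columns are built on a fine grid of ``tr/10``, convolved with
    the gamma HRF and sampled at TR midpoints.  Regressors with no events
    (e.g. no invalid trials this session) are dropped with a logged warning
    to preserve full column rank.
    """
    if spec not in GLM_SPECS:
        raise ParameterError(f"unknown GLM spec {spec!r}; expected one of {GLM_SPECS}")
    trials = list(trials)
    if not trials:
        raise ParameterError("no trials supplied")
    if spec in ("GLM1", "GLM2"):
        if not isinstance(trials[0], Exp1Trial):
            raise ParameterError(f"{spec} requires repetition-suppression trials")
        table = exp1_event_table(trials, spec, tr=tr, invalid_rt_threshold=invalid_rt_threshold)
    else:
        if not isinstance(trials[0], TrialRecord):
            raise ParameterError("GLM3 requires cue-arbitration trials")
        table = exp2_event_table(trials, tr=tr)

    if n_timepoints is None:
        last = max(float(np.max(r.onsets + r.durations)) for r in table if not r.empty)
        n_timepoints = int(np.ceil((last + 25.0) / tr))
    return design_from_events(table, confounds=confounds, tr=tr, n_timepoints=n_timepoints)


def design_from_events(
    table: EventTable,
    confounds: np.ndarray | None = None,
    tr: float = 1.48,
    n_timepoints: int = 0,
) -> DesignMatrix:
    if n_timepoints < 1:
        raise ParameterError("n_timepoints must be positive")
    dt = tr / UPSAMPLE
    n_fine = n_timepoints * UPSAMPLE
    kernel = hrf_kernel(dt)
    cols, names, conv = [], [], []
    for reg in table:
        if reg.empty:
            logger.warning("regressor %r has no events; dropped from the design", reg.name)
            continue
        if reg.convolve:
            fine = convolve_events(reg.onsets, reg.durations, reg.amplitudes, n_fine, dt, kernel)
            col = decimate_to_tr(fine, n_timepoints)
        else:
            u = np.zeros(n_fine)
            for on, dur, amp in zip(reg.onsets, reg.durations, reg.amplitudes):
                i0 = int(np.ceil(on / dt - 1e-9))
                u[i0 : min(int(np.ceil((on + dur) / dt - 1e-9)), n_fine)] += amp
            col = decimate_to_tr(u, n_timepoints)
        cols.append(col)
        names.append(reg.name)
        conv.append(reg.convolve)
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_timepoints:
            raise ParameterError("confound rows must match the series length")
        for k in range(confounds.shape[1]):
            cols.append(confounds[:, k])
            names.append(f"confound_{k + 1}")
            conv.append(False)
    X = np.column_stack(cols)
    return DesignMatrix(X=X, column_names=names, convolved_mask=np.array(conv), tr=tr)


# ---------------------------------------------------------------------------
# filtering and fitting


def highpass_filter(series: np.ndarray, tr: float, cutoff: float = 100.0) -> np.ndarray:
    """Remove slow drift with a Gaussian-weighted running-line fit.

    At each timepoint a local line is fit under Gaussian weights of width
    sigma = cutoff/4 and its value subtracted, so fluctuations slower than
    the cutoff are suppressed while task-band frequencies pass nearly
    untouched (a constant input maps to zero).
    """
    series = np.asarray(series, dtype=float)
    if cutoff <= 2 * tr:
        raise ParameterError(f"cutoff must exceed 2*tr = {2 * tr}")
    n = len(series)
    if n < cutoff / tr:
        warnings.warn("series shorter than the cutoff; high-pass filter skipped")
        return series.copy()
    sigma = cutoff / 4.0
    t = np.arange(n) * tr
    d = t[None, :] - t[:, None]  # d[i, j] = t_j - t_i
    W = np.exp(-0.5 * (d / sigma) ** 2)
    S0 = W.sum(axis=1)
    S1 = (W * d).sum(axis=1)
    S2 = (W * d**2).sum(axis=1)
    Sy = W @ series
    Sxy = (W * d) @ series
    denom = S0 * S2 - S1**2
    trend = (S2 * Sy - S1 * Sxy) / denom
    return series - trend


def highpass_design(design: DesignMatrix, cutoff: float = 100.0) -> DesignMatrix:
    """Apply the identical high-pass filter to every design column."""
    X = np.column_stack(
        [highpass_filter(design.X[:, j], design.tr, cutoff) for j in range(design.X.shape[1])]
    )
    return DesignMatrix(X, list(design.column_names), design.convolved_mask.copy(), design.tr)


def fit_glm(series: ROITimeSeries | np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares fit of one session's series on the design."""
    y = series.values if isinstance(series, ROITimeSeries) else np.asarray(series, dtype=float)
    X = design.X
    if len(y) != X.shape[0]:
        raise ParameterError("series and design have different lengths")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(design.column_names[j])
        raise ParameterError(f"design is rank deficient; collinear columns: {bad}")
    betas, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ betas
    dof = len(y) - X.shape[1]
    if dof < 1:
        raise ParameterError("non-positive residual degrees of freedom")
    return GLMFit(
        betas=betas,
        column_names=list(design.column_names),
        residuals=resid,
        sigma2=float(resid @ resid / dof),
        dof=dof,
    )


@dataclass(frozen=True)
class GroupContrast:
    estimate: float
    t: float | None
    p: float | None
    n_sessions: int
    degenerate: bool = False
    session_values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def contrast_vector(design_names: Sequence[str], weights: dict[str, float]) -> np.ndarray:
    """Contrast over named columns; names missing from the design error out."""
    c = np.zeros(len(design_names))
    for name, w in weights.items():
        if name not in design_names:
            raise ParameterError(f"contrast names column {name!r} absent from the design")
        c[list(design_names).index(name)] = w
    return c


def contrast_group(session_fits: Sequence[GLMFit], contrast: np.ndarray | dict[str, float]) -> GroupContrast:
    """Random-effects group test of a contrast, sessions as the unit.

    Per-session contrast values are summarized by a two-sided one-sample t
    test; with zero between-session variance the exact-equality diagnostic
    is reported instead of a t statistic.
    """
    if len(session_fits) < 3:
        raise ParameterError("need at least 3 sessions for group inference")
    values = []
    for fit in session_fits:
        c = contrast if isinstance(contrast, np.ndarray) else contrast_vector(fit.column_names, contrast)
        if len(c) != len(fit.betas):
            raise ParameterError("contrast length does not match the design")
        values.append(float(c @ fit.betas))
    values = np.asarray(values)
    if np.allclose(values, values.mean(), rtol=1e-10, atol=1e-12):
        return GroupContrast(
            estimate=float(values.mean()),
            t=None,
            p=None,
            n_sessions=len(values),
            degenerate=True,
            session_values=values,
        )
    res = st.ttest_1samp(values, 0.0)
    return GroupContrast(
        estimate=float(values.mean()),
        t=float(res.statistic),
        p=float(res.pvalue),
        n_sessions=len(values),
        session_values=values,
    )
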
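"""Synthetic ROI BOLD generation with known injected effects.

Every downstream stage (design/GLM fitting, time-course regression, PPI,
permutation inference) is validated against series produced here, because
the generative amplitudes, coupling and noise are known exactly.

Signal model, built on a fine grid of ``tr/10`` and decimated to the TR
grid:

    baseline
    + [congruency-dependent event boxcars (x) HRF]
    + [RT-modulated event boxcars (x) HRF]
    + coupling x physio x incongruent-epoch indicator      (optional)
    + slow cosine drift (periods above the high-pass cutoff)
    + AR(1) noise (+ optional white noise) at the TR grid
    + a small admixture of the motion-confound columns

The HRF is a single gamma density with mean lag 3 s and SD 1.5 s
(moment-matched shape 4, scale 0.75 s), normalized to unit integral so
event amplitudes stay in signal units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats as st

from ._rng import derived_rng
from .task import ParameterError, TrialRecord

ROI_LABELS = ("dmFPC", "mSTS", "lateral_mSTS", "AM", "EVC", "area47_12o", "other")

DEFAULT_TR = 1.48
UPSAMPLE = 10  # fine-grid samples per TR, shared with the analysis side

HRF_MEAN = 3.0  # s
HRF_SD = 1.5  # s
HRF_SUPPORT = 30.0  # s


def hrf_kernel(dt: float) -> np.ndarray:
    """Gamma-density hemodynamic kernel sampled on [0, 30] s.

    Shape and scale are moment-matched to mean 3 s / SD 1.5 s:
    shape = (mean/SD)^2 = 4, scale = SD^2/mean = 0.75 s.  The discrete
    kernel is renormalized to unit integral (sum(k) * dt == 1).
    """
    if not 0 < dt <= 0.2:
        raise ParameterError(f"dt must be in (0, 0.2] s, got {dt}")
    shape = (HRF_MEAN / HRF_SD) ** 2
    scale = HRF_SD**2 / HRF_MEAN
    t = np.arange(0.0, HRF_SUPPORT + dt / 2, dt)
    k = st.gamma.pdf(t, a=shape, scale=scale)
    k /= k.sum() * dt
    return k


def tr_sample_times(n: int, tr: float) -> np.ndarray:
    """Acquisition times of the TR grid (midpoint convention)."""
    return (np.arange(n) + 0.5) * tr


def decimate_to_tr(fine: np.ndarray, n: int) -> np.ndarray:
    """Sample a fine-grid series at the TR midpoints (every UPSAMPLE-th bin)."""
    return fine[UPSAMPLE // 2 :: UPSAMPLE][:n]


def convolve_events(
    onsets: Sequence[float],
    durations: Sequence[float],
    amplitudes: Sequence[float],
    n_fine: int,
    dt: float,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Boxcar event train convolved with the HRF on the fine grid."""
    u = np.zeros(n_fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        # half-open boxcar [on, on+dur): sample j active iff on <= j*dt < on+dur
        i0 = int(np.ceil(on / dt - 1e-9))
        i1 = int(np.ceil((on + dur) / dt - 1e-9))
        if i0 < 0 or i0 >= n_fine:
            raise ParameterError(f"event onset {on} s outside the series")
        u[i0 : min(i1, n_fine)] += amp
    if kernel is None:
        kernel = hrf_kernel(dt)
    return np.convolve(u, kernel)[:n_fine] * dt


@dataclass
class ROITimeSeries:
    """One session's ROI signal at the TR grid with confound columns."""

    values: np.ndarray
    tr: float
    roi_label: str
    confounds: np.ndarray
    session_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.confounds = np.asarray(self.confounds, dtype=float)
        if self.confounds.ndim == 1:
            self.confounds = self.confounds[:, None]
        if self.tr <= 0:
            raise ParameterError(f"tr must be positive, got {self.tr}")
        if len(self.values) != self.confounds.shape[0]:
            raise ParameterError("values and confounds must have equal length")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GroundTruthEffects:
    """Injected effect sizes; serialized next to each simulated series."""

    amp_congruent: float = 0.0
    amp_incongruent: float = 0.0
    amp_rt: float = 0.0
    ppi_beta: float = 0.0
    noise_sd: float = 0.5
    white_sd: float = 0.0
    ar1_phi: float = 0.3
    drift_amp: float = 1.0
    baseline: float = 100.0
    confound_weight: float = 0.0
    event_duration: float = 1.0
    n_confounds: int = 13

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.white_sd < 0:
            raise ParameterError("noise SDs must be non-negative")
        if not -1 < self.ar1_phi < 1:
            raise ParameterError(f"ar1_phi must be in (-1, 1), got {self.ar1_phi}")


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def motion_confounds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Standardized smooth random walks emulating motion/warp components."""
    c = np.cumsum(rng.normal(size=(n, k)), axis=0)
    c -= c.mean(axis=0)
    sd = c.std(axis=0)
    sd[sd == 0] = 1.0
    return c / sd


def simulate_roi_bold(
    schedule: Sequence[TrialRecord],
    effects: GroundTruthEffects,
    roi: str = "dmFPC",
    duration: float | None = None,
    seed: int = 0,
    tr: float = DEFAULT_TR,
    physio: ROITimeSeries | None = None,
) -> ROITimeSeries:
    """Simulate one session's ROI series for a completed trial schedule.

    Event responses are boxcars at the decision onsets with amplitude
    ``amp_congruent`` or ``amp_incongruent`` by trial type plus
    ``amp_rt`` x z-scored RT, convolved with the HRF.  When ``physio`` is
    given, ``ppi_beta`` x (demeaned physio) is added during incongruent-trial
    epochs, injecting condition-dependent coupling onto this target ROI.
    RNG streams are derived per (seed, session, ROI).
    """
    if roi not in ROI_LABELS:
        raise ParameterError(f"unknown ROI label {roi!r}")
    if len(schedule) == 0:
        raise ParameterError("schedule is empty")
    session_id = schedule[0].session_id
    last = max(t.onset_outcome for t in schedule)
    if duration is None:
        duration = last + 30.0
    if last >= duration - 30.0 + 1e-9:
        raise ParameterError("all event onsets must end 30 s before the series end")

    rng = derived_rng(seed, "bold", session_id, roi)
    n = int(round(duration / tr))
    dt = tr / UPSAMPLE
    n_fine = n * UPSAMPLE
    kernel = hrf_kernel(dt)

    onsets = [t.onset_decision for t in schedule]
    amps = [effects.amp_incongruent if not t.congruent else effects.amp_congruent for t in schedule]
    durs = [effects.event_duration] * len(schedule)
    fine = convolve_events(onsets, durs, amps, n_fine, dt, kernel)

    rts = np.array([t.rt if t.rt is not None else np.nan for t in schedule], dtype=float)
    if effects.amp_rt != 0 and np.isfinite(rts).any():
        z = np.zeros_like(rts)
        m = np.isfinite(rts)
        if m.sum() > 1 and np.nanstd(rts[m]) > 0:
            z[m] = (rts[m] - rts[m].mean()) / rts[m].std()
        fine += convolve_events(onsets, durs, effects.amp_rt * z, n_fine, dt, kernel)

    if physio is not None and effects.ppi_beta != 0:
        t_fine = np.arange(n_fine) * dt
        phys = np.interp(t_fine, tr_sample_times(physio.n, physio.tr), physio.values)
        phys = phys - phys.mean()
        gate = np.zeros(n_fine)
        for t in schedule:
            if not t.congruent:
                i0 = int(round(t.onset_decision / dt))
                i1 = int(round((t.onset_decision + 7.0) / dt))
                gate[i0 : min(i1, n_fine)] = 1.0
        fine += effects.ppi_beta * phys * gate

    signal = effects.baseline + decimate_to_tr(fine, n)

    # background drawn independently of the amplitudes so that the signal is
    # linear in the injected effects at fixed seed
    ts = tr_sample_times(n, tr)
    drift = np.zeros(n)
    if effects.drift_amp > 0:
        for period in (128.0, 256.0, 512.0):
            drift += np.cos(2 * np.pi * ts / period + rng.uniform(0, 2 * np.pi))
        drift *= effects.drift_amp / max(drift.std(), 1e-12)
    noise = _ar1(n, effects.ar1_phi, effects.noise_sd, rng)
    if effects.white_sd > 0:
        noise = noise + rng.normal(0, effects.white_sd, n)
    confounds = motion_confounds(n, effects.n_confounds, rng)
    mix = np.zeros(n)
    if effects.confound_weight != 0:
        w = rng.normal(0, effects.confound_weight, effects.n_confounds)
        mix = confounds @ w

    return ROITimeSeries(
        values=signal + drift + noise + mix,
        tr=tr,
        roi_label=roi,
        confounds=confounds,
        session_id=session_id,
    )


def to_nifti(series: ROITimeSeries, path: str) -> None:
    """Export as a single-voxel 4D volume series (requires nibabel)."""
    import nibabel as nib

    data = series.values.reshape(1, 1, 1, -1).astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = series.tr
    nib.save(img, path)
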
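# Methods

`socialcue` simulates and analyses a two-alternative decision task in which
a social cue (a conspecific's gaze direction) and a non-social cue (which of
two flanking objects has the higher reward probability) jointly predict the
rewarded side, with block-wise cue reliabilities of 90%/60% (Face block),
60%/90% (Object block) and 90%/90% (Mixed block). The scientific questions
the pipeline serves are (i) how strongly each cue drives choice as a
function of its reliability, and (ii) how ROI-level BOLD activity and
inter-areal coupling change on *incongruent* trials — trials on which the
gaze points away from the better object and the subject must arbitrate.

## Task and agent simulation (`socialcue.task`)

Each trial draws the better object's side uniformly; the rewarded side
equals it with probability `p_object`; the gaze points at the rewarded side
with probability `p_face`. The draws are independent across trials, which
implies an incongruent-trial fraction of `1 − (p_face·p_object +
(1−p_face)(1−p_object))` — 0.42 in the Face and Object blocks and 0.18 in
the Mixed block. Event timing uses the task's printed ranges: 3–4 s
inter-trial intervals and a 3–5 s decision-to-outcome delay (300 ms in the
stimulation experiment variant), drawn uniformly.

Choice agents come in two parameterizations:

* a **logistic policy**, P(right) = σ(w_face·f + w_object·o + bias) with
  cues coded −1/+1, plus a uniform lapse;
* a **mixture policy** that follows the gaze with probability q and the
  better object otherwise. Under −1/+1 coding its conditional mean choice
  is exactly q·f + (1−q)·o, which makes it the analytic oracle for the
  linear-link regression models.

Agents miss a fraction of trials (default 5% no-response) and respond
slower than the 10 s validity limit on another 2%; these rates emulate the
missed/invalid trials real sessions contain (sessions missing more than a
fifth of trials were excluded in the study this emulates) and are also what
keeps the full event-related design matrix of the imaging model at full
column rank.

**Accuracy convention.** Accuracy is 1 iff the choice matches the side
indicated by the block's high-reliability source (gaze in the Face block,
better object in the Object block). In the Mixed block both sources are
maximally reliable: on congruent trials the common side scores, on
incongruent trials either choice scores 1 (each side is indicated by one
90%-reliable source). A reward-based convention (accuracy = reward receipt)
is available via `accuracy_convention="reward"`.

**Stimulation model.** Transcranial ultrasound disruption is emulated as a
multiplicative down-weighting (default factor 0.5) of cue weights: an mSTS
hit scales `w_face`, an EVC hit scales `w_object`, and a dmFPC hit scales
the weight of whichever cue is reliable in the current block — so its
behavioral cost concentrates on incongruent trials in *both* blocks. For
mixture agents the follow-probability contracts toward 0.5 by the same
factor.

**Randomness.** One top-level seed; every session, ROI and permutation run
derives an independent stream from (seed, string key) via CRC32 into a
`SeedSequence`, so schedules and simulations are bit-reproducible and
insensitive to the order in which sessions are generated.

## Behavioral mixed models (`socialcue.behavior`)

Four trial-level regressions, each with a per-session random intercept and
random slopes (independent variance components), estimated by maximum
likelihood through `statsmodels.MixedLM`:

1. choice ~ face + object + face:object (per block);
2. accuracy ~ incongruency (0 congruent / 1 incongruent);
3. accuracy ~ stimulation (0 sham / 1 active), per congruency subset, or
   with incongruency and its interaction added;
4. choice ~ cue + stimulation + cue:stimulation.

Sides are coded −1/+1 and the response −1/+1 under the default
**linear-probability link**; coefficient magnitudes are then directly
interpretable as choice-probability effects (a slope of q for a mixture-q
agent). A logistic link is available for the choice model as a
fixed-effects logistic regression (no mixed-logistic estimator exists in
the installed stack); complete separation falls back to the linear link
with a warning.

**Inference.** Each coefficient is tested with an F statistic whose
denominator degrees of freedom use the Satterthwaite approximation:
df = 2·f²/Var(f) with f the coefficient's sampling variance at the ML
variance estimates and Var(f) obtained by the delta method over the
variance-parameter covariance. That covariance is the inverse curvature of
the ML likelihood *profiled over the fixed effects*, evaluated in
log-variance space; the profiled likelihood itself is computed from
per-session sufficient statistics (X'X, X'y, y'y) via the Woodbury
identity, so each evaluation costs O(sessions·q³) regardless of trial
counts. The optimum reported by `MixedLM` is polished by Nelder-Mead in
log-variance space before the curvature is taken. Estimates, Satterthwaite
df and log-likelihoods agree with R's `lmerTest` to ~1e-4 on shared data
(tested).

**Boundary and fallback rules.** ML routinely drives some variance
components to zero. Components below 1e-6 of the residual variance are
pinned to the boundary and excluded from the curvature computation (they
contribute no sampling uncertainty), mirroring how lmerTest treats singular
fits. If the remaining (interior) Hessian is still not positive definite,
or every component is at the boundary, the model is refit with all terms as
fixed effects — all at once, not by stepwise pruning — and flagged
(`fell_back_to_fixed`). Residual normality is recorded as a
Kolmogorov-Smirnov p-value in the Lilliefors form (null parameters are
estimated from the residuals; the plain KS null would be severely
conservative — its rejection rate on truly normal residuals is ~0 instead
of the nominal 5%). Nested models are compared by likelihood ratio, with
the df equal to the difference in free parameter counts.

## BOLD simulation (`socialcue.bold`)

The hemodynamic kernel is a single gamma density with mean lag 3 s and SD
1.5 s; moment matching gives shape (3/1.5)² = 4 and scale 1.5²/3 = 0.75 s.
It is sampled on [0, 30] s and normalized to unit discrete integral, so
injected event amplitudes are in signal units. (No undershoot term: the
task's kernel is specified only through these two moments.)

A session's ROI series is built on a fine grid of TR/10 = 0.148 s and
sampled at TR midpoints: baseline + congruency-dependent 1 s boxcars (×
HRF) + RT-modulated boxcars (× HRF) + an optional coupling term
(`ppi_beta` × demeaned source-ROI signal during 7 s incongruent-trial
windows) + slow cosine drift (periods 128–512 s, i.e. below the high-pass
cutoff) + AR(1) noise at the TR grid (stationary SD `noise_sd`, default
φ = 0.3, optional additional white noise) + a small admixture of the 13
standardized random-walk confound columns that stand in for the motion/warp
regressors. Noise and drift are drawn before and independently of the
amplitudes, so the signal is exactly linear in the injected effects at a
fixed seed (property-tested). Boxcars are half-open intervals `[on,
on+dur)` sampled on the fine grid.

## Event-related GLMs (`socialcue.design`)

Design matrices reproduce the three regressor sets: the two
repetition-suppression models (13 task regressors, 500 ms convolved
boxcars, direction- vs identity-repeat variants) and the cue-arbitration
model (14 task regressors; 1 s decision boxcars, 2 s outcome boxcars;
incongruent trials split by which cue was followed). Unconvolved movement
regressors last one TR and sit at the moment of movement (decision onset +
RT) — as do the convolved response-side regressors, since they model the
motor event; this also removes the exact collinearity that would otherwise
tie the three decision-category regressors to the two response-side
regressors in a session without missed trials. Regressors with no events
(or all-zero amplitudes, e.g. a z-scored RT over a single invalid trial)
are dropped with a logged warning rather than kept as zero columns. RT
modulators are z-scored within session.

High-pass filtering removes a Gaussian-weighted running-line fit
(local linear regression) at each timepoint, with σ = cutoff/4 and a
default cutoff of 100 s. With this width a 200 s-period oscillation is
attenuated by more than half while a 20 s-period signal passes at >90%
amplitude (tested empirically); a pure linear trend is removed exactly.
The same filter is applied to the data series and to every design column.

Per-session fits are ordinary least squares (no prewhitening; group
inference across sessions is the contract); rank deficiency raises an
error naming the collinear columns. Group inference treats sessions as
random effects: per-session contrast values enter a two-sided one-sample
t test, with a degenerate-variance diagnostic path when all sessions agree
exactly.

## Time-course inference (`socialcue.timecourse`)

Each session's series is residualized against its confound columns plus an
intercept, up-sampled ×10 by linear interpolation, and cut into per-trial
epochs from each event onset (snapped to the nearest fine-grid point) to
7 s after it — 48 samples at TR 1.48 s. At every epoch timepoint a linear
regression is fit across trials: intercept + trial type (+ z-scored RT)
for activity analyses, or intercept + incongruency + source-ROI signal +
their product for the coupling (PPI) analysis, whose interaction
coefficient is the quantity of interest.

The coefficient series is averaged across sessions; significance per
timepoint comes from a permutation null: trial labels are shuffled within
session (1,000 shuffles by default), coefficients refit and re-averaged.
Shuffling permutes the labels only — RT and the source-ROI rows stay
paired to their trials — testing the labeled effect while preserving the
nuisance structure; row shuffling is available via `shuffle="rows"`.
P-values are two-sided with the add-one estimator, p = (1 + #{|null| ≥
|observed|})/(1 + n_perm), so the attainable floor is 1/(n_perm+1) and the
test is valid under exchangeability. Benjamini-Hochberg FDR is applied
across timepoints in the window from onset to the hemodynamic peak (3 s);
Holm-Bonferroni is applied across ROIs on top of the FDR-corrected values
(the composition order is this package's convention). Both corrections are
property-tested against brute-force implementations of their definitions.

## Pipeline and formats (`socialcue.io`, `socialcue.pipeline`, CLI)

Trial tables are tab-separated files in a BIDS-events-style dialect
(columns `onset`, `duration`, `trial_type` plus the trial fields; one file
per session; UTF-8; mandatory header; common deposited-data column names
accepted through an alias map). ROI series are delimited matrices (time ×
[signal, confounds]) with a JSON sidecar carrying TR, ROI label and any
simulation ground truth; a single-voxel NIfTI export is available when
nibabel is installed. The `socialcue` CLI chains simulate → behavior → glm
→ timecourse → report; every run writes a manifest with the seed, a
parameter digest and SHA-256 hashes of each output, and a repeated run
with the same config reproduces every file bit-identically (tested). Exit
codes: 0 ok, 1 user error, 2 internal error.

## What the synthetic generator does and does not emulate

It reproduces the block/reliability structure, congruency statistics,
event timing, reliability-weighted choice behavior with session-to-session
heterogeneity, miss/slow-response rates, event-locked BOLD with
condition-dependent amplitudes of either sign, condition-gated inter-areal
coupling, drift, autocorrelated noise and motion-like confounds. It does
not emulate spatial structure (no voxels, smoothing or registration),
learning of the reliabilities (agents are stationary, as subjects were
trained to near-optimal performance before testing), visual stimulus
properties, eye movements, or hardware/physiological artifacts beyond the
confound stand-ins. Passing tests therefore demonstrate the correctness
and calibration of the statistical machinery under the stated generative
assumptions, not the physiological claims themselves.

## Problem sizes and defaults used by the test suite

Parameter-recovery tests run 100 replicates at the study's size (46
sessions × 50 trials for the choice and accuracy models; 8 sham + 8 active
sessions for the stimulation models) and require ≥90% CI coverage of the
generative coefficients. Recovery generators draw per-session parameters —
linear-probability slopes 0.5 ± 0.1 (face) and 0.2 ± 0.05 (object) for the
choice model; follow-probabilities q ~ Beta(9, 3) with lapse 0.1 for the
accuracy model, whose analytic incongruency effect is
(1−lapse)(E[q]−1) = −0.225; q jitter ± 0.03 for the stimulation models.
Session-to-session heterogeneity of this order is what makes the
random-effect variances estimable, matches the spread implied by
session-level CIs in real datasets of this design, and is how real animals
behave; a deterministic agent with no heterogeneity puts every variance at
the boundary and gives congruent trials zero residual variance, a
heteroscedastic extreme under which any homoscedastic mixed model
undercovers. Permutation
calibration uses 200 replicates × 200 shuffles (4 sessions × 40 trials);
sign-pattern checks use 16 sessions per block with ±0.5 injected
congruency-amplitude differences at noise SD 0.5. Kernel, convolution,
FDR/Holm and PPI checks are exact-oracle comparisons and run in seconds.
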
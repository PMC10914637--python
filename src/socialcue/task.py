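"""Trial schedules and synthetic choice agents for the gaze-vs-object cue task.

The task: on each trial a monkey face gazes left or right while two objects
of unequal reward probability flank it.  Cue reliabilities differ by block —
Face 90/60, Object 60/90, Mixed 90/90 — so on "incongruent" trials (gaze away
from the better object) the subject must arbitrate between the two sources.
This module generates reproducible schedules with that reliability structure,
simulates reliability-weighting agents (optionally perturbed to emulate
focal neural disruption), and builds the balanced 2x2 repetition schedules
used for the face direction/identity adaptation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from ._rng import derived_rng

Side = Literal["left", "right"]
Condition = Literal["Face", "Object", "Mixed"]
TusSite = Literal["sham", "dmFPC", "mSTS", "EVC"]

CONDITIONS: tuple[Condition, ...] = ("Face", "Object", "Mixed")
TUS_SITES: tuple[TusSite, ...] = ("sham", "dmFPC", "mSTS", "EVC")
SIDES: tuple[Side, ...] = ("left", "right")

#: nominal (face, object) cue reliabilities per block
CONDITION_RELIABILITIES: dict[str, tuple[float, float]] = {
    "Face": (0.9, 0.6),
    "Object": (0.6, 0.9),
    "Mixed": (0.9, 0.9),
}

#: which cue is the high-reliability one in each block (Mixed: both)
RELIABLE_CUE: dict[str, str] = {"Face": "face", "Object": "object", "Mixed": "both"}


class ParameterError(ValueError):
    """Invalid argument to a schedule or agent constructor."""


class StateError(RuntimeError):
    """Operation applied to a record whose required fields are unset."""


def _side_sign(side: str) -> int:
    # left -> -1, right -> +1
    if side == "left":
        return -1
    if side == "right":
        return 1
    raise StateError(f"side field not set (got {side!r})")


def _sign_side(x: float) -> Side:
    return "right" if x > 0 else "left"


@dataclass
class TrialRecord:
    """A single two-alternative trial with its event timing.

    ``choice``/``accuracy``/``rt`` are None until an agent (or a real
    subject's data file) fills them in.
    """

    session_id: str
    condition: str
    trial_index: int
    face_direction: Side
    better_object_side: Side
    rewarded_side: Side
    congruent: bool
    onset_decision: float
    onset_outcome: float
    choice: str | None = None  # "left" | "right" | "none"
    accuracy: int | None = None
    rt: float | None = None
    valid: bool = True
    tus_site: str = "sham"
    extras: dict = field(default_factory=dict)  # unknown file columns, preserved

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.tus_site not in TUS_SITES:
            raise ParameterError(f"unknown TUS site {self.tus_site!r}")
        if not (self.onset_outcome > self.onset_decision >= 0):
            raise ParameterError(
                f"need onset_outcome > onset_decision >= 0, got "
                f"({self.onset_decision}, {self.onset_outcome})"
            )


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the synthetic choice policy.

    Two parameterizations are supported:

    * logistic policy (default): P(right) = sigmoid(w_face*f + w_object*o +
      side_bias) with cues coded -1/+1, overridden by a uniform lapse;
    * mixture policy (``follow_face_prob`` set): follow the face cue with
      that probability, otherwise follow the better object.
    """

    w_face: float = 0.0
    w_object: float = 0.0
    side_bias: float = 0.0
    lapse: float = 0.0
    follow_face_prob: float | None = None
    rt_mean: float = 1.0
    rt_sd: float = 0.3
    p_no_response: float = 0.05
    p_slow: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ParameterError(f"lapse must be in [0,1], got {self.lapse}")
        for name in ("p_no_response", "p_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if self.follow_face_prob is not None and not 0.0 <= self.follow_face_prob <= 1.0:
            raise ParameterError(f"follow_face_prob must be in [0,1], got {self.follow_face_prob}")
        if self.rt_sd < 0:
            raise ParameterError(f"rt_sd must be >= 0, got {self.rt_sd}")


@dataclass
class Exp1Trial:
    """One trial of the repetition-suppression experiment.

    A first face (neutral or directed) is followed by a directed second face;
    when the first face is directed the second always repeats its direction,
    so direction novelty is confounded-free only through the neutral trials.
    """

    first_face: str  # neutral | left | right
    first_identity: str
    second_face: Side
    second_identity: str
    direction_repeat: bool
    identity_repeat: bool
    correct: bool = True
    # timing fields used by design-matrix construction
    onset_first: float = 0.0
    onset_decision: float = 0.0
    onset_outcome: float = 0.0
    rt: float = 0.5
    response: Side = "left"
    rewarded: bool = True
    valid: bool = True

    def __post_init__(self) -> None:
        if self.first_face in SIDES:
            if self.second_face != self.first_face or not self.direction_repeat:
                raise ParameterError("directed first face must repeat its direction")
        elif self.first_face == "neutral":
            if self.direction_repeat:
                raise ParameterError("direction_repeat requires a directed first face")
        else:
            raise ParameterError(f"unknown first_face {self.first_face!r}")


# ---------------------------------------------------------------------------
# schedule generation


def label_congruency(trial: TrialRecord) -> bool:
    """True iff the face gazes toward the better of the two objects.

    Deterministic in (face_direction, better_object_side) and invariant to a
    global left/right mirror of both fields.
    """
    if trial.face_direction not in SIDES or trial.better_object_side not in SIDES:
        raise StateError("face_direction and better_object_side must be set")
    return trial.face_direction == trial.better_object_side


@dataclass(frozen=True)
class ScheduleTiming:
    """Event-timing configuration (uniform ranges, seconds)."""

    iti: tuple[float, float] = (3.0, 4.0)
    outcome_delay: tuple[float, float] = (3.0, 5.0)
    decision_window: float = 10.0
    start: float = 10.0


def make_session_schedule(
    condition: str,
    n_trials: int,
    reliabilities: tuple[float, float] | None = None,
    seed: int = 0,
    session_id: str | None = None,
    timing: ScheduleTiming | None = None,
    tus_site: str = "sham",
) -> list[TrialRecord]:
    """Generate one block of trials with the given cue reliabilities.

    Per trial, independently: the better object's side is uniform; the
    rewarded side equals it with probability ``p_object``; the face gazes at
    the rewarded side with probability ``p_face``.  Onsets advance with the
    configured inter-trial interval and decision-to-outcome delay.
    """
    if n_trials < 1:
        raise ParameterError(f"n_trials must be >= 1, got {n_trials}")
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}")
    if reliabilities is None:
        reliabilities = CONDITION_RELIABILITIES[condition]
    p_face, p_object = reliabilities
    for name, p in (("p_face", p_face), ("p_object", p_object)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} must be a probability, got {p}")
    timing = timing or ScheduleTiming()
    session_id = session_id or f"{condition}-s{seed}"
    rng = derived_rng(seed, "schedule", session_id)

    trials: list[TrialRecord] = []
    t = timing.start
    for i in range(n_trials):
        better = SIDES[rng.integers(2)]
        rewarded = better if rng.random() < p_object else _other(better)
        face = rewarded if rng.random() < p_face else _other(rewarded)
        onset_decision = t
        onset_outcome = onset_decision + rng.uniform(*timing.outcome_delay)
        rec = TrialRecord(
            session_id=session_id,
            condition=condition,
            trial_index=i,
            face_direction=face,
            better_object_side=better,
            rewarded_side=rewarded,
            congruent=face == better,
            onset_decision=onset_decision,
            onset_outcome=onset_outcome,
            tus_site=tus_site,
        )
        rec.congruent = label_congruency(rec)
        trials.append(rec)
        t = onset_outcome + rng.uniform(*timing.iti)
    return trials


def _other(side: Side) -> Side:
    return "left" if side == "right" else "right"


# ---------------------------------------------------------------------------
# choice agents


def reliable_side(trial: TrialRecord) -> str | None:
    """Side indicated by the block's high-reliability source.

    Face block: gaze direction; Object block: better object.  Mixed block:
    both sources are reliable — the common side on congruent trials, and
    None on incongruent trials (either choice defensible; accuracy is
    scored 1 there under the reliable-cue convention).
    """
    cue = RELIABLE_CUE[trial.condition]
    if cue == "face":
        return trial.face_direction
    if cue == "object":
        return trial.better_object_side
    return trial.face_direction if trial.congruent else None


def score_accuracy(trial: TrialRecord, convention: str = "reliable_cue") -> int | None:
    """Accuracy of a completed trial.

    ``reliable_cue`` (default): 1 iff the choice matches the side the
    block's high-reliability source indicates (deterministic given the
    schedule).  ``reward``: 1 iff the chosen side was rewarded.
    """
    if trial.choice in (None, "none"):
        return None
    if convention == "reward":
        return int(trial.choice == trial.rewarded_side)
    if convention == "reliable_cue":
        target = reliable_side(trial)
        return 1 if target is None else int(trial.choice == target)
    raise ParameterError(f"unknown accuracy convention {convention!r}")


def simulate_agent_choices(
    schedule: Sequence[TrialRecord],
    params: AgentParams,
    seed: int = 0,
    accuracy_convention: str = "reliable_cue",
) -> list[TrialRecord]:
    """Complete a schedule with choices, RTs and accuracies from the policy.

    Returns new records; the input schedule is untouched.  Cues are coded
    -1/+1 (left/right); the logistic policy chooses right with probability
    sigmoid(w_face*face + w_object*object + side_bias), a lapse draws the
    side uniformly, and RTs come from a normal truncated at 0.1 s.  A
    fraction of trials is missed (no response) or answered slowly enough to
    be invalid (> 10 s), as real sessions are.
    """
    if len(schedule) == 0:
        raise ParameterError("schedule is empty")
    rng = derived_rng(seed, "agent", schedule[0].session_id)
    out: list[TrialRecord] = []
    for trial in schedule:
        u_miss = rng.random()
        if u_miss < params.p_no_response:
            done = replace(trial, choice="none", rt=None, valid=False)
            done.accuracy = None
            out.append(done)
            continue
        slow = u_miss < params.p_no_response + params.p_slow
        if params.follow_face_prob is not None:
            followed = (
                trial.face_direction
                if rng.random() < params.follow_face_prob
                else trial.better_object_side
            )
            choice = followed
        else:
            f = _side_sign(trial.face_direction)
            o = _side_sign(trial.better_object_side)
            u = params.w_face * f + params.w_object * o + params.side_bias
            p_right = 1.0 / (1.0 + np.exp(-u))
            choice = "right" if rng.random() < p_right else "left"
        if params.lapse > 0 and rng.random() < params.lapse:
            choice = SIDES[rng.integers(2)]
        if slow:
            rt = rng.uniform(10.5, 12.0)  # beyond the 10 s validity limit
        else:
            rt = max(0.1, rng.normal(params.rt_mean, params.rt_sd))
        done = replace(trial, choice=choice, rt=float(rt), valid=not slow)
        done.accuracy = score_accuracy(done, accuracy_convention)
        out.append(done)
    return out


#: default multiplicative down-weighting applied by active stimulation
DEFAULT_TUS_FACTOR = 0.5


def apply_tus_perturbation(
    params: AgentParams,
    site: str,
    reliable_cue: str = "face",
    factor: float = DEFAULT_TUS_FACTOR,
) -> AgentParams:
    """Emulate focal disruption as a down-weighting of cue weights.

    sham: identity.  mSTS: scales ``w_face`` only (social information
    uniformly down-weighted).  EVC: scales ``w_object`` only.  dmFPC: scales
    the weight of whichever cue is reliable in the current block
    (``reliable_cue``), so performance suffers in both Face and Object
    blocks.  For mixture agents the follow-probability is shrunk toward 0.5
    by the same factor.
    """
    if site not in TUS_SITES:
        raise ParameterError(f"unknown TUS site {site!r}")
    if reliable_cue not in ("face", "object"):
        raise ParameterError(f"reliable_cue must be 'face' or 'object', got {reliable_cue!r}")
    if site == "sham":
        return params
    target = {"mSTS": "face", "EVC": "object", "dmFPC": reliable_cue}[site]
    if params.follow_face_prob is not None:
        # one degree of freedom: shrinking either cue's follow-probability
        # toward chance reduces to the same contraction of q toward 0.5
        q = 0.5 + (params.follow_face_prob - 0.5) * factor
        return replace(params, follow_face_prob=float(np.clip(q, 0.0, 1.0)))
    if target == "face":
        return replace(params, w_face=params.w_face * factor)
    return replace(params, w_object=params.w_object * factor)


# ---------------------------------------------------------------------------
# repetition-suppression schedules


@dataclass(frozen=True)
class Exp1Timing:
    first_face_duration: float = 0.5
    blank: float = 0.5
    iti: tuple[float, float] = (3.0, 4.0)
    outcome_delay: float = 0.3
    start: float = 10.0


def make_exp1_schedule(
    n_trials: int,
    n_identities: int = 5,
    seed: int = 0,
    timing: Exp1Timing | None = None,
    p_invalid: float = 0.05,
    p_error: float = 0.1,
) -> list[Exp1Trial]:
    """Balanced 2 (direction repeat) x 2 (identity repeat) schedule.

    Directed first faces are always repeated in direction; neutral first
    faces are followed by left/right second faces in balance, so the
    direction-novelty contrast is carried by the neutral-first trials.  A
    ``p_invalid`` fraction of trials is marked invalid (slow responses),
    as in real sessions.
    """
    if n_trials % 4 != 0:
        raise ParameterError(f"n_trials must be divisible by 4, got {n_trials}")
    if n_identities < 2:
        raise ParameterError(f"need at least 2 identities, got {n_identities}")
    timing = timing or Exp1Timing()
    rng = derived_rng(seed, "exp1")
    cells = [(dr, ir) for dr in (True, False) for ir in (True, False)]
    per_cell = n_trials // 4
    plan: list[tuple[bool, bool]] = [c for c in cells for _ in range(per_cell)]
    rng.shuffle(plan)  # type: ignore[arg-type]
    identities = [f"face{i}" for i in range(n_identities)]

    trials: list[Exp1Trial] = []
    t = timing.start
    # alternate second-face direction among the two cell types to keep
    # left/right in balance within direction_repeat strata
    side_counter = {True: 0, False: 0}
    for dr, ir in plan:
        second = SIDES[side_counter[dr] % 2]
        side_counter[dr] += 1
        first_id = identities[rng.integers(n_identities)]
        if ir:
            second_id = first_id
        else:
            second_id = identities[(identities.index(first_id) + 1 + rng.integers(n_identities - 1)) % n_identities]
        first = second if dr else "neutral"
        onset_first = t
        onset_second = onset_first + timing.first_face_duration + timing.blank
        invalid = rng.random() < p_invalid
        error = not invalid and rng.random() < p_error
        rt = float(rng.uniform(1.6, 2.9)) if invalid else float(max(0.15, rng.normal(0.6, 0.15)))
        onset_decision = onset_second
        onset_outcome = onset_decision + rt + timing.outcome_delay
        trials.append(
            Exp1Trial(
                first_face=first,
                first_identity=first_id,
                second_face=second,
                second_identity=second_id,
                direction_repeat=dr,
                identity_repeat=first_id == second_id,
                onset_first=onset_first,
                onset_decision=onset_decision,
                onset_outcome=onset_outcome,
                rt=rt,
                response=_other(second) if error else second,
                correct=not error,
                rewarded=not invalid and not error,
                valid=not invalid,
            )
        )
        t = onset_outcome + rng.uniform(*timing.iti)
    return trials


def realized_reliabilities(trials: Iterable[TrialRecord]) -> tuple[float, float]:
    """Empirical (face, object) reliabilities of a schedule."""
    trials = list(trials)
    face = np.mean([t.face_direction == t.rewarded_side for t in trials])
    obj = np.mean([t.better_object_side == t.rewarded_side for t in trials])
    return float(face), float(obj)
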
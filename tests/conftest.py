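"""Shared fixtures: synthetic sessions at small, fast sizes."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from socialcue.task import (
    AgentParams,
    TrialRecord,
    make_session_schedule,
    score_accuracy,
    simulate_agent_choices,
)


def simulate_linear_choice_sessions(
    n_sessions: int,
    n_trials: int,
    beta_face: float,
    beta_object: float,
    sd_face: float = 0.0,
    sd_object: float = 0.0,
    sd_intercept: float = 0.0,
    condition: str = "Face",
    seed: int = 0,
    session_prefix: str = "S",
    tus_site: str = "sham",
) -> list[TrialRecord]:
    """Sessions whose choices follow the linear-probability model exactly.

    P(right) = 0.5 + 0.5 (b0_s + bf_s * face + bo_s * object) with cues
    coded -1/+1, so the generative coefficients are exactly the linear-link
    regression slopes — the analytic oracle for recovery tests.
    """
    rng = np.random.default_rng(seed)
    out: list[TrialRecord] = []
    for s in range(n_sessions):
        bf = beta_face + rng.normal(0, sd_face) if sd_face else beta_face
        bo = beta_object + rng.normal(0, sd_object) if sd_object else beta_object
        b0 = rng.normal(0, sd_intercept) if sd_intercept else 0.0
        sched = make_session_schedule(
            condition, n_trials, seed=seed + 1000 + s,
            session_id=f"{session_prefix}{s:02d}", tus_site=tus_site,
        )
        for t in sched:
            f = 1 if t.face_direction == "right" else -1
            o = 1 if t.better_object_side == "right" else -1
            p_right = np.clip(0.5 + 0.5 * (b0 + bf * f + bo * o), 0.0, 1.0)
            choice = "right" if rng.random() < p_right else "left"
            done = replace(t, choice=choice, rt=float(max(0.1, rng.normal(1.0, 0.3))))
            done.accuracy = score_accuracy(done)
            out.append(done)
    return out


@pytest.fixture
def face_sessions() -> list[TrialRecord]:
    """Ten deterministic Face-block sessions from a reliability-weighting agent."""
    trials = []
    for s in range(10):
        sched = make_session_schedule("Face", 50, seed=300 + s, session_id=f"F{s:02d}")
        trials += simulate_agent_choices(
            sched, AgentParams(w_face=2.0, w_object=0.5), seed=400 + s
        )
    return trials
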
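"""File formats: event TSVs, ROI series matrices, configs and manifests.

Trial tables are tab-separated files in a BIDS-events-style dialect: the
mandatory header carries ``onset``, ``duration`` and ``trial_type`` plus
one column per trial field; one file per session; UTF-8.  ROI series are
delimited numeric matrices (time x [signal, confound_1..k]) with a JSON
sidecar holding the sampling interval, ROI label and any ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bold import GroundTruthEffects, ROITimeSeries
from .task import CONDITIONS, SIDES, TUS_SITES, ParameterError, TrialRecord


class ParseError(ValueError):
    """Malformed events file; the message names the offending row."""


EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "session_id",
    "condition",
    "trial_index",
    "face_direction",
    "better_object_side",
    "rewarded_side",
    "congruent",
    "choice",
    "accuracy",
    "rt",
    "onset_decision",
    "onset_outcome",
    "valid",
    "tus_site",
]

#: accepted aliases for deposited-data style column names
COLUMN_ALIASES = {
    "session": "session_id",
    "block": "condition",
    "trial": "trial_index",
    "facedirection": "face_direction",
    "objectdirection": "better_object_side",
    "response": "choice",
    "correct": "accuracy",
    "reaction_time": "rt",
    "site": "tus_site",
}


def write_events(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """One session (or several) of trials as a BIDS-events-style TSV."""
    extra_cols: list[str] = []
    for t in trials:
        for k in t.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    rows = []
    for t in trials:
        rows.append(
            dict(
                {k: t.extras.get(k, "n/a") for k in extra_cols},
                onset=t.onset_decision,
                duration=max(t.onset_outcome - t.onset_decision, 0.0),
                trial_type=t.condition,
                session_id=t.session_id,
                condition=t.condition,
                trial_index=t.trial_index,
                face_direction=t.face_direction,
                better_object_side=t.better_object_side,
                rewarded_side=t.rewarded_side,
                congruent=int(t.congruent),
                choice=t.choice if t.choice is not None else "n/a",
                accuracy=t.accuracy if t.accuracy is not None else "n/a",
                rt=t.rt if t.rt is not None else "n/a",
                onset_decision=t.onset_decision,
                onset_outcome=t.onset_outcome,
                valid=int(t.valid),
                tus_site=t.tus_site,
            )
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS + extra_cols).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def _opt_float(v, row: int, name: str) -> float | None:
    if v in ("n/a", "", None) or (isinstance(v, float) and np.isnan(v)):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: cannot parse {name}={v!r}")


def read_events(path: str | Path, alias_map: dict[str, str] | None = None) -> list[TrialRecord]:
    """Parse a trial-table TSV into records, validating every row.

    ``alias_map`` extends the built-in column aliases, so deposited-data
    style layouts can be read without renaming files by hand.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    aliases = dict(COLUMN_ALIASES)
    if alias_map:
        aliases.update(alias_map)
    df = df.rename(columns={c: aliases.get(c, c) for c in df.columns})
    required = {"onset", "session_id", "condition", "face_direction", "better_object_side", "rewarded_side"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"malformed header: missing columns {sorted(missing)}")

    trials: list[TrialRecord] = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # header is line 1
        onset = _opt_float(rec.get("onset_decision", rec["onset"]), i, "onset")
        if onset is None or onset < 0:
            raise ParseError(f"row {i}: onset must be a non-negative number, got {rec['onset']!r}")
        outcome = _opt_float(rec.get("onset_outcome", ""), i, "onset_outcome")
        if outcome is None:
            outcome = onset + float(rec.get("duration", 1.0) or 1.0)
        for col, allowed in (
            ("condition", CONDITIONS),
            ("face_direction", SIDES),
            ("better_object_side", SIDES),
            ("rewarded_side", SIDES),
            ("tus_site", TUS_SITES),
        ):
            v = rec.get(col, "sham" if col == "tus_site" else None)
            if v not in allowed and not (col == "tus_site" and v in ("", None)):
                raise ParseError(f"row {i}: unknown {col} value {v!r}")
        choice = rec.get("choice", "n/a")
        if choice not in (*SIDES, "none", "n/a", ""):
            raise ParseError(f"row {i}: unknown choice value {choice!r}")
        acc = _opt_float(rec.get("accuracy", "n/a"), i, "accuracy")
        congruent = rec.get("congruent", "")
        extras = {k: v for k, v in rec.items() if k not in EVENT_COLUMNS}
        trial = TrialRecord(
            session_id=rec["session_id"],
            condition=rec["condition"],
            trial_index=int(float(rec.get("trial_index", len(trials)) or len(trials))),
            face_direction=rec["face_direction"],
            better_object_side=rec["better_object_side"],
            rewarded_side=rec["rewarded_side"],
            congruent=bool(int(float(congruent))) if congruent not in ("", "n/a") else rec["face_direction"] == rec["better_object_side"],
            onset_decision=onset,
            onset_outcome=outcome,
            choice=None if choice in ("n/a", "") else choice,
            accuracy=None if acc is None else int(acc),
            rt=_opt_float(rec.get("rt", "n/a"), i, "rt"),
            valid=bool(int(float(rec.get("valid", 1) or 1))),
            tus_site=rec.get("tus_site") or "sham",
            extras=extras,
        )
        trials.append(trial)
    return trials


# ---------------------------------------------------------------------------
# series I/O


def write_series(series: ROITimeSeries, path: str | Path, ground_truth: GroundTruthEffects | None = None) -> None:
    """Delimited matrix time x [signal, confounds] plus a JSON sidecar."""
    path = Path(path)
    mat = np.column_stack([series.values, series.confounds])
    header = "\t".join(["signal"] + [f"confound_{k + 1}" for k in range(series.confounds.shape[1])])
    np.savetxt(path, mat, delimiter="\t", header=header, comments="")
    sidecar = {
        "tr": series.tr,
        "roi_label": series.roi_label,
        "session_id": series.session_id,
        "ground_truth": asdict(ground_truth) if ground_truth is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_series(path: str | Path) -> tuple[ROITimeSeries, dict]:
    path = Path(path)
    mat = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    series = ROITimeSeries(
        values=mat[:, 0],
        tr=float(sidecar["tr"]),
        roi_label=sidecar["roi_label"],
        confounds=mat[:, 1:],
        session_id=sidecar["session_id"],
    )
    return series, sidecar


# ---------------------------------------------------------------------------
# results tables and manifests


def results_table(results: dict[str, "object"], path: str | Path | None = None) -> pd.DataFrame:
    """Fixed-effect table (one row per model x term) from fit results."""
    rows = []
    for label, res in results.items():
        for term, fe in res.fixed_effects.items():
            rows.append(
                dict(
                    model=res.model,
                    condition=label,
                    term=term,
                    estimate=fe.estimate,
                    ci_low=fe.estimate - fe.ci95_halfwidth,
                    ci_high=fe.estimate + fe.ci95_halfwidth,
                    F=fe.f_stat,
                    df1=fe.df[0],
                    df2=fe.df[1],
                    p=fe.p,
                    fell_back_to_fixed=res.fell_back_to_fixed,
                )
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunConfig:
    """Run-level configuration; all randomness derives from ``seed``."""

    seed: int = 0
    out_dir: str = "socialcue_run"
    n_sessions: int = 4
    n_trials: int = 50
    conditions: tuple[str, ...] = ("Face", "Object")
    reliabilities: dict = field(default_factory=lambda: {
        "Face": (0.9, 0.6), "Object": (0.6, 0.9), "Mixed": (0.9, 0.9)
    })
    agent: dict = field(default_factory=lambda: {"w_face": 2.0, "w_object": 1.0})
    tus_site: str = "sham"
    tus_factor: float = 0.5
    tr: float = 1.48
    n_perm: int = 1000
    window: float = 3.0
    highpass_cutoff: float = 100.0
    accuracy_convention: str = "reliable_cue"
    invalid_rt_threshold: dict = field(default_factory=lambda: {"default": 1.5, "T": 2.5})

    def __post_init__(self) -> None:
        for cond, (pf, po) in self.reliabilities.items():
            if not (0 <= pf <= 1 and 0 <= po <= 1):
                raise ParameterError(f"reliabilities for {cond} must be probabilities")
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.n_perm < 100:
            raise ParameterError("n_perm must be >= 100")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["reliabilities"] = {k: tuple(v) for k, v in data.get("reliabilities", {}).items()} or None
        data = {k: v for k, v in data.items() if v is not None}
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))
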
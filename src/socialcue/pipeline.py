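"""End-to-end pipeline: simulate -> behavior -> glm -> timecourse -> report.

Each stage reads only files written by earlier stages (or supplied by the
user), writes its outputs under the run directory, and appends a manifest
entry with the seed, parameter digest and SHA-256 of every file it wrote,
so a run can be reproduced bit-identically from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior, design, timecourse
from .bold import GroundTruthEffects, simulate_roi_bold
from .io import RunConfig, file_sha256, read_events, read_series, results_table, write_events, write_series
from .task import (
    AgentParams,
    ParameterError,
    RELIABLE_CUE,
    apply_tus_perturbation,
    make_session_schedule,
    simulate_agent_choices,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "behavior", "glm", "timecourse", "report")


class StageError(RuntimeError):
    """A stage is missing its upstream outputs."""


def _digest(obj) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_digest": _digest(asdict(config)), "stages": {}}

    for stage in stages:
        written = _STAGE_FUNCS[stage](config, out)
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(out)): file_sha256(p) for p in written},
            "params": _digest({"stage": stage, "seed": config.seed}),
        }
        logger.info("stage %s: wrote %d files", stage, len(written))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _events_paths(out: Path) -> list[Path]:
    return sorted(out.glob("events_*.tsv"))


def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    written = []
    base = AgentParams(**config.agent)
    for cond in config.conditions:
        params = apply_tus_perturbation(
            base, config.tus_site, reliable_cue=RELIABLE_CUE.get(cond, "face"), factor=config.tus_factor
        ) if config.tus_site != "sham" else base
        for s in range(config.n_sessions):
            sid = f"{cond}-{config.tus_site}-{s:02d}"
            schedule = make_session_schedule(
                cond,
                config.n_trials,
                config.reliabilities[cond],
                seed=config.seed,
                session_id=sid,
                tus_site=config.tus_site,
            )
            trials = simulate_agent_choices(
                schedule, params, seed=config.seed, accuracy_convention=config.accuracy_convention
            )
            p = out / f"events_{sid}.tsv"
            write_events(trials, p)
            written.append(p)

            effects = GroundTruthEffects(
                amp_congruent=0.2,
                amp_incongruent=0.6 if cond == "Face" else -0.2,
                noise_sd=0.5,
            )
            series = simulate_roi_bold(trials, effects, roi="dmFPC", seed=config.seed, tr=config.tr)
            sp = out / f"bold_{sid}_dmFPC.tsv"
            write_series(series, sp, effects)
            written += [sp, sp.with_suffix(".json")]
    return written


def _stage_behavior(config: RunConfig, out: Path) -> list[Path]:
    paths = _events_paths(out)
    if not paths:
        raise StageError("behavior stage needs events_*.tsv from the simulate stage")
    trials = [t for p in paths for t in read_events(p)]
    results = {}
    for cond in config.conditions:
        sub = [t for t in trials if t.condition == cond]
        if not sub:
            continue
        results[cond] = behavior.check_model_diagnostics(behavior.fit_choice_model(sub, cond))
        try:
            results[f"{cond}-accuracy"] = behavior.fit_accuracy_congruency_model(sub)
        except ParameterError:
            pass
    table_path = out / "behavior_results.tsv"
    results_table(results, table_path)
    meta = {
        name: {"loglik": r.loglik, "converged": r.converged, "fell_back_to_fixed": r.fell_back_to_fixed, "ks_p": r.ks_p}
        for name, r in results.items()
    }
    meta_path = out / "behavior_results_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return [table_path, meta_path]


def _stage_glm(config: RunConfig, out: Path) -> list[Path]:
    bold_paths = sorted(out.glob("bold_*.tsv"))
    if not bold_paths:
        raise StageError("glm stage needs bold_*.tsv from the simulate stage")
    fits = []
    for bp in bold_paths:
        series, _ = read_series(bp)
        trials = read_events(out / f"events_{series.session_id}.tsv")
        dm = design.build_design(trials, "GLM3", confounds=series.confounds, tr=series.tr, n_timepoints=series.n)
        dm = design.highpass_design(dm, config.highpass_cutoff)
        y = design.highpass_filter(series.values, series.tr, config.highpass_cutoff)
        fits.append(design.fit_glm(y, dm))
    rows = [{"session": bp.stem, **dict(zip(f.column_names, f.betas))} for bp, f in zip(bold_paths, fits)]
    betas_path = out / "glm_betas.tsv"
    pd.DataFrame(rows).to_csv(betas_path, sep="\t", index=False)
    common = set(fits[0].column_names)
    for f in fits[1:]:
        common &= set(f.column_names)
    report = {}
    if {"face", "object"} <= common and len(fits) >= 3:
        g = design.contrast_group(fits, {"face": 1.0, "object": -1.0})
        report["face_minus_object"] = {"estimate": g.estimate, "t": g.t, "p": g.p, "n_sessions": g.n_sessions}
    contrast_path = out / "glm_group_contrast.json"
    contrast_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return [betas_path, contrast_path]


def _stage_timecourse(config: RunConfig, out: Path) -> list[Path]:
    bold_paths = sorted(out.glob("bold_*.tsv"))
    if not bold_paths:
        raise StageError("timecourse stage needs bold_*.tsv from the simulate stage")
    sessions = []
    for bp in bold_paths:
        series, _ = read_series(bp)
        trials = read_events(out / f"events_{series.session_id}.tsv")
        up = timecourse.preprocess_timecourse(series)
        epochs, kept = timecourse.extract_epochs(up, [t.onset_decision for t in trials])
        labels = np.array([0 if t.congruent else 1 for t in trials], dtype=float)[kept]
        rts = np.array([t.rt if t.rt is not None else 0.0 for t in trials])[kept]
        rts = (rts - rts.mean()) / rts.std() if rts.std() > 0 else rts * 0
        sessions.append(timecourse.SessionEpochData(epochs, labels, rt=rts, session_id=series.session_id))
    res = timecourse.permutation_inference(
        sessions, n_perm=config.n_perm, window=config.window, seed=config.seed
    )
    sem = np.std([timecourse._session_beta(s, s.labels, "activity") for s in sessions], axis=0, ddof=1) / np.sqrt(len(sessions))
    df = pd.DataFrame(
        {
            "time": res.time_axis,
            "mean_beta": res.observed,
            "sem": sem,
            "p_raw": res.p_raw,
            "p_fdr": res.p_fdr,
        }
    )
    tc_path = out / "timecourse_dmFPC.tsv"
    df.to_csv(tc_path, sep="\t", index=False)
    man_path = out / "timecourse_manifest.json"
    man_path.write_text(
        json.dumps({"seed": config.seed, "n_perm": config.n_perm, "window": config.window}, indent=2)
    )
    return [tc_path, man_path]


def _stage_report(config: RunConfig, out: Path) -> list[Path]:
    behav = out / "behavior_results.tsv"
    if not behav.exists():
        raise StageError("report stage needs behavior_results.tsv from the behavior stage")
    df = pd.read_csv(behav, sep="\t")
    choice = df[(df.model == "choice") & df.term.isin(["face", "object"])]
    pivot = choice.pivot_table(index="term", columns="condition", values="estimate")
    report_path = out / "report_coefficients.tsv"
    pivot.to_csv(report_path, sep="\t")
    return [report_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "behavior": _stage_behavior,
    "glm": _stage_glm,
    "timecourse": _stage_timecourse,
    "report": _stage_report,
}
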
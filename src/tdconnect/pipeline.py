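"""Estimation-side orchestration: behavior fits -> GLM -> DCM -> prediction.

Every function here consumes only the observable side of a cohort
(trial events and BOLD series); ground truth is never read.  The stages
mirror the analysis order: fit discounting per subject, build and fit
the value GLMs, invert the two-region DCM per subject and run, compare
driving-input families, and assemble the feature table for the
out-of-sample prediction of discount rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tdconnect import dcm_engine, glm_first_level as glm, offers_behavior as ob
from tdconnect.dcm_engine import DCMPosterior, DCMSpec, full_model_spec
from tdconnect.model_space import FAMILY_DRIVES
from tdconnect.synthetic_cohort import Cohort


def fit_cohort_behavior(cohort: Cohort) -> list[ob.SubjectBehavior]:
    """Fit (k, b) and assign the wait/now group for every subject."""
    out = []
    for s in cohort.subjects:
        trials = s.behavior.trials
        fit = ob.fit_discounting(trials)
        out.append(ob.SubjectBehavior(
            trials=trials, fit=fit, group=ob.assign_group(trials),
            subject_id=s.behavior.subject_id,
        ))
    return out


def _run_inputs(behavior: ob.SubjectBehavior, run: int, cohort: Cohort,
                dt: float) -> np.ndarray:
    cfg = cohort.config
    run_trials = [t for t in behavior.trials if t.run_index == run]
    rdsv = ob.rdsv_series(run_trials, behavior.fit, behavior.group)
    return dcm_engine.build_input_streams(run_trials, cfg.run_duration_s, rdsv, dt=dt)


def invert_cohort(cohort: Cohort, spec: DCMSpec | None = None, *,
                  behaviors: list[ob.SubjectBehavior] | None = None,
                  bold_override: np.ndarray | None = None,
                  runs: tuple[int, ...] | None = None,
                  fast: bool = True) -> list[list[DCMPosterior]]:
    """Invert one DCM specification for every subject and run.

    ``fast`` caps the Gauss-Newton iterations and uses a 0.25 s
    integration step for the model prediction (the generator's finer
    grid is only needed when simulating, not when inverting);
    ``bold_override`` (subjects, runs, volumes, 2) substitutes the
    observed series, e.g. for the region-swap specificity harness.
    """
    spec = spec or full_model_spec(family=1)
    behaviors = behaviors or fit_cohort_behavior(cohort)
    cfg = cohort.config
    runs = runs or tuple(range(1, cfg.runs_per_subject + 1))
    max_iter = 12 if fast else 24
    dt = 0.25 if fast else cfg.microtime_dt
    out = []
    for i, (s, beh) in enumerate(zip(cohort.subjects, behaviors)):
        posts = []
        for run in runs:
            u = _run_inputs(beh, run, cohort, dt)
            y = (bold_override[i, run - 1] if bold_override is not None
                 else s.bold[run - 1])
            posts.append(dcm_engine.invert(
                y, spec, u, dt=dt, tr=cfg.tr_seconds, max_iter=max_iter,
            ))
        out.append(posts)
    return out


def extract_features(cohort: Cohort, *, bold_override: np.ndarray | None = None,
                     runs: tuple[int, ...] | None = None,
                     fast: bool = True) -> pd.DataFrame:
    """Fit behavior, invert the full model, and build the feature table."""
    from tdconnect.prediction import feature_table

    behaviors = fit_cohort_behavior(cohort)
    posts = invert_cohort(cohort, behaviors=behaviors,
                          bold_override=bold_override, runs=runs, fast=fast)
    log_k = np.log([b.fit.k for b in behaviors])
    return feature_table(posts, log_k)


def family_evidence(cohort: Cohort, *, runs: tuple[int, ...] = (1,),
                    fast: bool = True) -> np.ndarray:
    """Per-subject free energy for the four families' full models.

    Returns an (n_subjects, 4) matrix of free energies summed over the
    requested runs, columns ordered family 1..4.
    """
    behaviors = fit_cohort_behavior(cohort)
    evid = np.zeros((len(cohort.subjects), len(FAMILY_DRIVES)))
    for col, family in enumerate(sorted(FAMILY_DRIVES)):
        spec = full_model_spec(family=family)
        posts = invert_cohort(cohort, spec, behaviors=behaviors, runs=runs, fast=fast)
        evid[:, col] = [sum(p.free_energy for p in subject) for subject in posts]
    return evid


def glm_stage(cohort: Cohort, *, behaviors: list[ob.SubjectBehavior] | None = None,
              modulator: str = "rdsv") -> dict:
    """First-level GLMs for both regions plus group-level summaries.

    Builds the per-run designs with the chosen value modulator (``dsv``
    or ``rdsv``), concatenates runs, fits each region's series with
    AR(1) correction, and returns per-subject contrasts, group t-tests,
    and the full-versus-reduced value-model comparison on the vmPFC
    series.
    """
    behaviors = behaviors or fit_cohort_behavior(cohort)
    cfg = cohort.config
    results = {"subjects": [], "modulator": modulator}
    v_series, v_designs = [], []
    for s, beh in zip(cohort.subjects, behaviors):
        designs = []
        for run in range(1, cfg.runs_per_subject + 1):
            run_trials = [t for t in beh.trials if t.run_index == run]
            if modulator == "rdsv":
                vals = ob.rdsv_series(run_trials, beh.fit, beh.group)
            else:
                vals = ob.dsv_series(run_trials, beh.fit)
            try:
                d = glm.build_design(run_trials, vals, cfg.volumes_per_run,
                                     cfg.tr_seconds, dt=cfg.microtime_dt)
            except glm.DesignError:
                # one-sided choosers have a constant Accept modulator;
                # they contribute no Accept contrast
                d = glm.build_design(run_trials, vals, cfg.volumes_per_run,
                                     cfg.tr_seconds, dt=cfg.microtime_dt,
                                     include_accept=False)
            designs.append(d)
        if not all("accept" in d.attrs["task"] for d in designs):
            designs = [d.drop(columns=["accept"], errors="ignore") for d in designs]
            for d in designs:
                d.attrs["task"] = [c for c in ("condition", "value") if c in d.columns]
                d.attrs["tr"] = cfg.tr_seconds
        design = glm.concat_runs(designs)
        series = {r: np.concatenate([s.bold[run, :, i] for run in range(cfg.runs_per_subject)])
                  for i, r in enumerate(("d", "v"))}
        fits = {r: glm.fit_glm(series[r], design) for r in ("d", "v")}
        results["subjects"].append({r: fits[r].contrasts for r in fits})
        v_series.append(series["v"])
        v_designs.append(design)
    for region in ("d", "v"):
        for contrast in ("value", "accept"):
            vals = np.array([sub[region][contrast]["estimate"]
                             for sub in results["subjects"]
                             if contrast in sub[region]])
            t, p = glm.group_ttest(vals)
            results[f"group_{region}_{contrast}"] = {"t": t, "p": p, "n": len(vals)}
    evidence, bms = glm.compare_full_vs_reduced(v_series, v_designs)
    results["value_model_evidence"] = evidence
    results["value_model_exceedance_full"] = float(bms.exceedance_prob[0])
    return results
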
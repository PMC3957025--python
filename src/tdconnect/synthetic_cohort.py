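"""Synthetic study generator: behavior, ground-truth coupling, and BOLD.

Emulates a cohort of subjects performing the intertemporal choice task
in the scanner: heterogeneous hyperbolic discount rates, softmax
choices, truncated-lognormal reaction times with a wait/now-group by
choice interaction, occasional missed responses, and two-region BOLD
series generated from the bilinear DCM forward model with subject-level
coupling optionally linked to discounting (the planted prediction
effect).

Defaults mirror the study design: 27 subjects, 2 runs, 323 volumes per
run at TR = 2.5 s, 216 trials per subject on the published offer grid.
``log k ~ Normal(-4.5, 1.0)`` (per-day units) spans mostly-wait to
mostly-now behavior on this grid.  Ground truth is stored alongside the
generated data but is never consumed by the estimation code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tdconnect import dcm_engine, offers_behavior as ob
from tdconnect.dcm_engine import DCMSpec, full_model_spec


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 27
    runs_per_subject: int = 2
    volumes_per_run: int = 323
    tr_seconds: float = 2.5
    log_k_mean: float = -4.5
    log_k_sd: float = 1.0
    log_b_mean: float = float(np.log(0.5))
    log_b_sd: float = 0.3
    rt_congruent_mean_s: float = 1.13  # group-consistent choices are faster
    rt_incongruent_mean_s: float = 1.28
    rt_log_sd: float = 0.25
    missed_rate: float = 0.02
    bold_noise_sd: float = 1.0  # marginal sd, percent-signal units
    bold_noise_ar1: float = 0.2
    effect_size: float = 0.15  # Hz of the planted parameter per SD of -log k
    effect_param: str = "later.d_to_v"  # which coupling tracks discounting
    effect_noise_sd: float = 0.05
    # (name, value) pairs overriding the population-mean coupling
    base_dcm_overrides: tuple = ()
    coupling_jitter_sd: float = 0.05  # inter-subject sd on the other couplings
    microtime_dt: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.runs_per_subject, self.volumes_per_run) <= 0:
            raise ValueError("counts must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        # normalize for round-tripping through JSON/YAML
        object.__setattr__(self, "base_dcm_overrides",
                           tuple((str(k), float(v)) for k, v in self.base_dcm_overrides))

    @property
    def run_duration_s(self) -> float:
        return self.volumes_per_run * self.tr_seconds


#: Population-mean generative coupling (family-1 full model), Hz.
BASE_DCM_PARAMS = {
    "fixed.v_to_d": 0.0, "fixed.d_to_v": 0.05,
    "fixed.d_self": 0.0, "fixed.v_self": 0.0,
    "all.v_to_d": 0.0, "all.v_self": 0.1, "all.d_to_v": 0.3, "all.d_self": 0.1,
    "later.v_to_d": 0.0, "later.v_self": 0.0, "later.d_to_v": 0.2, "later.d_self": 0.0,
    "drive.value_to_v": 0.3, "drive.accept_to_d": 0.5,
}


@dataclass
class GroundTruth:
    """Generative quantities for one subject; estimation code never reads this."""

    k: float
    b: float
    group: str
    dcm_params: dict[str, float]


@dataclass
class SubjectData:
    behavior: ob.SubjectBehavior
    bold: np.ndarray  # (runs, volumes, 2) percent-signal, region order (d, v)
    ground_truth: GroundTruth


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectData]

    @property
    def true_log_k(self) -> np.ndarray:
        return np.log([s.ground_truth.k for s in self.subjects])


def _draw_rt(rng, mean_s: float, log_sd: float) -> float:
    mu = np.log(mean_s) - 0.5 * log_sd**2
    for _ in range(100):
        rt = float(rng.lognormal(mu, log_sd))
        if rt <= ob.DECISION_WINDOW_S:
            return rt
    return ob.DECISION_WINDOW_S  # pathological parameters only


def simulate_subject_behavior(config: CohortConfig, subject_index: int,
                              k: float, b: float, rng: np.random.Generator,
                              grid: ob.OfferGrid | None = None) -> ob.SubjectBehavior:
    """Realize one subject's 216-trial session.

    Choices are Bernoulli draws from the softmax model at the subject's
    (k, b); reaction times are truncated lognormal with the
    group-by-choice interaction (choices consistent with the subject's
    overall tendency are faster); about ``missed_rate`` of trials get no
    response.  Sessions whose final event would spill past the run are
    redrawn with a shifted session seed.
    """
    grid = grid or ob.load_offer_grid()
    margin = ob.DECISION_WINDOW_S + ob.FEEDBACK_S
    session_seed = int(rng.integers(2**31))
    for attempt in range(20):
        trials = ob.build_session(grid, session_seed + attempt, n_runs=config.runs_per_subject)
        last_end = max(t.onset for t in trials) + margin
        if last_end <= config.run_duration_s:
            break
    else:
        raise RuntimeError("could not fit session into run duration")

    p = np.array([ob.p_accept(ob.discounted_value(t.offer, k), b) for t in trials])
    accept = rng.random(len(trials)) < p
    missed = rng.random(len(trials)) < config.missed_rate
    # overall tendency from the generative model, for the RT interaction
    wait_tendency = p.mean() > 0.5
    for t, a, m in zip(trials, accept, missed):
        if m:
            t.choice = "missed"
            t.rt = None
            continue
        t.choice = "accept" if a else "reject"
        congruent = (a and wait_tendency) or (not a and not wait_tendency)
        mean_rt = config.rt_congruent_mean_s if congruent else config.rt_incongruent_mean_s
        t.rt = _draw_rt(rng, mean_rt, config.rt_log_sd)
    return ob.SubjectBehavior(trials=trials, subject_id=f"sub-{subject_index + 1:02d}")


def draw_cohort_dcm_params(log_k: np.ndarray, config: CohortConfig,
                           rng: np.random.Generator) -> list[dict[str, float]]:
    """Per-subject generative coupling with the planted prediction effect.

    Every coupling gets independent inter-subject jitter; the
    dlPFC-to-vmPFC later-choice modulation additionally tracks
    ``-log k`` (standardized) with slope ``effect_size``, so that less
    impulsive subjects have stronger top-down modulation.  With
    ``effect_size = 0`` the cohort is a null cohort.
    """
    log_k = np.asarray(log_k, dtype=float)
    z = -(log_k - log_k.mean())
    sd = log_k.std()
    if sd > 0:
        z = z / sd
    base = dict(BASE_DCM_PARAMS)
    base.update(dict(config.base_dcm_overrides))
    if config.effect_param not in base:
        raise KeyError(f"unknown effect parameter {config.effect_param}")
    out = []
    for i in range(len(log_k)):
        params = dict(base)
        for name in params:
            if not name.startswith("drive."):
                params[name] += float(rng.normal(0, config.coupling_jitter_sd))
        params[config.effect_param] = (
            base[config.effect_param]
            + config.effect_size * float(z[i])
            + float(rng.normal(0, config.effect_noise_sd))
        )
        out.append(params)
    return out


def plant_prediction_effect(cohort: "Cohort", effect_size: float,
                            seed: int | None = None) -> "Cohort":
    """Re-plant the d->v later-choice modulation at a new effect size.

    Redraws the ground-truth coupling (and hence the BOLD) with the
    given coupling between the planted parameter and -log k; used to
    build matched planted/null cohorts from one behavioral realization.
    """
    if effect_size < 0:
        raise ValueError("effect size must be non-negative")
    cfg = CohortConfig(**{**asdict(cohort.config), "effect_size": effect_size,
                          "seed": cohort.config.seed if seed is None else seed})
    return generate_cohort(cfg)


def simulate_subject_bold(behavior: ob.SubjectBehavior, dcm_params: dict[str, float],
                          config: CohortConfig, rng: np.random.Generator,
                          true_k: float, true_group: str,
                          spec: DCMSpec | None = None) -> np.ndarray:
    """Generate (runs, volumes, 2) BOLD from the DCM forward model.

    Driving and modulatory input streams are built from the subject's
    realized events using the *generative* discount rate and group (the
    estimation path later rebuilds them from fitted values).  AR(1)
    Gaussian observation noise is added with marginal sd
    ``bold_noise_sd``.
    """
    spec = spec or full_model_spec(family=1)
    theta = np.array([dcm_params[name] for name in spec.param_names])
    fit = ob.DiscountFit(k=true_k, b=1.0, loglik=0.0, converged=True)
    out = np.zeros((config.runs_per_subject, config.volumes_per_run, 2))
    for run in range(1, config.runs_per_subject + 1):
        run_trials = [t for t in behavior.trials if t.run_index == run]
        rdsv = ob.rdsv_series(run_trials, fit, true_group)
        u = dcm_engine.build_input_streams(
            run_trials, config.run_duration_s, rdsv, dt=config.microtime_dt,
        )
        clean = dcm_engine.simulate_bold(
            spec, u, theta=theta, dt=config.microtime_dt,
            tr=config.tr_seconds, n_volumes=config.volumes_per_run,
        )
        rho = config.bold_noise_ar1
        w = rng.normal(0, config.bold_noise_sd * np.sqrt(1 - rho**2),
                       size=clean.shape)
        noise = np.zeros_like(clean)
        noise[0] = rng.normal(0, config.bold_noise_sd, size=2)
        for t in range(1, len(noise)):
            noise[t] = rho * noise[t - 1] + w[t]
        out[run - 1] = clean + noise
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic study for the given configuration."""
    root = np.random.SeedSequence(config.seed)
    ss_k, ss_dcm, *ss_subj = root.spawn(2 + config.n_subjects)
    rng_k = np.random.default_rng(ss_k)
    log_k = rng_k.normal(config.log_k_mean, config.log_k_sd, config.n_subjects)
    log_b = rng_k.normal(config.log_b_mean, config.log_b_sd, config.n_subjects)
    dcm_params = draw_cohort_dcm_params(log_k, config, np.random.default_rng(ss_dcm))

    grid = ob.load_offer_grid()
    subjects = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(ss_subj[i])
        k, b = float(np.exp(log_k[i])), float(np.exp(log_b[i]))
        behavior = simulate_subject_behavior(config, i, k, b, rng, grid=grid)
        # generative group from the model's own accept tendency
        p = np.array([ob.p_accept(ob.discounted_value(t.offer, k), b)
                      for t in behavior.trials])
        group = "WG" if p.mean() > 0.5 else "NG"
        bold = simulate_subject_bold(behavior, dcm_params[i], config, rng, k, group)
        subjects.append(SubjectData(
            behavior=behavior, bold=bold,
            ground_truth=GroundTruth(k=k, b=b, group=group, dcm_params=dcm_params[i]),
        ))
    return Cohort(config=config, subjects=subjects)


# ---------------------------------------------------------------------------
# on-disk format: events TSV + series CSV + ground-truth JSON sidecar


def save_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for s in cohort.subjects:
        sid = s.behavior.subject_id
        ev_path = outdir / f"{sid}_events.tsv"
        ob.trials_to_events(s.behavior.trials).to_csv(ev_path, sep="\t", index=False)
        written.append(ev_path)
        for run in range(cohort.config.runs_per_subject):
            ts_path = outdir / f"{sid}_run-{run + 1}_bold.csv"
            df = pd.DataFrame({
                "time": np.arange(cohort.config.volumes_per_run) * cohort.config.tr_seconds,
                "region_d": s.bold[run, :, 0],
                "region_v": s.bold[run, :, 1],
            })
            df.to_csv(ts_path, index=False, float_format="%.8g")
            written.append(ts_path)
        gt_path = outdir / f"{sid}_truth.json"
        gt_path.write_text(json.dumps(asdict(s.ground_truth), indent=1))
        written.append(gt_path)
    cfg_path = outdir / "cohort_config.json"
    cfg_path.write_text(json.dumps(asdict(cohort.config), indent=1))
    written.append(cfg_path)
    return written


def load_cohort(outdir: str | Path) -> Cohort:
    outdir = Path(outdir)
    config = CohortConfig(**json.loads((outdir / "cohort_config.json").read_text()))
    subjects = []
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:02d}"
        trials = ob.events_to_trials(pd.read_csv(outdir / f"{sid}_events.tsv", sep="\t"))
        bold = np.stack([
            pd.read_csv(outdir / f"{sid}_run-{run + 1}_bold.csv")[["region_d", "region_v"]].to_numpy()
            for run in range(config.runs_per_subject)
        ])
        gt = GroundTruth(**json.loads((outdir / f"{sid}_truth.json").read_text()))
        subjects.append(SubjectData(
            behavior=ob.SubjectBehavior(trials=trials, subject_id=sid),
            bold=bold, ground_truth=gt,
        ))
    return Cohort(config=config, subjects=subjects)
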
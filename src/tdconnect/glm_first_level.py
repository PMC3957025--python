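"""First-level GLM with parametric value modulators and AR(1) correction.

Each run's design has three task columns built on a microtime grid and
down-sampled to the TR grid after convolution with a canonical
double-gamma HRF:

1. an indicator for the decision screen (onset to response),
2. the indicator modulated by the trial's discounted value (dSV, or the
   relative recoding rdSV),
3. the indicator modulated by Accept (1 when the delayed option was
   chosen), orthogonalized against the preceding task columns so that
   shared variance is assigned to the value regressor.

Modulators are mean-centered per run before convolution.  Nuisance
columns comprise a per-run intercept, linear trend, and a discrete
cosine high-pass basis (128 s cutoff).  Fitting uses feasible GLS with a
first-order autoregressive error model (statsmodels GLSAR); the log
model evidence is approximated by -BIC/2 (Laplace under a flat prior),
which is what the full-versus-reduced value-model comparison feeds into
random-effects Bayesian model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_1samp
import statsmodels.api as sm

from tdconnect.offers_behavior import TrialRecord

TASK_COLUMNS = ("condition", "value", "accept")
HIGHPASS_CUTOFF_S = 128.0


class DesignError(ValueError):
    pass


def hrf(time_grid: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response on the given grid.

    Difference of gamma densities (shape 6 and 16, unit time scale, the
    undershoot weighted 1/6), zero at the origin, peaking near 5 s with
    an undershoot around 15 s; normalized to unit peak.
    """
    from scipy.stats import gamma

    t = np.asarray(time_grid, dtype=float)
    h = gamma.pdf(t, 6) - gamma.pdf(t, 16) / 6.0
    peak = h.max()
    if peak <= 0:
        raise ValueError("time grid must cover the HRF peak")
    return h / peak


def _dct_basis(n: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete cosine high-pass basis (excluding the constant term)."""
    order = int(np.floor(2.0 * n * tr / cutoff_s))
    if order < 1:
        return np.empty((n, 0))
    t = np.arange(n)
    return np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * n)) for k in range(1, order + 1)]
    )


def build_design(trials: list[TrialRecord], value_modulator: np.ndarray,
                 volumes: int, tr: float, *, dt: float = 0.1,
                 include_accept: bool = True,
                 highpass: bool = True) -> pd.DataFrame:
    """Build one run's design matrix on the TR grid.

    ``value_modulator`` gives the per-trial parametric value (dSV or
    rdSV) aligned with ``trials``; missed trials are excluded from all
    three task columns.  Returns a DataFrame whose ``attrs['task']``
    names the task columns.

    Raises
    ------
    DesignError
        If events extend past the run or the resulting matrix is rank
        deficient (listing the collinear columns).
    """
    value_modulator = np.asarray(value_modulator, dtype=float)
    if len(value_modulator) != len(trials):
        raise DesignError("value modulator must align with trials")
    responded = [(t, v) for t, v in zip(trials, value_modulator) if t.responded()]
    if not responded:
        raise DesignError("no responded trials in run")
    duration_s = volumes * tr
    n_micro = int(round(duration_s / dt))
    cond = np.zeros(n_micro)
    vals = np.array([v for _, v in responded])
    vals = vals - vals.mean()
    accepts = np.array([1.0 if t.choice == "accept" else 0.0 for t, _ in responded])
    accepts = accepts - accepts.mean()
    value_s = np.zeros(n_micro)
    accept_s = np.zeros(n_micro)
    for (t, _), v, a in zip(responded, vals, accepts):
        i0 = int(round(t.onset / dt))
        i1 = int(round((t.onset + (t.rt or 0.0)) / dt))
        if i1 > n_micro:
            raise DesignError(f"event at {t.onset}s extends past run end {duration_s}s")
        cond[i0:i1] = 1.0
        value_s[i0:i1] = v
        accept_s[i0:i1] = a

    kernel = hrf(np.arange(0, 32.0, dt))
    keep = np.round(np.arange(volumes) * tr / dt).astype(int)

    def conv(x):
        return np.convolve(x, kernel)[:n_micro][keep]

    cols = {"condition": conv(cond), "value": conv(value_s)}
    if include_accept:
        acc = conv(accept_s)
        # assign shared variance to the earlier task columns
        basis = np.column_stack([cols["condition"], cols["value"]])
        coef, *_ = np.linalg.lstsq(basis, acc, rcond=None)
        cols["accept"] = acc - basis @ coef
    X = pd.DataFrame(cols)
    X["intercept"] = 1.0
    X["trend"] = np.linspace(-0.5, 0.5, volumes)
    if highpass:
        dct = _dct_basis(volumes, tr, HIGHPASS_CUTOFF_S)
        for k in range(dct.shape[1]):
            X[f"dct{k + 1}"] = dct[:, k]
    _check_rank(X)
    X.attrs["task"] = [c for c in TASK_COLUMNS if c in X.columns]
    X.attrs["tr"] = tr
    return X


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = np.empty((mat.shape[0], 0))
        for name in X.columns:
            cand = np.column_stack([cur, X[name].to_numpy()])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")


def concat_runs(designs: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-run designs: task columns shared, nuisance per run."""
    frames = []
    task = designs[0].attrs["task"]
    for i, d in enumerate(designs):
        renamed = d.rename(
            columns={c: f"run{i + 1}_{c}" for c in d.columns if c not in task}
        )
        frames.append(renamed)
    out = pd.concat(frames, axis=0, ignore_index=True).fillna(0.0)
    out.attrs["task"] = task
    out.attrs["tr"] = designs[0].attrs["tr"]
    _check_rank(out)
    return out


@dataclass
class GLMResult:
    """Betas, AR(1) coefficient, contrasts, and approximate log evidence."""

    params: pd.Series
    rho: float
    contrasts: dict  # name -> {"estimate", "se", "t", "p"}
    log_evidence: float
    resid_var: float
    df_resid: float


def fit_glm(series: np.ndarray, design: pd.DataFrame,
            contrasts: dict[str, str] | None = None) -> GLMResult:
    """Fit one region's series with AR(1)-corrected least squares.

    The AR coefficient is estimated from OLS residuals and the model
    refit on prewhitened data (two feasible-GLS iterations).  Contrasts
    default to each task column against baseline.  The log evidence is
    the Bayesian information criterion approximation ``llf - k/2 ln n``.
    """
    y = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in series")
    if len(y) != len(design):
        raise ValueError(f"series length {len(y)} != design rows {len(design)}")
    X = design.to_numpy()
    model = sm.GLSAR(y, X, rho=1)
    res = model.iterative_fit(maxiter=3)
    rho = float(model.rho[0])
    if contrasts is None:
        contrasts = {c: c for c in design.attrs.get("task", []) if c in design.columns}
    out = {}
    for cname, col in contrasts.items():
        c = np.zeros(X.shape[1])
        c[design.columns.get_loc(col)] = 1.0
        tt = res.t_test(c)
        out[cname] = {
            "estimate": float(np.squeeze(tt.effect)),
            "se": float(np.squeeze(tt.sd)),
            "t": float(np.squeeze(tt.tvalue)),
            "p": float(np.squeeze(tt.pvalue)),
        }
    n_eff = res.nobs
    k = X.shape[1]
    log_evidence = float(res.llf - 0.5 * k * np.log(n_eff))
    return GLMResult(
        params=pd.Series(res.params, index=design.columns),
        rho=rho, contrasts=out, log_evidence=log_evidence,
        resid_var=float(res.scale), df_resid=float(res.df_resid),
    )


def group_ttest(values: np.ndarray) -> tuple[float, float]:
    """One-sample two-sided t-test of subject contrast values against zero."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 subjects")
    if np.isclose(v.std(ddof=1), 0.0):
        if np.isclose(v.mean(), 0.0):
            raise ValueError("zero variance and zero mean: t undefined")
        return float(np.sign(v.mean()) * np.inf), 0.0
    res = ttest_1samp(v, 0.0)
    return float(res.statistic), float(res.pvalue)


def compare_full_vs_reduced(series_by_subject: list[np.ndarray],
                            designs_by_subject: list[pd.DataFrame],
                            *, seed: int = 0, n_draws: int = 100_000):
    """Evidence-based comparison of the value model against its reduction.

    For each subject, fits the full design and a reduced design with the
    parametric value column removed, records the approximate log
    evidence of each, and feeds the per-subject evidence pairs into
    random-effects Bayesian model selection.  Returns the (n, 2)
    evidence matrix (columns: full, reduced) and the BMS result; the
    first exceedance probability is the belief that the full model is
    the more frequent in the population.
    """
    from tdconnect.model_space import rfx_bms

    rows = []
    for y, X in zip(series_by_subject, designs_by_subject):
        full = fit_glm(y, X)
        reduced_design = X.drop(columns=["value"]).copy()
        reduced_design.attrs["task"] = [c for c in X.attrs["task"] if c != "value"]
        reduced_design.attrs["tr"] = X.attrs["tr"]
        reduced = fit_glm(y, reduced_design)
        rows.append([full.log_evidence, reduced.log_evidence])
    evidence = np.array(rows)
    bms = rfx_bms(evidence, seed=seed, n_draws=n_draws)
    return evidence, bms
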
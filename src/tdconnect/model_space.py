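"""Model space, random-effects Bayesian model selection, and parameter averaging.

The candidate space crosses four driving-input placements (families)
with sixteen patterns of inter-region coupling modulation, giving 64
models.  Families differ in where the trial-wise value stream and the
accept stream enter:

    family 1: value -> vmPFC, accept -> dlPFC
    family 2: value -> vmPFC, accept -> vmPFC
    family 3: value -> dlPFC, accept -> dlPFC
    family 4: value -> dlPFC, accept -> vmPFC

Within a family, the default enumeration policy toggles the four
cross-connection modulation switches (d->v and v->d during all-choice
and later-choice periods); fixed coupling in both directions, the
self-modulations, and the driving inputs are present in every model, and
fixation-period coupling is carried by the fixed matrix.  The policy is
pluggable so alternative readings of the within-family composition can
be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy.special import digamma
from scipy.stats import norm, ttest_1samp

from tdconnect.dcm_engine import DCMPosterior, DCMSpec

FAMILY_DRIVES = {
    1: ("drive.value_to_v", "drive.accept_to_d"),
    2: ("drive.value_to_v", "drive.accept_to_v"),
    3: ("drive.value_to_d", "drive.accept_to_d"),
    4: ("drive.value_to_d", "drive.accept_to_v"),
}

_BASE_PARAMS = ("fixed.v_to_d", "fixed.d_to_v", "fixed.d_self", "fixed.v_self",
                "all.v_self", "all.d_self", "later.v_self", "later.d_self")
_SWITCHES = ("all.d_to_v", "all.v_to_d", "later.d_to_v", "later.v_to_d")


def cross_switch_policy(family: int) -> list[tuple[str, ...]]:
    """Default within-family policy: all on/off combinations of the four
    cross-connection modulation switches, ordered so index 15 is the
    fully connected model."""
    patterns = []
    for bits in product((0, 1), repeat=len(_SWITCHES)):
        patterns.append(tuple(s for s, bit in zip(_SWITCHES, bits) if bit))
    return patterns


@dataclass(frozen=True)
class ModelSpace:
    """An ordered list of DCM specifications with family labels."""

    models: tuple[DCMSpec, ...]

    @property
    def family_labels(self) -> np.ndarray:
        return np.array([m.family for m in self.models])

    def full_model(self, family: int) -> DCMSpec:
        for m in self.models:
            if m.family == family and set(_SWITCHES) <= set(m.param_names):
                return m
        raise KeyError(f"no full model in family {family}")


def enumerate_models(policy: Callable[[int], list[tuple[str, ...]]] = cross_switch_policy
                     ) -> ModelSpace:
    """Enumerate the 4-family x 16-model space."""
    models = []
    for family, drives in FAMILY_DRIVES.items():
        for idx, switches in enumerate(policy(family)):
            names = _BASE_PARAMS + tuple(switches) + drives
            models.append(DCMSpec(
                name=f"family{family}_m{idx}", param_names=names,
                family=family, index=idx,
            ))
    return ModelSpace(models=tuple(models))


# ---------------------------------------------------------------------------
# random-effects BMS (hierarchical Dirichlet over model frequencies)


@dataclass
class BMSResult:
    alpha: np.ndarray  # Dirichlet concentration
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    labels: tuple | None = None


def rfx_bms(log_evidence: np.ndarray, *, alpha0: float = 1.0,
            n_draws: int = 1_000_000, seed: int = 0,
            max_iter: int = 200, tol: float = 1e-6) -> BMSResult:
    """Random-effects Bayesian model selection.

    Fits the hierarchical model in which each subject draws its
    generating model from population frequencies with a Dirichlet prior,
    via the standard variational updates; exceedance probabilities (the
    belief that each model is the most frequent in the population) are
    estimated by Monte-Carlo draws from the fitted Dirichlet.

    Parameters
    ----------
    log_evidence
        Array (n_subjects, n_models) of log model evidences.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need an (n_subjects, n_models>=2) evidence matrix")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    n, m = L.shape
    alpha = np.full(m, alpha0, dtype=float)
    for _ in range(max_iter):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=m) / n_draws
    return BMSResult(alpha=alpha, expected_prob=alpha / alpha.sum(), exceedance_prob=xp)


def family_bms(log_evidence: np.ndarray, family_labels: Sequence, *,
               families: Sequence | None = None, alpha0: float = 1.0,
               n_draws: int = 1_000_000, seed: int = 0) -> BMSResult:
    """Family-level comparison with uniform within-family priors.

    The Dirichlet prior mass is split evenly within each family so that
    families with more members are not favored a priori; family
    exceedance is estimated by aggregating Dirichlet draws over family
    members before taking the argmax.
    """
    L = np.asarray(log_evidence, dtype=float)
    labels = np.asarray(family_labels)
    if labels.shape[0] != L.shape[1]:
        raise ValueError("family labels must match the number of models")
    fams = sorted(set(labels.tolist())) if families is None else list(families)
    sizes = {f: int(np.sum(labels == f)) for f in fams}
    if any(s == 0 for s in sizes.values()):
        raise ValueError(f"empty family among {fams}")
    # uniform prior over families, split within family
    per_model_alpha0 = np.array([alpha0 / sizes[f] for f in labels], dtype=float)
    n, m = L.shape
    alpha = per_model_alpha0.copy()
    for _ in range(200):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = per_model_alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < 1e-6:
            alpha = new_alpha
            break
        alpha = new_alpha
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    fam_draws = np.stack([draws[:, labels == f].sum(axis=1) for f in fams], axis=1)
    xp = np.bincount(np.argmax(fam_draws, axis=1), minlength=len(fams)) / n_draws
    fam_alpha = np.array([alpha[labels == f].sum() for f in fams])
    return BMSResult(alpha=fam_alpha, expected_prob=fam_alpha / fam_alpha.sum(),
                     exceedance_prob=xp, labels=tuple(fams))


# ---------------------------------------------------------------------------
# Bayesian parameter averaging


@dataclass
class BPAResult:
    param_names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def prob_positive(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(norm.sf(0.0, loc=self.mean[i], scale=np.sqrt(self.cov[i, i])))


def bpa(posteriors: Sequence[DCMPosterior]) -> BPAResult:
    """Bayesian parameter averaging across subjects.

    Multiplies the subject posteriors and divides out the (n-1)-fold
    repeated prior:  group precision = sum of subject precisions minus
    (n-1) x prior precision, and correspondingly for the
    precision-weighted means.  With a single posterior this returns it
    unchanged.
    """
    if not posteriors:
        raise ValueError("need at least one posterior")
    names = posteriors[0].spec.param_names
    if any(p.spec.param_names != names for p in posteriors):
        raise ValueError("posteriors must share a parameterization")
    n = len(posteriors)
    prior_prec = np.diag(1.0 / np.asarray(posteriors[0].spec.prior_var, dtype=float))
    prior_mu = np.asarray(posteriors[0].spec.prior_mean, dtype=float)
    prec_sum = sum(np.linalg.inv(p.cov) for p in posteriors)
    wmean_sum = sum(np.linalg.inv(p.cov) @ p.mean for p in posteriors)
    group_prec = prec_sum - (n - 1) * prior_prec
    group_cov = np.linalg.inv(group_prec)
    group_mean = group_cov @ (wmean_sum - (n - 1) * (prior_prec @ prior_mu))
    group_cov = 0.5 * (group_cov + group_cov.T)
    return BPAResult(param_names=names, mean=group_mean, cov=group_cov)


def connectivity_tests(posteriors: Sequence[DCMPosterior],
                       params: Sequence[str] | None = None) -> dict:
    """Group tests on coupling parameters: classical t and BPA posterior.

    For each named parameter, reports the across-subject one-sample
    two-tailed t-test of the posterior means against zero, alongside the
    Bayesian-parameter-average posterior probability that the parameter
    exceeds zero.
    """
    if len(posteriors) < 3:
        raise ValueError("need at least 3 subjects")
    names = posteriors[0].spec.param_names
    if params is None:
        params = [p for p in names if p.endswith(("d_to_v", "v_to_d"))]
    group = bpa(posteriors)
    out = {}
    for name in params:
        i = names.index(name)
        values = np.array([p.mean[i] for p in posteriors])
        if np.allclose(values.std(), 0):
            raise ValueError(f"zero variance across subjects for {name}")
        t = ttest_1samp(values, 0.0)
        out[name] = {
            "mean": float(values.mean()),
            "t": float(t.statistic),
            "p": float(t.pvalue),
            "bpa_mean": float(group.mean[i]),
            "bpa_prob_positive": group.prob_positive(name),
        }
    return out
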
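"""Intertemporal-choice offers, trials, and the hyperbolic discounting model.

The task: on each trial the subject chooses between a fixed immediate
reward (by default $25) and a single delayed offer of $A in D days.
Subjective value of the delayed offer follows a hyperbolic discount
function ``dSV = A / (1 + k * D)`` with subject-specific discount rate
``k`` (per day), and choice follows a softmax psychometric function
``P(accept) = 1 / (1 + exp(b * (reference - dSV)))`` with non-negative
slope ``b``.

This module owns the offer grid, session construction (trial ordering
and onsets), maximum-likelihood fitting of (k, b), the wait-group /
now-group assignment, and the relative-value (rdSV) recoding used by the
downstream GLM and connectivity stages.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

#: Value of the constant immediate option, in dollars.  Named so that
#: alternative reference amounts can be simulated.
REFERENCE_AMOUNT = 25.0

#: Maximum time allowed for a response, seconds.
DECISION_WINDOW_S = 3.0

#: Duration of the Yes/No feedback screen, seconds.
FEEDBACK_S = 0.25

#: Inter-trial fixation interval bounds (uniform), seconds.
ITI_RANGE_S = (2.0, 6.0)

#: Bounds for the discount-rate search, per day.  Outside this range the
#: 7-200 day offer grid carries essentially no information about k.
K_BOUNDS = (1e-6, 1.0)
B_BOUNDS = (1e-3, 1e2)

Choice = Literal["accept", "reject", "missed"]


class OfferGridError(ValueError):
    """Raised when an offer table violates the task's design invariants."""


@dataclass(frozen=True)
class Offer:
    """A single delayed option: $``amount`` in ``delay`` days."""

    amount: float
    delay: float

    def __post_init__(self) -> None:
        if self.amount <= 0 or self.delay <= 0:
            raise ValueError(f"offer must be positive, got {self}")


@dataclass(frozen=True)
class OfferGrid:
    """The 18-delay x 6-amount offer design shared by all subjects."""

    delays: tuple[float, ...]
    amounts: tuple[tuple[float, ...], ...]  # one row of 6 per delay

    def __post_init__(self) -> None:
        if len(self.delays) != 18:
            raise OfferGridError(f"expected 18 delay rows, got {len(self.delays)}")
        if any(len(row) != 6 for row in self.amounts):
            raise OfferGridError("each delay row must list exactly 6 amounts")
        if list(self.delays) != sorted(set(self.delays)):
            raise OfferGridError("delays must be strictly increasing")
        for row in self.amounts:
            if list(row) != sorted(row):
                raise OfferGridError("amounts must be nondecreasing within a row")
        flat = [a for row in self.amounts for a in row]
        if min(flat) < 25 or max(flat) > 54:
            raise OfferGridError("amounts must lie in [25, 54]")
        if min(self.delays) < 7 or max(self.delays) > 200:
            raise OfferGridError("delays must lie in [7, 200]")

    @property
    def offers(self) -> list[Offer]:
        """All 108 (delay, amount) combinations, row-major."""
        return [
            Offer(amount=a, delay=d)
            for d, row in zip(self.delays, self.amounts)
            for a in row
        ]


@dataclass
class TrialRecord:
    """One realized (or not-yet-realized) trial of the choice task."""

    offer: Offer
    onset: float  # seconds from run start
    rt: float | None = None  # seconds; None iff missed / unrealized
    choice: Choice | None = None  # None for unrealized sessions
    run_index: int = 1

    def responded(self) -> bool:
        return self.choice in ("accept", "reject")


@dataclass
class DiscountFit:
    """Maximum-likelihood estimate of the discounting model for one subject."""

    k: float
    b: float
    loglik: float
    converged: bool
    at_bound: bool = False
    degenerate: bool = False  # likelihood flat in k (e.g. b ~ 0 or one-sided data)


@dataclass
class SubjectBehavior:
    """Trials plus fitted model and wait/now group label for one subject."""

    trials: list[TrialRecord]
    fit: DiscountFit | None = None
    group: Literal["WG", "NG"] | None = None
    subject_id: str = ""


def load_offer_grid(source=None) -> OfferGrid:
    """Load and validate the offer grid.

    Parameters
    ----------
    source
        Path or file-like of a tab-separated table with a header row
        ``delay amount1..amount6``.  ``None`` loads the packaged copy of
        the published 18 x 6 design.
    """
    if source is None:
        source = importlib.resources.files("tdconnect.data") / "offer_grid.tsv"
    try:
        table = pd.read_csv(source, sep="\t")
    except Exception as exc:  # malformed file
        raise OfferGridError(f"cannot parse offer grid: {exc}") from exc
    if table.shape[1] != 7:
        raise OfferGridError(f"expected 7 columns, got {table.shape[1]}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.all(values == values.astype(int)):
        raise OfferGridError("offer grid cells must be integers")
    return OfferGrid(
        delays=tuple(float(d) for d in values[:, 0]),
        amounts=tuple(tuple(float(a) for a in row) for row in values[:, 1:]),
    )


def build_session(grid: OfferGrid, seed: int, n_runs: int = 2) -> list[TrialRecord]:
    """Build an unrealized 216-trial session from the offer grid.

    Every (delay, amount) pair appears exactly twice.  Trial order is
    shuffled by ``seed`` and trials are split evenly across ``n_runs``
    runs.  Onsets reserve the full 3 s decision window plus the 0.25 s
    feedback screen per trial, with inter-trial fixation drawn uniformly
    on [2, 6] s; realized reaction times never exceed the reserved slot,
    so onsets are independent of the eventual choices.
    """
    rng = np.random.default_rng(seed)
    offers = grid.offers * 2
    order = rng.permutation(len(offers))
    per_run = len(offers) // n_runs
    trials: list[TrialRecord] = []
    for run in range(n_runs):
        t = 0.0
        for idx in order[run * per_run : (run + 1) * per_run]:
            t += rng.uniform(*ITI_RANGE_S)
            trials.append(TrialRecord(offer=offers[idx], onset=t, run_index=run + 1))
            t += DECISION_WINDOW_S + FEEDBACK_S
    return trials


def discounted_value(offer: Offer, k: float) -> float:
    """Hyperbolic discounted stimulus value ``A / (1 + k D)``."""
    if k < 0:
        raise ValueError(f"discount rate must be non-negative, got {k}")
    return offer.amount / (1.0 + k * offer.delay)


def p_accept(dsv, b: float, reference: float = REFERENCE_AMOUNT):
    """Softmax probability of accepting the delayed option.

    ``P = 1 / (1 + exp(b * (reference - dSV)))``; equals 0.5 when the
    discounted value matches the immediate reference, for every b.
    """
    if b < 0:
        raise ValueError(f"softmax slope must be non-negative, got {b}")
    x = np.asarray(b * (np.asarray(dsv, dtype=float) - reference))
    # numerically stable logistic
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, None, 500))),
                   np.exp(np.clip(x, -500, None)) / (1.0 + np.exp(np.clip(x, -500, None))))
    return float(out) if out.ndim == 0 else out


def _neg_loglik(log_params: np.ndarray, amounts: np.ndarray, delays: np.ndarray,
                accepted: np.ndarray, reference: float) -> float:
    k = np.exp(log_params[0])
    b = np.exp(log_params[1])
    dsv = amounts / (1.0 + k * delays)
    x = b * (dsv - reference)
    # log P(accept) = -log(1+exp(-x)); log P(reject) = -log(1+exp(x))
    ll = -np.logaddexp(0.0, np.where(accepted, -x, x)).sum()
    return -ll


def fit_discounting(trials: Sequence[TrialRecord],
                    reference: float = REFERENCE_AMOUNT,
                    n_starts: int = 9) -> DiscountFit:
    """Fit (k, b) by maximum likelihood on the responded trials.

    Optimization runs in (log k, log b) with bounded L-BFGS-B from a
    3 x 3 grid of starting points; missed trials are excluded from the
    likelihood.  One-sided data (all accepts or all rejects) is returned
    with the boundary flag set rather than raising.
    """
    responded = [t for t in trials if t.responded()]
    if not responded:
        raise ValueError("no responded trials to fit")
    amounts = np.array([t.offer.amount for t in responded])
    delays = np.array([t.offer.delay for t in responded])
    accepted = np.array([t.choice == "accept" for t in responded])

    lo = np.log([K_BOUNDS[0], B_BOUNDS[0]])
    hi = np.log([K_BOUNDS[1], B_BOUNDS[1]])
    side = int(np.sqrt(n_starts))
    k_starts = np.linspace(np.log(1e-4), np.log(0.3), side)
    b_starts = np.linspace(np.log(0.05), np.log(5.0), side)

    best = None
    for lk in k_starts:
        for lb in b_starts:
            res = minimize(
                _neg_loglik, x0=np.array([lk, lb]),
                args=(amounts, delays, accepted, reference),
                method="L-BFGS-B", bounds=list(zip(lo, hi)),
            )
            if best is None or res.fun < best.fun:
                best = res

    k, b = np.exp(best.x)
    at_bound = bool(
        np.any(np.isclose(best.x, lo, atol=1e-6)) or np.any(np.isclose(best.x, hi, atol=1e-6))
    )
    # the likelihood depends on k only through b * dSV: a near-zero fitted
    # slope leaves k unidentified, as does one-sided data
    dsv_spread = float(np.std(amounts / (1.0 + k * delays)))
    degenerate = bool(accepted.all() or (~accepted).all() or b * dsv_spread < 0.05)
    return DiscountFit(
        k=float(k), b=float(b), loglik=float(-best.fun),
        converged=bool(best.success), at_bound=at_bound or degenerate,
        degenerate=degenerate,
    )


def assign_group(trials: Sequence[TrialRecord]) -> Literal["WG", "NG"]:
    """Wait group iff the delayed option was accepted on >50% of responded trials.

    A subject exactly at 50% falls in the now group (the wait-group rule
    is strict).
    """
    responded = [t for t in trials if t.responded()]
    if not responded:
        raise ValueError("no responded trials; group undefined")
    frac = np.mean([t.choice == "accept" for t in responded])
    return "WG" if frac > 0.5 else "NG"


def dsv_series(trials: Sequence[TrialRecord], fit: DiscountFit) -> np.ndarray:
    """Per-trial discounted stimulus values under the fitted k."""
    return np.array([discounted_value(t.offer, fit.k) for t in trials])


def rdsv_series(trials: Sequence[TrialRecord], fit: DiscountFit,
                group: Literal["WG", "NG"],
                reference: float = REFERENCE_AMOUNT) -> np.ndarray:
    """Relative discounted value: dSV - reference for WG, reference - dSV for NG.

    Recodes value relative to each subject's most frequent choice, so
    that the sign convention is shared across wait-group and now-group
    subjects.
    """
    dsv = dsv_series(trials, fit)
    return dsv - reference if group == "WG" else reference - dsv


# ---------------------------------------------------------------------------
# events table I/O (BIDS-events-like TSV dialect)

EVENT_COLUMNS = ["onset", "duration", "amount", "delay", "choice", "rt", "run"]


def trials_to_events(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Serialize trials to the events-table dialect (onset/duration in s)."""
    rows = []
    for t in trials:
        rows.append({
            "onset": t.onset,
            "duration": t.rt if t.rt is not None else DECISION_WINDOW_S,
            "amount": t.offer.amount,
            "delay": t.offer.delay,
            "choice": t.choice if t.choice is not None else "n/a",
            "rt": t.rt if t.rt is not None else "n/a",
            "run": t.run_index,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def events_to_trials(events: pd.DataFrame) -> list[TrialRecord]:
    """Parse an events table back into trial records."""
    trials = []
    for _, row in events.iterrows():
        choice = None if pd.isna(row["choice"]) or row["choice"] == "n/a" else row["choice"]
        rt = None if pd.isna(row["rt"]) or str(row["rt"]) == "n/a" else float(row["rt"])
        if choice == "missed" and rt is not None:
            raise ValueError("missed trials cannot carry a reaction time")
        if choice in ("accept", "reject") and (rt is None or rt > DECISION_WINDOW_S):
            raise ValueError(f"responded trial needs rt <= {DECISION_WINDOW_S}, got {rt}")
        trials.append(TrialRecord(
            offer=Offer(amount=float(row["amount"]), delay=float(row["delay"])),
            onset=float(row["onset"]), rt=rt, choice=choice,
            run_index=int(row["run"]),
        ))
    return trials
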
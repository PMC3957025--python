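"""Offer grid, session construction, and discounting-model fitting."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdconnect import offers_behavior as ob
from tests.conftest import simulate_choices


class TestOfferGrid:
    def test_packaged_grid_dimensions(self, grid):
        assert len(grid.delays) == 18
        pairs = {(o.delay, o.amount) for o in grid.offers}
        assert len(pairs) == 108

    def test_packaged_grid_ranges(self, grid):
        amounts = [o.amount for o in grid.offers]
        delays = [o.delay for o in grid.offers]
        assert (min(amounts), max(amounts)) == (25, 54)
        assert (min(delays), max(delays)) == (7, 200)

    def test_wrong_row_count_rejected(self, grid):
        rows = ["delay\tamount1\tamount2\tamount3\tamount4\tamount5\tamount6"]
        for d, amts in list(zip(grid.delays, grid.amounts))[:17]:
            rows.append("\t".join(str(int(x)) for x in (d, *amts)))
        with pytest.raises(ob.OfferGridError):
            ob.load_offer_grid(io.StringIO("\n".join(rows)))

    def test_non_integer_cell_rejected(self):
        bad = "delay\tamount1\tamount2\tamount3\tamount4\tamount5\tamount6\n" \
              "7\t25\t26.5\t28\t30\t32\t35\n"
        with pytest.raises(ob.OfferGridError):
            ob.load_offer_grid(io.StringIO(bad))


class TestBuildSession:
    def test_each_pair_twice_216_trials(self, grid):
        trials = ob.build_session(grid, seed=7)
        assert len(trials) == 216
        counts = {}
        for t in trials:
            counts[(t.offer.delay, t.offer.amount)] = counts.get(
                (t.offer.delay, t.offer.amount), 0) + 1
        assert set(counts.values()) == {2}
        assert sorted({t.run_index for t in trials}) == [1, 2]
        assert sum(t.run_index == 1 for t in trials) == 108

    def test_deterministic_under_seed(self, grid):
        a = ob.build_session(grid, seed=3)
        b = ob.build_session(grid, seed=3)
        assert [(t.offer.amount, t.offer.delay, t.onset) for t in a] == \
               [(t.offer.amount, t.offer.delay, t.onset) for t in b]

    def test_itis_within_bounds(self, grid):
        trials = ob.build_session(grid, seed=5)
        for run in (1, 2):
            onsets = [t.onset for t in trials if t.run_index == run]
            gaps = np.diff(onsets) - (ob.DECISION_WINDOW_S + ob.FEEDBACK_S)
            assert np.all(gaps >= ob.ITI_RANGE_S[0] - 1e-9)
            assert np.all(gaps <= ob.ITI_RANGE_S[1] + 1e-9)


class TestDiscountedValue:
    @pytest.mark.parametrize("amount,delay,k,expected", [
        (35, 200, 0.0, 35.0),
        (30, 10, 0.1, 15.0),
        (54, 200, 0.01, 18.0),
    ])
    def test_formula(self, amount, delay, k, expected):
        assert ob.discounted_value(ob.Offer(amount, delay), k) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ob.discounted_value(ob.Offer(30, 10), -0.1)

    @given(k1=st.floats(0, 1), k2=st.floats(0, 1),
           amount=st.integers(25, 54), delay=st.integers(7, 200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decreasing_in_rate(self, k1, k2, amount, delay):
        lo, hi = sorted((k1, k2))
        offer = ob.Offer(amount, delay)
        assert ob.discounted_value(offer, hi) <= ob.discounted_value(offer, lo)


class TestPAccept:
    def test_indifference_at_reference(self):
        for b in (0.0, 0.1, 1.0, 50.0):
            assert ob.p_accept(25.0, b) == pytest.approx(0.5)

    def test_flat_when_slope_zero(self):
        for dsv in (1.0, 25.0, 54.0):
            assert ob.p_accept(dsv, 0.0) == pytest.approx(0.5)

    def test_steep_slope_saturates(self):
        assert ob.p_accept(35.0, 100.0) > 0.999
        assert ob.p_accept(15.0, 100.0) < 0.001

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            ob.p_accept(30.0, -1.0)


def _brute_force_loglik(trials, k, b):
    """Direct product of Bernoulli terms, no shared code with the fit."""
    total = 0.0
    for t in trials:
        p = 1.0 / (1.0 + np.exp(b * (25.0 - t.offer.amount / (1.0 + k * t.offer.delay))))
        total += np.log(p if t.choice == "accept" else 1.0 - p)
    return total


class TestFitDiscounting:
    def test_likelihood_matches_brute_force(self, grid):
        rng = np.random.default_rng(0)
        trials = simulate_choices(ob.build_session(grid, seed=1), 0.02, 0.5, rng)
        for _ in range(20):
            k = float(rng.uniform(1e-4, 0.5))
            b = float(rng.uniform(0.01, 5.0))
            ours = -ob._neg_loglik(
                np.log([k, b]),
                np.array([t.offer.amount for t in trials]),
                np.array([t.offer.delay for t in trials]),
                np.array([t.choice == "accept" for t in trials]),
                25.0,
            )
            assert ours == pytest.approx(_brute_force_loglik(trials, k, b), abs=1e-10)

    def test_recovery_matches_grid_search_oracle(self, grid):
        rng = np.random.default_rng(42)
        trials = []
        for s in range(10):  # ~2000 trials
            trials += simulate_choices(ob.build_session(grid, seed=100 + s), 0.02, 0.5, rng)
        fit = ob.fit_discounting(trials)
        assert abs(fit.k - 0.02) / 0.02 < 0.2
        # dense grid search as an independent check on the optimum
        ks = np.geomspace(1e-4, 0.3, 60)
        bs = np.geomspace(0.05, 5, 40)
        best = max(
            ((k, b, _brute_force_loglik(trials, k, b)) for k in ks for b in bs),
            key=lambda kbv: kbv[2],
        )
        assert fit.loglik >= best[2] - 1e-6
        assert abs(np.log(fit.k) - np.log(best[0])) < 0.2

    def test_flat_likelihood_flagged(self, grid):
        rng = np.random.default_rng(1)
        trials = simulate_choices(ob.build_session(grid, seed=2), 0.02, 0.0, rng)
        fit = ob.fit_discounting(trials)
        assert fit.degenerate and fit.at_bound

    def test_optimum_beats_reference_point(self, grid):
        rng = np.random.default_rng(2)
        trials = simulate_choices(ob.build_session(grid, seed=3), 0.05, 1.0, rng)
        fit = ob.fit_discounting(trials)
        assert fit.loglik >= _brute_force_loglik(trials, 1.0, 1.0)

    def test_one_sided_data_flagged_not_raised(self, grid):
        trials = ob.build_session(grid, seed=4)
        for t in trials:
            t.choice, t.rt = "accept", 1.0
        fit = ob.fit_discounting(trials)
        assert fit.at_bound

    def test_missed_trials_excluded(self, grid):
        rng = np.random.default_rng(3)
        trials = simulate_choices(ob.build_session(grid, seed=5), 0.02, 0.5, rng)
        fit_full = ob.fit_discounting(trials)
        for t in trials[:5]:
            t.choice, t.rt = "missed", None
        fit_missed = ob.fit_discounting(trials)
        assert fit_missed.loglik > fit_full.loglik  # fewer terms


class TestGroupsAndRelativeValue:
    def _trials_with_accept_fraction(self, grid, frac):
        trials = ob.build_session(grid, seed=9)
        n_accept = int(round(frac * len(trials)))
        for i, t in enumerate(trials):
            t.choice = "accept" if i < n_accept else "reject"
            t.rt = 1.0
        return trials

    @pytest.mark.parametrize("frac,expected", [(0.6, "WG"), (0.4, "NG"), (0.5, "NG")])
    def test_group_rule(self, grid, frac, expected):
        assert ob.assign_group(self._trials_with_accept_fraction(grid, frac)) == expected

    def test_no_responses_is_an_error(self, grid):
        trials = ob.build_session(grid, seed=9)
        for t in trials:
            t.choice = "missed"
        with pytest.raises(ValueError):
            ob.assign_group(trials)

    def test_rdsv_sign_flip(self, grid):
        trials = self._trials_with_accept_fraction(grid, 0.6)
        fit = ob.DiscountFit(k=0.01, b=1.0, loglik=0.0, converged=True)
        wg = ob.rdsv_series(trials, fit, "WG")
        ng = ob.rdsv_series(trials, fit, "NG")
        assert np.allclose(wg, -ng)
        dsv = ob.dsv_series(trials, fit)
        assert np.allclose(wg, dsv - 25)
        # value exactly at the reference recodes to zero either way
        assert ob.rdsv_series(
            [ob.TrialRecord(offer=ob.Offer(25, 7), onset=0.0, rt=1.0, choice="accept")],
            ob.DiscountFit(k=0.0, b=1.0, loglik=0.0, converged=True), "WG",
        )[0] == pytest.approx(0.0)


class TestEventsRoundTrip:
    def test_round_trip(self, grid):
        rng = np.random.default_rng(5)
        trials = simulate_choices(ob.build_session(grid, seed=11), 0.02, 0.5, rng)
        trials[0].choice, trials[0].rt = "missed", None
        back = ob.events_to_trials(ob.trials_to_events(trials))
        assert len(back) == len(trials)
        for a, b in zip(trials, back):
            assert (a.offer, a.onset, a.rt, a.choice, a.run_index) == \
                   (b.offer, b.onset, b.rt, b.choice, b.run_index)

    def test_rt_on_missed_trial_rejected(self, grid):
        trials = ob.build_session(grid, seed=12)[:1]
        trials[0].choice, trials[0].rt = "accept", 1.0
        events = ob.trials_to_events(trials)
        events.loc[0, "choice"] = "missed"
        with pytest.raises(ValueError):
            ob.events_to_trials(events)
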
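"""Kaplan-Meier estimation and pseudo-IPD reconstruction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import mcrc_cea as m
from mcrc_cea.km import (
    KMCurve,
    guyot_reconstruct,
    kaplan_meier,
    km_median,
    km_rmst,
)
from mcrc_cea.trial import CensorSpec, emit_digitized_km, simulate_arm_ipd


class TestKaplanMeier:
    def test_hand_computation_all_events(self):
        c = kaplan_meier([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert np.allclose(c.survival, [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_all_censored_stays_at_one(self):
        c = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert c.survival_at(10.0) == 1.0

    def test_events_precede_censors_at_ties(self):
        # {2 event, 2 censored, 3 event}: S(2) = 2/3, S(3) = 0
        c = kaplan_meier([2, 2, 3], [1, 0, 1])
        assert c.survival_at(2.0) == pytest.approx(2.0 / 3.0)
        assert c.survival_at(3.0) == pytest.approx(0.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [1, 1])

    @given(
        times=st.lists(st.floats(0.1, 50.0), min_size=1, max_size=30),
        events=st.data(),
    )
    @hyp_settings(max_examples=40, deadline=None)
    def test_step_function_invariants(self, times, events):
        flags = events.draw(
            st.lists(st.integers(0, 1), min_size=len(times), max_size=len(times))
        )
        c = kaplan_meier(times, flags)
        assert np.all(np.diff(c.survival) <= 1e-12)
        if len(c.survival):
            assert c.survival.min() >= -1e-12 and c.survival[0] <= 1.0


class TestMedianAndRmst:
    def test_first_time_at_or_below_half(self):
        c = kaplan_meier([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert km_median(c) == 3.0

    def test_not_reached(self):
        c = kaplan_meier([1, 2, 3], [1, 0, 0])
        assert km_median(c) is None

    def test_exact_half_counts(self):
        # 2 events out of 4 at t=10: S(10) = 0.5 -> median 10 (<= rule)
        c = kaplan_meier([10, 10, 20, 20], [1, 1, 0, 0])
        assert km_median(c) == 10.0

    def test_rmst_step_integral(self):
        c = kaplan_meier([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        # integral of steps 1,.8,.6,.4,.2 over unit gaps
        assert km_rmst(c, 5.0) == pytest.approx(1 + 0.8 + 0.6 + 0.4 + 0.2)


def _exhaustive_reconstruct(t, s, trisk, nrisk):
    """Brute-force oracle: enumerate all integer event/censor allocations.

    Returns (best_max_dev, best_events_per_click).  Censors are allocated per
    click gap; interior risk-table targets must be matched exactly.  Only
    feasible for tiny instances.
    """
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    n0 = int(nrisk[0])
    boundaries = {}
    for j in range(1, len(trisk)):
        # index of first click >= trisk[j]
        boundaries[int(np.searchsorted(t, trisk[j], side="left"))] = int(nrisk[j])

    best = [np.inf, None]

    def recurse(i, n_at_risk, km, devs, events):
        if i in boundaries and boundaries[i] != n_at_risk:
            return
        if i == len(t):
            dev = max(devs) if devs else 0.0
            if dev < best[0]:
                best[0], best[1] = dev, list(events)
            return
        if max(devs, default=0.0) >= best[0]:
            return
        for d in range(n_at_risk + 1):
            km_new = km * (1 - d / n_at_risk) if n_at_risk else km
            dev = abs(km_new - s[i])
            for c in range(n_at_risk - d + 1):
                recurse(i + 1, n_at_risk - d - c, km_new, devs + [dev], events + [d])

    recurse(0, n0, 1.0, [], [])
    return best[0], best[1]


class TestGuyotReconstruction:
    def test_single_interval_forced_split(self):
        # survival 1.0 -> 0.5 with at-risk 10 -> 4: 5 events, 1 censor
        curve = pd.DataFrame({"time_months": [0.0, 1.0], "survival": [1.0, 0.5]})
        risk = pd.DataFrame({"time_months": [0.0, 2.0], "n_at_risk": [10, 4]})
        res = guyot_reconstruct(curve, risk)
        assert res.interval_events[0] == 5
        assert res.interval_censors[0] == 1
        # exhaustive-search oracle agrees this split is optimal
        dev, events = _exhaustive_reconstruct(
            [0.0, 1.0], [1.0, 0.5], [0.0, 2.0], [10, 4]
        )
        assert events[1] == 5
        assert res.max_abs_deviation == pytest.approx(dev, abs=1e-12)

    def test_no_censoring_counts_forced(self, arm_specs):
        ipd = simulate_arm_ipd(arm_specs[("control", "PFS")], 20, None, seed=3)
        ts = np.sort(ipd["time_months"].to_numpy())
        curve, risk = emit_digitized_km(
            ipd, np.concatenate(([0.0], ts)), np.arange(0.0, ts.max(), 6.0)
        )
        res = guyot_reconstruct(curve, risk)
        assert res.max_abs_deviation == pytest.approx(0.0, abs=1e-12)
        assert res.pseudo_ipd["event"].sum() == 20
        # exact event times recovered (4-decimal rounding)
        assert np.allclose(
            np.sort(res.pseudo_ipd.loc[res.pseudo_ipd.event == 1, "time_months"]),
            np.round(ts, 4),
            atol=1e-4,
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_small_instances(self, seed):
        # corner-digitized instances, n <= 12, <= 3 intervals: the iterative
        # algorithm must achieve the exhaustive search's optimal deviation
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        times = np.sort(rng.uniform(0.5, 11.5, n))
        events = rng.integers(0, 2, n)
        events[0] = 1
        curve_km = kaplan_meier(times, events)
        t = np.concatenate(([0.0], curve_km.times))
        s = np.concatenate(([1.0], curve_km.survival))
        trisk = [0.0, 4.0, 8.0]
        nrisk = [(times >= tt - 1e-12).sum() for tt in trisk]
        res = guyot_reconstruct(
            pd.DataFrame({"time_months": t, "survival": s}),
            pd.DataFrame({"time_months": trisk, "n_at_risk": nrisk}),
        )
        dev_opt, _ = _exhaustive_reconstruct(t, s, trisk, nrisk)
        assert res.max_abs_deviation <= dev_opt + 1e-9

    def test_conservation_of_subjects(self, arm_specs):
        ipd = simulate_arm_ipd(
            arm_specs[("control", "PFS")], 102, CensorSpec(), seed=5
        )
        tmax = ipd["time_months"].max()
        curve, risk = emit_digitized_km(
            ipd, np.linspace(0, tmax, 25), np.arange(0, tmax, 3.0)
        )
        res = guyot_reconstruct(curve, risk)
        assert len(res.pseudo_ipd) == 102
        assert sum(res.interval_events) + sum(res.interval_censors) == 102

    @pytest.mark.parametrize("seed", list(range(10)))
    def test_round_trip_median_and_rmst(self, seed, arm_specs):
        """Synthesize -> KM -> digitize -> reconstruct preserves the survival
        summaries; per-seed errors are recorded by the acceptance suite."""
        ipd = simulate_arm_ipd(
            arm_specs[("control", "PFS")], 102, CensorSpec(), seed=seed
        )
        tmax = ipd["time_months"].max()
        curve, risk = emit_digitized_km(
            ipd, np.linspace(0, tmax, 25), np.arange(0, tmax, 3.0)
        )
        # uniform grid samples (not step corners): midgap placement avoids
        # the systematic rightward bias in reconstructed event times
        res = guyot_reconstruct(curve, risk, event_placement="midgap")
        km_src = kaplan_meier(ipd["time_months"], ipd["event"])
        km_rec = kaplan_meier(res.pseudo_ipd["time_months"], res.pseudo_ipd["event"])
        med_err = abs(km_median(km_rec) - km_median(km_src)) / km_median(km_src)
        rmst_err = abs(km_rmst(km_rec, 30) - km_rmst(km_src, 30)) / km_rmst(km_src, 30)
        # a 25-point grid quantizes the median to ~half a grid step
        assert med_err <= 0.10
        assert rmst_err <= 0.05
        assert res.max_abs_deviation <= 0.05

    def test_inconsistent_risk_table_rejected(self):
        curve = pd.DataFrame({"time_months": [0.0, 1.0], "survival": [1.0, 0.5]})
        risk = pd.DataFrame({"time_months": [0.0, 2.0], "n_at_risk": [10, 12]})
        with pytest.raises(ValueError):
            guyot_reconstruct(curve, risk)

    def test_noisy_coordinates_isotonically_clipped(self):
        # a small digitization inversion must not crash reconstruction
        curve = pd.DataFrame(
            {"time_months": [0.0, 1.0, 2.0, 3.0], "survival": [1.0, 0.7, 0.72, 0.4]}
        )
        risk = pd.DataFrame({"time_months": [0.0, 4.0], "n_at_risk": [10, 2]})
        res = guyot_reconstruct(curve, risk)
        rec = kaplan_meier(res.pseudo_ipd["time_months"], res.pseudo_ipd["event"])
        assert np.all(np.diff(rec.survival) <= 1e-12)
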
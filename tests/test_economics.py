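"""Costs, utilities, accumulation and ICER arithmetic."""

import numpy as np
import pytest

import mcrc_cea as m
from mcrc_cea.cohort import DAYS_PER_YEAR, ModelSettings, StateTrace
from mcrc_cea.economics import (
    ArmResult,
    DrugDose,
    Patient,
    accumulate,
    arm_value_vectors,
    cycle_values,
    dose_cost,
    icer,
    run_cea,
    with_aci_price,
)


class TestDoseCost:
    def test_weight_based_bevacizumab(self, patient):
        drug = DrugDose("bevacizumab", 7.5, "per_kg", 1)
        # 7.5 mg/kg x 65 kg = 487.5 mg
        assert drug.mg_per_cycle(patient) == pytest.approx(487.5)
        assert dose_cost(drug, patient, {"bevacizumab": 2.0}) == pytest.approx(975.0)

    def test_bsa_based_oxaliplatin(self, patient):
        drug = DrugDose("oxaliplatin", 130.0, "per_m2", 1)
        # 130 mg/m2 x 1.79 m2 = 232.7 mg
        assert drug.mg_per_cycle(patient) == pytest.approx(232.7)

    def test_zero_price_gives_zero(self, patient):
        drug = DrugDose("capecitabine", 1000.0, "per_m2", 28)
        assert dose_cost(drug, patient, {"capecitabine": 0.0}) == 0.0

    def test_unknown_drug_rejected(self, patient):
        with pytest.raises(KeyError):
            dose_cost(DrugDose("nivolumab", 3.0, "per_kg"), patient, {})


class TestCycleValues:
    def test_aci_price_charged_in_induction(self, econ, schedule, patient, settings):
        cost_aci, _ = cycle_values("aci", 3, "PFS", econ, schedule, patient, settings)
        cost_ctl, _ = cycle_values("control", 3, "PFS", econ, schedule, patient,
                                   settings)
        assert cost_aci - cost_ctl == pytest.approx(6819.45)

    def test_maintenance_drops_oxaliplatin_and_aci(self, econ, schedule, patient,
                                                   settings):
        c_ind, _ = cycle_values("control", 6, "PFS", econ, schedule, patient, settings)
        c_mnt, _ = cycle_values("control", 7, "PFS", econ, schedule, patient, settings)
        oxali = dose_cost(DrugDose("oxaliplatin", 130.0, "per_m2"), patient,
                          econ.drug_prices)
        assert c_ind - c_mnt == pytest.approx(oxali)
        c_aci_mnt, _ = cycle_values("aci", 7, "PFS", econ, schedule, patient, settings)
        assert c_aci_mnt == pytest.approx(c_mnt)

    def test_first_cycle_ae_terms_vanish_without_incidence(self, econ, schedule,
                                                           patient, settings):
        import dataclasses

        no_ae = dataclasses.replace(econ, ae_items=())
        v1 = cycle_values("aci", 1, "PFS", no_ae, schedule, patient, settings)
        v2 = cycle_values("aci", 2, "PFS", no_ae, schedule, patient, settings)
        assert v1 == pytest.approx(v2)

    def test_first_cycle_disutility_subtracted(self, econ, schedule, patient,
                                               settings):
        _, q1 = cycle_values("aci", 1, "PFS", econ, schedule, patient, settings)
        _, q2 = cycle_values("aci", 2, "PFS", econ, schedule, patient, settings)
        expected_loss = sum(
            ae.incidence["aci"] * ae.disutility * ae.duration_days / DAYS_PER_YEAR
            for ae in econ.ae_items
        )
        assert q2 - q1 == pytest.approx(expected_loss)

    def test_vectorized_values_match_scalar(self, econ, schedule, patient, settings):
        cost_pfs, qaly_pfs, cost_pd, qaly_pd = arm_value_vectors(
            "aci", econ, schedule, patient, settings
        )
        for j in (1, 2, 6, 7, 100):
            c, q = cycle_values("aci", j, "PFS", econ, schedule, patient, settings)
            assert cost_pfs[j - 1] == pytest.approx(c)
            assert qaly_pfs[j - 1] == pytest.approx(q)
        c_pd, q_pd = cycle_values("aci", 10, "PD", econ, schedule, patient, settings)
        assert cost_pd == pytest.approx(c_pd)
        assert qaly_pd == pytest.approx(q_pd)

    def test_invalid_inputs_rejected(self, econ, schedule, patient, settings):
        with pytest.raises(ValueError):
            cycle_values("aci", 0, "PFS", econ, schedule, patient, settings)
        with pytest.raises(ValueError):
            cycle_values("aci", 1, "Death", econ, schedule, patient, settings)


def _toy_trace(settings, pfs, pd_, death, entrants=None):
    n = settings.n_cycles
    import numpy as np

    d = m.per_cycle_discount(settings.discount_annual, settings.cycle_days)
    return StateTrace(
        times_months=np.arange(n + 1) * settings.cycle_months,
        pfs=np.asarray(pfs, float),
        pd=np.asarray(pd_, float),
        death=np.asarray(death, float),
        discount=d ** np.arange(n + 1),
        pd_entrants=np.asarray(entrants if entrants is not None else np.zeros(n + 1)),
        settings=settings,
    )


class TestAccumulate:
    def test_immediate_death_costs_terminal_only(self, econ, schedule, patient):
        settings = ModelSettings(horizon_years=1.0, n_cycles_override=2)
        tr = _toy_trace(settings, [0, 0, 0], [0, 0, 0], [1, 1, 1])
        # death occurs before cycle 0 ends: no incremental deaths, no state costs
        res = accumulate(tr, "control", econ, schedule, patient)
        assert res.total_cost == 0.0
        tr2 = _toy_trace(settings, [1, 0, 0], [0, 0, 0], [0, 1, 1])
        res2 = accumulate(tr2, "control", econ, schedule, patient)
        c1, _ = cycle_values("control", 1, "PFS", econ, schedule, patient, settings)
        assert res2.total_cost == pytest.approx(c1 + econ.terminal_cost)

    def test_single_cycle_qaly_hand_value(self, econ, schedule, patient):
        import dataclasses

        settings = ModelSettings(horizon_years=1.0, n_cycles_override=1)
        no_ae = dataclasses.replace(econ, ae_items=(),
                                    u_pfs={"aci": 0.8, "control": 0.8})
        tr = _toy_trace(settings, [1, 1], [0, 0], [0, 0])
        res = accumulate(tr, "control", no_ae, schedule, patient)
        assert res.total_qaly == pytest.approx(0.8 * 21.0 / 365.25)

    def test_discounting_reduces_totals(self, curve_sets, econ, schedule, patient):
        control = curve_sets[0]
        undisc = m.occupancy_trace(control.pfs, control.os,
                                   ModelSettings(discount_annual=0.0))
        disc = m.occupancy_trace(control.pfs, control.os, ModelSettings())
        r0 = accumulate(undisc, "control", econ, schedule, patient)
        r5 = accumulate(disc, "control", econ, schedule, patient)
        assert r0.total_cost > r5.total_cost
        assert r0.total_qaly > r5.total_qaly


class TestIcer:
    def test_printed_table_arithmetic(self):
        # worked example from the published per-arm totals
        res = icer(ArmResult("aci", 108136.35, 3.91), ArmResult("control", 46106.57, 2.18))
        assert res.incremental_cost == pytest.approx(62029.78, abs=0.01)
        assert res.incremental_qaly == pytest.approx(1.73, abs=1e-9)
        assert res.icer == pytest.approx(62029.78 / 1.73, abs=0.01)

    def test_zero_incremental_cost(self):
        res = icer(ArmResult("aci", 100.0, 2.0), ArmResult("control", 100.0, 1.0))
        assert res.icer == 0.0

    def test_dominance_labels(self):
        assert icer(ArmResult("aci", 90.0, 2.0),
                    ArmResult("control", 100.0, 1.0)).label == "dominant"
        assert icer(ArmResult("aci", 110.0, 1.0),
                    ArmResult("control", 100.0, 2.0)).label == "dominated"

    def test_undefined_when_equal_qalys(self):
        res = icer(ArmResult("aci", 110.0, 1.0), ArmResult("control", 100.0, 1.0))
        assert res.icer is None and res.label == "undefined"


class TestPriceStructure:
    def test_cost_affine_increasing_in_aci_price(self, curve_sets, econ, settings,
                                                 schedule, patient):
        control, aci = curve_sets
        costs = []
        for p in (0.0, 1000.0, 2000.0):
            res = run_cea(control, aci, with_aci_price(econ, p), settings,
                          schedule, patient)
            costs.append(res.incremental_cost)
        slope1 = costs[1] - costs[0]
        slope2 = costs[2] - costs[1]
        assert slope1 > 0
        assert slope1 == pytest.approx(slope2, rel=1e-9)

    def test_qalys_invariant_to_prices(self, curve_sets, econ, settings, schedule,
                                       patient):
        control, aci = curve_sets
        import dataclasses

        expensive = dataclasses.replace(
            with_aci_price(econ, 99999.0),
            drug_prices={k: v * 10 for k, v in econ.drug_prices.items()},
        )
        a = run_cea(control, aci, econ, settings, schedule, patient)
        b = run_cea(control, aci, expensive, settings, schedule, patient)
        assert a.qaly_aci == b.qaly_aci
        assert a.qaly_control == b.qaly_control

    def test_raising_u_pd_raises_both_arms(self, curve_sets, econ, settings,
                                           schedule, patient):
        import dataclasses

        control, aci = curve_sets
        hi = dataclasses.replace(econ, u_pd=econ.u_pd + 0.1)
        a = run_cea(control, aci, econ, settings, schedule, patient)
        b = run_cea(control, aci, hi, settings, schedule, patient)
        assert b.qaly_aci > a.qaly_aci
        assert b.qaly_control > a.qaly_control
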
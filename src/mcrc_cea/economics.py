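"""Costs, utilities, and incremental cost-effectiveness.

Attaches per-cycle costs and utilities to a cohort trace:

* drug acquisition from the dosing schedule (bevacizumab 7.5 mg/kg d1,
  oxaliplatin 130 mg/m2 d1, capecitabine 1,000 mg/m2 twice daily d1-14,
  repeated every 21 days for six induction cycles; maintenance thereafter is
  bevacizumab + capecitabine), with the ACI infusion priced per cycle during
  induction in the immunotherapy arm;
* grade >=3 adverse events with incidence > 2%, costed in the first cycle and
  their disutilities subtracted after duration adjustment;
* best supportive care + follow-up in the PD state, a one-off
  subsequent-therapy cost on PD entry weighted by the uptake probability, and
  a terminal-care cost charged on each incremental death;
* utilities per health state converted to QALYs at 21/365.25 years per cycle,
  discounted per cycle.

Only direct medical costs are modelled.  The default parameter values live in
:mod:`mcrc_cea.config`; they are a documented plausible set for the Chinese
healthcare system, not trial-specific inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import DAYS_PER_YEAR, ModelSettings, StateTrace, occupancy_trace
from .fitting import CurveSet

ARMS = ("control", "aci")
STATES = ("PFS", "PD")


@dataclass(frozen=True)
class Patient:
    height_cm: float = 165.0
    weight_kg: float = 65.0
    bsa_m2: float = 1.79  # config-supplied average body surface area

    def __post_init__(self) -> None:
        if min(self.height_cm, self.weight_kg, self.bsa_m2) <= 0:
            raise ValueError("patient measurements must be > 0")


@dataclass(frozen=True)
class DrugDose:
    """One drug administration pattern within a 21-day cycle."""

    name: str
    dose: float            # mg per kg, per m2, or absolute mg
    basis: str             # "per_kg" | "per_m2" | "flat"
    doses_per_cycle: int = 1

    def mg_per_cycle(self, patient: Patient) -> float:
        if self.basis == "per_kg":
            unit = self.dose * patient.weight_kg
        elif self.basis == "per_m2":
            unit = self.dose * patient.bsa_m2
        elif self.basis == "flat":
            unit = self.dose
        else:
            raise ValueError(f"unknown dosing basis {self.basis!r}")
        return unit * self.doses_per_cycle


@dataclass(frozen=True)
class Schedule:
    """XELOX + bevacizumab regimen: 6 induction cycles then maintenance.

    Capecitabine 1,000 mg/m2 is interpreted as twice daily on days 1-14
    (standard XELOX); the frequency is exposed via ``doses_per_cycle``.
    """

    induction_cycles: int = 6
    induction_drugs: tuple[DrugDose, ...] = (
        DrugDose("bevacizumab", 7.5, "per_kg", 1),
        DrugDose("oxaliplatin", 130.0, "per_m2", 1),
        DrugDose("capecitabine", 1000.0, "per_m2", 28),
    )
    maintenance_drugs: tuple[DrugDose, ...] = (
        DrugDose("bevacizumab", 7.5, "per_kg", 1),
        DrugDose("capecitabine", 1000.0, "per_m2", 28),
    )

    def __post_init__(self) -> None:
        if self.induction_cycles < 0:
            raise ValueError("induction_cycles must be >= 0")


@dataclass(frozen=True)
class AEItem:
    """A grade >=3 adverse event included in the model (incidence > 2%)."""

    name: str
    incidence: dict  # arm -> probability
    cost: float      # management cost, $ per affected patient
    disutility: float
    duration_days: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.disutility < 0 or self.duration_days < 0:
            raise ValueError("AE cost/disutility/duration must be >= 0")
        for v in self.incidence.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("AE incidence must lie in [0, 1]")


@dataclass(frozen=True)
class EconParams:
    """Unit costs and utilities (all monetary values in US$)."""

    drug_prices: dict          # name -> $ per mg
    aci_price_per_cycle: float = 6819.45
    ae_items: tuple[AEItem, ...] = ()
    u_pfs: dict = field(default_factory=lambda: {"aci": 0.82, "control": 0.80})
    u_pd: float = 0.58
    subsequent_tx_prob: dict = field(
        default_factory=lambda: {"aci": 0.560, "control": 0.647}
    )
    subsequent_tx_cost: float = 8000.0     # lump sum on PD entry
    bsc_cost_per_cycle: float = 400.0
    followup_cost_per_cycle: float = 150.0
    terminal_cost: float = 2000.0

    def __post_init__(self) -> None:
        for u in (*self.u_pfs.values(), self.u_pd):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")
        for p in self.subsequent_tx_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        costs = [
            self.aci_price_per_cycle,
            self.subsequent_tx_cost,
            self.bsc_cost_per_cycle,
            self.followup_cost_per_cycle,
            self.terminal_cost,
            *self.drug_prices.values(),
        ]
        if any(c < 0 for c in costs):
            raise ValueError("costs must be >= 0")


def dose_cost(drug: DrugDose, patient: Patient, prices: dict) -> float:
    """Cost of one cycle's administrations of one drug (mg x unit price)."""
    if drug.name not in prices:
        raise KeyError(f"no unit price for drug {drug.name!r}")
    return drug.mg_per_cycle(patient) * prices[drug.name]


def _ae_first_cycle(arm: str, econ: EconParams) -> tuple[float, float]:
    """Expected AE management cost and duration-adjusted QALY loss, cycle 1."""
    cost = sum(ae.incidence[arm] * ae.cost for ae in econ.ae_items)
    qaly_loss = sum(
        ae.incidence[arm] * ae.disutility * ae.duration_days / DAYS_PER_YEAR
        for ae in econ.ae_items
    )
    return cost, qaly_loss


def cycle_values(
    arm: str,
    cycle_index: int,
    state: str,
    econ: EconParams,
    schedule: Schedule,
    patient: Patient,
    settings: ModelSettings,
) -> tuple[float, float]:
    """(cost, QALY) accrued over one cycle at full occupancy of ``state``.

    ``cycle_index`` is 1-based.  PFS cycles within the induction window accrue
    induction drugs (plus the ACI price in the immunotherapy arm); later PFS
    cycles accrue maintenance.  The first cycle adds the expected AE cost and
    subtracts the duration-adjusted AE disutility.  PD cycles accrue BSC +
    follow-up.  One-off costs (subsequent therapy on PD entry, terminal care)
    are handled in :func:`accumulate`, not here.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}")
    cyc_years = settings.cycle_years
    if state == "PFS":
        drugs = (
            schedule.induction_drugs
            if cycle_index <= schedule.induction_cycles
            else schedule.maintenance_drugs
        )
        cost = sum(dose_cost(d, patient, econ.drug_prices) for d in drugs)
        if arm == "aci" and cycle_index <= schedule.induction_cycles:
            cost += econ.aci_price_per_cycle
        qaly = econ.u_pfs[arm] * cyc_years
        if cycle_index == 1:
            ae_cost, ae_loss = _ae_first_cycle(arm, econ)
            cost += ae_cost
            qaly -= ae_loss
    else:
        cost = econ.bsc_cost_per_cycle + econ.followup_cost_per_cycle
        qaly = econ.u_pd * cyc_years
    return cost, qaly


def arm_value_vectors(
    arm: str,
    econ: EconParams,
    schedule: Schedule,
    patient: Patient,
    settings: ModelSettings,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Vectorized per-cycle values: (cost_pfs[j], qaly_pfs[j], cost_pd, qaly_pd).

    Index j = 0 corresponds to cycle 1.  Equivalent to calling
    :func:`cycle_values` cycle by cycle.
    """
    n = settings.n_cycles
    ind_cost = sum(
        dose_cost(d, patient, econ.drug_prices) for d in schedule.induction_drugs
    )
    maint_cost = sum(
        dose_cost(d, patient, econ.drug_prices) for d in schedule.maintenance_drugs
    )
    j = np.arange(1, n + 1)
    cost_pfs = np.where(j <= schedule.induction_cycles, ind_cost, maint_cost).astype(
        float
    )
    if arm == "aci":
        cost_pfs[j <= schedule.induction_cycles] += econ.aci_price_per_cycle
    qaly_pfs = np.full(n, econ.u_pfs[arm] * settings.cycle_years)
    ae_cost, ae_loss = _ae_first_cycle(arm, econ)
    if n > 0:
        cost_pfs[0] += ae_cost
        qaly_pfs[0] -= ae_loss
    cost_pd = econ.bsc_cost_per_cycle + econ.followup_cost_per_cycle
    qaly_pd = econ.u_pd * settings.cycle_years
    return cost_pfs, qaly_pfs, cost_pd, qaly_pd


@dataclass
class ArmResult:
    arm: str
    total_cost: float
    total_qaly: float


def accumulate(
    trace: StateTrace,
    arm: str,
    econ: EconParams,
    schedule: Schedule,
    patient: Patient,
) -> ArmResult:
    """Discounted total cost and QALY for one arm over the trace horizon.

    State values use start-of-cycle occupancy (or the start/end average under
    the half-cycle correction); subsequent-therapy and terminal-care lump
    sums are charged in the cycle they occur.
    """
    settings = trace.settings
    n = settings.n_cycles
    cost_pfs, qaly_pfs, cost_pd, qaly_pd = arm_value_vectors(
        arm, econ, schedule, patient, settings
    )
    if settings.half_cycle_correction:
        occ_pfs = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
        occ_pd = 0.5 * (trace.pd[:-1] + trace.pd[1:])
    else:
        occ_pfs = trace.pfs[:-1]
        occ_pd = trace.pd[:-1]
    d = trace.discount[:-1]
    cost = float(np.sum(d * (occ_pfs * cost_pfs + occ_pd * cost_pd)))
    qaly = float(np.sum(d * (occ_pfs * qaly_pfs + occ_pd * qaly_pd)))
    # one-off costs: subsequent therapy on PD entry, terminal care on death
    entrants = trace.pd_entrants[1:]
    cost += float(
        np.sum(d * entrants) * econ.subsequent_tx_prob[arm] * econ.subsequent_tx_cost
    )
    deaths = np.diff(trace.death)
    cost += float(np.sum(d * deaths) * econ.terminal_cost)
    return ArmResult(arm=arm, total_cost=cost, total_qaly=qaly)


@dataclass
class CEAResult:
    """Cost-effectiveness comparison of the ACI arm vs control."""

    cost_aci: float
    qaly_aci: float
    cost_control: float
    qaly_control: float
    incremental_cost: float
    incremental_qaly: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "undefined"


def icer(result_aci: ArmResult, result_control: ArmResult) -> CEAResult:
    """Incremental cost-effectiveness ratio with dominance labelling."""
    dc = result_aci.total_cost - result_control.total_cost
    de = result_aci.total_qaly - result_control.total_qaly
    if abs(de) < 1e-9:
        value, label = None, "undefined"
    elif de > 0 and dc <= 0:
        value, label = dc / de, "dominant"
    elif de < 0 and dc >= 0:
        value, label = dc / de, "dominated"
    else:
        value, label = dc / de, "icer"
    return CEAResult(
        cost_aci=result_aci.total_cost,
        qaly_aci=result_aci.total_qaly,
        cost_control=result_control.total_cost,
        qaly_control=result_control.total_qaly,
        incremental_cost=dc,
        incremental_qaly=de,
        icer=value,
        label=label,
    )


def evaluate_arm(
    curves: CurveSet,
    econ: EconParams,
    settings: ModelSettings,
    schedule: Schedule,
    patient: Patient,
    trace: StateTrace | None = None,
) -> ArmResult:
    """Build (or reuse) the occupancy trace for an arm and accumulate values."""
    if trace is None:
        trace = occupancy_trace(curves.pfs, curves.os, settings)
    return accumulate(trace, curves.arm_label, econ, schedule, patient)


def run_cea(
    control_curves: CurveSet,
    aci_curves: CurveSet,
    econ: EconParams,
    settings: ModelSettings,
    schedule: Schedule | None = None,
    patient: Patient | None = None,
    traces: tuple[StateTrace, StateTrace] | None = None,
) -> CEAResult:
    """Full base-case evaluation: both arms under identical settings."""
    schedule = schedule or Schedule()
    patient = patient or Patient()
    tr_ctrl, tr_aci = traces if traces is not None else (None, None)
    res_ctrl = evaluate_arm(control_curves, econ, settings, schedule, patient, tr_ctrl)
    res_aci = evaluate_arm(aci_curves, econ, settings, schedule, patient, tr_aci)
    return icer(res_aci, res_ctrl)


def with_aci_price(econ: EconParams, price: float) -> EconParams:
    """Copy of the parameter set with a different ACI per-cycle price."""
    if price < 0:
        raise ValueError("price must be >= 0")
    return replace(econ, aci_price_per_cycle=price)
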
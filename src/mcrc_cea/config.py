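"""Configuration: default parameter set, YAML load/save, curve-set builders.

The default economic inputs are a *plausible defaults* set for the Chinese
healthcare system (post-negotiation biosimilar/generic price magnitudes and
published mCRC health-state utilities).  The source trial's supplementary
cost/utility tables are not publicly available, so these values are the
package's own documented calibration; they are chosen so the base case sits
in the published magnitude range and are exercised by property-based tests
rather than value-matching ones.  Every default can be overridden from a YAML
config file (see ``default_config_dict`` / ``load_config``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import yaml

from . import trial
from .cohort import ModelSettings
from .economics import AEItem, EconParams, Patient, Schedule
from .fitting import CurveSet

#: 2024 per-capita GDP anchor used for WTP thresholds (3x GDP = $36,721.86)
GDP_PER_CAPITA = 36721.86 / 3.0
WTP_MULTIPLIERS = (1.5, 1.94, 3.0)


def default_ae_items() -> tuple[AEItem, ...]:
    """Grade >=3 AEs with incidence > 2% (anemia, neutropenia, leukopenia,
    thrombocytopenia); per-arm incidences sum to the trial's overall 20.0% /
    23.5% grade >=3 rates.  Costs, disutilities and durations are plausible
    literature-scale values, not trial-specific inputs."""
    return (
        AEItem("anemia", {"aci": 0.045, "control": 0.055}, 500.0, 0.07, 14.0),
        AEItem("neutropenia", {"aci": 0.070, "control": 0.085}, 700.0, 0.09, 10.0),
        AEItem("leukopenia", {"aci": 0.050, "control": 0.060}, 600.0, 0.09, 10.0),
        AEItem("thrombocytopenia", {"aci": 0.035, "control": 0.035}, 800.0, 0.05, 12.0),
    )


def default_econ_params() -> EconParams:
    return EconParams(
        drug_prices={
            # $ per mg, post-NRDL biosimilar/generic magnitude
            "bevacizumab": 0.45,
            "oxaliplatin": 0.85,
            "capecitabine": 0.002,
        },
        aci_price_per_cycle=6819.45,
        ae_items=default_ae_items(),
        u_pfs={"aci": 0.82, "control": 0.80},
        u_pd=0.58,
        subsequent_tx_prob={"aci": 0.560, "control": 0.647},
        subsequent_tx_cost=8000.0,
        bsc_cost_per_cycle=400.0,
        followup_cost_per_cycle=150.0,
        terminal_cost=2000.0,
    )


def default_settings() -> ModelSettings:
    return ModelSettings()


def trial_curve_sets() -> tuple[CurveSet, CurveSet]:
    """(control, aci) curve sets from the calibrated trial generator."""
    specs = trial.default_arm_specs()
    control = CurveSet(
        arm_label="control",
        s_pfs=specs[("control", trial.PFS)].survival(),
        s_os=specs[("control", trial.OS)].survival(),
    )
    aci = CurveSet(
        arm_label="aci",
        s_pfs=specs[("aci", trial.PFS)].survival(),
        s_os=specs[("aci", trial.OS)].survival(),
    )
    return control, aci


def default_config_dict() -> dict:
    """Full default configuration as a plain dict (YAML-serializable)."""
    econ = default_econ_params()
    return {
        "trial": {
            "pfs_median_control": trial.TRIAL_SUMMARY["pfs_median_control"],
            "pfs_median_aci": trial.TRIAL_SUMMARY["pfs_median_aci"],
            "pfs_hr": trial.TRIAL_SUMMARY["pfs_hr"],
            "os_median_control": trial.TRIAL_SUMMARY["os_median_control"],
            "os_hr": trial.TRIAL_SUMMARY["os_hr"],
            "n_per_arm": dict(trial.TRIAL_SUMMARY["n_per_arm"]),
            # censoring is an assumption: the trial's follow-up is unreported
            "censoring": {"accrual_window": 18.0, "max_followup": 36.0,
                          "assumed": True},
        },
        "settings": {
            "cycle_days": 21.0,
            "horizon_years": 20.0,
            "discount_annual": 0.05,
            "half_cycle_correction": False,
            "n_cycles_override": None,
        },
        "patient": {"height_cm": 165.0, "weight_kg": 65.0, "bsa_m2": 1.79},
        "schedule": {"induction_cycles": 6, "capecitabine_doses_per_cycle": 28},
        "economics": {
            "drug_prices": dict(econ.drug_prices),
            "aci_price_per_cycle": econ.aci_price_per_cycle,
            "u_pfs": dict(econ.u_pfs),
            "u_pd": econ.u_pd,
            "subsequent_tx_prob": dict(econ.subsequent_tx_prob),
            "subsequent_tx_cost": econ.subsequent_tx_cost,
            "bsc_cost_per_cycle": econ.bsc_cost_per_cycle,
            "followup_cost_per_cycle": econ.followup_cost_per_cycle,
            "terminal_cost": econ.terminal_cost,
            "ae_items": [
                {
                    "name": ae.name,
                    "incidence": dict(ae.incidence),
                    "cost": ae.cost,
                    "disutility": ae.disutility,
                    "duration_days": ae.duration_days,
                }
                for ae in econ.ae_items
            ],
        },
        "uncertainty": {
            "n_psa": 1000,
            "variation_default": 0.25,
            "variation_high_uncertainty": 0.30,
            "discount_range": [0.0, 0.08],
        },
        "price": {
            "gdp_per_capita": GDP_PER_CAPITA,
            "wtp_multipliers": list(WTP_MULTIPLIERS),
        },
        "scenarios": {"horizon_years": [10, 15, 20]},
    }


@dataclass
class Config:
    """Parsed configuration bundle."""

    raw: dict
    settings: ModelSettings
    econ: EconParams
    patient: Patient
    schedule: Schedule


def config_from_dict(d: dict) -> Config:
    base = default_config_dict()
    merged = _deep_merge(base, d or {})
    s = merged["settings"]
    settings = ModelSettings(
        cycle_days=s["cycle_days"],
        horizon_years=s["horizon_years"],
        discount_annual=s["discount_annual"],
        half_cycle_correction=s["half_cycle_correction"],
        n_cycles_override=s["n_cycles_override"],
    )
    e = merged["economics"]
    econ = EconParams(
        drug_prices=dict(e["drug_prices"]),
        aci_price_per_cycle=e["aci_price_per_cycle"],
        ae_items=tuple(
            AEItem(a["name"], dict(a["incidence"]), a["cost"], a["disutility"],
                   a["duration_days"])
            for a in e["ae_items"]
        ),
        u_pfs=dict(e["u_pfs"]),
        u_pd=e["u_pd"],
        subsequent_tx_prob=dict(e["subsequent_tx_prob"]),
        subsequent_tx_cost=e["subsequent_tx_cost"],
        bsc_cost_per_cycle=e["bsc_cost_per_cycle"],
        followup_cost_per_cycle=e["followup_cost_per_cycle"],
        terminal_cost=e["terminal_cost"],
    )
    p = merged["patient"]
    patient = Patient(p["height_cm"], p["weight_kg"], p["bsa_m2"])
    schedule = Schedule(induction_cycles=merged["schedule"]["induction_cycles"])
    return Config(raw=merged, settings=settings, econ=econ, patient=patient,
                  schedule=schedule)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path) -> Config:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return config_from_dict(d)


def save_config(d: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
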
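"""Deterministic (tornado) and probabilistic sensitivity analyses.

OWSA varies each parameter to its lower/upper bound (default +/-25%,
high-uncertainty cost items +/-30%, discount rate over 0-8%) with two full
model evaluations per row, sorted by ICER range for the tornado diagram.

PSA draws 1,000 Monte Carlo parameter vectors — gamma for costs, beta for
probabilities/proportions/utilities, moment-matched from (mean, sd) — and
re-evaluates the model per draw.  Dispersions default to
sd = (high - low) / (2 * 1.96), tying the PSA spread to the OWSA bounds so a
single uncertainty description drives both analyses.  Survival-curve
parameters are not sampled; curve uncertainty is handled by the distribution
cross-validation grid instead.

The CEAC reports, per willingness-to-pay value, the fraction of draws with
incremental cost <= WTP x incremental QALY (counting, no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import ModelSettings
from .economics import AEItem, CEAResult, EconParams


@dataclass
class ParamSpec:
    """One parameter varied in the sensitivity analyses."""

    name: str
    base: float
    low: float
    high: float
    kind: str  # "cost" | "utility" | "probability" | "rate"
    setter: Callable[[EconParams, ModelSettings, float], tuple[EconParams, ModelSettings]]

    @property
    def sd(self) -> float:
        """Moment-matching dispersion: (high - low) / (2 * 1.96)."""
        return (self.high - self.low) / (2.0 * 1.96)


def _set_attr(attr):
    def setter(econ, settings, v):
        return replace(econ, **{attr: v}), settings
    return setter


def _set_price(drug):
    def setter(econ, settings, v):
        prices = dict(econ.drug_prices)
        prices[drug] = v
        return replace(econ, drug_prices=prices), settings
    return setter


def _set_utility(key):
    def setter(econ, settings, v):
        if key == "u_pd":
            return replace(econ, u_pd=v), settings
        u = dict(econ.u_pfs)
        u[key] = v
        return replace(econ, u_pfs=u), settings
    return setter


def _set_subseq_prob(arm):
    def setter(econ, settings, v):
        p = dict(econ.subsequent_tx_prob)
        p[arm] = v
        return replace(econ, subsequent_tx_prob=p), settings
    return setter


def _set_ae_cost(index):
    def setter(econ, settings, v):
        items = list(econ.ae_items)
        ae = items[index]
        items[index] = AEItem(ae.name, dict(ae.incidence), v, ae.disutility,
                              ae.duration_days)
        return replace(econ, ae_items=tuple(items)), settings
    return setter


def _set_discount(econ, settings, v):
    return econ, replace(settings, discount_annual=v)


def default_sensitivity_params(
    econ: EconParams,
    settings: ModelSettings,
    variation: float = 0.25,
    variation_high: float = 0.30,
    discount_range: tuple[float, float] = (0.0, 0.08),
) -> list[ParamSpec]:
    """Default varied-parameter registry.

    AE management, BSC and terminal-care costs carry the wider
    high-uncertainty band; utilities, probabilities and remaining costs the
    default band; the discount rate spans its guideline range.
    """
    lo = 1.0 - variation
    hi = 1.0 + variation
    lo_h = 1.0 - variation_high
    hi_h = 1.0 + variation_high
    params: list[ParamSpec] = [
        ParamSpec("aci_price_per_cycle", econ.aci_price_per_cycle,
                  econ.aci_price_per_cycle * lo, econ.aci_price_per_cycle * hi,
                  "cost", _set_attr("aci_price_per_cycle")),
        ParamSpec("subsequent_tx_cost", econ.subsequent_tx_cost,
                  econ.subsequent_tx_cost * lo, econ.subsequent_tx_cost * hi,
                  "cost", _set_attr("subsequent_tx_cost")),
        ParamSpec("followup_cost_per_cycle", econ.followup_cost_per_cycle,
                  econ.followup_cost_per_cycle * lo,
                  econ.followup_cost_per_cycle * hi,
                  "cost", _set_attr("followup_cost_per_cycle")),
        ParamSpec("bsc_cost_per_cycle", econ.bsc_cost_per_cycle,
                  econ.bsc_cost_per_cycle * lo_h, econ.bsc_cost_per_cycle * hi_h,
                  "cost", _set_attr("bsc_cost_per_cycle")),
        ParamSpec("terminal_cost", econ.terminal_cost,
                  econ.terminal_cost * lo_h, econ.terminal_cost * hi_h,
                  "cost", _set_attr("terminal_cost")),
        ParamSpec("u_pd", econ.u_pd, min(econ.u_pd * lo, 1.0),
                  min(econ.u_pd * hi, 1.0), "utility", _set_utility("u_pd")),
        ParamSpec("discount_rate", settings.discount_annual,
                  discount_range[0], discount_range[1], "rate", _set_discount),
    ]
    for arm in ("aci", "control"):
        params.append(
            ParamSpec(f"u_pfs_{arm}", econ.u_pfs[arm],
                      min(econ.u_pfs[arm] * lo, 1.0), min(econ.u_pfs[arm] * hi, 1.0),
                      "utility", _set_utility(arm))
        )
        p = econ.subsequent_tx_prob[arm]
        params.append(
            ParamSpec(f"subsequent_tx_prob_{arm}", p, max(p * lo, 0.0),
                      min(p * hi, 1.0), "probability", _set_subseq_prob(arm))
        )
    for drug, price in econ.drug_prices.items():
        params.append(
            ParamSpec(f"price_{drug}", price, price * lo, price * hi,
                      "cost", _set_price(drug))
        )
    for i, ae in enumerate(econ.ae_items):
        params.append(
            ParamSpec(f"ae_cost_{ae.name}", ae.cost, ae.cost * lo_h,
                      ae.cost * hi_h, "cost", _set_ae_cost(i))
        )
    return params


@dataclass
class OwsaRow:
    parameter: str
    low_input: float
    high_input: float
    icer_low: float | None
    icer_high: float | None
    range: float


RunFn = Callable[[EconParams, ModelSettings], CEAResult]


def owsa(
    run_fn: RunFn,
    base_econ: EconParams,
    base_settings: ModelSettings,
    params: Sequence[ParamSpec],
) -> list[OwsaRow]:
    """One-way sensitivity analysis; rows sorted by ICER range descending.

    Non-finite ICERs are kept and labelled by a NaN entry; their range counts
    only the finite endpoints.
    """
    rows = []
    for p in params:
        icers = []
        for v in (p.low, p.high):
            econ_v, settings_v = p.setter(base_econ, base_settings, v)
            res = run_fn(econ_v, settings_v)
            icers.append(res.icer if res.icer is not None else np.nan)
        finite = [x for x in icers if np.isfinite(x)]
        rng = float(max(finite) - min(finite)) if len(finite) == 2 else (
            0.0 if not finite else np.nan
        )
        rows.append(OwsaRow(p.name, p.low, p.high, icers[0], icers[1], rng))
    rows.sort(key=lambda r: (-(r.range if np.isfinite(r.range) else np.inf),
                             r.parameter))
    return rows


def owsa_frame(rows: Sequence[OwsaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "low_input": [r.low_input for r in rows],
            "high_input": [r.high_input for r in rows],
            "icer_low": [r.icer_low for r in rows],
            "icer_high": [r.icer_high for r in rows],
            "range": [r.range for r in rows],
        }
    )


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma(shape, scale) from (mean, sd): shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moment matching needs mean > 0 and sd > 0")
    return mean * mean / (sd * sd), sd * sd / mean


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) from (mean, sd); requires sd^2 < mean(1 - mean)."""
    if not 0.0 < mean < 1.0:
        raise ValueError("beta moment matching needs mean in (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: sd^2 = {var:.4g} >= mean(1-mean) = "
            f"{mean * (1.0 - mean):.4g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def draw_psa(
    params: Sequence[ParamSpec], rng: np.random.Generator
) -> dict[str, float]:
    """One PSA parameter vector: gamma for costs, beta for utilities and
    probabilities; rate-type parameters (discount) are held at base.

    A parameter with sd = 0 (degenerate bounds) collapses to its base value.
    """
    out = {}
    for p in params:
        if p.kind == "rate" or p.sd <= 0 or p.base == 0:
            out[p.name] = p.base
        elif p.kind == "cost":
            shape, scale = gamma_moments(p.base, p.sd)
            out[p.name] = float(rng.gamma(shape, scale))
        elif p.kind in ("utility", "probability"):
            try:
                a, b = beta_moments(p.base, p.sd)
            except ValueError:
                raise ValueError(f"infeasible beta moments for parameter {p.name!r}")
            out[p.name] = float(rng.beta(a, b))
        else:
            raise ValueError(f"unknown parameter kind {p.kind!r}")
    return out


def apply_draw(
    base_econ: EconParams,
    base_settings: ModelSettings,
    params: Sequence[ParamSpec],
    draw: dict[str, float],
) -> tuple[EconParams, ModelSettings]:
    econ, settings = base_econ, base_settings
    for p in params:
        econ, settings = p.setter(econ, settings, draw[p.name])
    return econ, settings


def run_psa(
    run_fn: RunFn,
    base_econ: EconParams,
    base_settings: ModelSettings,
    params: Sequence[ParamSpec],
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo PSA: one full model evaluation per draw (seeded)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for it in range(n_iter):
        draw = draw_psa(params, rng)
        econ_v, settings_v = apply_draw(base_econ, base_settings, params, draw)
        res = run_fn(econ_v, settings_v)
        records.append(
            {
                "iteration": it,
                "cost_aci": res.cost_aci,
                "qaly_aci": res.qaly_aci,
                "cost_control": res.cost_control,
                "qaly_control": res.qaly_control,
                "incremental_cost": res.incremental_cost,
                "incremental_qaly": res.incremental_qaly,
                **{f"param_{k}": v for k, v in draw.items()},
            }
        )
    return pd.DataFrame(records)


def ceac(samples: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Acceptability fraction per WTP: count of dC <= wtp * dE draws."""
    if len(samples) == 0:
        raise ValueError("no PSA samples")
    dc = samples["incremental_cost"].to_numpy(dtype=float)
    de = samples["incremental_qaly"].to_numpy(dtype=float)
    probs = [float(np.mean(dc <= w * de)) for w in wtp_grid]
    return pd.DataFrame({"wtp": list(wtp_grid), "probability": probs})
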
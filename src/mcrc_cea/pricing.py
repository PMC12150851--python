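"""Value-based price inversion for the ACI per-cycle price.

Incremental cost is affine in the ACI per-cycle price p:

    dC(p) = dC0 + slope * p,

where dC0 is the incremental cost at p = 0 and the slope equals the
discounted PFS occupancy summed over the induction cycles in which the
infusion is given.  Incremental QALYs do not depend on price, so the maximum
price satisfying ICER(p) <= WTP has the closed form

    p* = (WTP * dE - dC0) / slope,   floored at 0.

The closed form is the primary solver; iterative re-running of the model
(bisection on the actual ICER) is retained as a cross-check and both must
agree to $0.01.  Thresholds are multiples (1.5x, 1.94x, 3x) of per-capita
GDP, stored once and derived to avoid rounding drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .config import GDP_PER_CAPITA, WTP_MULTIPLIERS
from .economics import CEAResult


@dataclass(frozen=True)
class WtpSpec:
    gdp_per_capita: float = GDP_PER_CAPITA
    multipliers: tuple[float, ...] = WTP_MULTIPLIERS

    def thresholds(self) -> list[float]:
        return [round(m * self.gdp_per_capita, 2) for m in self.multipliers]


def threshold_table(wtp_spec: WtpSpec | None = None) -> list[dict]:
    """WTP thresholds in $ per QALY, cent-rounded products of GDP multiples."""
    spec = wtp_spec or WtpSpec()
    return [
        {"multiplier": m, "threshold": t}
        for m, t in zip(spec.multipliers, spec.thresholds())
    ]


@dataclass
class PriceCoefficients:
    """Affine map dC(p) = dc0 + slope * p, plus the (price-free) dQALY."""

    dc0: float
    slope: float
    delta_qaly: float


RunAtPrice = Callable[[float], CEAResult]


def icer_price_coefficients(
    run_at_price: RunAtPrice, probe_price: float = 1000.0, rtol: float = 1e-6
) -> PriceCoefficients:
    """Determine the affine ICER-price map from two model evaluations.

    A third evaluation at twice the probe price verifies affinity to ``rtol``
    relative; a violation (which would indicate price-dependent dynamics)
    raises ``ValueError`` so the caller can fall back to bisection.
    """
    if probe_price <= 0:
        raise ValueError("probe_price must be > 0")
    r0 = run_at_price(0.0)
    r1 = run_at_price(probe_price)
    dc0 = r0.incremental_cost
    slope = (r1.incremental_cost - dc0) / probe_price
    r2 = run_at_price(2.0 * probe_price)
    predicted = dc0 + slope * 2.0 * probe_price
    scale = max(abs(r2.incremental_cost), 1.0)
    if abs(r2.incremental_cost - predicted) > rtol * scale:
        raise ValueError("incremental cost is not affine in price")
    if abs(r1.incremental_qaly - r0.incremental_qaly) > 1e-9:
        raise ValueError("incremental QALY must not depend on price")
    return PriceCoefficients(dc0=dc0, slope=slope, delta_qaly=r0.incremental_qaly)


@dataclass
class PriceSolveResult:
    wtp: float
    price_star: float
    icer_at_price_star: float | None
    method: str  # "closed_form" | "bisection"
    achievable: bool = True


def solve_price(
    wtp: float,
    coefficients: PriceCoefficients,
    run_at_price: RunAtPrice | None = None,
    price_cap: float = 1e6,
    tol: float = 0.01,
) -> PriceSolveResult:
    """Maximum ACI per-cycle price with ICER(price) <= WTP.

    Closed form, cross-checked against bisection on the actual model when
    ``run_at_price`` is supplied; the two must agree within ``tol`` dollars.
    """
    c = coefficients
    if c.slope <= 0:
        raise ValueError("price slope must be > 0")
    if c.delta_qaly <= 0:
        raise ValueError("delta_qaly must be > 0 for a price inversion")
    target = wtp * c.delta_qaly
    if target < c.dc0:
        return PriceSolveResult(wtp=wtp, price_star=0.0,
                                icer_at_price_star=c.dc0 / c.delta_qaly,
                                method="closed_form", achievable=False)
    p_star = (target - c.dc0) / c.slope
    if run_at_price is not None:
        p_bis = _bisect_price(run_at_price, wtp, price_cap, tol)
        if abs(p_bis - p_star) > tol:
            raise AssertionError(
                f"closed-form ({p_star:.4f}) and bisection ({p_bis:.4f}) disagree"
            )
    icer_at = (c.dc0 + c.slope * p_star) / c.delta_qaly
    return PriceSolveResult(wtp=wtp, price_star=p_star, icer_at_price_star=icer_at,
                            method="closed_form")


def _bisect_price(run_at_price: RunAtPrice, wtp: float, cap: float, tol: float) -> float:
    def excess(p: float) -> float:
        r = run_at_price(p)
        return r.incremental_cost - wtp * r.incremental_qaly

    lo, hi = 0.0, cap
    if excess(lo) > 0:
        return 0.0
    if excess(hi) < 0:
        return hi
    while hi - lo > tol / 4.0:
        mid = 0.5 * (lo + hi)
        if excess(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def price_table(
    run_at_price: RunAtPrice,
    wtp_spec: WtpSpec | None = None,
    cross_check: bool = True,
) -> list[dict]:
    """Price ceilings at each WTP multiplier (the price-simulation output)."""
    spec = wtp_spec or WtpSpec()
    coeffs = icer_price_coefficients(run_at_price)
    rows = []
    for m, t in zip(spec.multipliers, spec.thresholds()):
        res = solve_price(t, coeffs, run_at_price if cross_check else None)
        rows.append(
            {
                "multiplier": m,
                "threshold": t,
                "price_star": res.price_star,
                "achievable": res.achievable,
            }
        )
    return rows
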
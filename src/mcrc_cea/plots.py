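"""Figure helpers: KM overlays, tornado, CEAC, PSA scatter, price curve.

All functions take an output path, save a PNG with a non-interactive backend
and return the path; they are presentation-layer only and carry no model
logic.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .km import KMCurve


def km_overlay(curve: KMCurve, fits, tmax: float, path, title: str = "") -> str:
    """KM step curve with fitted parametric survival overlays."""
    grid = np.linspace(0, tmax, 300)
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.step(
        np.concatenate(([0.0], curve.times)),
        np.concatenate(([1.0], curve.survival)),
        where="post", color="black", lw=2, label="Kaplan-Meier",
    )
    for fit in fits:
        ax.plot(grid, fit.survival(grid), lw=1, label=fit.family)
    ax.set_xlabel("Time (months)")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def tornado(rows, base_icer: float, path) -> str:
    """Tornado diagram from OWSA rows (already sorted by range)."""
    rows = [r for r in rows if np.isfinite(r.range) and r.range > 0][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(rows), 4) + 1.5))
    for i, r in enumerate(rows):
        lo, hi = sorted([r.icer_low, r.icer_high])
        ax.barh(i, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(base_icer, color="black", ls="--", lw=1, label="base-case ICER")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r.parameter for r in rows], fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def psa_scatter(samples: pd.DataFrame, wtp: float, path) -> str:
    """Incremental cost vs incremental QALY cloud with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(samples["incremental_qaly"], samples["incremental_cost"],
               s=6, alpha=0.4)
    xs = np.linspace(0, samples["incremental_qaly"].max() * 1.05, 10)
    ax.plot(xs, wtp * xs, color="red", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.set_xlabel("Incremental QALY")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def ceac_plot(ceac_df: pd.DataFrame, path) -> str:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_df["wtp"], ceac_df["probability"], lw=1.5)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def price_curve(coeffs, prices, path) -> str:
    """ICER as a function of the ACI per-cycle price (affine)."""
    prices = np.asarray(prices, dtype=float)
    icers = (coeffs.dc0 + coeffs.slope * prices) / coeffs.delta_qaly
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(prices, icers, lw=1.5)
    ax.set_xlabel("ACI price ($/cycle)")
    ax.set_ylabel("ICER ($/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def crossval_hist(report, path) -> str:
    fig, ax = plt.subplots(figsize=(6, 4))
    finite = report.icers[np.isfinite(report.icers)]
    ax.hist(finite, bins=40, color="#4878d0", alpha=0.85)
    ax.axvline(report.wtp, color="red", ls="--", lw=1, label="WTP")
    ax.set_xlabel("ICER ($/QALY)")
    ax.set_ylabel("Model pairings")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
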
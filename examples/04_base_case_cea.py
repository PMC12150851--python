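"""Base-case cost-effectiveness analysis.

Drives the three-state (PFS/PD/Death) cohort model with the trial-calibrated
survival curves over a 20-year horizon at 21-day cycles, attaches the default
cost/utility set, and prints discounted totals per arm, the increments, and
the ICER.  The ICER is the incremental cost per quality-adjusted life-year of
adding adoptive cellular immunotherapy to XELOX + bevacizumab.
"""

import mcrc_cea as m

control, aci = m.trial_curve_sets()
econ = m.default_econ_params()
settings = m.ModelSettings()  # 20 years, 21-day cycles, 5% discount

res = m.run_cea(control, aci, econ, settings)
print(f"{'arm':14s} {'cost ($)':>12s} {'QALY':>7s}")
print(f"{'immunotherapy':14s} {res.cost_aci:12,.2f} {res.qaly_aci:7.2f}")
print(f"{'control':14s} {res.cost_control:12,.2f} {res.qaly_control:7.2f}")
print(f"\nincremental cost  {res.incremental_cost:12,.2f} $")
print(f"incremental QALY  {res.incremental_qaly:12.2f}")
print(f"ICER              {res.icer:12,.2f} $/QALY")

trace = m.occupancy_trace(control.pfs, control.os, settings)
print(f"\ncontrol-arm death-state occupancy at 20 y: {100 * trace.death[-1]:.2f}%")
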
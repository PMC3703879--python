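"""Marginal bone loss and in-bone positioning depth.

Sweeps the crestal bone-loss fraction (0-50 % of the cortical thickness,
conical crater) for implant 8 placed crestally, then compares the three
placement depths P0 / P05 / P1.  Peaks are raw Gauss-point extrema over the
control regions.
"""

from perifem.study import (StudyRunner, boneloss_sweep, percent_change,
                           positioning_scenarios)

runner = StudyRunner(hi_ratio=0.2, h0_ratio=0.2)

study, table = boneloss_sweep(runner, "8", (0.0, 0.10, 0.25, 0.50))
sub = table[(table.measure == "sigma_vm")]
print("von Mises peaks vs crestal bone loss (MPa / % increase vs no loss):")
print(sub.pivot_table(index="bone_loss_fraction", columns="region",
                      values=["peak", "increase_vs_noloss_pct"]).round(1))
print("\ncratering removes crestal cortical support: stresses climb with "
      "the crater depth, most visibly at the trabecular crest.")

pos = runner.run_study(positioning_scenarios("8"))
print("\ncortical overloading risk peak by placement depth:")
for name in sorted(pos.results):
    print(f"  {name}: R_peak = "
          f"{pos.value(name, 'cortical', 'risk', 'peak'):.3f}")
p0 = pos.value("8/P0", "cortical", "risk", "peak")
p05 = pos.value("8/P05", "cortical", "risk", "peak")
change = percent_change(p0, p05)
verdict = "lower than" if change > 0 else "comparable to or above"
print(f"\ncortical risk peak at the intermediate subcrestal placement P05 is "
      f"{verdict} crestal P0 (with its 10 % marginal bone loss): "
      f"{change:+.1f} % change. The comparison probes the balance between "
      "cratering and apposition; at coarse mesh settings it sits within the "
      "raw-peak noise band (see the methods note).")
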
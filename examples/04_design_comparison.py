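"""Compare implant designs: diameter vs length vs thread shape.

Runs four catalogue implants at the P1 subcrestal placement with shared
mesh settings and reports the percent reduction of the cortical peak
compressive principal stress |sigma_C| between design pairs -- the study's
headline comparison.  A positive percentage means the second design loads
the crestal cortical bone less.
"""

from perifem.study import StudyRunner, comparison_table, p1_sweep_scenarios

runner = StudyRunner(hi_ratio=0.2, h0_ratio=0.2)
study = runner.run_study(p1_sweep_scenarios(["1", "2", "3", "9"]))

pairs = [
    ("2", "3", "cortical", "sigma_c_abs", "peak"),   # D: 3.6 -> 4.3 mm
    ("2", "9", "cortical", "sigma_c_abs", "peak"),   # L: 5.5 -> 9 mm
    ("1", "2", "cortical", "sigma_c_abs", "peak"),   # thread: saw -> trapezoid
]
table = comparison_table(study, pairs)
print(table.round(2).to_string(index=False))

d_eff, l_eff, t_eff = table.reduction_pct
print(f"\nincreasing the diameter cuts the cortical compressive peak by "
      f"{d_eff:.0f} %, increasing the length by {l_eff:.0f} % -- the "
      "diameter is the more effective design lever on this synthetic bone.")
print(f"the thread-shape change moves the peak by only {t_eff:.0f} % here: "
      "in the axisymmetric fin model the collar bearing, not the flank "
      "shape, controls the cortical peak (see the methods note).")
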
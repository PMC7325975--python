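"""Build the two copper-delivery schedules and audit their equivalence.

The design question of the whole package: deliver the same total exposure
(dose-days, the discrete area under the concentration-time curve) and the
same 1 mM endpoint, either as nine small daily steps or as one jump on
day 5.
"""

import custress as cs

gradual = cs.build_gradual_schedule(final_conc=1.0, n_days=9)
abrupt = cs.build_abrupt_schedule(final_conc=1.0, n_days=9, step_day=5)

print("day :", *range(1, 10))
print("grad:", *(f"{c:.2f}" for c in gradual.conc))
print("abr :", *(f"{c:.2f}" for c in abrupt.conc))
print(f"dose-days gradual = {cs.dose_days(gradual).value:g} mM*day")
print(f"dose-days abrupt  = {cs.dose_days(abrupt).value:g} mM*day")

report = cs.check_equivalence(gradual, abrupt)
print(f"equivalent (same dose and same endpoint): {report.equivalent}")

# Both arms deliver exactly 5 mM*day and end at 1 mM; they differ only in
# the *rate* at which the stressor arrives.
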
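"""Bootstrap effect sizes and the gradual-vs-abrupt contrast for one isolate.

The effect size is the raw difference of group means (treated - control,
negative = biomass reduction); its 95% CI comes from the percentile
bootstrap and the contrast p-value from the studentized bootstrap.
"""

import custress as cs

design = cs.default_design()
panel = cs.generate_isolate_panel(17, seed=11)
table = cs.simulate_experiment(design, panel, seed=11)

iso = "iso06"
sub = table[table["isolate"] == iso]
arms = {
    arm: sub.loc[sub["treatment"] == arm, "biomass_g"].to_numpy()
    for arm in ("control", "gradual", "abrupt")
}

es_g = cs.bootstrap_ci(arms["gradual"], arms["control"], n_boot=9999, seed=1)
es_a = cs.bootstrap_ci(arms["abrupt"], arms["control"], n_boot=9999, seed=2)
ctr = cs.compare_es(arms["gradual"], arms["abrupt"], arms["control"],
                    n_boot=9999, seed=3)

print(f"isolate {iso} (biomass, g dry weight)")
print(f"  ES gradual = {es_g.point:+.3f}  95% CI [{es_g.ci_low:+.3f}, {es_g.ci_high:+.3f}]")
print(f"  ES abrupt  = {es_a.point:+.3f}  95% CI [{es_a.ci_low:+.3f}, {es_a.ci_high:+.3f}]")
print(f"  delta (abrupt - gradual) = {ctr.delta:+.3f} "
      f"CI [{ctr.ci_low:+.3f}, {ctr.ci_high:+.3f}]  p_boot = {ctr.p_boot:.4f}")

# A negative ES means copper reduced biomass relative to the control; a
# positive significant delta means the gradual arm was hit harder.
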
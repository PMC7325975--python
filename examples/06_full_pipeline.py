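"""Simulate -> analyze -> classify -> signal-test -> report, end to end.

Equivalent to `custress all` on the command line. Writes the full bundle
of tidy CSVs plus a human-readable report, then prints the report.
"""

from pathlib import Path

import custress as cs

outdir = Path("custress_out")
cfg = cs.RunConfig(seed=1, outdir=str(outdir))

design, panel, table, tree = cs.simulate_run(cfg)
bundle = cs.run_pipeline(cfg, table, tree=tree)

print(f"outputs in {outdir}/: " + ", ".join(sorted(p.name for p in outdir.iterdir())))
print()
print((outdir / "report.txt").read_text())
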
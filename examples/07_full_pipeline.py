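"""End-to-end run on the mini fixture.

Simulates the 12-site estuary, then runs chronology -> era binning ->
isoscapes -> change-point decomposition -> nitrogen budget, and prints
the report highlights.  Equivalent shell usage:

    paleoscape simulate --seed 1 --input-dir fixture
    paleoscape run-all  --seed 1 --input-dir fixture --outdir out
"""

import tempfile
from pathlib import Path

from paleoscape import PipelineConfig, run_all, run_simulate

tmp = Path(tempfile.mkdtemp(prefix="paleoscape_demo_"))
cfg = PipelineConfig(input_dir=str(tmp / "fixture"),
                     output_dir=str(tmp / "out"), seed=1)
run_simulate(cfg)
report = run_all(cfg)

print("\nmapping eras (derived from the composite chronology):")
print("  " + ", ".join(e["label"] for e in report["stages"]["eras"]))

print("\nd15N map mean by era (permil):")
for era, info in report["stages"]["isoscape"]["d15N"].items():
    print(f"  {era}: {info['mean']:.2f}")

print("\nDIF/ABS per focal site (d15N):")
for row in report["stages"]["changepoint"]["table"]:
    if row["variable"] == "d15N":
        print(f"  {row['site_id']}: DIF {row['dif']:+.2f}, ABS {row['abs']:.2f}, "
              f"inlet-attributed step: {row['attributed_to_inlet']}")

print(f"\noutputs in {cfg.output_dir}")
print("Rising era means and positive DIF at every site reproduce the")
print("injected 20th-century nutrient-enrichment signal.")
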
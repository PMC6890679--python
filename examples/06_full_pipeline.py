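"""End-to-end pipeline: synthesize -> fit -> risk -> uncertainty -> report.

One call generates a study world with known ground truth, fits every
input distribution, runs the requested case and writes the report
tables (fitted_params.csv, risk_summary.csv, uncertainty_report.csv)
plus a manifest that makes the run bit-for-bit reproducible.
"""

import pandas as pd

import allergenrisk as ar

truth = ar.GroundTruth(
    consumption_params=(-3.719, 0.747),
    concentration_family="lognormal",
    concentration_params=(3.496, 1.283),
    threshold_family="lognormal",
    threshold_params=(4.088, 2.987),
)
cfg = ar.RunConfig(
    out_dir="scratch/pipeline_demo", case_id="B", K=1000, n=10_000,
    seed=8, synthesize=True, truth=truth,
)
out = ar.run_pipeline(cfg)
print(f"outputs in {out}/:")
print(pd.read_csv(out / "risk_summary.csv")
      [["case", "mean", "sd", "p2.5", "median", "p97.5"]].to_string(index=False))
print()
print(pd.read_csv(out / "uncertainty_report.csv").to_string(index=False))
# The risk row should bracket the generating truth's closed-form risk;
# rerunning with the same seed reproduces every file byte-for-byte.
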
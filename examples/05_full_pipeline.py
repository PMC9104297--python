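"""End-to-end pipeline run with tidy CSV outputs and a manifest.

Equivalent to the `eda-sites` command line; everything lands in
scratch/example_run (correlations, index tests, ROC points, quality table,
site ranking, manifest.json).
"""

import pandas as pd

from edasites import SimulationConfig, run_pipeline

manifest = run_pipeline(
    "scratch/example_run",
    mode="simulate",
    sim_config=SimulationConfig(n_subjects=8),
    seed=42,
)

print("outputs:")
for key, path in manifest.outputs.items():
    print(f"  {key}: {path}")

ranking = pd.read_csv(manifest.outputs["site_ranking"])
print("\nsite ranking along the three comparison axes")
print("(correlation with reference, stress-significant indices, motion Pn):")
print(ranking.to_string(index=False))
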
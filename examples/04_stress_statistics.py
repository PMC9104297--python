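"""Which body sites discriminate cognitive stress from baseline?

Runs the full cohort analysis on a synthetic 12-subject cohort and prints
the per-site correlation with the finger reference, the baseline-vs-stress
test for each EDA index (normality-gated paired t / rank-sum), and the
ROC AUC for the SCR count.
"""

import logging

from edasites import SimulationConfig, analyze_cohort, simulate_cohort
from edasites.stats import significance_stars

logging.basicConfig(level=logging.WARNING)

cfg = SimulationConfig(n_subjects=12, seed=21)
cohort = simulate_cohort(cfg)
report = analyze_cohort([rec for rec, _ in cohort], cfg.annotations())

print("within-subject correlation with the finger (baseline+scwt window):")
print(report.correlation_summary.to_string(index=False))

print("\nbaseline vs cognitive stress, per site and index:")
for t in report.tests:
    mark = significance_stars(t.p_value)
    print(f"  {t.site:9s} {t.index_name:16s} {t.stat_name:10s} "
          f"p={t.p_value:7.4f} {mark}")

print("\nROC AUC for the SCR count (positive class = stress):")
for r in report.rocs:
    if r.index_name == "n_scr":
        print(f"  {r.site:9s} auc={r.auc:.3f}")
# Expected pattern: finger and foot carry the stress signal (small p, high
# AUC); the sparsely innervated forehead and neck mostly do not.
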
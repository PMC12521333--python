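#!/usr/bin/env python
"""The statistical battery over the demo cohort.

Runs the default comparison set: group contrasts of per-lung mean MPI
(Welch t), left-vs-right within group, basal-segment FHPI contrasts,
correlations of patient mean MPI with day-1 MAP / FiO2 / RSS / VT and the
radiological grade (Pearson), and the repeated-measures analyses across
days 1/3/7 (RM-ANOVA with Bonferroni pairwise contrasts; Friedman with
Conover post hoc).  Writes stats_report.csv and a text rendering.
"""

from pathlib import Path

import pandas as pd

from cxraer.pipeline import PipelineConfig, stats_stage

OUT = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    cfg = PipelineConfig(out_dir=OUT)
    report = stats_stage(
        cfg,
        pd.read_csv(OUT / "lung_summaries.csv"),
        pd.read_csv(OUT / "measurements.csv"),
        pd.read_csv(OUT / "clinical.csv"),
        pd.read_csv(OUT / "patients.csv"),
    )
    sig = report[report.p < 0.05]
    print(f"{len(report)} comparisons, {len(sig)} with p < 0.05:")
    print(sig[["comparison", "method", "statistic", "p"]].round(4).to_string(index=False))
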
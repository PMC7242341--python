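#!/usr/bin/env python
"""Region statistics: does the analysis recover the injected CT contrast?

Takes the feature table from scratch/run/, reduces each subject x sensor
multiscale curve to its AUC, pools the AUCs into four (group x region)
cells, and reports the one-way ANOVA per measure. Copies the small
summary tables (ANOVA, heatmap, group curves) into results/.

Run analysis/02_extract_features.py first.
"""

import shutil
from pathlib import Path

import pandas as pd

from eegrqa.features import read_feature_table
from eegrqa.stats import region_anova

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"

MEASURES = ("SampE", "TT", "Lmax", "Lmean")


def main() -> None:
    table = read_feature_table(RUN / "features.csv")
    RESULTS.mkdir(exist_ok=True)
    print(f"{'measure':8s} {'F(3, n-4)':>10s} {'p':>10s}   cell means "
          f"(case/CT  case/non  contr/CT  contr/non)")
    for measure in MEASURES:
        s = region_anova(table, measure)
        m = s.cell_means
        cells = "  ".join(
            f"{m[c]:8.3f}" for c in
            [("case", "CT"), ("case", "nonCT"), ("contrast", "CT"), ("contrast", "nonCT")]
        )
        print(f"{measure:8s} {s.anova.F:10.2f} {s.anova.p:10.2e}   {cells}")
    for name in (
        [f"anova_{m}.csv" for m in MEASURES]
        + [f"heatmap_{m}.csv" for m in MEASURES]
        + [f"curves_{m}.csv" for m in MEASURES]
    ):
        shutil.copy(RUN / name, RESULTS / name)
    print(f"summary tables copied to {RESULTS}")


if __name__ == "__main__":
    main()
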
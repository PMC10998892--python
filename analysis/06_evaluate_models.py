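"""Cross-validation diagnostics: fold z-scores, outliers, normality.

Standardizes each metric over the FCNET folds, checks for single outliers
with the two-tailed Grubbs test, and correlates observed against theoretical
normal quantiles (Q-Q) — the guards against the model overfitting a subset
of similar subjects.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"

from tumorconn.pipeline import METRIC_NAMES, _write_tsv, evaluate_stage


def main() -> None:
    fold_path = RESULTS / "fold_metrics.tsv"
    if not fold_path.exists():
        print("run 05_predict_surgery.py first")
        return 1
    fold_df = pd.read_csv(fold_path, sep="\t")
    _, zscores, tests = evaluate_stage(fold_df)
    _write_tsv(zscores, RESULTS / "zscores.tsv")
    _write_tsv(tests, RESULTS / "normality_tests.tsv")

    z = zscores["zscore"].to_numpy()
    print(f"z-scores within +/-1 sd: {100 * np.mean(np.abs(z) <= 1):.0f}%, "
          f"within +/-2 sd: {100 * np.mean(np.abs(z) <= 2):.0f}%")
    outliers = tests[tests["grubbs_outlier"]]
    if outliers.empty:
        print("Grubbs test: no fold is a unique outlier on any metric (alpha 0.05)")
    else:
        print(f"Grubbs test flags: {', '.join(outliers['metric'])}")
    worst = tests.loc[tests["qq_r"].idxmin()]
    print(f"Q-Q normality: r >= {worst['qq_r']:.3f} across "
          f"{len(tests)}/{len(METRIC_NAMES)} metrics "
          f"(weakest: {worst['metric']}, p = {worst['qq_p']:.2g})")
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    sys.exit(main())
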
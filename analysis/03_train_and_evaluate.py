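#!/usr/bin/env python
"""Train the four classifier families and evaluate them both ways.

For each family: pooled 10-fold stratified CV, plus 200 repeated random
66 % train / 34 % test splits (mean / max / min accuracy). Writes
results/accuracy_table.tsv and results/metrics_table.tsv.
"""

from pathlib import Path

import pandas as pd

from hpscore import SplitPlan, repeated_random_split_eval, stratified_kfold_cv
from hpscore.io import read_feature_matrix
from hpscore.pipeline import classifier_factory

SEED = 0
ITERATIONS = 200  # scaled-down repeated-split budget for a desk run
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = read_feature_matrix(OUT / "feature_matrix.tsv")
    cv_plan = SplitPlan(k=10, seed=SEED)
    rep_plan = SplitPlan(protocol="repeated_split", train_fraction=0.66,
                         iterations=ITERATIONS, seed=SEED)
    acc_rows, met_rows = [], []
    for family in ("perceptron", "naive_bayes", "decision_tree", "svm"):
        fit = classifier_factory(family, seed=SEED)
        _, pooled = stratified_kfold_cv(data, fit, cv_plan)
        rep = repeated_random_split_eval(data, fit, rep_plan)
        acc_rows.append({
            "algorithm": family,
            "cv10_accuracy_pct": round(100 * pooled.accuracy, 2),
            "split66_mean_pct": round(100 * rep.mean_accuracy, 2),
            "split66_max_pct": round(100 * rep.max_accuracy, 2),
            "split66_min_pct": round(100 * rep.min_accuracy, 2),
        })
        met_rows.append({
            "algorithm": family,
            "sensitivity_pct": round(100 * pooled.sensitivity, 2),
            "specificity_pct": round(100 * pooled.specificity, 2),
            "precision_pct": round(100 * pooled.precision, 2),
            "f1_pct": round(100 * pooled.f1, 2),
            "mcc_pct": round(100 * pooled.mcc, 2),
        })
        print(f"{family:14s} CV {100 * pooled.accuracy:6.2f}%   "
              f"66% splits mean {100 * rep.mean_accuracy:6.2f}% "
              f"(max {100 * rep.max_accuracy:.2f}, "
              f"min {100 * rep.min_accuracy:.2f})")
    pd.DataFrame(acc_rows).to_csv(OUT / "accuracy_table.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(met_rows).to_csv(OUT / "metrics_table.tsv", sep="\t",
                                  index=False)
    print(f"\nwrote accuracy_table.tsv and metrics_table.tsv "
          f"({ITERATIONS} split iterations, seed {SEED})")


if __name__ == "__main__":
    main()
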
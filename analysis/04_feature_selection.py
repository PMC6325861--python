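#!/usr/bin/env python
"""Feature-selection analyses on the scored matrix.

Single-feature impact ranking, CFS subset, PCA-based ranking, pairwise
feature correlations, and the exhaustive 511-subset search (naive Bayes
under 10-fold CV). Writes the corresponding TSVs under results/.
"""

from pathlib import Path

import pandas as pd

from hpscore import SplitPlan
from hpscore.feature_selection import (
    cfs_select,
    exhaustive_subset_search,
    pca_rank,
    pearson_feature_correlations,
    rank_feature_impact,
)
from hpscore.io import read_feature_matrix
from hpscore.pipeline import classifier_factory
from hpscore.scoring import FEATURE_NAMES

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = read_feature_matrix(OUT / "feature_matrix.tsv")
    nb = classifier_factory("naive_bayes")
    plan = SplitPlan(k=10, seed=SEED)

    ranks = rank_feature_impact(data, nb, plan)
    pd.DataFrame(
        [{"feature": f, "name": FEATURE_NAMES[f], "rank": r}
         for f, r in sorted(ranks.items())]
    ).to_csv(OUT / "impact_ranking.tsv", sep="\t", index=False)
    print("single-feature impact ranks (1 = high impact):")
    for f, r in sorted(ranks.items(), key=lambda t: (t[1], t[0])):
        print(f"  rank {r}: f{f} ({FEATURE_NAMES[f]})")

    cfs = sorted(cfs_select(data))
    pca = pca_rank(data)
    print(f"CFS subset: {cfs}")
    print(f"PCA ranking (variance-weighted loadings): {list(pca.order)}")
    pd.DataFrame(
        [{"method": "cfs", "subset": ",".join(map(str, cfs))},
         {"method": "pca_ranker", "subset": ",".join(map(str, pca.order))}]
    ).to_csv(OUT / "selection_subsets.tsv", sep="\t", index=False)

    corr = pearson_feature_correlations(data)
    pd.DataFrame(
        [{"feature_i": i, "feature_j": j, "pearson_r": round(r, 4),
          "p_two_tailed": f"{p:.3g}"}
         for i, j, r, p in corr.pairs]
    ).to_csv(OUT / "feature_correlations.tsv", sep="\t", index=False)
    top = sorted(corr.pairs, key=lambda t: -abs(t[2]))[:5]
    print("strongest feature correlations (pooled classes):")
    for i, j, r, p in top:
        print(f"  f{i}-f{j}: r={r:.3f} p={p:.2g}")

    best, table = exhaustive_subset_search(data, nb, plan)
    pd.DataFrame(
        [{"subset": ",".join(map(str, t.subset)),
          "accuracy": round(t.accuracy, 6), "n_features": t.n_features}
         for t in table]
    ).to_csv(OUT / "subset_search.tsv", sep="\t", index=False)
    full = next(t for t in table if len(t.subset) == 9)
    print(f"exhaustive search: {len(table)} subsets; best "
          f"{list(best.subset)} at {100 * best.accuracy:.2f}% "
          f"(full set {100 * full.accuracy:.2f}%)")


if __name__ == "__main__":
    main()
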
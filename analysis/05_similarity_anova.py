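#!/usr/bin/env python
"""Jaccard similarity of HP feature profiles and one-way ANOVA.

Writes the pairwise Jaccard similarities (long format) and prints the
per-class ANOVA across the nine feature-score columns.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hpscore.io import read_feature_matrix
from hpscore.similarity import anova_oneway, class_feature_groups, jaccard_matrix

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = read_feature_matrix(OUT / "feature_matrix.tsv")
    sim = jaccard_matrix(data)
    iu = np.triu_indices(len(sim.ids), k=1)
    pd.DataFrame(
        {"id1": [sim.ids[i] for i in iu[0]],
         "id2": [sim.ids[j] for j in iu[1]],
         "jaccard": np.round(sim.values[iu], 6),
         "distance": np.round(1.0 - sim.values[iu], 6)}
    ).to_csv(OUT / "jaccard_long.tsv", sep="\t", index=False)

    vals = sim.values[iu]
    print(f"Jaccard pairs: {vals.size}; mean {vals.mean():.3f}, "
          f"min {vals.min():.3f}, max {vals.max():.3f}")
    within_pos = [
        sim.values[i, j] for i, j in zip(*iu)
        if data.y[i] == 1 and data.y[j] == 1
    ]
    within_neg = [
        sim.values[i, j] for i, j in zip(*iu)
        if data.y[i] == 0 and data.y[j] == 0
    ]
    print(f"mean within-class similarity: positives "
          f"{np.mean(within_pos):.3f}, negatives {np.mean(within_neg):.3f}")

    for side, positive in (("positive", True), ("negative", False)):
        res = anova_oneway(class_feature_groups(data, positive=positive))
        print(f"one-way ANOVA across feature columns, {side} class: "
              f"F={res.F:.2f}, p={res.p:.3g}, "
              f"significant at 0.05: {res.significant}")


if __name__ == "__main__":
    main()
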
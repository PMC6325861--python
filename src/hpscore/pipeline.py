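"""End-to-end orchestration of the study replica.

``run_pipeline`` chains: dataset generation (or ingest) -> evidence
scoring -> TRS -> training and evaluation of the configured classifiers ->
feature-selection analyses -> similarity/ANOVA, and writes one report
bundle: an accuracy table (one row per classifier), a six-metric table,
selection tables (impact ranking, CFS/PCA subsets, best exhaustive
subsets), the pairwise correlation report, the Jaccard matrix, and a
provenance manifest. Every output is a ``#``-headed TSV or JSON and is a
deterministic function of (config, seed).

The tables mirror the shapes of the study's published tables but are
computed on synthetic data; the footer of each report names its data
source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .classifiers import (
    KernelSpec,
    PerceptronConfig,
    fit_bernoulli_naive_bayes,
    fit_decision_tree,
    fit_pocket_perceptron,
    fit_svm_smo,
)
from .dataset import LabeledDataset
from .evaluation import (
    SplitPlan,
    compute_metrics,
    repeated_random_split_eval,
    stratified_kfold_cv,
)
from .feature_selection import (
    cfs_select,
    exhaustive_subset_search,
    pca_rank,
    pearson_feature_correlations,
    rank_feature_impact,
)
from .scoring import RuleConfig, build_feature_matrix
from .similarity import anova_oneway, class_feature_groups, jaccard_matrix
from .simulate import DatasetSpec, generate_evidence_records, generate_labeled_dataset

DEFAULT_CLASSIFIERS = ("perceptron", "naive_bayes", "decision_tree", "svm")
DEFAULT_SELECTION = ("impact", "cfs", "pca", "exhaustive")


def classifier_factory(name: str, seed: int = 0, **kwargs):
    """Classifier factories keyed by family name (fresh model per call)."""
    if name == "perceptron":
        cfg = PerceptronConfig(seed=seed, **kwargs)
        return lambda d: fit_pocket_perceptron(d, cfg)
    if name == "naive_bayes":
        return lambda d: fit_bernoulli_naive_bayes(d, **kwargs)
    if name == "decision_tree":
        return lambda d: fit_decision_tree(d, **kwargs)
    if name == "svm":
        kernel = KernelSpec(**kwargs.pop("kernel", {}))
        return lambda d: fit_svm_smo(d, kernel=kernel, seed=seed, **kwargs)
    raise ValueError(f"unknown classifier family {name!r}")


@dataclass(frozen=True)
class PipelineConfig:
    dataset: DatasetSpec | str = field(default_factory=DatasetSpec)
    rules: RuleConfig = field(default_factory=RuleConfig)
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    evaluation: SplitPlan = field(default_factory=SplitPlan)
    selection: tuple[str, ...] = DEFAULT_SELECTION
    repeated_iterations: int = 200
    output_dir: str = "results/pipeline"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "dataset": (
                self.dataset
                if isinstance(self.dataset, str)
                else self.dataset.to_dict()
            ),
            "rules": self.rules.to_dict(),
            "classifiers": list(self.classifiers),
            "evaluation": self.evaluation.to_dict(),
            "selection": list(self.selection),
            "repeated_iterations": self.repeated_iterations,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }


def _write_table(df: pd.DataFrame, path: Path, provenance: dict,
                 footer: str) -> None:
    with open(path, "w") as fh:
        for line in hio.provenance_lines(**provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)
        fh.write(f"# source: {footer}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a manifest of written files."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # the hash covers the scientific configuration, not the output location
    chash = hio.config_hash(
        {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    )
    prov = {"config_hash": chash, "seed": config.seed}
    footer = "synthetic replication profile (not the study's real dataset)"
    manifest: dict = {"config_hash": chash, "seed": config.seed, "files": []}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_table(df, path, prov, footer)
        manifest["files"].append(name)

    # --- stage 1: dataset ---------------------------------------------------
    try:
        if isinstance(config.dataset, str):
            data = hio.read_feature_matrix(config.dataset)
        else:
            spec = config.dataset
            if spec.seed != config.seed:
                spec = DatasetSpec(**{**spec.to_dict(), "seed": config.seed})
            data = generate_labeled_dataset(spec)
            records = generate_evidence_records(
                data, config.rules, seed=config.seed + 1
            )
            hio.write_evidence_records(records, out / "evidence.jsonl")
            manifest["files"].append("evidence.jsonl")
            labels = {
                pid: ("positive" if lab == 1 else "negative")
                for pid, lab in zip(data.ids, data.y)
            }
            # rescore the emitted evidence: the scoring stage is exercised
            # end to end, and must reproduce the generated matrix
            data = build_feature_matrix(records, config.rules, labels=labels)
    except Exception as exc:
        raise RuntimeError(f"stage 'dataset' failed: {exc}") from exc
    hio.write_feature_matrix(data, out / "feature_matrix.tsv", prov)
    manifest["files"].append("feature_matrix.tsv")
    manifest["n_rows"] = len(data)
    manifest["n_positive"] = int(data.y.sum()) if data.y is not None else None

    factories = {
        name: classifier_factory(name, seed=config.seed)
        for name in config.classifiers
    }

    # --- stage 2: train + evaluate -------------------------------------------
    if factories and data.y is not None:
        try:
            acc_rows, metric_rows = [], []
            for name, fit in factories.items():
                _, pooled = stratified_kfold_cv(data, fit, config.evaluation)
                rep_plan = SplitPlan(
                    protocol="repeated_split",
                    train_fraction=config.evaluation.train_fraction,
                    iterations=config.repeated_iterations,
                    stratified=config.evaluation.stratified,
                    seed=config.seed,
                )
                rep = repeated_random_split_eval(data, fit, rep_plan)
                acc_rows.append(
                    {
                        "algorithm": name,
                        "cv_accuracy_pct": round(100 * pooled.accuracy, 2),
                        "split_mean_pct": round(100 * rep.mean_accuracy, 2),
                        "split_max_pct": round(100 * rep.max_accuracy, 2),
                        "split_min_pct": round(100 * rep.min_accuracy, 2),
                    }
                )
                metric_rows.append(
                    {"algorithm": name,
                     **{k: (round(v, 4) if isinstance(v, float) else v)
                        for k, v in pooled.to_dict().items()
                        if k != "undefined"}}
                )
            emit("accuracy_table.tsv", pd.DataFrame(acc_rows))
            emit("metrics_table.tsv", pd.DataFrame(metric_rows))
        except Exception as exc:
            raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    # --- stage 3: feature selection ------------------------------------------
    if config.selection and data.y is not None:
        try:
            nb = classifier_factory("naive_bayes")
            if "impact" in config.selection:
                ranks = rank_feature_impact(data, nb, config.evaluation)
                emit(
                    "impact_ranking.tsv",
                    pd.DataFrame(
                        [{"feature": f, "rank": r}
                         for f, r in sorted(ranks.items())]
                    ),
                )
            sel_rows = []
            if "cfs" in config.selection:
                subset = cfs_select(data)
                sel_rows.append(
                    {"method": "cfs",
                     "subset": ",".join(map(str, sorted(subset)))}
                )
            if "pca" in config.selection:
                ranking = pca_rank(data)
                sel_rows.append(
                    {"method": "pca_ranker",
                     "subset": ",".join(map(str, ranking.order))}
                )
            if sel_rows:
                emit("selection_subsets.tsv", pd.DataFrame(sel_rows))
            if "exhaustive" in config.selection:
                best, table = exhaustive_subset_search(
                    data, nb, config.evaluation
                )
                emit(
                    "subset_search.tsv",
                    pd.DataFrame(
                        [{"subset": ",".join(map(str, r.subset)),
                          "accuracy": round(r.accuracy, 6),
                          "n_features": r.n_features}
                         for r in table]
                    ),
                )
                manifest["best_subset"] = list(best.subset)
                manifest["best_subset_accuracy"] = best.accuracy
        except Exception as exc:
            raise RuntimeError(f"stage 'select' failed: {exc}") from exc

    # --- stage 4: similarity + correlation + ANOVA ----------------------------
    try:
        corr = pearson_feature_correlations(data)
        emit(
            "feature_correlations.tsv",
            pd.DataFrame(
                [{"feature_i": i, "feature_j": j,
                  "pearson_r": round(r, 6) if r == r else "NA",
                  "p_two_tailed": f"{p:.6g}" if p == p else "NA"}
                 for i, j, r, p in corr.pairs]
            ),
        )
        sim = jaccard_matrix(data)
        mat = pd.DataFrame(
            np.round(sim.values, 6), index=sim.ids, columns=sim.ids
        )
        with open(out / "jaccard_matrix.tsv", "w") as fh:
            for line in hio.provenance_lines(**prov):
                fh.write(line + "\n")
            mat.to_csv(fh, sep="\t", index_label="protein_id")
        manifest["files"].append("jaccard_matrix.tsv")
        iu = np.triu_indices(len(sim.ids), k=1)
        emit(
            "jaccard_long.tsv",
            pd.DataFrame(
                {"id1": [sim.ids[i] for i in iu[0]],
                 "id2": [sim.ids[j] for j in iu[1]],
                 "jaccard": np.round(sim.values[iu], 6),
                 "distance": np.round(1.0 - sim.values[iu], 6)}
            ),
        )
        if data.y is not None:
            anova = {
                "grouping": "per-feature score columns within each class",
                "positive": anova_oneway(
                    class_feature_groups(data, positive=True)
                ).to_dict(),
                "negative": anova_oneway(
                    class_feature_groups(data, positive=False)
                ).to_dict(),
            }
            with open(out / "anova.json", "w") as fh:
                json.dump({**prov, **anova}, fh, indent=1)
            manifest["files"].append("anova.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'similarity' failed: {exc}") from exc

    manifest["config"] = config.to_dict()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
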
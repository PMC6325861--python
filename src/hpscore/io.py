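"""File formats: TSV feature matrices, JSONL evidence, JSON models.

Every tabular output starts with ``#``-prefixed provenance lines carrying
the seed and a hash of the effective configuration, so any file can be
traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import ClassifierModel, model_from_dict
from .dataset import LabeledDataset, feature_columns
from .scoring import EvidenceRecord, HitEvidence, RuleConfig


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def config_hash(obj: dict) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(**fields) -> list[str]:
    return [f"# {key}: {value}" for key, value in fields.items()]


def write_feature_matrix(
    data: LabeledDataset, path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    lines = provenance_lines(**(provenance or {}))
    df = data.to_frame()
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> LabeledDataset:
    """Read a scored matrix; malformed cells are reported with line numbers."""
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} columns, "
                    f"got {len(parts)}"
                )
            rows.append([lineno, *parts])
    if header is None:
        raise ParseError(f"{path}: no header line found")
    fcols = [c for c in header if c.startswith("f") and c[1:].isdigit()]
    required = {"protein_id", *fcols}
    missing = required - set(header)
    if missing or not fcols:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    col_of = {name: i for i, name in enumerate(header)}
    ids, X, y = [], [], []
    has_label = "label" in header
    for lineno, *parts in rows:
        ids.append(parts[col_of["protein_id"]])
        scores = []
        for c in fcols:
            cell = parts[col_of[c]]
            if cell not in ("0", "1"):
                raise ParseError(
                    f"{path}: line {lineno}: non-binary score {cell!r} "
                    f"in column {c}"
                )
            scores.append(int(cell))
        if "trs" in col_of:
            trs = parts[col_of["trs"]]
            if trs != str(sum(scores)):
                raise ParseError(
                    f"{path}: line {lineno}: trs {trs} inconsistent with "
                    f"scores (sum {sum(scores)})"
                )
        X.append(scores)
        if has_label:
            lab = parts[col_of["label"]]
            if lab not in ("positive", "negative"):
                raise ParseError(
                    f"{path}: line {lineno}: unknown label {lab!r}"
                )
            y.append(1 if lab == "positive" else 0)
    m = len(fcols)
    return LabeledDataset(
        ids=ids,
        X=np.array(X, dtype=np.int8).reshape(len(ids), m),
        y=np.array(y, dtype=np.int8) if has_label else None,
    )


# --- evidence records (JSON Lines) -----------------------------------------


def _hit_to_dict(h: HitEvidence) -> dict:
    return {
        "rank": h.rank,
        "organism": h.organism,
        "e_value": h.e_value,
        "bit_score": h.bit_score,
        "percent_identity": h.percent_identity,
        "has_atg_start_any_frame": h.has_atg_start_any_frame,
        "is_ncrna_annotated": h.is_ncrna_annotated,
        "is_pdb_template": h.is_pdb_template,
        "flags": sorted(h.flags),
    }


def write_evidence_records(
    records: list[EvidenceRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "protein_id": rec.protein_id,
                        "feature_id": rec.feature_id,
                        "hits": [_hit_to_dict(h) for h in rec.hits],
                        "flags": sorted(rec.flags),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_evidence_records(path: str | Path) -> list[EvidenceRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                d = json.loads(line)
                hits = tuple(
                    HitEvidence(
                        rank=h["rank"],
                        organism=h.get("organism", ""),
                        e_value=h.get("e_value", 0.0),
                        bit_score=h.get("bit_score", 0.0),
                        percent_identity=h.get("percent_identity", 0.0),
                        has_atg_start_any_frame=h.get(
                            "has_atg_start_any_frame", True
                        ),
                        is_ncrna_annotated=h.get("is_ncrna_annotated", False),
                        is_pdb_template=h.get("is_pdb_template", False),
                        flags=frozenset(h.get("flags", ())),
                    )
                    for h in d.get("hits", ())
                )
                records.append(
                    EvidenceRecord(
                        protein_id=d["protein_id"],
                        feature_id=d["feature_id"],
                        hits=hits,
                        flags=frozenset(d.get("flags", ())),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


# --- models and configs -----------------------------------------------------


def save_model(model: ClassifierModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path: str | Path) -> ClassifierModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def load_config_file(path: str | Path) -> dict:
    """YAML or JSON configuration (YAML is a superset, so one loader)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return data


def load_rule_config(path: str | Path | None) -> RuleConfig:
    if path is None:
        return RuleConfig()
    return RuleConfig.from_dict(load_config_file(path))
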
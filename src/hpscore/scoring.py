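"""Nine-point binary scoring schema for hypothetical proteins.

Each candidate protein is annotated against nine evidence features:

1. Pfam domain match          4. bidirectional best BLAST hit
2. orthology inference        5. subcellular localization
3. protein interactions       6. functional linkages
7. pseudogene linkage         8. homology modelling (PDB template)
9. non-coding RNA linkage

Every feature contributes a binary score (1 = criterion met, 0 = not met);
their sum is the Total Reliability Score (TRS), an integer in [0, 9].

The three structure-specific rules (pseudogene, homology modelling, ncRNA)
are implemented exactly; the six legacy features are driven by a generic
per-feature rule engine (E-value cutoff / hit presence / minimum score)
because their detailed criteria are configurable, not fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import LabeledDataset

HUMAN = "Homo sapiens"

#: flags that disqualify a hit from consideration in every rule
EXCLUSION_FLAGS = frozenset({"predicted", "synthetic", "end_to_end_alignment"})

FEATURE_NAMES = {
    1: "pfam",
    2: "orthology",
    3: "protein_interactions",
    4: "bidirectional_best_blast_hits",
    5: "subcellular_localization",
    6: "functional_linkages",
    7: "pseudogenes",
    8: "homology_modelling",
    9: "non_coding_rnas",
}


class ContractViolation(ValueError):
    """A scoring rule was applied to a record of the wrong feature."""


class ConfigurationError(ValueError):
    """A rule needs a cutoff that the configuration does not provide."""


@dataclass(frozen=True)
class HitEvidence:
    """One database/search hit supporting (or failing to support) a feature."""

    rank: int
    organism: str = HUMAN
    e_value: float = 0.0
    bit_score: float = 0.0
    percent_identity: float = 0.0
    has_atg_start_any_frame: bool = True
    is_ncrna_annotated: bool = False
    is_pdb_template: bool = False
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError(f"hit rank must be >= 1, got {self.rank}")
        if self.e_value < 0:
            raise ValueError(f"E-value must be non-negative, got {self.e_value}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity must be in [0, 100], got {self.percent_identity}"
            )
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class EvidenceRecord:
    """All hits gathered for one protein under one feature."""

    protein_id: str
    feature_id: int
    hits: tuple[HitEvidence, ...] = ()
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.feature_id not in FEATURE_NAMES:
            raise ValueError(f"feature_id must be in 1..9, got {self.feature_id}")
        hits = tuple(sorted(self.hits, key=lambda h: h.rank))
        object.__setattr__(self, "hits", hits)
        object.__setattr__(self, "flags", frozenset(self.flags))

    def retained_hits(self) -> list[HitEvidence]:
        """Hits after discarding predicted/synthetic/end-to-end evidence.

        Record-level flags apply to every hit; rule semantics are identical
        either way.
        """
        out = []
        for h in self.hits:
            if (h.flags | self.flags) & EXCLUSION_FLAGS:
                continue
            out.append(h)
        return out


@dataclass(frozen=True)
class FeatureVector:
    """The nine binary scores plus TRS for one protein."""

    protein_id: str
    scores: tuple[int, ...]
    trs: int = -1

    def __post_init__(self):
        if len(self.scores) != 9:
            raise ValueError(f"expected 9 scores, got {len(self.scores)}")
        if any(s not in (0, 1) for s in self.scores):
            raise ValueError(f"scores must be binary, got {self.scores}")
        if self.trs == -1:
            object.__setattr__(self, "trs", sum(self.scores))
        elif self.trs != sum(self.scores):
            raise ValueError(f"trs {self.trs} != sum(scores) {sum(self.scores)}")


@dataclass(frozen=True)
class LegacyRule:
    """Threshold/presence rule for one of the six legacy features.

    kind:
      - ``evalue``:    best retained hit must have e_value <= cutoff
      - ``presence``:  at least one retained hit
      - ``min_score``: best retained hit must have bit_score >= cutoff
    """

    kind: str
    cutoff: float = 0.0

    def __post_init__(self):
        if self.kind not in ("evalue", "presence", "min_score"):
            raise ConfigurationError(f"unknown legacy rule kind {self.kind!r}")


def _default_legacy_rules() -> dict[int, LegacyRule]:
    return {
        1: LegacyRule("evalue", 1e-3),      # Pfam domain E-value
        2: LegacyRule("presence"),          # ortholog hit present
        3: LegacyRule("min_score", 0.4),    # interaction confidence score
        4: LegacyRule("presence"),          # reciprocal best hit present
        5: LegacyRule("presence"),          # predicted localization present
        6: LegacyRule("min_score", 0.7),    # functional-linkage confidence
    }


@dataclass(frozen=True)
class RuleConfig:
    """Tunable thresholds of the scoring schema.

    The homology threshold is strict (> 30 % identity scores 1); the
    pseudogene E-value cutoff defaults to 1.0 (E < 1 is "significant" for
    this rule); the ncRNA rule examines the top 3 human hits, widened to 5
    when the relative bit-score spread among the top 5 is below 5 %.
    """

    homology_identity_threshold: float = 30.0
    pseudogene_evalue_cutoff: float = 1.0
    ncrna_top_k: int = 3
    ncrna_extended_k: int = 5
    ncrna_score_spread_fraction: float = 0.05
    legacy_rule_cutoffs: dict[int, LegacyRule] = field(
        default_factory=_default_legacy_rules
    )

    def __post_init__(self):
        if self.homology_identity_threshold <= 0:
            raise ValueError("homology_identity_threshold must be positive")
        if self.pseudogene_evalue_cutoff <= 0:
            raise ValueError("pseudogene_evalue_cutoff must be positive")
        if self.ncrna_top_k > self.ncrna_extended_k:
            raise ValueError("ncrna_top_k must be <= ncrna_extended_k")

    def to_dict(self) -> dict:
        return {
            "homology_identity_threshold": self.homology_identity_threshold,
            "pseudogene_evalue_cutoff": self.pseudogene_evalue_cutoff,
            "ncrna_top_k": self.ncrna_top_k,
            "ncrna_extended_k": self.ncrna_extended_k,
            "ncrna_score_spread_fraction": self.ncrna_score_spread_fraction,
            "legacy_rule_cutoffs": {
                str(fid): {"kind": r.kind, "cutoff": r.cutoff}
                for fid, r in sorted(self.legacy_rule_cutoffs.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleConfig":
        d = dict(d)
        legacy = d.pop("legacy_rule_cutoffs", None)
        if legacy is not None:
            d["legacy_rule_cutoffs"] = {
                int(fid): LegacyRule(r["kind"], r.get("cutoff", 0.0))
                for fid, r in legacy.items()
            }
        return cls(**d)


def _require_feature(record: EvidenceRecord, allowed: set[int]) -> None:
    if record.feature_id not in allowed:
        raise ContractViolation(
            f"record for feature {record.feature_id} passed to a rule "
            f"expecting feature(s) {sorted(allowed)}"
        )


def score_pseudogene(record: EvidenceRecord, config: RuleConfig) -> int:
    """Pseudogene linkage rule (feature 7).

    After discarding predicted/synthetic/end-to-end hits, score 1 iff some
    Homo sapiens hit below the E-value cutoff lacks an ATG start codon in
    all six reading frames (no methionine start => pseudogene candidate).
    """
    _require_feature(record, {7})
    for hit in record.retained_hits():
        if (
            hit.organism == HUMAN
            and hit.e_value < config.pseudogene_evalue_cutoff
            and not hit.has_atg_start_any_frame
        ):
            return 1
    return 0


def score_homology_model(record: EvidenceRecord, config: RuleConfig) -> int:
    """Homology modelling rule (feature 8).

    Score 1 iff some retained PDB-template hit shares strictly more than
    ``homology_identity_threshold`` percent identity with the query.
    """
    _require_feature(record, {8})
    for hit in record.retained_hits():
        if hit.is_pdb_template and (
            hit.percent_identity > config.homology_identity_threshold
        ):
            return 1
    return 0


def score_ncrna(record: EvidenceRecord, config: RuleConfig) -> int:
    """Non-coding RNA linkage rule (feature 9).

    The top ``ncrna_top_k`` Homo sapiens hits are examined; the window is
    widened to ``ncrna_extended_k`` when the relative bit-score spread
    among the top ``ncrna_extended_k`` hits is below
    ``ncrna_score_spread_fraction`` (no considerable difference between
    scores). Score 1 iff any examined hit is annotated as an ncRNA.
    """
    _require_feature(record, {9})
    human = [h for h in record.retained_hits() if h.organism == HUMAN]
    k = config.ncrna_top_k
    window = human[: config.ncrna_extended_k]
    if len(window) >= 2:
        scores = [h.bit_score for h in window]
        top = max(abs(s) for s in scores)
        if top > 0:
            spread = (max(scores) - min(scores)) / top
            if spread < config.ncrna_score_spread_fraction:
                k = config.ncrna_extended_k
    return int(any(h.is_ncrna_annotated for h in human[:k]))


def score_legacy_feature(record: EvidenceRecord, config: RuleConfig) -> int:
    """Generic rule for the six legacy features (1-6)."""
    _require_feature(record, {1, 2, 3, 4, 5, 6})
    rule = config.legacy_rule_cutoffs.get(record.feature_id)
    if rule is None:
        raise ConfigurationError(
            f"no legacy rule configured for feature {record.feature_id}"
        )
    hits = record.retained_hits()
    if not hits:
        return 0
    if rule.kind == "presence":
        return 1
    if rule.kind == "evalue":
        return int(min(h.e_value for h in hits) <= rule.cutoff)
    return int(max(h.bit_score for h in hits) >= rule.cutoff)


def score_record(record: EvidenceRecord, config: RuleConfig) -> int:
    """Dispatch a record to the rule for its feature."""
    if record.feature_id == 7:
        return score_pseudogene(record, config)
    if record.feature_id == 8:
        return score_homology_model(record, config)
    if record.feature_id == 9:
        return score_ncrna(record, config)
    return score_legacy_feature(record, config)


def compute_trs(vector: FeatureVector) -> int:
    """Total Reliability Score: sum of the nine binary scores."""
    if any(s not in (0, 1) for s in vector.scores):
        raise ValueError(f"non-binary score in {vector.scores}")
    return sum(vector.scores)


def build_feature_matrix(
    records: list[EvidenceRecord],
    config: RuleConfig | None = None,
    labels: dict[str, str] | None = None,
) -> LabeledDataset:
    """Score every record and assemble per-protein feature vectors.

    Proteins appear in input order; a protein missing a record for some
    feature receives score 0 there (absence of evidence = criterion not
    met). Duplicate (protein, feature) records are rejected.
    """
    config = config or RuleConfig()
    order: list[str] = []
    scores: dict[str, dict[int, int]] = {}
    for rec in records:
        per = scores.get(rec.protein_id)
        if per is None:
            order.append(rec.protein_id)
            per = scores[rec.protein_id] = {}
        if rec.feature_id in per:
            raise ValueError(
                f"duplicate record for protein {rec.protein_id!r} "
                f"feature {rec.feature_id}"
            )
        per[rec.feature_id] = score_record(rec, config)

    X = np.zeros((len(order), 9), dtype=np.int8)
    for i, pid in enumerate(order):
        for fid, s in scores[pid].items():
            X[i, fid - 1] = s
    y = None
    if labels is not None:
        y = np.array(
            [1 if labels[pid] == "positive" else 0 for pid in order], dtype=np.int8
        )
    return LabeledDataset(ids=list(order), X=X, y=y)
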
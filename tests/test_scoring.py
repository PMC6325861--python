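"""Scoring-rule semantics: worked examples, truth-table oracles, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpscore.scoring import (
    HUMAN,
    ContractViolation,
    EvidenceRecord,
    FeatureVector,
    HitEvidence,
    LegacyRule,
    RuleConfig,
    build_feature_matrix,
    compute_trs,
    score_homology_model,
    score_legacy_feature,
    score_ncrna,
    score_pseudogene,
)

CFG = RuleConfig()


def rec(fid, *hits, flags=frozenset()):
    return EvidenceRecord(
        protein_id="P1", feature_id=fid, hits=tuple(hits), flags=flags
    )


class TestPseudogeneRule:
    def test_qualifying_human_hit_without_atg_scores_one(self):
        hit = HitEvidence(rank=1, organism=HUMAN, e_value=1e-20,
                          has_atg_start_any_frame=False)
        assert score_pseudogene(rec(7, hit), CFG) == 1

    def test_no_hits_scores_zero(self):
        assert score_pseudogene(rec(7), CFG) == 0

    @pytest.mark.parametrize("flag", ["predicted", "synthetic",
                                      "end_to_end_alignment"])
    def test_exclusion_flag_disqualifies_only_qualifying_hit(self, flag):
        hit = HitEvidence(rank=1, organism=HUMAN, e_value=1e-20,
                          has_atg_start_any_frame=False,
                          flags=frozenset({flag}))
        assert score_pseudogene(rec(7, hit), CFG) == 0

    def test_record_level_flag_applies_to_all_hits(self):
        hit = HitEvidence(rank=1, organism=HUMAN, e_value=1e-20,
                          has_atg_start_any_frame=False)
        assert score_pseudogene(
            rec(7, hit, flags=frozenset({"synthetic"})), CFG) == 0

    def test_atg_start_or_wrong_organism_or_high_evalue_disqualify(self):
        atg = HitEvidence(rank=1, organism=HUMAN, e_value=1e-20)
        mouse = HitEvidence(rank=1, organism="Mus musculus", e_value=1e-20,
                            has_atg_start_any_frame=False)
        weak = HitEvidence(rank=1, organism=HUMAN, e_value=5.0,
                           has_atg_start_any_frame=False)
        for h in (atg, mouse, weak):
            assert score_pseudogene(rec(7, h), CFG) == 0

    def test_wrong_feature_id_rejected(self):
        with pytest.raises(ContractViolation):
            score_pseudogene(rec(8), CFG)


class TestHomologyRule:
    @pytest.mark.parametrize(
        "identity,expected",
        [(35.0, 1), (30.1, 1), (30.0, 0), (29.9, 0), (100.0, 1), (0.0, 0)],
    )
    def test_strict_identity_threshold(self, identity, expected):
        hit = HitEvidence(rank=1, is_pdb_template=True,
                          percent_identity=identity)
        assert score_homology_model(rec(8, hit), CFG) == expected

    def test_non_template_hit_ignored(self):
        hit = HitEvidence(rank=1, is_pdb_template=False, percent_identity=90.0)
        assert score_homology_model(rec(8, hit), CFG) == 0

    def test_no_hits_scores_zero(self):
        assert score_homology_model(rec(8), CFG) == 0

    def test_configurable_threshold(self):
        hit = HitEvidence(rank=1, is_pdb_template=True, percent_identity=35.0)
        strict = RuleConfig(homology_identity_threshold=40.0)
        assert score_homology_model(rec(8, hit), strict) == 0

    def test_raising_threshold_never_raises_score(self):
        hits = [HitEvidence(rank=r, is_pdb_template=True,
                            percent_identity=idp)
                for r, idp in enumerate([12.0, 31.0, 55.0], start=1)]
        record = rec(8, *hits)
        prev = 1
        for thr in (10.0, 30.0, 54.0, 60.0, 99.0):
            s = score_homology_model(
                record, RuleConfig(homology_identity_threshold=thr))
            assert s <= prev
            prev = s


def ncrna_hits(scores, ncrna_rank, organisms=None):
    hits = []
    for i, s in enumerate(scores, start=1):
        hits.append(HitEvidence(
            rank=i,
            organism=(organisms[i - 1] if organisms else HUMAN),
            bit_score=s,
            is_ncrna_annotated=(i == ncrna_rank),
        ))
    return hits


class TestNcrnaRule:
    def test_ncrna_hit_in_top_three_scores_one(self):
        hits = ncrna_hits([100, 80, 60, 40, 20], ncrna_rank=2)
        assert score_ncrna(rec(9, *hits), CFG) == 1

    def test_non_human_hits_score_zero(self):
        hits = ncrna_hits([100, 80, 60], ncrna_rank=1,
                          organisms=["Mus musculus"] * 3)
        assert score_ncrna(rec(9, *hits), CFG) == 0

    def test_window_widens_when_scores_are_close(self):
        # spread 2% over top 5: hit at rank 5 is examined
        close = ncrna_hits([100, 99.6, 99.2, 98.8, 98.4], ncrna_rank=5)
        assert score_ncrna(rec(9, *close), CFG) == 1
        # spread 20%: window stays at 3, rank-5 hit not examined
        wide = ncrna_hits([100, 95, 90, 85, 80], ncrna_rank=5)
        assert score_ncrna(rec(9, *wide), CFG) == 0

    def test_no_hits_scores_zero(self):
        assert score_ncrna(rec(9), CFG) == 0


class TestLegacyRules:
    def test_pfam_evalue_cutoff(self):
        good = HitEvidence(rank=1, e_value=1e-6)
        bad = HitEvidence(rank=1, e_value=0.5)
        assert score_legacy_feature(rec(1, good), CFG) == 1
        assert score_legacy_feature(rec(1, bad), CFG) == 0

    def test_presence_rules(self):
        assert score_legacy_feature(rec(4), CFG) == 0
        assert score_legacy_feature(rec(4, HitEvidence(rank=1)), CFG) == 1
        assert score_legacy_feature(rec(2, HitEvidence(rank=1)), CFG) == 1

    def test_min_score_rule(self):
        strong = HitEvidence(rank=1, bit_score=0.9)
        weak = HitEvidence(rank=1, bit_score=0.2)
        assert score_legacy_feature(rec(6, strong), CFG) == 1
        assert score_legacy_feature(rec(6, weak), CFG) == 0

    def test_flagged_hits_are_discarded(self):
        flagged = HitEvidence(rank=1, flags=frozenset({"predicted"}))
        assert score_legacy_feature(rec(4, flagged), CFG) == 0

    def test_missing_cutoff_is_configuration_error(self):
        from hpscore.scoring import ConfigurationError
        cfg = RuleConfig(legacy_rule_cutoffs={1: LegacyRule("evalue", 1e-3)})
        with pytest.raises(ConfigurationError):
            score_legacy_feature(rec(5, HitEvidence(rank=1)), cfg)

    def test_wrong_feature_rejected(self):
        with pytest.raises(ContractViolation):
            score_legacy_feature(rec(7), CFG)


# --- truth-table oracles ----------------------------------------------------
# Independent, directly coded restatements of the Table-1 rules, evaluated
# against the implementation over exhaustively enumerated evidence sets.


def oracle_pseudogene(record: EvidenceRecord, cfg: RuleConfig) -> int:
    for h in record.hits:
        excluded = bool((h.flags | record.flags) & {
            "predicted", "synthetic", "end_to_end_alignment"})
        if excluded:
            continue
        if h.organism != HUMAN:
            continue
        if h.e_value >= cfg.pseudogene_evalue_cutoff:
            continue
        if not h.has_atg_start_any_frame:
            return 1
    return 0


def oracle_homology(record: EvidenceRecord, cfg: RuleConfig) -> int:
    for h in record.hits:
        excluded = bool((h.flags | record.flags) & {
            "predicted", "synthetic", "end_to_end_alignment"})
        if not excluded and h.is_pdb_template and (
            h.percent_identity > cfg.homology_identity_threshold
        ):
            return 1
    return 0


def _pseudogene_hit_variants():
    variants = []
    for org, ev, atg, flag in itertools.product(
        [HUMAN, "Mus musculus"],
        [1e-20, 5.0],
        [False, True],
        [None, "predicted", "synthetic", "end_to_end_alignment"],
    ):
        variants.append(dict(
            organism=org, e_value=ev, has_atg_start_any_frame=atg,
            flags=frozenset() if flag is None else frozenset({flag}),
        ))
    return variants


def _homology_hit_variants():
    variants = []
    for pdb, ident, flag in itertools.product(
        [True, False], [29.9, 30.0, 30.1], [None, "end_to_end_alignment"]
    ):
        variants.append(dict(
            is_pdb_template=pdb, percent_identity=ident,
            flags=frozenset() if flag is None else frozenset({flag}),
        ))
    return variants


@pytest.mark.parametrize(
    "fid,variants,impl,oracle",
    [
        (7, _pseudogene_hit_variants(), score_pseudogene, oracle_pseudogene),
        (8, _homology_hit_variants(), score_homology_model, oracle_homology),
    ],
    ids=["pseudogene", "homology"],
)
def test_rule_equals_truth_table_oracle_on_enumerated_evidence(
    fid, variants, impl, oracle
):
    """Exhaustive agreement on all <=2-hit evidence sets (plus 3-hit spot set)."""
    singles = [
        rec(fid, HitEvidence(rank=1, **v)) for v in variants
    ]
    doubles = [
        rec(fid, HitEvidence(rank=1, **a), HitEvidence(rank=2, **b))
        for a, b in itertools.product(variants, variants)
    ]
    triples = [
        rec(fid, HitEvidence(rank=1, **a), HitEvidence(rank=2, **b),
            HitEvidence(rank=3, **c))
        for a, b, c in zip(variants, reversed(variants), variants[1:])
    ]
    for record in [rec(fid), *singles, *doubles, *triples]:
        assert impl(record, CFG) == oracle(record, CFG), record


# --- feature vectors, TRS, matrix assembly ---------------------------------


class TestTrsAndMatrix:
    @pytest.mark.parametrize(
        "scores,expected",
        [((1,) * 9, 9), ((0,) * 9, 0), ((1, 0, 1, 0, 1, 0, 1, 0, 1), 5)],
    )
    def test_trs_is_sum_of_scores(self, scores, expected):
        assert compute_trs(FeatureVector("P1", scores)) == expected

    def test_non_binary_scores_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector("P1", (2, 0, 0, 0, 0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            FeatureVector("P1", (1, 1, 1), trs=3)

    def test_inconsistent_trs_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector("P1", (1,) * 9, trs=5)

    def test_missing_features_score_zero_and_order_is_preserved(self):
        hit = HitEvidence(rank=1, is_pdb_template=True, percent_identity=50.0)
        records = [
            EvidenceRecord("B", 8, (hit,)),
            EvidenceRecord("A", 4, (HitEvidence(rank=1),)),
        ]
        data = build_feature_matrix(records, CFG)
        assert data.ids == ["B", "A"]
        assert data.X[0].tolist() == [0, 0, 0, 0, 0, 0, 0, 1, 0]
        assert data.X[1].tolist() == [0, 0, 0, 1, 0, 0, 0, 0, 0]
        assert data.trs.tolist() == [1, 1]

    def test_duplicate_protein_feature_pair_rejected(self):
        records = [rec(8), rec(8)]
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_matrix(records, CFG)

    def test_empty_record_list_gives_empty_nine_column_matrix(self):
        data = build_feature_matrix([], CFG)
        assert len(data) == 0 and data.X.shape == (0, 9)

    def test_scoring_is_pure(self):
        hit = HitEvidence(rank=1, organism=HUMAN, e_value=1e-5,
                          has_atg_start_any_frame=False)
        records = [EvidenceRecord("P", 7, (hit,))]
        a = build_feature_matrix(records, CFG)
        b = build_feature_matrix(records, CFG)
        assert a == b


# --- property tests ---------------------------------------------------------

hit_strategy = st.builds(
    HitEvidence,
    rank=st.integers(min_value=1, max_value=5),
    organism=st.sampled_from([HUMAN, "Mus musculus"]),
    e_value=st.sampled_from([0.0, 1e-20, 1e-3, 0.9, 5.0]),
    bit_score=st.floats(min_value=0, max_value=500, allow_nan=False),
    percent_identity=st.floats(min_value=0, max_value=100, allow_nan=False),
    has_atg_start_any_frame=st.booleans(),
    is_ncrna_annotated=st.booleans(),
    is_pdb_template=st.booleans(),
    flags=st.sets(
        st.sampled_from(["predicted", "synthetic", "end_to_end_alignment"]),
        max_size=1,
    ).map(frozenset),
)


@settings(max_examples=80, derandomize=True)
@given(hits=st.lists(hit_strategy, max_size=4), fid=st.integers(1, 9))
def test_every_rule_output_is_binary(hits, fid):
    from hpscore.scoring import score_record
    record = EvidenceRecord("P", fid, tuple(hits))
    assert score_record(record, CFG) in (0, 1)


@settings(max_examples=60, derandomize=True)
@given(hits=st.lists(hit_strategy, max_size=3))
def test_adding_qualifying_hit_never_decreases_pseudogene_score(hits):
    record = EvidenceRecord("P", 7, tuple(hits))
    before = score_pseudogene(record, CFG)
    extra = HitEvidence(rank=len(hits) + 1, organism=HUMAN, e_value=1e-9,
                        has_atg_start_any_frame=False)
    after = score_pseudogene(
        EvidenceRecord("P", 7, tuple(hits) + (extra,)), CFG)
    assert after >= before
    assert after == 1
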
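"""Curator statistics: TP/FP/FN, the confidence gate, overlaps, revalidation."""

import random

import pytest

from conftest import make_record
from ruleprop.engine import apply_rule
from ruleprop.fixtures import FixtureSpec, generate_corpus, generate_rules
from ruleprop.quality_stats import (
    annotation_key,
    compute_coverage_depth,
    compute_rule_stats,
    detect_overlaps,
    revalidate_rules,
)
from ruleprop.engine import annotate_all
from ruleprop.rule_model import (
    Annotation,
    CommonConditions,
    Condition,
    ConditionSet,
    Rule,
    SpecialCase,
)

FUNCTION = Annotation("comment", "function", "Required for normal Golgi function")


def keyword_rule(rule_id="UR000000010", signature="PF1", value="Membrane"):
    return Rule(
        rule_id=rule_id,
        common=CommonConditions(
            [ConditionSet([Condition(kind="signature", signature_id=signature)])]
        ),
        base_annotations=[Annotation("keyword", "", value)],
    )


def function_rule(value="F1", rule_id="UR000000011", signature="PF1"):
    return Rule(
        rule_id=rule_id,
        common=CommonConditions(
            [ConditionSet([Condition(kind="signature", signature_id=signature)])]
        ),
        base_annotations=[Annotation("comment", "function", value)],
    )


def reviewed_corpus(n_match, n_carrying, rule_ann, n_outside_carrying=0, signature="PF1"):
    """n_match in-condition records of which n_carrying carry the annotation."""
    records = []
    for i in range(n_match):
        anns = [rule_ann] if i < n_carrying else []
        records.append(
            make_record(f"RV{i:03d}", signatures=(signature,), reviewed=True, annotations=anns)
        )
    for i in range(n_outside_carrying):
        records.append(
            make_record(f"FN{i:03d}", signatures=(), reviewed=True, annotations=[rule_ann])
        )
    return records


# ---------------------------------------------------------------------------
# the confidence gate
# ---------------------------------------------------------------------------

def test_19_of_20_supports_confidence_095_and_passes():
    rule = function_rule()
    stats = compute_rule_stats(rule, reviewed_corpus(20, 19, rule.base_annotations[0]))
    (s,) = stats.per_annotation
    assert (s.tp, s.fp, s.fn) == (19, 1, 0)
    assert s.confidence == pytest.approx(0.95)
    assert stats.accepted


def test_18_of_20_fails_the_gate():
    rule = function_rule()
    stats = compute_rule_stats(rule, reviewed_corpus(20, 18, rule.base_annotations[0]))
    assert stats.per_annotation[0].confidence == pytest.approx(0.90)
    assert not stats.accepted


def test_gate_monotone_in_threshold():
    rule = function_rule()
    corpus = reviewed_corpus(20, 19, rule.base_annotations[0])
    accepted = [
        compute_rule_stats(rule, corpus, threshold=t).accepted
        for t in (0.5, 0.9, 0.95, 0.96, 1.0)
    ]
    # once rejected, raising the threshold never re-accepts
    assert accepted == sorted(accepted, reverse=True)


def test_out_of_condition_carrier_counts_as_fn_only():
    rule = function_rule()
    base = reviewed_corpus(20, 19, rule.base_annotations[0])
    with_fn = reviewed_corpus(20, 19, rule.base_annotations[0], n_outside_carrying=1)
    s0 = compute_rule_stats(rule, base).per_annotation[0]
    s1 = compute_rule_stats(rule, with_fn).per_annotation[0]
    assert (s1.tp, s1.fp) == (s0.tp, s0.fp)
    assert s1.fn == s0.fn + 1
    assert s1.confidence == s0.confidence


def test_exclusions_remove_records_from_all_counts():
    rule = function_rule()
    ann = rule.base_annotations[0]
    corpus = reviewed_corpus(20, 19, ann)
    # exclude the one FP record (RV019 carries nothing)
    exclusions = {("RV019", ann): "semantic variation"}
    s = compute_rule_stats(rule, corpus, exclusions=exclusions).per_annotation[0]
    assert (s.tp, s.fp, s.fn) == (19, 0, 0)
    assert s.excluded_records == ["RV019"]
    assert s.confidence == 1.0


def test_all_matching_excluded_means_unsupported_and_rejected():
    rule = function_rule()
    ann = rule.base_annotations[0]
    corpus = reviewed_corpus(3, 3, ann)
    exclusions = {(r.accession, ann): "x" for r in corpus}
    stats = compute_rule_stats(rule, corpus, exclusions=exclusions)
    assert stats.per_annotation[0].unsupported
    assert stats.per_annotation[0].confidence is None
    assert not stats.accepted


def test_special_case_annotations_scored_on_subgroup():
    rule = Rule(
        rule_id="UR000000012",
        common=CommonConditions(
            [ConditionSet([Condition(kind="signature", signature_id="PF1")])]
        ),
        base_annotations=[Annotation("keyword", "", "Membrane")],
        special_cases=[
            SpecialCase(
                ConditionSet([Condition(kind="taxon", taxon="Fungi")]),
                [Annotation("comment", "function", "Fungal role")],
            )
        ],
    )
    fungal = [
        make_record(f"F{i}", signatures=("PF1",), reviewed=True,
                    annotations=[Annotation("keyword", "", "Membrane"),
                                 Annotation("comment", "function", "Fungal role")])
        for i in range(5)
    ]
    metazoan = [
        make_record(f"M{i}", ("Eukaryota", "Metazoa"), ("PF1",), reviewed=True,
                    annotations=[Annotation("keyword", "", "Membrane")])
        for i in range(5)
    ]
    stats = compute_rule_stats(rule, fungal + metazoan)
    by_scope = {s.scope: s for s in stats.per_annotation}
    assert (by_scope["base"].tp, by_scope["base"].fp) == (10, 0)
    # the metazoan records are outside the special case, so they are not FP for it
    assert (by_scope["special_case_0"].tp, by_scope["special_case_0"].fp) == (5, 0)
    assert stats.accepted


def test_free_text_comparator_folds_case_and_whitespace():
    a = Annotation("comment", "function", "Required  for normal\tGolgi function")
    b = Annotation("comment", "function", "required for NORMAL Golgi function")
    assert annotation_key(a) == annotation_key(b)
    # controlled vocabularies compare exactly
    assert annotation_key(Annotation("keyword", "", "Membrane")) != annotation_key(
        Annotation("keyword", "", "membrane")
    )


def test_tp_fp_excluded_partition_matching_records():
    rules = generate_rules(3, seed=31)
    reviewed, _ = generate_corpus(FixtureSpec(seed=32, n_records=25, annotation_noise=0.2), rules)
    for rule in rules:
        stats = compute_rule_stats(rule, reviewed)
        for s in stats.per_annotation:
            if s.scope != "base":
                continue
            from ruleprop.engine import satisfies_common
            n_match = sum(1 for r in reviewed if satisfies_common(rule, r))
            assert s.tp + s.fp + len(s.excluded_records) == n_match


# ---------------------------------------------------------------------------
# overlap detection
# ---------------------------------------------------------------------------

def test_disjoint_rules_produce_no_pairs():
    a = keyword_rule("UR000000021", "PF1")
    b = keyword_rule("UR000000022", "PF2")
    records = [
        make_record("X1", signatures=("PF1",)),
        make_record("X2", signatures=("PF2",)),
    ]
    assert detect_overlaps([a, b], records).pairs == []


def test_conflicting_function_values_reported():
    a = function_rule("F1", "UR000000023")
    b = function_rule("F2", "UR000000024")
    records = [make_record("X1", signatures=("PF1",))]
    report = detect_overlaps([a, b], records)
    (pair,) = report.pairs
    assert pair.shared_accessions == ["X1"]
    (conflict,) = pair.conflicts
    assert (conflict.value_a, conflict.value_b) == ("F1", "F2")
    assert pair.duplicates == []


def test_identical_annotations_are_duplicates_not_conflicts():
    a = keyword_rule("UR000000025", "PF1", "Membrane")
    b = keyword_rule("UR000000026", "PF1", "Membrane")
    report = detect_overlaps([a, b], [make_record("X1", signatures=("PF1",))])
    (pair,) = report.pairs
    assert pair.conflicts == []
    assert pair.duplicates == [("X1", "keyword", "", "Membrane")]


def test_overlap_report_symmetric_in_rule_order():
    a = function_rule("F1", "UR000000023")
    b = function_rule("F2", "UR000000024")
    records = [make_record("X1", signatures=("PF1",))]
    r1 = detect_overlaps([a, b], records)
    r2 = detect_overlaps([b, a], records)
    assert r1 == r2


def test_overlaps_agree_with_bruteforce_intersection():
    rules = generate_rules(6, seed=41)
    _, unreviewed = generate_corpus(FixtureSpec(seed=42, n_records=1, n_unreviewed=40), rules)
    report = detect_overlaps(rules, unreviewed)
    matched = {
        rule.rule_id: {r.accession for r in unreviewed if apply_rule(rule, r)}
        for rule in rules
    }
    expected_pairs = {
        tuple(sorted((a, b)))
        for a in matched for b in matched
        if a < b and matched[a] & matched[b]
    }
    assert {(p.rule_a, p.rule_b) for p in report.pairs} == expected_pairs
    for p in report.pairs:
        assert set(p.shared_accessions) == matched[p.rule_a] & matched[p.rule_b]


# ---------------------------------------------------------------------------
# revalidation
# ---------------------------------------------------------------------------

def test_withdrawn_signature_flagged():
    rule = function_rule()
    corpus = reviewed_corpus(10, 10, rule.base_annotations[0])
    (res,) = revalidate_rules([rule], corpus, known_signatures={"PF9"})
    assert "withdrawn_signature" in res.flags
    assert "PF1" in res.details


def test_annotation_drift_flagged():
    rule = function_rule()
    corpus = reviewed_corpus(10, 9, rule.base_annotations[0])  # confidence 0.90
    (res,) = revalidate_rules([rule], corpus, known_signatures={"PF1"})
    assert res.flags == ("inconsistent_annotation",)
    assert "0.90" in res.details


def test_both_flags_may_apply():
    rule = function_rule()
    corpus = reviewed_corpus(10, 9, rule.base_annotations[0])
    (res,) = revalidate_rules([rule], corpus, known_signatures=set())
    assert set(res.flags) == {"withdrawn_signature", "inconsistent_annotation"}


def test_untouched_passing_rule_is_ok():
    rule = function_rule()
    corpus = reviewed_corpus(10, 10, rule.base_annotations[0])
    (res,) = revalidate_rules([rule], corpus, known_signatures={"PF1"})
    assert res.flags == () and res.status == "ok"


# ---------------------------------------------------------------------------
# coverage and depth
# ---------------------------------------------------------------------------

def test_coverage_counts_annotated_fraction():
    rule = keyword_rule()
    records = [make_record(f"U{i}", signatures=("PF1",) if i < 3 else ()) for i in range(10)]
    results = annotate_all([rule], records)
    cd = compute_coverage_depth(results, records)
    assert cd.n_unreviewed == 10 and cd.n_annotated == 3
    assert cd.coverage == pytest.approx(0.30)
    assert cd.coverage_by_taxon["Eukaryota"] == pytest.approx(0.30)


def test_depth_buckets_and_partition():
    rule = Rule(
        rule_id="UR000000030",
        common=CommonConditions(
            [ConditionSet([Condition(kind="signature", signature_id="PF1")])]
        ),
        base_annotations=[
            Annotation("protein_name", "full", "Some protein"),
            Annotation("comment", "function", "Does things"),
            Annotation("keyword", "", "Membrane"),
        ],
    )
    records = [make_record("U1", signatures=("PF1",)), make_record("U2", signatures=())]
    results = annotate_all([rule], records)
    cd = compute_coverage_depth(results, records)
    assert cd.depth[3] == pytest.approx(1.0)
    assert sum(cd.depth.values()) == pytest.approx(1.0)


def test_depth_partition_on_random_corpus():
    rules = generate_rules(4, seed=51)
    _, unreviewed = generate_corpus(FixtureSpec(seed=52, n_records=1, n_unreviewed=40), rules)
    results = annotate_all(rules, unreviewed)
    cd = compute_coverage_depth(results, unreviewed)
    if cd.n_annotated:
        assert sum(cd.depth.values()) == pytest.approx(1.0)
    assert 0.0 <= cd.coverage <= 1.0
    for frac in cd.coverage_by_taxon.values():
        assert 0.0 <= frac <= 1.0
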
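"""Curator-facing quality statistics for rules.

A candidate rule is judged on the reviewed corpus it was built from: for
each annotation it proposes, TP counts the reviewed records meeting the
rule's conditions that carry the annotation, FP those that do not, and FN
the annotation-carrying records *outside* the condition set.  A rule is
accepted only when every annotation's confidence TP/(TP+FP) reaches the
threshold (default 0.95).  Curators may exclude specific (record,
annotation) pairs from the counts — the standard remedy for free-text
semantic variation that is not a biological disagreement.

Also here: inter-rule overlap/conflict detection on the unreviewed set,
release-time revalidation (withdrawn signatures, annotation drift), and the
coverage/depth summary of an annotation run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from .engine import apply_rule, satisfies_common, evaluate_condition, AnnotationResult
from .formats_io import ProteinRecord
from .positional_features import align_to_template, match_pattern
from .rule_model import Annotation, Rule

#: Categories compared exactly (controlled vocabularies); everything else is
#: free text and compared after whitespace normalisation and case-folding.
CONTROLLED_CATEGORIES = frozenset({"keyword", "go_term"})

#: The four top-level annotation categories used in depth reporting; every
#: comment-like category collapses onto "comment".
_DEPTH_GROUPS = {
    "protein_name": "protein_name",
    "comment": "comment",
    "go_term": "comment",
    "subcellular_location": "comment",
    "catalytic_activity": "comment",
    "pathway": "comment",
    "sequence_feature": "sequence_feature",
    "keyword": "keyword",
}


def annotation_key(ann: Annotation) -> tuple[str, str, str]:
    """Equality key for annotation comparison in statistics and benchmarks.

    (category, subtype, value); free-text values are whitespace-normalised
    and case-folded, controlled-vocabulary values compared exactly.  The
    residue position of sequence features is deliberately ignored — site
    positions legitimately differ between homologous records.
    """
    value = ann.value
    if ann.category not in CONTROLLED_CATEGORIES:
        value = " ".join(value.split()).casefold()
    return (ann.category, ann.subtype, value)


@dataclass
class AnnotationStatistics:
    """TP/FP/FN and confidence for a single rule annotation."""

    annotation: Annotation
    scope: str  # "base", "special_case_<k>" or "positional"
    tp: int = 0
    fp: int = 0
    fn: int = 0
    confidence: float | None = None
    unsupported: bool = False
    excluded_records: list[str] = field(default_factory=list)


@dataclass
class RuleStatistics:
    """Per-annotation statistics and the acceptance verdict for one rule."""

    rule_id: str
    per_annotation: list[AnnotationStatistics]
    threshold: float
    accepted: bool


def _positional_scope(rule: Rule, pattern) -> Callable[[ProteinRecord], bool]:
    def in_scope(record: ProteinRecord) -> bool:
        if not satisfies_common(rule, record) or not record.sequence:
            return False
        pmap = align_to_template(record.sequence, rule.positional.template_sequence)
        return match_pattern(record.sequence, pattern, pmap) is not None

    return in_scope


def _annotation_targets(rule: Rule):
    """Yield (annotation, scope label, scope predicate) for every rule annotation."""
    for ann in rule.base_annotations:
        yield ann, "base", lambda r, rule=rule: satisfies_common(rule, r)
    for k, case in enumerate(rule.special_cases):
        def in_case(r, rule=rule, case=case):
            return satisfies_common(rule, r) and all(
                evaluate_condition(c, r) for c in case.extra_conditions.conditions
            )
        for ann in case.annotations:
            yield ann, f"special_case_{k}", in_case
    if rule.positional is not None:
        for pat in rule.positional.patterns:
            yield pat.annotation, "positional", _positional_scope(rule, pat)


def compute_rule_stats(
    rule: Rule,
    reviewed: list[ProteinRecord],
    exclusions: Mapping[tuple[str, Annotation], str] | None = None,
    threshold: float = 0.95,
) -> RuleStatistics:
    """Score every annotation of a rule over a reviewed corpus.

    ``exclusions`` maps (accession, annotation) pairs to a curator's reason;
    excluded pairs are removed from TP, FP and FN alike.  An annotation with
    no non-excluded in-scope record (TP+FP = 0) has undefined confidence, is
    flagged unsupported, and blocks acceptance.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    excluded_keys = {
        (acc, annotation_key(ann)): reason
        for (acc, ann), reason in (exclusions or {}).items()
    }
    carried = {rec.accession: {annotation_key(a) for a in rec.annotations} for rec in reviewed}
    per: list[AnnotationStatistics] = []
    for ann, scope, in_scope in _annotation_targets(rule):
        key = annotation_key(ann)
        stat = AnnotationStatistics(annotation=ann, scope=scope)
        for rec in reviewed:
            excluded = (rec.accession, key) in excluded_keys
            has = key in carried[rec.accession]
            if in_scope(rec):
                if excluded:
                    stat.excluded_records.append(rec.accession)
                elif has:
                    stat.tp += 1
                else:
                    stat.fp += 1
            elif has and not excluded:
                stat.fn += 1
        if stat.tp + stat.fp == 0:
            stat.unsupported = True
        else:
            stat.confidence = stat.tp / (stat.tp + stat.fp)
        per.append(stat)
    accepted = bool(per) and all(
        not s.unsupported and s.confidence >= threshold for s in per
    )
    return RuleStatistics(
        rule_id=rule.rule_id, per_annotation=per, threshold=threshold, accepted=accepted
    )


# ---------------------------------------------------------------------------
# Overlap and conflict detection
# ---------------------------------------------------------------------------


@dataclass
class AnnotationConflict:
    accession: str
    category: str
    subtype: str
    value_a: str
    value_b: str


@dataclass
class OverlapPair:
    rule_a: str
    rule_b: str
    shared_accessions: list[str]
    duplicates: list[tuple[str, str, str, str]]  # (accession, category, subtype, value)
    conflicts: list[AnnotationConflict]


@dataclass
class OverlapReport:
    pairs: list[OverlapPair]


def detect_overlaps(rules: list[Rule], records: list[ProteinRecord]) -> OverlapReport:
    """Find rule pairs annotating the same unreviewed records.

    For every unordered pair of rules whose matched unreviewed record sets
    intersect, reports the shared accessions, the identical annotations both
    rules emit on a record (duplicates), and the annotations where both set
    the same (category, subtype) on a record with *different* values
    (conflicts).  Symmetric in rule order.
    """
    emitted: dict[str, dict[str, list[Annotation]]] = {}
    for rule in rules:
        hits: dict[str, list[Annotation]] = {}
        for rec in records:
            if rec.reviewed:
                continue
            results = apply_rule(rule, rec)
            if results:
                hits[rec.accession] = [r.annotation for r in results]
        emitted[rule.rule_id] = hits
    ordered_ids = sorted(emitted)
    pairs: list[OverlapPair] = []
    for i, rid_a in enumerate(ordered_ids):
        for rid_b in ordered_ids[i + 1 :]:
            shared = sorted(set(emitted[rid_a]) & set(emitted[rid_b]))
            if not shared:
                continue
            duplicates: list[tuple[str, str, str, str]] = []
            conflicts: list[AnnotationConflict] = []
            for acc in shared:
                by_slot_a: dict[tuple[str, str], set[str]] = {}
                by_slot_b: dict[tuple[str, str], set[str]] = {}
                for ann in emitted[rid_a][acc]:
                    by_slot_a.setdefault((ann.category, ann.subtype), set()).add(ann.value)
                for ann in emitted[rid_b][acc]:
                    by_slot_b.setdefault((ann.category, ann.subtype), set()).add(ann.value)
                for slot in sorted(set(by_slot_a) & set(by_slot_b)):
                    norm = lambda v, c=slot[0]: (
                        v if c in CONTROLLED_CATEGORIES else " ".join(v.split()).casefold()
                    )
                    va = {norm(v): v for v in by_slot_a[slot]}
                    vb = {norm(v): v for v in by_slot_b[slot]}
                    for shared_val in sorted(set(va) & set(vb)):
                        duplicates.append((acc, slot[0], slot[1], va[shared_val]))
                    for na in sorted(set(va) - set(vb)):
                        for nb in sorted(set(vb) - set(va)):
                            conflicts.append(
                                AnnotationConflict(acc, slot[0], slot[1], va[na], vb[nb])
                            )
            pairs.append(OverlapPair(rid_a, rid_b, shared, duplicates, conflicts))
    return OverlapReport(pairs=pairs)


# ---------------------------------------------------------------------------
# Release-time revalidation
# ---------------------------------------------------------------------------


@dataclass
class RevalidationResult:
    """Outcome of a release-time check on one rule.

    ``flags`` may contain ``withdrawn_signature`` and/or
    ``inconsistent_annotation``; both can apply to the same rule.
    """

    rule_id: str
    flags: tuple[str, ...]
    details: str

    @property
    def status(self) -> str:
        return "+".join(self.flags) if self.flags else "ok"


def _referenced_signatures(rule: Rule) -> set[str]:
    sigs = set()
    for cset in rule.common.sets:
        for cond in cset.conditions:
            if cond.kind == "signature":
                sigs.add(cond.signature_id)
    for case in rule.special_cases:
        for cond in case.extra_conditions.conditions:
            if cond.kind == "signature":
                sigs.add(cond.signature_id)
    return sigs


def revalidate_rules(
    rules: list[Rule],
    reviewed: list[ProteinRecord],
    known_signatures: set[str],
    threshold: float = 0.95,
    exclusions: Mapping[tuple[str, Annotation], str] | None = None,
) -> list[RevalidationResult]:
    """Re-check rules against current signature releases and reviewed data.

    Flags ``withdrawn_signature`` when a rule references a signature absent
    from ``known_signatures`` (revised or withdrawn upstream) and
    ``inconsistent_annotation`` when the reviewed support no longer clears
    the confidence gate; a clean rule reports ``ok``.
    """
    out: list[RevalidationResult] = []
    for rule in rules:
        flags: list[str] = []
        details: list[str] = []
        missing = sorted(_referenced_signatures(rule) - set(known_signatures))
        if missing:
            flags.append("withdrawn_signature")
            details.append(f"signatures not in current release: {', '.join(missing)}")
        stats = compute_rule_stats(rule, reviewed, exclusions=exclusions, threshold=threshold)
        if not stats.accepted:
            flags.append("inconsistent_annotation")
            failing = [
                f"{s.annotation.category}/{s.annotation.subtype}"
                f"={'unsupported' if s.unsupported else f'{s.confidence:.2f}'}"
                for s in stats.per_annotation
                if s.unsupported or s.confidence < threshold
            ]
            details.append(f"below-threshold annotations: {'; '.join(failing)}")
        out.append(RevalidationResult(rule.rule_id, tuple(flags), "; ".join(details)))
    return out


# ---------------------------------------------------------------------------
# Coverage and depth
# ---------------------------------------------------------------------------


@dataclass
class CoverageDepth:
    """Coverage of the unreviewed set and depth among annotated records.

    ``coverage`` is the fraction of unreviewed records receiving at least
    one annotation; ``coverage_by_taxon`` groups it by the first (root)
    lineage element.  ``depth`` maps 1..4 to the fraction of annotated
    records receiving exactly that many of the four top-level annotation
    categories (protein name, comment-like, sequence feature, keyword); the
    fractions partition the annotated records.
    """

    n_unreviewed: int
    n_annotated: int
    coverage: float
    coverage_by_taxon: dict[str, float]
    depth: dict[int, float]


def compute_coverage_depth(
    results: Iterable[AnnotationResult], records: list[ProteinRecord]
) -> CoverageDepth:
    unreviewed = [r for r in records if not r.reviewed]
    categories_by_acc: dict[str, set[str]] = {}
    for res in results:
        group = _DEPTH_GROUPS.get(res.annotation.category)
        if group is not None:
            categories_by_acc.setdefault(res.accession, set()).add(group)
    known = {r.accession for r in unreviewed}
    annotated = {acc for acc in categories_by_acc if acc in known}
    n = len(unreviewed)
    coverage = len(annotated) / n if n else 0.0
    by_taxon: dict[str, list[ProteinRecord]] = {}
    for rec in unreviewed:
        root = rec.lineage[0].label if rec.lineage else "unclassified"
        by_taxon.setdefault(root, []).append(rec)
    coverage_by_taxon = {
        root: sum(1 for r in group if r.accession in annotated) / len(group)
        for root, group in sorted(by_taxon.items())
    }
    depth_counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for acc in annotated:
        depth_counts[len(categories_by_acc[acc])] += 1
    depth = {
        k: (v / len(annotated) if annotated else 0.0) for k, v in depth_counts.items()
    }
    return CoverageDepth(
        n_unreviewed=n,
        n_annotated=len(annotated),
        coverage=coverage,
        coverage_by_taxon=coverage_by_taxon,
        depth=depth,
    )
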
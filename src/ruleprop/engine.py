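"""Condition evaluation and annotation propagation.

Every unreviewed record is evaluated against every rule; where a record
meets a rule's common conditions the rule's base annotations are attached,
special-case annotations are added for the subgroups that also meet the
case conditions, and positional features are propagated by alignment to the
rule's template.  Each emitted annotation carries an evidence tag combining
the automatic-assertion evidence code with the source rule id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .formats_io import ProteinRecord
from .rule_model import (
    Condition,
    Evidence,
    Rule,
    Annotation,
    ECO_AUTOMATIC_ASSERTION,
)

logger = logging.getLogger(__name__)


class UnsupportedConditionError(RuntimeError):
    """Raised for condition kinds that cannot be evaluated on a record."""


@dataclass(frozen=True)
class AnnotationResult:
    """One propagated annotation on one record, with its provenance.

    ``provenance`` is ``"base"``, ``"special_case_<k>"`` (index of the firing
    case) or ``"positional"``.
    """

    accession: str
    annotation: Annotation
    evidence: Evidence
    provenance: str = "base"


def _taxon_hit(cond: Condition, record: ProteinRecord) -> bool:
    # Exact label or numeric-id match anywhere in the lineage; the numeric id
    # is preferred whenever both sides provide one.
    for entry in record.lineage:
        if cond.taxon_id is not None and entry.taxon_id is not None:
            if entry.taxon_id == cond.taxon_id:
                return True
        elif cond.taxon is not None and entry.label == cond.taxon:
            return True
    return False


def evaluate_condition(condition: Condition, record: ProteinRecord) -> bool:
    """Test one condition against one record; ``negated`` complements it."""
    if condition.kind == "signature":
        hit = any(m.signature_id == condition.signature_id for m in record.matches)
    elif condition.kind == "taxon":
        hit = _taxon_hit(condition, record)
    elif condition.kind == "sequence_length":
        hit = condition.length_min <= record.length <= condition.length_max
    elif condition.kind == "gene_tree":
        if not record.tree_ids:
            raise UnsupportedConditionError(
                f"unsupported condition kind 'gene_tree' for record "
                f"{record.accession}: no gene-tree memberships available"
            )
        hit = condition.tree_id in record.tree_ids
    else:
        raise UnsupportedConditionError(f"unsupported condition kind '{condition.kind}'")
    return hit != condition.negated


def satisfies_common(rule: Rule, record: ProteinRecord) -> bool:
    """OR over condition sets, AND within each set."""
    return any(
        all(evaluate_condition(c, record) for c in cset.conditions)
        for cset in rule.common.sets
    )


def apply_rule(rule: Rule, record: ProteinRecord) -> list[AnnotationResult]:
    """Apply one rule to one record.

    Returns the empty list when the common conditions fail.  Otherwise emits
    the base annotations, the annotations of every special case whose extra
    conditions hold, and alignment-mapped positional features.  When two
    firing special cases supply the same (category, subtype) with different
    values, both results are emitted and a warning is logged — conflict
    resolution is a curation concern, not an engine one.
    """
    if not satisfies_common(rule, record):
        return []
    evidence = Evidence(source_rule=rule.rule_id)
    results = [
        AnnotationResult(record.accession, ann, evidence, provenance="base")
        for ann in rule.base_annotations
    ]
    fired: dict[tuple[str, str], tuple[int, str]] = {}
    for k, case in enumerate(rule.special_cases):
        if all(evaluate_condition(c, record) for c in case.extra_conditions.conditions):
            for ann in case.annotations:
                key = (ann.category, ann.subtype)
                if key in fired and fired[key][1] != ann.value:
                    logger.warning(
                        "rule %s, record %s: special cases %d and %d both set %s "
                        "with different values",
                        rule.rule_id, record.accession, fired[key][0], k, key,
                    )
                else:
                    fired[key] = (k, ann.value)
                results.append(
                    AnnotationResult(
                        record.accession, ann, evidence,
                        provenance=f"special_case_{k}",
                    )
                )
    if rule.positional is not None:
        from .positional_features import propagate_features  # lazy: avoids cycle

        results.extend(propagate_features(rule, record))
    return results


def annotate_all(rules: list[Rule], records: list[ProteinRecord]) -> list[AnnotationResult]:
    """Evaluate every rule against every unreviewed record.

    Reviewed records are skipped: rules are built on them and annotate the
    unreviewed section only.  Output is sorted by (accession, rule id), with
    within-rule emission order preserved.  Duplicate rule ids are an error.
    """
    seen = set()
    for rule in rules:
        if rule.rule_id in seen:
            raise ValueError(f"duplicate rule id '{rule.rule_id}'")
        seen.add(rule.rule_id)
    results: list[AnnotationResult] = []
    for record in records:
        if record.reviewed:
            continue
        for rule in rules:
            results.extend(apply_rule(rule, record))
    results.sort(key=lambda r: (r.accession, r.evidence.source_rule))
    return results


def format_evidence(evidence: Evidence) -> str:
    """Render an evidence tag, e.g. ``ECO:0000256|UniRule:UR001001756``."""
    return f"{evidence.eco_code}|UniRule:{evidence.source_rule}"


def parse_evidence(text: str) -> Evidence:
    """Inverse of :func:`format_evidence`."""
    eco, _, rest = text.partition("|")
    prefix, _, rule_id = rest.partition(":")
    if not eco.startswith("ECO:") or prefix != "UniRule" or not rule_id:
        raise ValueError(f"malformed evidence string '{text}'")
    return Evidence(source_rule=rule_id, eco_code=eco)
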
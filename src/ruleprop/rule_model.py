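"""Domain model for annotation rules.

A rule selects proteins through *conditions* (protein-family signature
presence, taxonomic lineage membership, sequence length, and — recognised
but not evaluated by default — gene-tree membership) and propagates
*annotations* (names, free-text comments, keywords, GO terms, subcellular
locations, catalytic activities, pathways and positional sequence features)
to every record that satisfies them.

The condition logic is an OR-of-ANDs: a rule's *common conditions* are one
or more condition sets; within a set conditions are conjoined, and the sets
themselves are disjoined.  *Special cases* attach extra annotations to the
subgroup of records that additionally satisfy the case's own condition set
(e.g. a taxon-restricted function text).  An optional positional-feature
block nominates a template sequence and residue patterns whose matches, at
alignment-mapped positions, yield site-specific annotations.

Structural validation is non-raising: :func:`validate_rule` returns a list
of human-readable violations, empty for a well-formed rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Collection

#: Recognised condition kinds.  ``gene_tree`` is parsed and stored but only
#: evaluated against records that carry explicit tree memberships.
CONDITION_KINDS = frozenset({"signature", "taxon", "sequence_length", "gene_tree"})

#: Recognised annotation categories.
ANNOTATION_CATEGORIES = frozenset(
    {
        "protein_name",
        "comment",
        "keyword",
        "go_term",
        "subcellular_location",
        "catalytic_activity",
        "pathway",
        "sequence_feature",
    }
)

#: Keyword categories whose members must never be propagated by a rule,
#: seeded with the two categories that are organism- or pipeline-specific
#: rather than biological.  The mapping is configuration: callers may pass
#: their own (category -> keyword values) mapping to :func:`validate_rule`.
EXCLUDED_KEYWORD_CATEGORIES: dict[str, frozenset[str]] = {
    "Technical term": frozenset(
        {"Complete proteome", "Reference proteome", "Direct protein sequencing"}
    ),
    "Coding sequence diversity": frozenset(
        {"Alternative splicing", "Alternative initiation", "RNA editing", "Ribosomal frameshifting"}
    ),
}

_RULE_ID_RE = re.compile(r"^UR\d{9}$")

#: Evidence code attached to every propagated annotation: "match to sequence
#: model evidence used in automatic assertion".
ECO_AUTOMATIC_ASSERTION = "ECO:0000256"


@dataclass(frozen=True)
class Condition:
    """A single constraint a protein record must satisfy.

    Exactly the fields of the declared ``kind`` are populated:

    - ``signature``: ``signature_id`` (member-database or InterPro accession);
    - ``taxon``: ``taxon`` label and/or numeric ``taxon_id``;
    - ``sequence_length``: inclusive ``length_min``/``length_max``;
    - ``gene_tree``: ``tree_id``.

    ``negated`` inverts the test (e.g. taxon != Fungi).
    """

    kind: str
    negated: bool = False
    signature_id: str | None = None
    taxon: str | None = None
    taxon_id: int | None = None
    length_min: int | None = None
    length_max: int | None = None
    tree_id: str | None = None


@dataclass(frozen=True)
class ConditionSet:
    """A conjunction: a record satisfies the set iff it satisfies every member."""

    conditions: tuple[Condition, ...]

    def __init__(self, conditions):
        object.__setattr__(self, "conditions", tuple(conditions))


@dataclass(frozen=True)
class CommonConditions:
    """A disjunction over condition sets defining the rule's overall scope."""

    sets: tuple[ConditionSet, ...]

    def __init__(self, sets):
        object.__setattr__(self, "sets", tuple(sets))


@dataclass(frozen=True)
class Annotation:
    """One piece of propagated information.

    ``position`` is a 1-based inclusive residue range and is carried only by
    ``sequence_feature`` annotations.
    """

    category: str
    subtype: str = ""
    value: str = ""
    position: tuple[int, int] | None = None


@dataclass(frozen=True)
class SpecialCase:
    """Extra annotations for the subgroup also satisfying ``extra_conditions``."""

    extra_conditions: ConditionSet
    annotations: tuple[Annotation, ...]

    def __init__(self, extra_conditions, annotations):
        object.__setattr__(self, "extra_conditions", extra_conditions)
        object.__setattr__(self, "annotations", tuple(annotations))


@dataclass(frozen=True)
class PositionalPattern:
    """A residue pattern anchored to a template range, carrying its annotation.

    The pattern grammar is a PROSITE-style subset: literal residues, ``x``
    wildcard, ``[ABC]`` alternatives, ``{ABC}`` exclusions and ``(n)`` /
    ``(n,m)`` repeats; elements optionally separated by ``-``.
    """

    pattern: str
    template_start: int
    template_end: int
    annotation: Annotation


@dataclass(frozen=True)
class PositionalFeatureBlock:
    """Template sequence plus the patterns evaluated at mapped positions."""

    template_accession: str
    template_sequence: str
    patterns: tuple[PositionalPattern, ...]

    def __init__(self, template_accession, template_sequence, patterns):
        object.__setattr__(self, "template_accession", template_accession)
        object.__setattr__(self, "template_sequence", template_sequence)
        object.__setattr__(self, "patterns", tuple(patterns))


@dataclass
class Rule:
    """A complete annotation rule.

    ``metadata`` holds opaque maintenance strings (author, created, modified);
    they are preserved through I/O but never interpreted.
    """

    rule_id: str
    common: CommonConditions
    base_annotations: list[Annotation] = field(default_factory=list)
    special_cases: list[SpecialCase] = field(default_factory=list)
    positional: PositionalFeatureBlock | None = None
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Evidence:
    """Provenance tag attached to every propagated annotation."""

    source_rule: str
    eco_code: str = ECO_AUTOMATIC_ASSERTION


def _validate_condition(cond: Condition, where: str, out: list[str]) -> None:
    populated = {
        "signature_id": cond.signature_id is not None,
        "taxon": cond.taxon is not None or cond.taxon_id is not None,
        "length": cond.length_min is not None or cond.length_max is not None,
        "tree_id": cond.tree_id is not None,
    }
    expected = {
        "signature": "signature_id",
        "taxon": "taxon",
        "sequence_length": "length",
        "gene_tree": "tree_id",
    }
    if cond.kind not in CONDITION_KINDS:
        out.append(f"{where}: unknown condition kind '{cond.kind}'")
        return
    want = expected[cond.kind]
    if not populated[want]:
        out.append(f"{where}: condition of kind '{cond.kind}' lacks its '{want}' field")
    for name, is_set in populated.items():
        if name != want and is_set:
            out.append(
                f"{where}: condition of kind '{cond.kind}' populates unrelated field '{name}'"
            )
    if cond.kind == "sequence_length":
        lo, hi = cond.length_min, cond.length_max
        if lo is None or hi is None:
            out.append(f"{where}: sequence_length condition needs both length_min and length_max")
        else:
            if lo < 1 or hi < 1:
                out.append(f"{where}: length bounds must be >= 1 (got {lo}..{hi})")
            if lo > hi:
                out.append(f"{where}: length_min > length_max ({lo} > {hi})")


def _validate_annotation(
    ann: Annotation,
    where: str,
    excluded_keywords: Mapping[str, Collection[str]],
    out: list[str],
) -> None:
    if ann.category not in ANNOTATION_CATEGORIES:
        out.append(f"{where}: unknown annotation category '{ann.category}'")
        return
    if ann.category == "sequence_feature":
        if ann.position is None:
            out.append(f"{where}: sequence_feature annotation lacks a position")
        elif not (1 <= ann.position[0] <= ann.position[1]):
            out.append(f"{where}: invalid position range {ann.position}")
    elif ann.position is not None:
        out.append(f"{where}: annotation of category '{ann.category}' must not carry a position")
    if ann.category == "keyword":
        for category, values in excluded_keywords.items():
            if ann.value in values:
                out.append(
                    f"{where}: keyword '{ann.value}' belongs to excluded category "
                    f"'{category}' and must not be propagated"
                )


def validate_rule(
    rule: Rule,
    excluded_keywords: Mapping[str, Collection[str]] | None = None,
) -> list[str]:
    """Check a structurally parsed rule against the model invariants.

    Returns a list of violation descriptions (empty iff the rule is valid).
    Validation is pure and idempotent; nothing is raised and the rule is
    never modified.
    """
    if excluded_keywords is None:
        excluded_keywords = EXCLUDED_KEYWORD_CATEGORIES
    out: list[str] = []
    rid = rule.rule_id
    if not _RULE_ID_RE.match(rid or ""):
        out.append(f"rule id '{rid}' does not match 'UR' + 9 digits")
    if not rule.common.sets:
        out.append(f"{rid}: common conditions contain no condition sets")
    for i, cset in enumerate(rule.common.sets):
        if not cset.conditions:
            out.append(f"{rid}: condition set {i} is empty")
        for j, cond in enumerate(cset.conditions):
            _validate_condition(cond, f"{rid}: common set {i} condition {j}", out)
    for i, ann in enumerate(rule.base_annotations):
        _validate_annotation(ann, f"{rid}: base annotation {i}", excluded_keywords, out)
    for k, case in enumerate(rule.special_cases):
        if not case.extra_conditions.conditions:
            out.append(f"{rid}: special case {k} has an empty condition set")
        for j, cond in enumerate(case.extra_conditions.conditions):
            _validate_condition(cond, f"{rid}: special case {k} condition {j}", out)
        if not case.annotations:
            out.append(f"{rid}: special case {k} carries no annotations")
        for j, ann in enumerate(case.annotations):
            _validate_annotation(
                ann, f"{rid}: special case {k} annotation {j}", excluded_keywords, out
            )
    pos = rule.positional
    if pos is not None:
        if not pos.template_sequence:
            out.append(f"{rid}: positional block has an empty template sequence")
        if not pos.patterns:
            out.append(f"{rid}: positional block has no patterns")
        for j, pat in enumerate(pos.patterns):
            where = f"{rid}: positional pattern {j}"
            if not pat.pattern:
                out.append(f"{where}: empty pattern string")
            if pat.template_start > pat.template_end:
                out.append(
                    f"{where}: template_start > template_end "
                    f"({pat.template_start} > {pat.template_end})"
                )
            if pat.template_start < 1:
                out.append(f"{where}: template_start must be >= 1")
            if pos.template_sequence and pat.template_end > len(pos.template_sequence):
                out.append(
                    f"{where}: template_end {pat.template_end} exceeds template length "
                    f"{len(pos.template_sequence)}"
                )
            if pat.annotation.category != "sequence_feature":
                out.append(f"{where}: positional annotation must be a sequence_feature")
    if not rule.base_annotations and not rule.special_cases and pos is None:
        out.append(f"{rid}: rule propagates nothing (no annotations, cases or positional block)")
    return out


def validate_rules(rules: list[Rule], **kwargs) -> list[str]:
    """Validate a rule set: per-rule invariants plus rule-id uniqueness."""
    out: list[str] = []
    seen: dict[str, int] = {}
    for i, rule in enumerate(rules):
        if rule.rule_id in seen:
            out.append(f"duplicate rule id '{rule.rule_id}' (rules {seen[rule.rule_id]} and {i})")
        else:
            seen[rule.rule_id] = i
        out.extend(validate_rule(rule, **kwargs))
    return out
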
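"""Readers and writers for the formats the engine consumes and produces.

Inputs: a self-contained rule XML dialect (see ``docs/rule-schema.xsd``),
standard FASTA, InterProScan-style 13-column TSV signature matches, and a
taxonomy lineage table.  Outputs: annotation results as TSV or as
UniProt-flavoured flat text lines carrying the evidence string.

All coordinates everywhere are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from lxml import etree

from .rule_model import (
    Annotation,
    CommonConditions,
    Condition,
    ConditionSet,
    PositionalFeatureBlock,
    PositionalPattern,
    Rule,
    SpecialCase,
    CONDITION_KINDS,
)


@dataclass(frozen=True)
class Taxon:
    """One lineage entry: a label with an optional numeric taxonomy id."""

    label: str
    taxon_id: int | None = None


@dataclass(frozen=True)
class SignatureMatch:
    """A family/domain signature hit on a protein (1-based inclusive span)."""

    signature_id: str
    source_db: str = ""
    start: int = 1
    end: int = 1

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid match span {self.start}..{self.end} for {self.signature_id}"
            )


@dataclass
class ProteinRecord:
    """A protein as seen by the engine.

    ``sequence`` may be empty when only the length is known (positional
    features then cannot be propagated).  ``lineage`` runs root -> leaf; an
    empty lineage makes every taxon condition unsatisfiable rather than being
    an error, so records assembled from partial inputs still flow through.
    ``annotations`` is populated for reviewed records and drives the curator
    statistics.  ``tree_ids`` lists explicit gene-tree memberships, if known.
    """

    accession: str
    sequence: str = ""
    length: int = 0
    lineage: list[Taxon] = field(default_factory=list)
    matches: list[SignatureMatch] = field(default_factory=list)
    reviewed: bool = False
    annotations: list[Annotation] = field(default_factory=list)
    tree_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.sequence:
            if self.length and self.length != len(self.sequence):
                raise ValueError(
                    f"{self.accession}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
            self.length = len(self.sequence)


# ---------------------------------------------------------------------------
# Rule XML dialect
# ---------------------------------------------------------------------------

_METADATA_ATTRS = ("author", "created", "modified")


def _condition_from_xml(el, rule_id: str) -> Condition:
    kind = el.get("kind", "")
    if kind not in CONDITION_KINDS:
        raise ValueError(f"unknown condition kind '{kind}' in rule {rule_id}")
    negated = el.get("negated", "false") == "true"
    tid = el.get("taxonId")
    return Condition(
        kind=kind,
        negated=negated,
        signature_id=el.get("signature"),
        taxon=el.get("taxon"),
        taxon_id=int(tid) if tid is not None else None,
        length_min=int(el.get("min")) if el.get("min") is not None else None,
        length_max=int(el.get("max")) if el.get("max") is not None else None,
        tree_id=el.get("tree"),
    )


def _condition_to_xml(cond: Condition) -> etree._Element:
    el = etree.Element("condition", kind=cond.kind)
    if cond.negated:
        el.set("negated", "true")
    if cond.signature_id is not None:
        el.set("signature", cond.signature_id)
    if cond.taxon is not None:
        el.set("taxon", cond.taxon)
    if cond.taxon_id is not None:
        el.set("taxonId", str(cond.taxon_id))
    if cond.length_min is not None:
        el.set("min", str(cond.length_min))
    if cond.length_max is not None:
        el.set("max", str(cond.length_max))
    if cond.tree_id is not None:
        el.set("tree", cond.tree_id)
    return el


def _condition_set_from_xml(el, rule_id: str) -> ConditionSet:
    return ConditionSet(
        _condition_from_xml(c, rule_id) for c in el.findall("condition")
    )


def _condition_set_to_xml(cset: ConditionSet) -> etree._Element:
    el = etree.Element("conditionSet")
    for cond in cset.conditions:
        el.append(_condition_to_xml(cond))
    return el


def _annotation_from_xml(el) -> Annotation:
    position = None
    if el.get("positionStart") is not None:
        position = (int(el.get("positionStart")), int(el.get("positionEnd")))
    return Annotation(
        category=el.get("category", ""),
        subtype=el.get("subtype", ""),
        value=el.text or "",
        position=position,
    )


def _annotation_to_xml(ann: Annotation) -> etree._Element:
    el = etree.Element("annotation", category=ann.category)
    if ann.subtype:
        el.set("subtype", ann.subtype)
    if ann.position is not None:
        el.set("positionStart", str(ann.position[0]))
        el.set("positionEnd", str(ann.position[1]))
    el.text = ann.value
    return el


def _rule_from_xml(el) -> Rule:
    rule_id = el.get("id", "")
    csets_el = el.find("conditionSets")
    sets = (
        [_condition_set_from_xml(s, rule_id) for s in csets_el.findall("conditionSet")]
        if csets_el is not None
        else []
    )
    anns_el = el.find("annotations")
    base = (
        [_annotation_from_xml(a) for a in anns_el.findall("annotation")]
        if anns_el is not None
        else []
    )
    cases = []
    cases_el = el.find("specialCases")
    if cases_el is not None:
        for case_el in cases_el.findall("case"):
            cset = _condition_set_from_xml(case_el.find("conditionSet"), rule_id)
            case_anns = [
                _annotation_from_xml(a)
                for a in case_el.find("annotations").findall("annotation")
            ]
            cases.append(SpecialCase(cset, case_anns))
    positional = None
    pos_el = el.find("positionalFeatures")
    if pos_el is not None:
        patterns = []
        for pat_el in pos_el.findall("pattern"):
            patterns.append(
                PositionalPattern(
                    pattern=pat_el.text or "",
                    template_start=int(pat_el.get("start")),
                    template_end=int(pat_el.get("end")),
                    annotation=Annotation(
                        category="sequence_feature",
                        subtype=pat_el.get("subtype", ""),
                        value=pat_el.get("value", ""),
                        position=(int(pat_el.get("start")), int(pat_el.get("end"))),
                    ),
                )
            )
        positional = PositionalFeatureBlock(
            template_accession=pos_el.get("template", ""),
            template_sequence=pos_el.get("sequence", ""),
            patterns=patterns,
        )
    metadata = {k: el.get(k) for k in _METADATA_ATTRS if el.get(k) is not None}
    return Rule(
        rule_id=rule_id,
        common=CommonConditions(sets),
        base_annotations=base,
        special_cases=cases,
        positional=positional,
        metadata=metadata,
    )


def _rule_to_xml(rule: Rule) -> etree._Element:
    el = etree.Element("rule", id=rule.rule_id)
    for key in _METADATA_ATTRS:
        if key in rule.metadata:
            el.set(key, rule.metadata[key])
    csets_el = etree.SubElement(el, "conditionSets")
    for cset in rule.common.sets:
        csets_el.append(_condition_set_to_xml(cset))
    if rule.base_annotations:
        anns_el = etree.SubElement(el, "annotations")
        for ann in rule.base_annotations:
            anns_el.append(_annotation_to_xml(ann))
    if rule.special_cases:
        cases_el = etree.SubElement(el, "specialCases")
        for case in rule.special_cases:
            case_el = etree.SubElement(cases_el, "case")
            case_el.append(_condition_set_to_xml(case.extra_conditions))
            case_anns_el = etree.SubElement(case_el, "annotations")
            for ann in case.annotations:
                case_anns_el.append(_annotation_to_xml(ann))
    if rule.positional is not None:
        pos_el = etree.SubElement(
            el,
            "positionalFeatures",
            template=rule.positional.template_accession,
            sequence=rule.positional.template_sequence,
        )
        for pat in rule.positional.patterns:
            pat_el = etree.SubElement(
                pos_el,
                "pattern",
                start=str(pat.template_start),
                end=str(pat.template_end),
            )
            if pat.annotation.subtype:
                pat_el.set("subtype", pat.annotation.subtype)
            if pat.annotation.value:
                pat_el.set("value", pat.annotation.value)
            pat_el.text = pat.pattern
    return el


def read_rules(path) -> list[Rule]:
    """Parse a rule XML document, returning rules in document order.

    Raises ``lxml.etree.XMLSyntaxError`` (naming the line) for malformed
    XML and ``ValueError`` for an unknown condition kind.  Structural
    validation beyond parseability is the caller's job
    (:func:`ruleprop.rule_model.validate_rule`).
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "rules":
        raise ValueError(f"expected root element <rules>, got <{root.tag}>")
    return [_rule_from_xml(el) for el in root.findall("rule")]


def write_rules(rules: Iterable[Rule], path) -> None:
    """Serialize rules to the XML dialect; inverse of :func:`read_rules`."""
    root = etree.Element("rules")
    for rule in rules:
        root.append(_rule_to_xml(rule))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# InterProScan-style TSV
# ---------------------------------------------------------------------------

def read_interproscan_tsv(path) -> dict[str, list[SignatureMatch]]:
    """Parse InterProScan 13-column TSV into per-accession signature matches.

    Each row yields a match for the member-database signature (column 5);
    when column 12 carries an InterPro accession a second match with that id
    is recorded over the same span, so rule conditions may reference either
    id level.  Score/status columns are ignored: all reported matches are
    treated as present.
    """
    matches: dict[str, list[SignatureMatch]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ValueError(
                    f"line {lineno}: expected >= 11 tab-separated columns, got {len(cols)}"
                )
            acc = cols[0]
            try:
                start, end = int(cols[6]), int(cols[7])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-integer match coordinates "
                    f"'{cols[6]}'/'{cols[7]}'"
                ) from None
            row = matches.setdefault(acc, [])
            row.append(SignatureMatch(cols[4], source_db=cols[3], start=start, end=end))
            if len(cols) > 11 and cols[11] not in ("", "-"):
                row.append(
                    SignatureMatch(cols[11], source_db="InterPro", start=start, end=end)
                )
    return matches


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_DB_DECORATION = re.compile(r"^[^|]+\|([^|]+)\|")


def _accession_from_header(token: str) -> str:
    m = _DB_DECORATION.match(token)
    return m.group(1) if m else token


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an accession -> sequence mapping.

    The accession is the first whitespace-delimited header token, with a
    leading ``db|ACC|name`` decoration stripped to ``ACC``.  Duplicate
    accessions are an error.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.id)
        if acc in out:
            raise ValueError(f"duplicate accession '{acc}' in {path}")
        out[acc] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    """Write an accession -> sequence mapping as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Lineage table
# ---------------------------------------------------------------------------

def _parse_lineage(text: str) -> list[Taxon]:
    out = []
    for entry in text.split(";"):
        entry = entry.strip()
        if not entry:
            continue
        head, sep, rest = entry.partition(":")
        if sep and head.isdigit():
            out.append(Taxon(rest.strip(), int(head)))
        else:
            out.append(Taxon(entry))
    return out


def read_lineage_table(path) -> dict[str, list[Taxon]]:
    """Read a TSV of accession -> semicolon-separated root-to-leaf lineage.

    Entries are either bare labels or ``taxid:label``; both forms are
    retained.  An empty lineage field is an error naming the accession.
    """
    out: dict[str, list[Taxon]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            acc, _, rest = line.partition("\t")
            lineage = _parse_lineage(rest)
            if not lineage:
                raise ValueError(f"empty lineage for accession '{acc}'")
            out[acc] = lineage
    return out


def write_lineage_table(lineages: Mapping[str, list[Taxon]], path) -> None:
    with open(path, "w") as fh:
        for acc, lineage in lineages.items():
            parts = [
                f"{t.taxon_id}:{t.label}" if t.taxon_id is not None else t.label
                for t in lineage
            ]
            fh.write(f"{acc}\t{';'.join(parts)}\n")


def build_records(
    sequences: Mapping[str, str] | None = None,
    matches: Mapping[str, list[SignatureMatch]] | None = None,
    lineages: Mapping[str, list[Taxon]] | None = None,
    lengths: Mapping[str, int] | None = None,
    reviewed: bool = False,
) -> list[ProteinRecord]:
    """Assemble protein records from whichever inputs exist.

    Accessions are unioned across the inputs; a record missing sequence,
    matches or lineage is built with what is present (a missing lineage makes
    taxon conditions unsatisfiable, a missing sequence disables positional
    features).  Output is sorted by accession.
    """
    sequences = sequences or {}
    matches = matches or {}
    lineages = lineages or {}
    lengths = lengths or {}
    accessions = sorted(set(sequences) | set(matches) | set(lineages) | set(lengths))
    return [
        ProteinRecord(
            accession=acc,
            sequence=sequences.get(acc, ""),
            length=lengths.get(acc, 0),
            lineage=list(lineages.get(acc, [])),
            matches=list(matches.get(acc, [])),
            reviewed=reviewed,
        )
        for acc in accessions
    ]


# ---------------------------------------------------------------------------
# Annotation output
# ---------------------------------------------------------------------------

ANNOTATION_TSV_HEADER = "accession\tcategory\tsubtype\tvalue\tposition\tevidence"

_FLAT_COMMENT_TOPICS = {
    "subcellular_location": "SUBCELLULAR LOCATION",
    "catalytic_activity": "CATALYTIC ACTIVITY",
    "pathway": "PATHWAY",
}


def _sorted_results(results):
    return sorted(
        results,
        key=lambda r: (r.accession, r.annotation.category, r.annotation.value),
    )


def _flat_line(result) -> str:
    from .engine import format_evidence  # local import avoids a cycle

    ann = result.annotation
    ev = "{" + format_evidence(result.evidence) + "}"
    if ann.category == "protein_name":
        return f"DE   RecName: Full={ann.value}; {ev}"
    if ann.category == "comment":
        topic = (ann.subtype or "function").upper()
        return f"CC   -!- {topic}: {ann.value} {ev}"
    if ann.category in _FLAT_COMMENT_TOPICS:
        return f"CC   -!- {_FLAT_COMMENT_TOPICS[ann.category]}: {ann.value} {ev}"
    if ann.category == "keyword":
        return f"KW   {ann.value} {ev}"
    if ann.category == "go_term":
        return f"DR   GO; {ann.value} {ev}"
    if ann.category == "sequence_feature":
        start, end = ann.position
        loc = str(start) if start == end else f"{start}..{end}"
        kind = (ann.subtype or "site").upper()
        return f'FT   {kind} {loc} /note="{ann.value}" {ev}'
    raise ValueError(f"unknown annotation category '{ann.category}'")


def write_annotations(results, path, format: str = "tsv") -> None:
    """Write annotation results as ``tsv`` or UniProt-flavoured ``flat`` text.

    TSV rows are sorted by (accession, category, value) and each carries the
    evidence string; flat output groups lines per accession, every line
    ending with the evidence string in braces.
    """
    from .engine import format_evidence

    if format not in ("tsv", "flat"):
        raise ValueError(f"unknown output format '{format}'")
    ordered = _sorted_results(results)
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write(ANNOTATION_TSV_HEADER + "\n")
            for r in ordered:
                ann = r.annotation
                pos = ""
                if ann.position is not None:
                    pos = f"{ann.position[0]}..{ann.position[1]}"
                fh.write(
                    "\t".join(
                        [
                            r.accession,
                            ann.category,
                            ann.subtype,
                            ann.value,
                            pos,
                            format_evidence(r.evidence),
                        ]
                    )
                    + "\n"
                )
        else:
            current = None
            for r in ordered:
                if r.accession != current:
                    if current is not None:
                        fh.write("//\n")
                    fh.write(f"AC   {r.accession}\n")
                    current = r.accession
                fh.write(_flat_line(r) + "\n")
            if current is not None:
                fh.write("//\n")


def read_annotation_tsv(path) -> list[tuple[str, Annotation]]:
    """Read (accession, annotation) pairs from the TSV written above.

    Also accepts 4-column files (accession, category, subtype, value) such
    as gold-standard corpora, where position and evidence are absent.
    """
    pairs: list[tuple[str, Annotation]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("accession\t"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 columns")
            position = None
            if len(cols) > 4 and cols[4]:
                lo, _, hi = cols[4].partition("..")
                position = (int(lo), int(hi or lo))
            pairs.append(
                (cols[0], Annotation(cols[1], cols[2], cols[3], position=position))
            )
    return pairs
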
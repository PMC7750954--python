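"""Deterministic synthetic rules and corpora for testing the full pipeline.

Everything here is driven by one seeded random generator, so identical
specs produce identical corpora.  The generator emulates the statistical
structure the rule system assumes: condition-defined sets of reviewed
records whose annotations are mostly consistent (a record omits a planted
annotation with probability ``annotation_noise``, producing false-positive
support), plus off-condition records that carry the annotations (producing
false negatives), plus unreviewed records mirroring the condition structure
without annotations.  Positional-feature targets are copies of the rule's
template with point mutations outside the pattern sites and, at
``insertion_rate``, insertions between sites.

Also ships a hand-built worked-example rule (:func:`fig1_rule`) for the
conserved oligomeric Golgi complex subunit 6 family.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .engine import evaluate_condition, satisfies_common
from .formats_io import (
    ProteinRecord,
    SignatureMatch,
    Taxon,
    write_fasta,
    write_lineage_table,
    write_rules,
)
from .positional_features import AMINO_ACIDS
from .rule_model import (
    Annotation,
    CommonConditions,
    Condition,
    ConditionSet,
    PositionalFeatureBlock,
    PositionalPattern,
    Rule,
    SpecialCase,
)

#: Numeric taxonomy ids for the labels the default lineage templates use.
TAXON_IDS = {
    "Eukaryota": 2759,
    "Fungi": 4751,
    "Metazoa": 33208,
    "Viridiplantae": 33090,
    "Bacteria": 2,
    "Proteobacteria": 1224,
    "Firmicutes": 1239,
    "Archaea": 2157,
    "Euryarchaeota": 28890,
    "Viruses": 10239,
}

_DEFAULT_TAXA = (
    ("Eukaryota", "Fungi", "Saccharomycetes"),
    ("Eukaryota", "Metazoa", "Mammalia"),
    ("Eukaryota", "Viridiplantae", "Magnoliopsida"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
    ("Bacteria", "Firmicutes", "Bacilli"),
    ("Archaea", "Euryarchaeota", "Methanococci"),
    ("Viruses", "Riboviria", "Orthornavirae"),
)

_DEFAULT_SIGNATURES = (
    "PF06419", "PF17073", "IPR031411", "PF00069", "PF00501",
    "PIRSF000876", "PS51257", "TIGR00344", "PF02518", "IPR000719",
)

_NAME_POOL = (
    "Conserved oligomeric Golgi complex subunit 6",
    "Serine/threonine-protein kinase",
    "Long-chain-fatty-acid--CoA ligase",
    "ATP-dependent Clp protease proteolytic subunit",
    "Ribosomal RNA small subunit methyltransferase A",
)
_FUNCTION_POOL = (
    "Required for normal Golgi function",
    "Catalyzes the phosphorylation of serine and threonine residues",
    "Activates fatty acids by forming acyl-CoA thioesters",
    "Participates in the degradation of misfolded proteins",
    "Methylates adenine residues in 16S rRNA",
)
_KEYWORD_POOL = (
    "Membrane", "Transport", "Kinase", "Golgi apparatus",
    "Metal-binding", "Transferase", "Protein transport",
)
_GO_POOL = ("GO:0005794", "GO:0016020", "GO:0006810", "GO:0016301", "GO:0005737")
_LOCATION_POOL = (
    "Golgi apparatus membrane", "Cytoplasm", "Cell membrane", "Nucleus",
)
_FEATURE_VALUE_POOL = ("Proton acceptor", "Zinc", "Phosphoserine", "Substrate")
_FEATURE_SUBTYPES = ("active_site", "binding_site", "modified_residue")


@dataclass
class FixtureSpec:
    """Study conditions for corpus generation.

    ``annotation_noise`` is the per-annotation probability that a reviewed
    in-condition record *omits* a planted annotation (false-positive
    support); ``insertion_rate`` the per-record probability that a
    positional-feature target carries an insertion relative to the template.
    """

    seed: int = 0
    n_records: int = 50
    n_unreviewed: int = 60
    n_offcondition: int = 5
    taxa: tuple[tuple[str, ...], ...] = _DEFAULT_TAXA
    signature_pool: tuple[str, ...] = _DEFAULT_SIGNATURES
    length_range: tuple[int, int] = (50, 400)
    annotation_noise: float = 0.0
    insertion_rate: float = 0.0

    def __post_init__(self):
        for name in ("annotation_noise", "insertion_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


#: Representative fungal function text for the worked-example rule.  Only
#: the non-fungal text is fixed by the source material; this value is a
#: synthetic stand-in phrased in the family's own terms.
COG6_FUNGAL_FUNCTION = (
    "Acts as a component of the peripheral membrane COG complex that is "
    "involved in intra-Golgi protein trafficking"
)


def fig1_rule() -> Rule:
    """The worked-example rule UR001001756 for the COG6 protein family.

    One common condition set (eukaryote AND Pfam signature PF06419 AND
    length 1-900), two base subcellular-location annotations, and two
    taxon-restricted function texts: one for fungi, one (taxon != Fungi)
    for all other eukaryotes.
    """
    common = CommonConditions(
        [
            ConditionSet(
                [
                    Condition(kind="taxon", taxon="Eukaryota", taxon_id=TAXON_IDS["Eukaryota"]),
                    Condition(kind="signature", signature_id="PF06419"),
                    Condition(kind="sequence_length", length_min=1, length_max=900),
                ]
            )
        ]
    )
    base = [
        Annotation("subcellular_location", "location", "Golgi apparatus membrane"),
        Annotation("subcellular_location", "topology", "Peripheral membrane protein"),
    ]
    fungi = Condition(kind="taxon", taxon="Fungi", taxon_id=TAXON_IDS["Fungi"])
    cases = [
        SpecialCase(
            ConditionSet([fungi]),
            [Annotation("comment", "function", COG6_FUNGAL_FUNCTION)],
        ),
        SpecialCase(
            ConditionSet([Condition(kind="taxon", negated=True, taxon="Fungi",
                                    taxon_id=TAXON_IDS["Fungi"])]),
            [Annotation("comment", "function", "Required for normal Golgi function")],
        ),
    ]
    return Rule(
        rule_id="UR001001756",
        common=common,
        base_annotations=base,
        special_cases=cases,
        metadata={"author": "fixture", "created": "2020-01-01"},
    )


def _taxon_condition(label: str, rng: random.Random, negated: bool = False) -> Condition:
    return Condition(
        kind="taxon", negated=negated, taxon=label, taxon_id=TAXON_IDS.get(label)
    )


def _random_annotations(rng: random.Random, k: int) -> list[Annotation]:
    candidates = (
        [("protein_name", "full", v) for v in _NAME_POOL]
        + [("comment", "function", v) for v in _FUNCTION_POOL]
        + [("keyword", "", v) for v in _KEYWORD_POOL]
        + [("go_term", "", v) for v in _GO_POOL]
        + [("subcellular_location", "location", v) for v in _LOCATION_POOL]
    )
    return [Annotation(c, s, v) for c, s, v in rng.sample(candidates, k)]


def _random_positional_block(rng: random.Random) -> PositionalFeatureBlock:
    length = rng.randint(40, 80)
    template = "".join(rng.choices(AMINO_ACIDS, k=length))
    n_patterns = rng.randint(1, 3)
    spans: list[tuple[int, int]] = []
    cursor = 1
    for _ in range(n_patterns):
        width = rng.randint(3, 5)
        start = rng.randint(cursor, cursor + 8)
        end = start + width - 1
        if end > length:
            break
        spans.append((start, end))
        cursor = end + 3
    if not spans:
        spans = [(1, 3)]
    patterns = [
        PositionalPattern(
            pattern="-".join(template[s - 1 : e]),
            template_start=s,
            template_end=e,
            annotation=Annotation(
                "sequence_feature",
                rng.choice(_FEATURE_SUBTYPES),
                rng.choice(_FEATURE_VALUE_POOL),
                position=(s, e),
            ),
        )
        for s, e in spans
    ]
    return PositionalFeatureBlock("TEMPLATE", template, patterns)


def generate_rules(
    n: int,
    seed: int | random.Random = 0,
    spec: FixtureSpec | None = None,
    with_positional: float = 0.25,
    with_special_case: float = 0.4,
) -> list[Rule]:
    """Generate ``n`` random structurally valid rules.

    Every condition set contains at least one signature condition, so a
    record with no matching signatures fails every rule — which is what the
    corpus generator relies on to build off-condition records.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    spec = spec or FixtureSpec()
    all_labels = sorted({label for template in spec.taxa for label in template})
    rules: list[Rule] = []
    used_ids: set[str] = set()
    for _ in range(n):
        while True:
            rule_id = f"UR{rng.randrange(1_000_000_000):09d}"
            if rule_id not in used_ids:
                used_ids.add(rule_id)
                break
        positional = _random_positional_block(rng) if rng.random() < with_positional else None
        sets = []
        for _ in range(1 if rng.random() < 0.7 else 2):
            conds = [Condition(kind="signature", signature_id=rng.choice(spec.signature_pool))]
            if rng.random() < 0.6:
                conds.append(
                    _taxon_condition(rng.choice(all_labels), rng, negated=rng.random() < 0.15)
                )
            if positional is not None:
                conds.append(
                    Condition(
                        kind="sequence_length",
                        length_min=1,
                        length_max=len(positional.template_sequence) + 50,
                    )
                )
            elif rng.random() < 0.5:
                lo = rng.randint(*spec.length_range)
                conds.append(
                    Condition(
                        kind="sequence_length",
                        length_min=lo,
                        length_max=lo + rng.randint(20, 200),
                    )
                )
            sets.append(ConditionSet(conds))
        base = _random_annotations(rng, rng.randint(1, 3))
        cases = []
        if rng.random() < with_special_case:
            # draw the subgroup taxon from a lineage template compatible with
            # the first common set, so the subgroup is populatable
            compatible = _templates_satisfying(sets[0].conditions, spec.taxa) or list(spec.taxa)
            label = rng.choice(rng.choice(compatible))
            cases.append(
                SpecialCase(
                    ConditionSet([_taxon_condition(label, rng)]),
                    [
                        Annotation(
                            "comment",
                            "function",
                            f"{rng.choice(_FUNCTION_POOL)} (lineage-specific, {label})",
                        )
                    ],
                )
            )
        rules.append(
            Rule(
                rule_id=rule_id,
                common=CommonConditions(sets),
                base_annotations=base,
                special_cases=cases,
                positional=positional,
                metadata={"author": "generator", "created": "2020-01-01"},
            )
        )
    return rules


def _lineage_for(template: tuple[str, ...]) -> list[Taxon]:
    return [Taxon(label, TAXON_IDS.get(label)) for label in template]


def _templates_satisfying(conditions, taxa):
    positive = [c.taxon for c in conditions if c.kind == "taxon" and not c.negated]
    negative = {c.taxon for c in conditions if c.kind == "taxon" and c.negated}
    return [
        t
        for t in taxa
        if all(p in t for p in positive) and not any(x in t for x in negative)
    ]


def _satisfying_lineage(cset: ConditionSet, spec: FixtureSpec, rng: random.Random):
    candidates = _templates_satisfying(cset.conditions, spec.taxa)
    if candidates:
        return _lineage_for(rng.choice(candidates))
    positive = [c.taxon for c in cset.conditions if c.kind == "taxon" and not c.negated]
    labels = positive or ["Eukaryota"]
    return [Taxon(label, TAXON_IDS.get(label)) for label in labels]


def _length_bounds(cset: ConditionSet, spec: FixtureSpec) -> tuple[int, int]:
    lo, hi = spec.length_range
    for c in cset.conditions:
        if c.kind == "sequence_length" and not c.negated:
            lo, hi = max(lo, c.length_min), min(hi, c.length_max)
    if lo > hi:  # length conditions narrower than the spec range
        lo = hi = max(1, min(hi, lo))
    return lo, hi


def _mutated_target(
    block: PositionalFeatureBlock, spec: FixtureSpec, rng: random.Random
) -> str:
    spans = [(p.template_start, p.template_end) for p in block.patterns]
    protected = {i for s, e in spans for i in range(s, e + 1)}
    residues = list(block.template_sequence)
    for i in range(len(residues)):
        if (i + 1) not in protected and rng.random() < 0.05:
            residues[i] = rng.choice(AMINO_ACIDS.replace(residues[i], ""))
    seq = "".join(residues)
    if rng.random() < spec.insertion_rate:
        # gap index p (0..len) splits a pattern span (s, e) iff s <= p < e
        allowed = [
            p for p in range(len(seq) + 1) if not any(s <= p < e for s, e in spans)
        ]
        p = rng.choice(allowed)
        insert = "".join(rng.choices(AMINO_ACIDS, k=rng.randint(1, 7)))
        seq = seq[:p] + insert + seq[p:]
    return seq


def _signature_matches(ids, length: int, rng: random.Random) -> list[SignatureMatch]:
    out = []
    for sig in ids:
        start = rng.randint(1, max(1, length // 2))
        end = rng.randint(start, length)
        db = "InterPro" if sig.startswith("IPR") else "Pfam"
        out.append(SignatureMatch(sig, source_db=db, start=start, end=end))
    return out


def _matching_record(
    rule: Rule, accession: str, spec: FixtureSpec, rng: random.Random, reviewed: bool
) -> ProteinRecord:
    cset = rule.common.sets[0]
    lineage = None
    if rule.special_cases and rng.random() < 0.5:
        # half the matching records also populate the first special-case
        # subgroup, so case annotations have reviewed support
        combined = list(cset.conditions) + list(
            rule.special_cases[0].extra_conditions.conditions
        )
        candidates = _templates_satisfying(combined, spec.taxa)
        if candidates:
            lineage = _lineage_for(rng.choice(candidates))
    if lineage is None:
        lineage = _satisfying_lineage(cset, spec, rng)
    required = [c.signature_id for c in cset.conditions if c.kind == "signature"]
    if rule.positional is not None:
        sequence = _mutated_target(rule.positional, spec, rng)
    else:
        lo, hi = _length_bounds(cset, spec)
        sequence = "".join(rng.choices(AMINO_ACIDS, k=rng.randint(lo, hi)))
    extras = [rng.choice(spec.signature_pool)] if rng.random() < 0.3 else []
    return ProteinRecord(
        accession=accession,
        sequence=sequence,
        lineage=lineage,
        matches=_signature_matches(dict.fromkeys(required + extras), len(sequence), rng),
        reviewed=reviewed,
    )


def _plant_annotations(
    record: ProteinRecord,
    rules: list[Rule],
    own_rule: Rule,
    spec: FixtureSpec,
    rng: random.Random,
) -> None:
    """Annotate a reviewed record consistently with *every* rule it satisfies.

    A reviewed corpus is globally coherent: a record inside the scope of
    several rules carries all of their annotations.  Each distinct planted
    annotation is omitted with probability ``annotation_noise`` (one draw
    per annotation, producing false-positive support for every rule whose
    scope contains the record).  Positional-feature annotations are planted
    only for the rule whose template the sequence derives from; for other
    rules the pattern sites are absent from the random sequence.
    """
    planted: list[Annotation] = []
    seen: set[tuple[str, str, str]] = set()
    for rule in rules:
        if not satisfies_common(rule, record):
            continue
        candidates = list(rule.base_annotations)
        for case in rule.special_cases:
            if all(evaluate_condition(c, record) for c in case.extra_conditions.conditions):
                candidates.extend(case.annotations)
        if rule is own_rule and rule.positional is not None:
            candidates.extend(p.annotation for p in rule.positional.patterns)
        for ann in candidates:
            key = (ann.category, ann.subtype, ann.value)
            if key in seen:
                continue
            seen.add(key)
            if rng.random() >= spec.annotation_noise:
                planted.append(ann)
    record.annotations = planted


def _nonmatching_record(
    rules: list[Rule], accession: str, spec: FixtureSpec, rng: random.Random,
    reviewed: bool, carry: Rule | None = None,
) -> ProteinRecord | None:
    """A record failing every rule; carries ``carry``'s annotations if given."""
    referenced = {
        c.signature_id
        for rule in rules
        for cset in rule.common.sets
        for c in cset.conditions
        if c.kind == "signature"
    }
    decoys = [s for s in spec.signature_pool if s not in referenced]
    for attempt in range(4):
        length = rng.randint(*spec.length_range)
        matches = (
            _signature_matches([rng.choice(decoys)], length, rng)
            if decoys and attempt == 0
            else []
        )
        record = ProteinRecord(
            accession=accession,
            sequence="".join(rng.choices(AMINO_ACIDS, k=length)),
            lineage=_lineage_for(rng.choice(spec.taxa)),
            matches=matches,
            reviewed=reviewed,
        )
        if not any(satisfies_common(rule, record) for rule in rules):
            if carry is not None:
                record.annotations = list(carry.base_annotations) + [
                    ann for case in carry.special_cases for ann in case.annotations
                ]
            return record
    return None


def generate_corpus(
    spec: FixtureSpec, rules: list[Rule]
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Generate (reviewed, unreviewed) corpora for a rule set.

    Per rule: ``spec.n_records`` reviewed records satisfying its first
    condition set and carrying its annotations (each dropped with
    probability ``annotation_noise``), plus ``spec.n_offcondition`` reviewed
    records outside all rules' conditions that carry the rule's annotations
    (false-negative support).  ``spec.n_unreviewed`` unreviewed records
    alternate between rule-matching and non-matching, all without
    annotations.  Deterministic for a fixed spec.
    """
    if any(
        c.kind == "signature"
        for rule in rules
        for cset in rule.common.sets
        for c in cset.conditions
    ) and not spec.signature_pool:
        raise ValueError("signature-conditioned rules require a non-empty signature pool")
    rng = random.Random(spec.seed)
    reviewed: list[ProteinRecord] = []
    for j, rule in enumerate(rules):
        for i in range(spec.n_records):
            rec = _matching_record(rule, f"RV{j:02d}{i:05d}", spec, rng, True)
            _plant_annotations(rec, rules, rule, spec, rng)
            reviewed.append(rec)
        for i in range(spec.n_offcondition):
            rec = _nonmatching_record(rules, f"FN{j:02d}{i:04d}", spec, rng, True, carry=rule)
            if rec is not None:
                reviewed.append(rec)
    unreviewed: list[ProteinRecord] = []
    for i in range(spec.n_unreviewed):
        acc = f"TR{i:05d}"
        if i % 2 == 0 and rules:
            unreviewed.append(
                _matching_record(rules[(i // 2) % len(rules)], acc, spec, rng, False)
            )
        else:
            rec = _nonmatching_record(rules, acc, spec, rng, False)
            if rec is not None:
                unreviewed.append(rec)
    return reviewed, unreviewed


def write_corpus(
    directory,
    rules: list[Rule],
    reviewed: list[ProteinRecord],
    unreviewed: list[ProteinRecord],
) -> dict[str, Path]:
    """Write a generated corpus in the same formats the readers consume.

    Produces the rule XML, plus FASTA / signature-match TSV / lineage TSV
    for the unreviewed set, the same trio for the reviewed set, and the
    reviewed annotations as a 4-column TSV usable as a gold standard.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "rules": directory / "rules.xml",
        "fasta": directory / "unreviewed.fasta",
        "ipr_tsv": directory / "unreviewed.ipr.tsv",
        "lineage": directory / "unreviewed.lineage.tsv",
        "reviewed_fasta": directory / "reviewed.fasta",
        "reviewed_ipr_tsv": directory / "reviewed.ipr.tsv",
        "reviewed_lineage": directory / "reviewed.lineage.tsv",
        "reviewed_annotations": directory / "reviewed.annotations.tsv",
    }
    write_rules(rules, paths["rules"])
    for prefix, records in (("", unreviewed), ("reviewed_", reviewed)):
        write_fasta({r.accession: r.sequence for r in records}, paths[f"{prefix}fasta"])
        with open(paths[f"{prefix}ipr_tsv"], "w") as fh:
            for rec in records:
                for m in rec.matches:
                    fh.write(
                        "\t".join(
                            [
                                rec.accession, "-", str(rec.length), m.source_db,
                                m.signature_id, "-", str(m.start), str(m.end),
                                "-", "T", "2020-01-01", "-", "-",
                            ]
                        )
                        + "\n"
                    )
        write_lineage_table(
            {r.accession: r.lineage for r in records}, paths[f"{prefix}lineage"]
        )
    with open(paths["reviewed_annotations"], "w") as fh:
        for rec in reviewed:
            for ann in rec.annotations:
                fh.write(f"{rec.accession}\t{ann.category}\t{ann.subtype}\t{ann.value}\n")
    return paths
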
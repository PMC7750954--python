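# Methods

`ruleprop` implements rule-based propagation of functional annotation from
expertly reviewed protein records to unreviewed ones, in the style of the
UniRule system used for large protein knowledgebases, together with the
curator-side quality machinery that keeps such a rule base trustworthy.
This note records the model, the numerical and design choices, and what the
synthetic corpora used in testing do and do not demonstrate.

## The rule model

A rule selects proteins with *conditions* and attaches *annotations* to the
selection.  Conditions test the attributes a protein record reliably has
before any manual curation:

- **signature** — presence of a protein-family or domain signature match
  (a member-database accession such as `PF06419`, or the integrated-database
  accession such as `IPR010490`; both id levels are indexed from scan
  output, and presence anywhere in the protein suffices — signatures are
  treated as family-membership evidence, not positional evidence);
- **taxon** — membership of a taxon anywhere in the record's root-to-leaf
  lineage.  Matching is by exact label or by numeric taxonomy id; the id is
  preferred whenever both the condition and the lineage entry carry one,
  since labels drift and ids do not;
- **sequence_length** — an inclusive residue-count interval.  Length
  conditions keep annotation inside the known length distribution of a
  family and are the standard guard against fusion proteins and against
  overlap with neighbouring rules;
- **gene_tree** — membership of a named phylogenetic gene tree.  The kind
  is parsed, stored and round-tripped, but evaluation raises an
  "unsupported condition kind" error unless the record carries explicit
  tree memberships: no tree-placement semantics are defined here, and a
  silent `False` would make rules that use the kind look disjoint from
  everything rather than unevaluable.

Any condition may be negated (e.g. taxon ≠ Fungi).  The *common conditions*
of a rule are a disjunction of conjunctive condition sets (OR between sets,
AND within a set); they define the rule's overall scope.  *Special cases*
add a further conjunctive set each, carving out subgroups — typically
taxonomic — that receive extra annotations on top of the base ones.  When
two special cases fire on the same record and disagree on the same
annotation slot, both results are emitted and a warning is logged:
conflicts are resolved at curation time, not silently inside the engine.

Annotations cover the eight categories a reviewed record exposes: protein
name, free-text comments (function, subunit, similarity, …), keywords,
GO terms, subcellular locations, catalytic activities, pathways and
positional sequence features.  Keywords from the "Technical term" and
"Coding sequence diversity" categories are refused by validation (the list
is configuration, seeded with the well-known members of those categories):
they describe how a record was produced, not what the protein does, and
must never be propagated.

Every propagated annotation carries the evidence tag
`ECO:0000256|UniRule:<rule id>` — the "match to sequence model evidence
used in automatic assertion" code plus the identifier of the rule
responsible — so downstream consumers can distinguish rule-derived
annotation from experimental assertion and trace it to its source.

## Positional features

Family-level signatures cannot place site-specific annotation (active
sites, cofactor-binding residues, modified residues).  For that, a rule
nominates a template sequence and a list of residue patterns with their
locations on the template.  A target record that meets the common
conditions is globally aligned to the template and each pattern is tested
at the alignment-mapped positions; on a match, the annotation is added at
the *target* coordinates.

Numerical choices:

- **Alignment.** Global pairwise alignment (end gaps penalised) with
  BLOSUM62, gap open 10, gap extend 0.5 — the field-standard defaults for
  homologous protein pairs; both penalties are parameters of
  `align_to_template`.  Among co-optimal alignments the aligner's first
  reported path is used, which is deterministic for fixed inputs.
- **Position map.** The alignment is reduced to a strictly increasing map
  from template to target positions; template positions aligned to gaps are
  absent from the map.
- **Pattern grammar.** A PROSITE-style subset: literal residues, `x`
  wildcard, `[ABC]` alternatives, `{ABC}` exclusions, `(n)`/`(n,m)`
  repeats, optional `-` separators.  No anchors: the location comes from
  the template range, not from the sequence ends.
- **Contiguity.** A pattern matches only if all its template positions are
  mapped *and* the mapped target positions are contiguous.  A site whose
  residues are separated by a target insertion is not the annotated site,
  even if the residues individually align.
- **Degenerate inputs.** Empty sequences and non-amino-acid symbols
  (anything outside the 20 standard residues plus `X`) are errors naming
  the offending symbol; a record without sequence logs a warning and
  yields no positional features rather than failing the whole rule.

## Quality statistics and the acceptance gate

For each annotation a rule proposes, over a reviewed corpus:

- **TP** — reviewed records meeting the annotation's conditions that carry
  the annotation;
- **FP** — records meeting the conditions that do not carry it;
- **FN** — records carrying the annotation but outside the condition set
  (counted over the whole reviewed corpus supplied, with no taxonomic
  restriction);
- **confidence** — TP/(TP+FP).

Base annotations are scored over records meeting the common conditions;
special-case annotations over records additionally meeting that case; and
positional annotations over records meeting the common conditions whose
sequence actually matches the pattern at the mapped positions (the pattern
is itself a condition, so a record without the site is outside that
annotation's scope, not an FP).  A rule is accepted only if every
annotation reaches the confidence threshold (default 0.95, configurable).
An annotation with no in-scope support (TP+FP = 0) has undefined
confidence, is flagged unsupported, and blocks acceptance — an unverifiable
annotation is treated as a failing one.

Curators may exclude specific (record, annotation) pairs from all three
counts, the standard remedy when free-text phrasing differs without
biological disagreement.  Beyond exclusions, the annotation comparator
normalises free text (whitespace collapsed, case folded) but compares
controlled vocabularies (keywords, GO terms) exactly; sequence-feature
comparison ignores the residue position, which legitimately differs between
homologous records.

Overlap detection applies every rule to the unreviewed set and reports,
for each rule pair with intersecting matches, the shared records, the
identical annotations both emit (duplicates) and the same-slot
different-value annotations (conflicts).  Scoring emitted annotations —
after special-case resolution — rather than declared annotation lists means
the report shows what records would actually receive.

Release-time revalidation re-checks each rule against the current signature
release (`withdrawn_signature` when a referenced accession has disappeared)
and against the current reviewed corpus (`inconsistent_annotation` when the
gate no longer passes); both flags can apply at once.

Coverage/depth reporting summarises an annotation run: coverage is the
fraction of unreviewed records receiving any annotation (overall and by
root taxon); depth is, among annotated records, the fraction receiving
exactly 1, 2, 3 or all 4 of the top-level categories (protein name,
comment-like, sequence feature, keyword) — a partition of the annotated
set.

## Benchmarking

Predictions are compared with later-reviewed gold annotation sets as
(accession, annotation) pairs using the comparator above, giving
P = TP/(TP+FP), R = TP/(TP+FN) and

    F_beta = (beta^2 + 1) P R / (beta^2 P + R),

the harmonic mean F1 at beta = 1.  The parameter beta is defined as R/P.
For a production rule system, precision is constrained to [0.95, 1] while
recall may fall anywhere in ]0, 1], so the operating-point beta is
estimated from the interval midpoints: 0.5 / 0.975 = 0.51 to two decimals
(`unp_beta()`, with both intervals configurable).  Some published accounts
print this derivation with numerator and denominator transposed; this
package follows the beta = R/P definition, which is the reading consistent
with the 0.51 value.  The per-period benchmark (`benchmark_series`) emits
one result per period and omits, with a warning, periods with no gold
records.

## The synthetic-data generator

No public corpus is bundled; `ruleprop.fixtures` generates rules and
corpora deterministically from a single seed.  It emulates the statistical
structure the method assumes:

- reviewed records are built to satisfy a rule's first condition set
  (lineage from a compatible template, required signature matches, length
  inside the bounds) and are annotated **globally consistently**: a record
  carries the annotations of *every* generated rule whose conditions it
  meets, with each planted annotation omitted with probability
  `annotation_noise` (default 0 — the noiseless regime; tests that probe
  the gate plant 0.05).  This is what makes planted noise recoverable as
  the FP fraction;
- half of the matching records for a rule with special cases are drawn
  from the case's subgroup, so case annotations always have reviewed
  support;
- off-condition reviewed records carry a rule's annotations while matching
  no rule at all (false-negative support);
- unreviewed records mirror the condition structure without annotations;
- positional-feature targets are copies of the template with point
  mutations (rate 0.05) outside the pattern sites and, with probability
  `insertion_rate`, an insertion of 1–7 residues placed so as not to split
  a site.

Default study conditions: 50 matching reviewed records per rule, 5
off-condition carriers, 60 unreviewed records, lengths 50–400 over a pool
of 10 signatures and 7 three-level lineage templates.  Sequences are
uniform over the 20 amino acids except at planted sites, and pattern
spans are at least 3 residues, so a pattern match is attributable to
planting rather than chance at fixture scale (~20⁻³ per mapped site).

What the generator does **not** emulate: realistic residue composition or
evolutionary divergence (targets are point-mutated copies, not homologs),
taxonomies deeper than three ranks, signature false positives (every scan
match is planted and correct), or free-text paraphrase requiring curator
exclusions.  Green tests therefore demonstrate the correctness of the
engine's logic and statistics under the stated noise model — not the
biological precision of any particular rule base on real data.

The worked-example rule (`fixtures.fig1_rule`, id `UR001001756`) encodes
the COG6 family rule: eukaryote ∧ `PF06419` ∧ length 1–900, two base
subcellular-location annotations, and taxon-restricted function texts for
fungi and non-fungi.  The non-fungal text ("Required for normal Golgi
function") and the length bound are fixed by the published description of
the rule; the fungal function text is a synthetic stand-in phrased in the
family's own terms.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
make the stochastic assertions sharp while keeping the suite fast: 1000
random rule/record instances for the condition-logic/enumeration
equivalence, 500 random template/pattern pairs for the alignment identity
property, 200 matching reviewed records per rule (3 rules) for noise-rate
recovery at 3 binomial standard deviations, and 200 random rules for the
XML round-trip.  Corpus-scale figures (tens of millions of records,
thousands of rules) are explicitly out of scope.

## Known limitations

- Gene-tree conditions are recognised but not evaluable without explicit
  membership data on the record.
- One template per rule; no profile/HMM alignment to the family model —
  pairwise alignment to a single template is cheaper and adequate for
  within-family site mapping, but will degrade for highly divergent
  targets.
- The rule XML dialect is self-defined (schema in `docs/rule-schema.xsd`);
  it is not byte-compatible with any production rule markup.
- FN counting runs over the entire reviewed corpus supplied; production
  systems may restrict it taxonomically.
- No incremental re-annotation between releases: every run evaluates every
  rule against every unreviewed record.
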
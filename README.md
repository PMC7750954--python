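# ruleprop

Rule-based functional annotation of protein sequences.

Most protein records in large sequence knowledgebases are predicted from
genomes and will never be experimentally characterised.  `ruleprop`
implements the UniRule-style answer to that gap: expertly specified rules
combine protein-family **signature** matches, **taxonomy** and **sequence
length** conditions to select proteins, and propagate annotations — names,
function comments, keywords, GO terms, subcellular locations, and
alignment-mapped site features — from reviewed records to unreviewed ones,
tagging every propagated annotation with the evidence string
`ECO:0000256|UniRule:<rule id>`.

It is a library plus a small CLI, aimed at people who want to run such
rules over their own sequences (given an InterProScan-style signature
scan), build and quality-check rules against a reviewed corpus, or study
the method's statistics.

## The model in brief

A rule's *common conditions* are an OR of AND-sets of conditions; records
satisfying them receive the rule's base annotations, and *special cases*
add annotations for subgroups (e.g. `taxon = Fungi`).  Positional features
are propagated by globally aligning the target to the rule's template
sequence (BLOSUM62, gap open 10 / extend 0.5) and testing PROSITE-style
residue patterns at the alignment-mapped positions.

On the curation side, each annotation of a candidate rule is scored over a
reviewed corpus as TP (in-condition records carrying it), FP (in-condition
records lacking it) and FN (carriers outside the conditions); the rule is
accepted only if every annotation's confidence TP/(TP+FP) ≥ 0.95.
Benchmarking against later-reviewed gold records reports
P = TP/(TP+FP), R = TP/(TP+FN), F1 and the precision-oriented

F<sub>β</sub> = (β² + 1)·P·R / (β²·P + R),  with β = R/P estimated from
the admissible intervals P ∈ [0.95, 1], R ∈ ]0, 1] as 0.5/0.975 ≈ **0.51**.

See `docs/methods.md` for the full account and `docs/rule-schema.xsd` for
the rule XML dialect.

## Worked example

The package ships a hand-built encoding of the COG6 family rule
`UR001001756` (eukaryote ∧ Pfam `PF06419` ∧ length ≤ 900, with
taxon-restricted function texts):

```python
from ruleprop import annotate_all, ProteinRecord, SignatureMatch, Taxon
from ruleprop.fixtures import fig1_rule
from ruleprop.formats_io import write_annotations

records = [
    ProteinRecord("A0A1X7R5V1", length=503,
                  lineage=[Taxon("Eukaryota", 2759), Taxon("Fungi", 4751)],
                  matches=[SignatureMatch("PF06419", "Pfam", 17, 410)]),
    ProteinRecord("A0A2K5XYZ9", length=657,
                  lineage=[Taxon("Eukaryota", 2759), Taxon("Metazoa", 33208)],
                  matches=[SignatureMatch("PF06419", "Pfam", 20, 430)]),
]
write_annotations(annotate_all([fig1_rule()], records), "out.flat", format="flat")
```

`out.flat` then contains:

```
AC   A0A1X7R5V1
CC   -!- FUNCTION: Acts as a component of the peripheral membrane COG complex that is involved in intra-Golgi protein trafficking {ECO:0000256|UniRule:UR001001756}
CC   -!- SUBCELLULAR LOCATION: Golgi apparatus membrane {ECO:0000256|UniRule:UR001001756}
CC   -!- SUBCELLULAR LOCATION: Peripheral membrane protein {ECO:0000256|UniRule:UR001001756}
//
AC   A0A2K5XYZ9
CC   -!- FUNCTION: Required for normal Golgi function {ECO:0000256|UniRule:UR001001756}
CC   -!- SUBCELLULAR LOCATION: Golgi apparatus membrane {ECO:0000256|UniRule:UR001001756}
CC   -!- SUBCELLULAR LOCATION: Peripheral membrane protein {ECO:0000256|UniRule:UR001001756}
//
```

Both proteins match the common conditions, so both receive the two
subcellular-location annotations; the fungal record gets the fungal
function text, the metazoan one gets "Required for normal Golgi function"
(the `taxon ≠ Fungi` special case).  A record of length 901, or without
the signature, would receive nothing.

## Command line

One subcommand per activity:

```sh
# generate a deterministic synthetic rule set + corpus
ruleprop fixtures --seed 7 --n-rules 3 --out-dir fixtures/

# propagate annotations onto scanned sequences
ruleprop annotate --rules fixtures/rules.xml --fasta fixtures/unreviewed.fasta \
    --ipr-tsv fixtures/unreviewed.ipr.tsv --lineage fixtures/unreviewed.lineage.tsv \
    --out annotations.tsv --format tsv

# structural validation + the 0.95 confidence gate over a reviewed corpus
ruleprop validate --rules fixtures/rules.xml --fasta fixtures/reviewed.fasta \
    --ipr-tsv fixtures/reviewed.ipr.tsv --lineage fixtures/reviewed.lineage.tsv \
    --annotations fixtures/reviewed.annotations.tsv

# inter-rule overlap / conflict report;  P/R/F benchmark vs a gold standard
ruleprop overlaps --rules ... --fasta ... --ipr-tsv ... --lineage ...
ruleprop benchmark --pred annotations.tsv --gold gold.tsv --beta unp
```

`validate` exits non-zero if any rule is rejected; `benchmark --beta unp`
resolves β to 0.51 in the report header.

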
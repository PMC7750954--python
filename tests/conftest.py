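import pytest

from ruleprop.fixtures import TAXON_IDS, fig1_rule
from ruleprop.formats_io import ProteinRecord, SignatureMatch, Taxon


def make_record(
    accession="P00001",
    lineage=("Eukaryota", "Fungi", "Saccharomycetes"),
    signatures=("PF06419",),
    length=500,
    sequence="",
    reviewed=False,
    annotations=(),
):
    """Terse protein-record builder used throughout the suite."""
    if sequence:
        length = 0
    return ProteinRecord(
        accession=accession,
        sequence=sequence,
        length=length,
        lineage=[Taxon(label, TAXON_IDS.get(label)) for label in lineage],
        matches=[
            SignatureMatch(sig, "Pfam", 1, max(1, length or len(sequence)))
            for sig in signatures
        ],
        reviewed=reviewed,
        annotations=list(annotations),
    )


@pytest.fixture
def cog6_rule():
    return fig1_rule()


@pytest.fixture
def fungal_record():
    return make_record("P10001", ("Eukaryota", "Fungi", "Saccharomycetes"))


@pytest.fixture
def metazoan_record():
    return make_record("P10002", ("Eukaryota", "Metazoa", "Mammalia"))
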
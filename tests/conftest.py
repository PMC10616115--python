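import pandas as pd
import pytest

from pure.de import DEGene, DEProfile
from pure.kb import Edge, KnowledgeBase


CTD_HEADER = (
    "ChemicalName\tChemicalID\tCasRN\tGeneSymbol\tGeneID\tGeneForms\t"
    "Organism\tOrganismID\tInteraction\tInteractionActions\tPubMedIDs"
)


def ctd_row(
    chem="Phenobarbital",
    chem_id="D010634",
    gene_symbol="GENE1",
    gene_id="1001",
    organism="Homo sapiens",
    actions="increases^expression",
):
    return (
        f"{chem}\t{chem_id}\t50-06-6\t{gene_symbol}\t{gene_id}\tmRNA\t"
        f"{organism}\t9606\t{chem} affects {gene_symbol}\t{actions}\t123"
    )


@pytest.fixture
def ctd_file(tmp_path):
    """Factory writing a CTD-style TSV from a list of row strings."""

    def _write(rows, header=CTD_HEADER, preamble=None):
        path = tmp_path / "ctd.tsv"
        lines = list(preamble or [])
        if header is not None:
            lines.append(header)
        lines.extend(rows)
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def tiny_kb():
    """Two CDTs, four genes, five signed edges."""
    edges = [
        Edge("C1", "g1", 1, organism="synthetic"),
        Edge("C1", "g2", -1, organism="synthetic"),
        Edge("C1", "g3", 1, organism="synthetic"),
        Edge("C2", "g2", 1, organism="synthetic"),
        Edge("C2", "g4", -1, organism="synthetic"),
    ]
    return KnowledgeBase(
        edges=edges, cdt_names={"C1": "drug one", "C2": "drug two"}, organism="synthetic"
    )


@pytest.fixture
def tiny_de_genes():
    """DE calls touching g1 (up), g2 (down), g5 (up, not in the KB)."""
    return [
        DEGene("g1", 1, 1.2, 0.001),
        DEGene("g2", -1, -0.9, 0.01),
        DEGene("g5", 1, 2.0, 0.0001),
    ]


@pytest.fixture
def de_profile_frame():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "log_fc": [1.2, -0.9, 0.1, -0.6, 2.0, 0.7],
            "p_value": [0.001, 0.01, 0.5, 0.001, 0.0001, 0.05],
        }
    )
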
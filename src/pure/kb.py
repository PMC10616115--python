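"""Signed chemical–gene knowledge bases.

Parses CTD-style chemical–gene interaction tables into a collection of
signed edges: a chemical/drug/toxicant (CDT) either *activates* a gene
(``increases^expression``, sign +1) or *inhibits* it
(``decreases^expression``, sign −1).  All other interaction-action types
(abundance, methylation, activity, cotreatment, ...) carry no expression
direction and are dropped.  Directionless expression annotations
(``affects^expression``) are also dropped and counted in the parse stats so
users can see how much curation was discarded.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

ACTIVATION = "increases^expression"
INHIBITION = "decreases^expression"
DIRECTIONLESS = "affects^expression"

#: Columns a CTD chem_gene_ixns table must provide.
REQUIRED_COLUMNS = (
    "ChemicalName",
    "ChemicalID",
    "GeneSymbol",
    "GeneID",
    "Organism",
    "InteractionActions",
)

#: Full CTD column set, used when the header must be recovered from the
#: commented preamble of a raw CTD download.
CTD_COLUMNS = (
    "ChemicalName",
    "ChemicalID",
    "CasRN",
    "GeneSymbol",
    "GeneID",
    "GeneForms",
    "Organism",
    "OrganismID",
    "Interaction",
    "InteractionActions",
    "PubMedIDs",
)

NORMALIZED_COLUMNS = ("cdt_id", "cdt_name", "gene_id", "sign", "weight", "organism")


class KnowledgeBaseFormatError(ValueError):
    """The input table is missing a required column or is malformed."""


class EmptyKnowledgeBaseError(ValueError):
    """No signed expression edge survived parsing/filtering."""


@dataclass(frozen=True)
class Edge:
    """A signed CDT→gene association.

    ``sign`` is +1 for activation, −1 for inhibition.  ``weight`` is the
    regulation weight used by the activation z-score; CTD supplies none, so
    it defaults to 1.  ``provenance`` points back at the source row.
    """

    cdt_id: str
    gene_id: str
    sign: int
    weight: float = 1.0
    organism: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if self.weight < 0:
            raise ValueError(f"edge weight must be >= 0, got {self.weight!r}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.cdt_id, self.gene_id, self.sign)


@dataclass
class KnowledgeBase:
    """A deduplicated collection of signed CDT→gene edges."""

    edges: list[Edge] = field(default_factory=list)
    cdt_names: dict[str, str] = field(default_factory=dict)
    organism: str = "all"
    parse_stats: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for e in self.edges:
            if e.key in seen:
                raise ValueError(f"duplicate edge {e.key} in knowledge base")
            seen.add(e.key)

    # -- identity ---------------------------------------------------------
    def signature(self) -> tuple:
        """Canonical content signature (ignores provenance and stats)."""
        edges = tuple(
            sorted((e.cdt_id, e.gene_id, e.sign, e.weight, e.organism) for e in self.edges)
        )
        return (edges, tuple(sorted(self.cdt_names.items())), self.organism)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self.signature() == other.signature()

    # -- views ------------------------------------------------------------
    @property
    def cdt_ids(self) -> list[str]:
        return sorted({e.cdt_id for e in self.edges})

    @property
    def gene_ids(self) -> list[str]:
        return sorted({e.gene_id for e in self.edges})

    def edges_of(self, cdt_id: str) -> list[Edge]:
        return [e for e in self.edges if e.cdt_id == cdt_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cdt_id": e.cdt_id,
                    "cdt_name": self.cdt_names.get(e.cdt_id, e.cdt_id),
                    "gene_id": e.gene_id,
                    "sign": e.sign,
                    "weight": e.weight,
                    "organism": e.organism,
                }
                for e in sorted(self.edges, key=lambda e: e.key)
            ],
            columns=list(NORMALIZED_COLUMNS),
        )

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the normalized edge table."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnowledgeBase":
        """Read a normalized edge table written by :meth:`to_tsv`."""
        df = pd.read_csv(path, sep="\t", dtype={"cdt_id": str, "gene_id": str})
        missing = [c for c in NORMALIZED_COLUMNS if c not in df.columns]
        if missing:
            raise KnowledgeBaseFormatError(
                f"normalized KB table is missing column(s): {', '.join(missing)}"
            )
        edges = []
        names: dict[str, str] = {}
        for i, row in enumerate(df.itertuples(index=False)):
            edges.append(
                Edge(
                    cdt_id=str(row.cdt_id),
                    gene_id=str(row.gene_id),
                    sign=int(row.sign),
                    weight=float(row.weight),
                    organism="" if pd.isna(row.organism) else str(row.organism),
                    provenance=f"{path}:{i + 2}",
                )
            )
            names.setdefault(str(row.cdt_id), str(row.cdt_name))
        return cls(edges=edges, cdt_names=names)

    def filter_organism(self, organism: Optional[str]) -> "KnowledgeBase":
        """Restrict to one organism (case-insensitive exact match).

        Edges with an empty organism field are dropped when a filter is
        set, matching CTD's convention of leaving organism blank for
        inferred rows.
        """
        if organism is None:
            return self
        want = organism.strip().casefold()
        kept = [e for e in self.edges if e.organism.strip().casefold() == want]
        names = {e.cdt_id: self.cdt_names.get(e.cdt_id, e.cdt_id) for e in kept}
        return KnowledgeBase(edges=kept, cdt_names=names, organism=organism)


def kb_summary(kb: KnowledgeBase) -> dict[str, int]:
    """Headline counts: CDTs, genes, edges, and the sign breakdown."""
    n_act = sum(1 for e in kb.edges if e.sign == 1)
    n_inh = sum(1 for e in kb.edges if e.sign == -1)
    return {
        "n_cdts": len(kb.cdt_ids),
        "n_genes": len(kb.gene_ids),
        "n_edges": len(kb.edges),
        "n_activation": n_act,
        "n_inhibition": n_inh,
    }


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CTD-style TSV, tolerating the commented preamble of raw
    CTD downloads (header recovered from the ``# Fields:`` block when the
    first data line is not preceded by a plain header row)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    header: list[str] | None = None
    data_start = 0
    comment_header: list[str] | None = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            fields = [f.strip() for f in stripped.split("\t")]
            if "ChemicalName" in fields:
                comment_header = fields
            continue
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if "ChemicalName" in fields:
            header = fields
            data_start = i + 1
        else:
            header = comment_header or list(CTD_COLUMNS)
            data_start = i
        break
    else:  # all lines were comments/blank
        raise EmptyKnowledgeBaseError("input contains no data rows")
    body = "\n".join(lines[data_start:])
    df = pd.read_csv(
        io.StringIO(body),
        sep="\t",
        names=header,
        dtype=str,
        keep_default_na=False,
        comment=None,
    )
    return df


def parse_ctd_interactions(
    path: str | Path, organism: Optional[str] = None
) -> KnowledgeBase:
    """Parse a CTD chemical–gene interaction table into a signed KB.

    Only rows whose ``InteractionActions`` contain an expression verb are
    retained: ``increases^expression`` yields a +1 (activation) edge and
    ``decreases^expression`` a −1 (inhibition) edge; a single row listing
    both yields two opposite-sign edges.  Duplicate (cdt, gene, sign)
    triples are collapsed.  With ``organism`` set, matching is exact and
    case-insensitive on the organism-name column; rows with an empty
    organism are excluded.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KnowledgeBaseFormatError(
            f"input is missing required column(s): {', '.join(missing)}"
        )

    want = organism.strip().casefold() if organism is not None else None
    stats = {
        "rows": len(df),
        "rows_other_organism": 0,
        "rows_directionless_expression": 0,
        "edges_retained": 0,
        "duplicates_collapsed": 0,
    }
    edges: dict[tuple[str, str, int], Edge] = {}
    names: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        org = str(row.Organism).strip()
        if want is not None and org.casefold() != want:
            stats["rows_other_organism"] += 1
            continue
        actions = str(row.InteractionActions)
        tokens = [t.strip() for t in actions.split("|")]
        if DIRECTIONLESS in tokens:
            stats["rows_directionless_expression"] += 1
        signs = []
        if ACTIVATION in tokens:
            signs.append(1)
        if INHIBITION in tokens:
            signs.append(-1)
        if not signs:
            continue
        cdt_id = str(row.ChemicalID).strip()
        gene_id = str(row.GeneID).strip()
        names.setdefault(cdt_id, str(row.ChemicalName).strip())
        for sign in signs:
            key = (cdt_id, gene_id, sign)
            if key in edges:
                stats["duplicates_collapsed"] += 1
                continue
            edges[key] = Edge(
                cdt_id=cdt_id,
                gene_id=gene_id,
                sign=sign,
                organism=org,
                provenance=f"{path}:row{i}",
            )
    if not edges:
        raise EmptyKnowledgeBaseError(
            "no signed expression edge retained; check the organism spelling "
            f"({organism!r}) and that InteractionActions uses CTD's verb^noun syntax"
        )
    stats["edges_retained"] = len(edges)
    if stats["rows_directionless_expression"]:
        logger.info(
            "stage=parse_kb directionless_expression_rows=%d (affects^expression "
            "carries no direction and is excluded)",
            stats["rows_directionless_expression"],
        )
    logger.info(
        "stage=parse_kb rows=%d edges=%d cdts=%d genes=%d organism=%s",
        stats["rows"],
        len(edges),
        len({k[0] for k in edges}),
        len({k[1] for k in edges}),
        organism or "all",
    )
    kept_names = {c: names[c] for c in sorted({k[0] for k in edges})}
    return KnowledgeBase(
        edges=sorted(edges.values(), key=lambda e: e.key),
        cdt_names=kept_names,
        organism=organism or "all",
        parse_stats=stats,
    )
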
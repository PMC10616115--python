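"""The PURE test proper.

For every chemical/drug/toxicant (CDT) two directional hypotheses are
tested against a differential-expression profile:

* H1 — the CDT's level is elevated in the phenotype: its activation edges
  should point at up-regulated genes and its inhibition edges at
  down-regulated ones (edge sign equals DE-gene sign).
* H2 — the CDT is lacking/absent: its edges should oppose the observed
  DE signs.

The knowledge base is first restricted to the DE genes; every surviving
edge supports exactly one of the two hypotheses.  Per CDT a 2×2
contingency table over edges is built —

===============  =============  ============
\                supporting H1  against H1
focal CDT        l              k
all other CDTs   m              n
===============  =============  ============

— and the one-sided (upper-tail) Fisher exact p-value is computed for H1;
the H2 p-value is the same test on the column-swapped table.  P-values are
Benjamini–Hochberg corrected and CDTs ranked with the average-rank tie
convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .de import DEGene
from .kb import KnowledgeBase

logger = logging.getLogger(__name__)

#: Below this total the tail is summed in exact integer arithmetic;
#: above it scipy's log-space hypergeometric survival function is used.
_EXACT_TOTAL_LIMIT = 1000

Call = Literal["present", "absent", "both", "none"]
_CALL_PRIORITY = {"present": 0, "absent": 1, "both": 2, "none": 3}


@dataclass(frozen=True)
class ContingencyTable:
    """Edge counts (l, k, m, n); see module docstring for the layout."""

    l: int
    k: int
    m: int
    n: int

    def __post_init__(self) -> None:
        for name in ("l", "k", "m", "n"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"contingency entry {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        """‖E‖, the number of edges in the overlap network."""
        return self.l + self.k + self.m + self.n

    @property
    def focal(self) -> int:
        """Number of edges of the focal CDT."""
        return self.l + self.k

    def swapped(self) -> "ContingencyTable":
        """Column swap: the H2 table corresponding to this H1 table."""
        return ContingencyTable(self.k, self.l, self.n, self.m)


@dataclass
class OverlapNetwork:
    """Restriction of a KB to the DE genes, with per-edge hypothesis labels.

    ``edges`` columns: cdt_id, gene_id, edge_sign, gene_sign, and (after
    :func:`label_edges`) boolean h1_support.
    """

    edges: pd.DataFrame
    gene_signs: dict[str, int]
    labeled: bool = False
    cdt_names: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_signs)

    @property
    def cdts(self) -> list[str]:
        return sorted(self.edges["cdt_id"].unique()) if len(self.edges) else []

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def flip_gene_signs(self) -> "OverlapNetwork":
        """Negate every DE sign (used for sign-symmetry checks)."""
        edges = self.edges.copy()
        edges["gene_sign"] = -edges["gene_sign"]
        if self.labeled:
            edges["h1_support"] = edges["edge_sign"] == edges["gene_sign"]
        return OverlapNetwork(
            edges=edges,
            gene_signs={g: -s for g, s in self.gene_signs.items()},
            labeled=self.labeled,
            cdt_names=dict(self.cdt_names),
        )


@dataclass
class CDTTestResult:
    """Per-CDT output: contingency counts, both p-values, FDRs, ranks, call."""

    cdt_id: str
    table_h1: ContingencyTable
    p_h1: float
    p_h2: float
    fdr_h1: float = math.nan
    fdr_h2: float = math.nan
    rank_h1: float = math.nan
    rank_h2: float = math.nan
    call: Call = "none"


def build_overlap(kb: KnowledgeBase, de_genes: Iterable[DEGene]) -> OverlapNetwork:
    """Restrict the KB to edges whose target gene is differentially expressed.

    G is the intersection of DE genes and KB genes; C the CDTs with at
    least one edge into G; E those edges.  An empty overlap yields an
    empty network (logged), not an error.
    """
    signs = {g.gene_id: g.sign for g in de_genes}
    rows = [
        {
            "cdt_id": e.cdt_id,
            "gene_id": e.gene_id,
            "edge_sign": e.sign,
            "gene_sign": signs[e.gene_id],
        }
        for e in kb.edges
        if e.gene_id in signs
    ]
    edges = pd.DataFrame(
        rows, columns=["cdt_id", "gene_id", "edge_sign", "gene_sign"]
    )
    gene_signs = {g: signs[g] for g in edges["gene_id"].unique()} if len(edges) else {}
    net = OverlapNetwork(edges=edges, gene_signs=gene_signs, cdt_names=dict(kb.cdt_names))
    logger.info(
        "stage=overlap genes_de=%d genes_overlap=%d edges=%d cdts=%d",
        len(signs),
        len(gene_signs),
        net.n_edges,
        len(net.cdts),
    )
    return net


def label_edges(net: OverlapNetwork) -> OverlapNetwork:
    """Label every edge with the hypothesis it supports.

    An edge supports H1 iff its sign equals the DE sign of its target
    gene; otherwise it supports H2.  The two label sets partition E.
    """
    edges = net.edges.copy()
    edges["h1_support"] = edges["edge_sign"] == edges["gene_sign"]
    return OverlapNetwork(
        edges=edges,
        gene_signs=dict(net.gene_signs),
        labeled=True,
        cdt_names=dict(net.cdt_names),
    )


def contingency_for(net: OverlapNetwork, cdt_id: str) -> ContingencyTable:
    """Build the focal-vs-rest H1 contingency table for one CDT."""
    if not net.labeled:
        raise ValueError("network must be labeled (run label_edges) first")
    mask = net.edges["cdt_id"] == cdt_id
    if not mask.any():
        raise KeyError(f"CDT {cdt_id!r} has no edge in the overlap network")
    h1 = net.edges["h1_support"].to_numpy()
    focal = mask.to_numpy()
    l = int(np.sum(focal & h1))
    k = int(np.sum(focal & ~h1))
    m = int(np.sum(~focal & h1))
    n = int(np.sum(~focal & ~h1))
    return ContingencyTable(l, k, m, n)


def _tail_p(l: int, r1: int, c1: int, total: int) -> float:
    """P[X >= l] for X ~ Hypergeometric(total, r1 successes, c1 draws).

    Exact integer arithmetic (correctly-rounded big-int division) up to
    ``_EXACT_TOTAL_LIMIT``; scipy's log-space survival function beyond.
    """
    amax = min(r1, c1)
    if l > amax:
        return 0.0
    amin = max(0, r1 + c1 - total)
    if l <= amin:
        return 1.0
    if total <= _EXACT_TOTAL_LIMIT:
        num = sum(
            math.comb(r1, a) * math.comb(total - r1, c1 - a) for a in range(l, amax + 1)
        )
        return num / math.comb(total, c1)
    return float(hypergeom.sf(l - 1, total, r1, c1))


def fisher_one_sided(t: ContingencyTable, *, strict: bool = False) -> float:
    """One-sided Fisher exact p-value for H1 (upper tail over l).

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose first cell is >= l (inclusive of the observed table; the
    exclusive tail, available via ``strict=True`` for sensitivity checks,
    is not a valid p-value because it vanishes on maximal tables).
    """
    if t.total < 1:
        raise ValueError("contingency table must contain at least one edge")
    lo = t.l + 1 if strict else t.l
    return _tail_p(lo, t.l + t.k, t.l + t.m, t.total)


def p_value_h2(t: ContingencyTable, *, strict: bool = False) -> float:
    """H2 p-value: the H1 test on the column-swapped table (k, l, n, m)."""
    return fisher_one_sided(t.swapped(), strict=strict)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_results(
    stats: Sequence[tuple[str, float]] | Sequence[float],
) -> np.ndarray | dict[str, float]:
    """Average ranks, smaller statistic = better (rank 1).

    Tied values receive the mean of the positions they occupy, so e.g.
    four tied at the top are each ranked 2.5.  Accepts either a plain
    sequence of statistics (returns an array) or (id, statistic) pairs
    (returns an id → rank mapping).
    """
    if len(stats) and isinstance(stats[0], tuple):
        ids = [s[0] for s in stats]  # type: ignore[index]
        vals = np.asarray([s[1] for s in stats], dtype=float)  # type: ignore[index]
        ranks = rankdata(vals, method="average")
        return dict(zip(ids, ranks.tolist()))
    return rankdata(np.asarray(stats, dtype=float), method="average")


def _rank_with_tiebreak(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Average ranks on (primary, secondary) lexicographic ordering."""
    order = np.lexsort((secondary, primary))
    keys = list(zip(primary[order], secondary[order]))
    # average positions of equal (primary, secondary) pairs
    out = np.empty(len(keys))
    i = 0
    while i < len(keys):
        j = i
        while j < len(keys) and keys[j] == keys[i]:
            j += 1
        out[i:j] = (i + 1 + j) / 2.0
        i = j
    ranks = np.empty(len(keys))
    ranks[order] = out
    return ranks


def test_all(
    net: OverlapNetwork,
    *,
    alpha: float = 0.05,
    fdr_mode: Literal["per_hypothesis", "pooled"] = "per_hypothesis",
    strict_tail: bool = False,
    min_edges: int = 0,
    tiebreak_raw_p: bool = False,
) -> list[CDTTestResult]:
    """Run both hypothesis tests for every CDT in the overlap network.

    Every CDT with at least ``min_edges`` edges (default 0: all of them)
    is tested under both hypotheses; p-values are BH-corrected either
    within each hypothesis family (default) or pooled, ranks use the
    average-rank convention on the adjusted p-values (optionally breaking
    ties by raw p), and calls are made at ``fdr <= alpha``.
    """
    if not net.labeled:
        net = label_edges(net)
    cdts = [c for c in net.cdts]
    results: list[CDTTestResult] = []
    for c in cdts:
        t = contingency_for(net, c)
        if t.focal < min_edges:
            continue
        results.append(
            CDTTestResult(
                cdt_id=c,
                table_h1=t,
                p_h1=fisher_one_sided(t, strict=strict_tail),
                p_h2=p_value_h2(t, strict=strict_tail),
            )
        )
    if not results:
        logger.info("stage=test empty overlap network; no CDT tested")
        return results

    p1 = np.array([r.p_h1 for r in results])
    p2 = np.array([r.p_h2 for r in results])
    if fdr_mode == "pooled":
        adj = fdr_adjust(np.concatenate([p1, p2]))
        f1, f2 = adj[: len(results)], adj[len(results):]
    elif fdr_mode == "per_hypothesis":
        f1, f2 = fdr_adjust(p1), fdr_adjust(p2)
    else:
        raise ValueError(f"unknown fdr_mode {fdr_mode!r}")

    if tiebreak_raw_p:
        r1 = _rank_with_tiebreak(f1, p1)
        r2 = _rank_with_tiebreak(f2, p2)
    else:
        r1 = rankdata(f1, method="average")
        r2 = rankdata(f2, method="average")

    for i, res in enumerate(results):
        res.fdr_h1 = float(f1[i])
        res.fdr_h2 = float(f2[i])
        res.rank_h1 = float(r1[i])
        res.rank_h2 = float(r2[i])
        sig1 = res.fdr_h1 <= alpha
        sig2 = res.fdr_h2 <= alpha
        res.call = (
            "both" if (sig1 and sig2) else "present" if sig1 else "absent" if sig2 else "none"
        )
    logger.info(
        "stage=test cdts=%d edges=%d significant=%d",
        len(results),
        net.n_edges,
        sum(1 for r in results if r.call != "none"),
    )
    return results


def significant_set(
    results: Iterable[CDTTestResult], alpha: float = 0.05
) -> list[CDTTestResult]:
    """CDTs significant under either hypothesis at ``fdr <= alpha``.

    The reported significant count is the size of this set; CDTs
    significant under both hypotheses keep the (hard to interpret but
    honest) call ``both``.
    """
    out = []
    for r in results:
        sig1 = r.fdr_h1 <= alpha
        sig2 = r.fdr_h2 <= alpha
        if sig1 or sig2:
            out.append(r)
    return out


def results_to_frame(
    results: Sequence[CDTTestResult],
    cdt_names: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Tabulate results, deterministically ordered by
    (call priority, best adjusted p, cdt_id)."""
    names = cdt_names or {}
    rows = []
    for r in results:
        t = r.table_h1
        rows.append(
            {
                "cdt_id": r.cdt_id,
                "cdt_name": names.get(r.cdt_id, r.cdt_id),
                "n_edges": t.focal,
                "l": t.l,
                "k": t.k,
                "m": t.m,
                "n": t.n,
                "p_h1": r.p_h1,
                "fdr_h1": r.fdr_h1,
                "rank_h1": r.rank_h1,
                "p_h2": r.p_h2,
                "fdr_h2": r.fdr_h2,
                "rank_h2": r.rank_h2,
                "call": r.call,
                "_prio": _CALL_PRIORITY[r.call],
                "_best": min(r.fdr_h1, r.fdr_h2),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["_prio", "_best", "cdt_id"], kind="mergesort")
        df = df.drop(columns=["_prio", "_best"]).reset_index(drop=True)
    return df


def write_results_tsv(
    results: Sequence[CDTTestResult],
    path,
    cdt_names: Optional[dict[str, str]] = None,
) -> None:
    """Write the results table with floats at 6 significant digits."""
    df = results_to_frame(results, cdt_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
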
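"""Benchmark comparator methods.

Five methods widely used for gene-set / upstream-regulator inference,
run against the same knowledge base and DE profile as PURE:

* ORA — hypergeometric over-representation of DE genes in a CDT's target
  set (sign-blind on both edges and genes).
* KS — two-sample Kolmogorov–Smirnov on the log fold-changes of DE genes
  targeted vs not targeted by the CDT (edge-sign blind).
* Wilcoxon — rank-sum of the targeted DE genes' fold-changes against the
  rest (edge-sign blind).
* GSEA — classic pre-ranked enrichment score with a gene-permutation
  null (weight exponent 1).
* IPA-style causal scoring — the overlap p-value (gene-level one-sided
  Fisher) and the activation z-score
  z = Σ w·s_R·s_D / sqrt(Σ w²), called activated at z ≥ 2 and inhibited
  at z ≤ −2.  "ipa_cdt_like" restricts candidates to the KB's chemical
  universe; with a CTD-derived KB that universe is already all-chemical,
  so it differs only by report label.

All methods emit a :class:`MethodReport` — the common currency of the
benchmark module: a ranked CDT list with a per-CDT statistic and a
significance flag at the method's stated criterion (BH-FDR ≤ 0.05 for the
p-value methods, |z| ≥ 2 for the z-score method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ks_2samp, mannwhitneyu, rankdata

from . import core
from .de import DEProfile, select_de_genes
from .kb import KnowledgeBase

METHODS = ("pure", "ora", "ks", "wilcoxon", "gsea", "ipa_like", "ipa_cdt_like")

DEFAULT_NPERM = 10_000
DEFAULT_MIN_SIZE = 15


@dataclass
class MethodReport:
    """Ranked, significance-flagged CDT list from one method.

    ``table`` columns: cdt_id, statistic, p_or_z, significant, rank.
    ``not_tested`` lists CDTs the method could not score (e.g. gene sets
    below GSEA's minimum size, or regulators without a defined z-score).
    """

    method: str
    params: dict = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    not_tested: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        if "significant" not in self.table.columns or not len(self.table):
            return 0
        return int(self.table["significant"].sum())

    def rank_of(self, cdt_id: str) -> Optional[float]:
        if not len(self.table):
            return None
        hit = self.table.loc[self.table["cdt_id"] == cdt_id, "rank"]
        return float(hit.iloc[0]) if len(hit) else None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

def ora_pvalue(N: int, M: int, n: int, x: int) -> float:
    """Hypergeometric upper tail P(X >= x): probability of observing x or
    more DE genes among the M targets of a CDT, given n DE genes in a
    background of N."""
    if not (0 <= x <= min(M, n) and 0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"impossible ORA counts N={N} M={M} n={n} x={x}")
    if x == 0:
        return 1.0
    # complement-sum identity 1 - P(X <= x-1), in exact integer arithmetic
    if N <= 1000:
        denom = math.comb(N, n)
        below = sum(math.comb(M, i) * math.comb(N - M, n - i) for i in range(x))
        return (denom - below) / denom
    return float(hypergeom.sf(x - 1, N, M, n))


def ks_test(de_hit_scores: Sequence[float], de_miss_scores: Sequence[float]):
    """Two-sided two-sample KS comparison of the fold-change distributions
    of targeted vs untargeted DE genes.  Returns (D, p)."""
    if len(de_hit_scores) == 0 or len(de_miss_scores) == 0:
        raise ValueError("KS test undefined for an empty group")
    res = ks_2samp(de_hit_scores, de_miss_scores, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_ranksum(de_hit_scores: Sequence[float], de_miss_scores: Sequence[float]):
    """Rank-sum W of the targeted DE genes over the pooled fold-change
    ranking, with a two-sided p-value (exact for small untied samples,
    normal approximation with tie correction otherwise).  Returns (W, p)."""
    hits = np.asarray(de_hit_scores, dtype=float)
    miss = np.asarray(de_miss_scores, dtype=float)
    if hits.size == 0 or miss.size == 0:
        raise ValueError("rank-sum test undefined for an empty group")
    res = mannwhitneyu(hits, miss, alternative="two-sided", method="auto")
    w = float(res.statistic) + hits.size * (hits.size + 1) / 2.0
    return w, float(res.pvalue)


def _enrichment_score(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Classic weighted KS-style running-sum extremum for one ordering."""
    nh = int(in_set.sum())
    n = in_set.size
    wsum = float(weights[in_set].sum())
    hit = np.where(in_set, weights / wsum if wsum > 0 else 1.0 / nh, 0.0)
    miss = np.where(~in_set, 1.0 / (n - nh), 0.0)
    running = np.cumsum(hit - miss)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    ranked_scores: pd.Series | dict[str, float],
    gene_set: Sequence[str],
    nperm: int = DEFAULT_NPERM,
    min_size: int = DEFAULT_MIN_SIZE,
    seed: Optional[int] = None,
):
    """Classic pre-ranked GSEA for one gene set.

    Genes are ordered by decreasing score (log fold-change); the running
    sum increments by |score|/Σ|score in set| on set members and decrements
    by 1/(N−Nh) otherwise; ES is the extremum.  The null is nperm random
    gene-label permutations; p = (1 + #{|ES_perm| ≥ |ES|}) / (nperm + 1).

    Returns (ES, p) or None when the intersected set is below
    ``min_size`` (a recorded "not tested" outcome).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    s = pd.Series(ranked_scores, dtype=float)
    s = s.sort_values(ascending=False, kind="mergesort")
    genes = s.index.to_numpy()
    scores = np.abs(s.to_numpy())
    in_set = np.isin(genes, np.asarray(list(gene_set), dtype=genes.dtype))
    nh = int(in_set.sum())
    if nh < min_size or nh == genes.size:
        return None
    es = _enrichment_score(in_set, scores)

    rng = np.random.default_rng(seed)
    n = genes.size
    exceed = 0
    chunk = max(1, min(nperm, 2_000_000 // max(n, 1)))
    done = 0
    base = in_set.astype(float)
    while done < nperm:
        b = min(chunk, nperm - done)
        mat = rng.permuted(np.tile(base, (b, 1)), axis=1).astype(bool)
        w = np.tile(scores, (b, 1))
        wsum = np.where(mat, w, 0.0).sum(axis=1)
        hit = np.where(mat, w / wsum[:, None], 0.0)
        miss = np.where(~mat, 1.0 / (n - nh), 0.0)
        running = np.cumsum(hit - miss, axis=1)
        idx = np.argmax(np.abs(running), axis=1)
        es_perm = running[np.arange(b), idx]
        exceed += int(np.sum(np.abs(es_perm) >= abs(es)))
        done += b
    p = (1 + exceed) / (nperm + 1)
    return es, p


def ipa_overlap_p(a: int, b: int, c: int, d: int) -> float:
    """Gene-level one-sided overlap p-value.

    a = DE genes regulated by r, b = DE genes not regulated by r,
    c = regulated non-DE genes, d = the remaining background.  Sums the
    hypergeometric probabilities of the observed and all more-extreme
    tables (first cell a+k, k = 0..min(b, c)) at fixed margins, in exact
    integer arithmetic.  For regulator tables — where the non-regulated
    DE genes b and the unannotated background d both dwarf the regulated
    set c — the limit equals the commonly quoted min(c, d); taking
    min(b, c) keeps the sum a complete upper tail (hence a valid p-value
    identical to the one-sided Fisher test) on degenerate tables too.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"count {name} must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("overlap table must contain at least one gene")
    denom = math.comb(n, a + c)
    num = 0
    for k in range(0, min(b, c) + 1):
        num += math.comb(a + b, a + k) * math.comb(c + d, c - k)
    return min(1.0, num / denom)


def ipa_zscore(edges_to_de: Sequence[tuple[float, int, int]]) -> Optional[float]:
    """Activation z-score over a regulator's edges to DE genes.

    Each element is (weight, s_R, s_D): regulation weight, edge sign, DE
    sign.  z = Σ w·s_R·s_D / sqrt(Σ w²).  Returns None (undefined score,
    mirroring reports that omit a z-score) for an empty collection or
    all-zero weights.
    """
    if not edges_to_de:
        return None
    w = np.array([e[0] for e in edges_to_de], dtype=float)
    sr = np.array([e[1] for e in edges_to_de], dtype=float)
    sd = np.array([e[2] for e in edges_to_de], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    denom = float(np.sqrt(np.sum(w**2)))
    if denom == 0.0:
        return None
    return float(np.sum(w * sr * sd) / denom)


def zscore_call(z: Optional[float]) -> str:
    if z is None:
        return "none"
    if z >= 2:
        return "activated"
    if z <= -2:
        return "inhibited"
    return "none"


# ---------------------------------------------------------------------------
# the common harness
# ---------------------------------------------------------------------------

@dataclass
class GeneSetView:
    """Sign-blind view of the KB against a profile: per-CDT target sets
    within a shared background (genes both measured and annotated)."""

    background: list[str]
    targets: dict[str, list[str]]

    @classmethod
    def from_inputs(cls, kb: KnowledgeBase, profile: DEProfile) -> "GeneSetView":
        measured = set(profile.gene_ids)
        targets: dict[str, set[str]] = {}
        bg: set[str] = set()
        for e in kb.edges:
            if e.gene_id in measured:
                targets.setdefault(e.cdt_id, set()).add(e.gene_id)
                bg.add(e.gene_id)
        return cls(
            background=sorted(bg),
            targets={c: sorted(g) for c, g in sorted(targets.items())},
        )


def _pvalue_report(
    method: str,
    params: dict,
    stats: list[tuple[str, float, float]],
    not_tested: list[str],
    alpha: float,
) -> MethodReport:
    """Assemble a report for a p-value method: BH-adjust, flag at
    fdr <= alpha, average-rank on the adjusted values."""
    if not stats:
        return MethodReport(method=method, params=params, not_tested=sorted(not_tested))
    ids = [s[0] for s in stats]
    statistic = np.array([s[1] for s in stats])
    pvals = np.array([s[2] for s in stats])
    fdr = core.fdr_adjust(pvals)
    ranks = rankdata(fdr, method="average")
    table = pd.DataFrame(
        {
            "cdt_id": ids,
            "statistic": statistic,
            "p_or_z": fdr,
            "significant": fdr <= alpha,
            "rank": ranks,
        }
    ).sort_values(["rank", "cdt_id"], kind="mergesort").reset_index(drop=True)
    return MethodReport(method=method, params=params, table=table, not_tested=sorted(not_tested))


def run_method(
    method: str,
    kb: KnowledgeBase,
    profile: DEProfile,
    params: Optional[dict] = None,
    seed: Optional[int] = None,
) -> MethodReport:
    """Run one method end to end on (KB, DE profile) → MethodReport.

    ``params`` keys understood: alpha (0.05), hypothesis ("H1"/"H2", used
    by pure), nperm/min_size (gsea), fdr_mode/strict_tail (pure).
    Deterministic given the seed.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    params = dict(params or {})
    alpha = float(params.get("alpha", 0.05))

    de_genes = select_de_genes(profile)
    de_by_id = {g.gene_id: g for g in de_genes}

    if method == "pure":
        hypothesis = params.get("hypothesis", "H1")
        net = core.label_edges(core.build_overlap(kb, de_genes))
        results = core.test_all(
            net,
            alpha=alpha,
            fdr_mode=params.get("fdr_mode", "per_hypothesis"),
            strict_tail=params.get("strict_tail", False),
            min_edges=params.get("min_edges", 0),
        )
        if not results:
            return MethodReport(method=method, params=params)
        if hypothesis == "H1":
            fdr = np.array([r.fdr_h1 for r in results])
            rank = np.array([r.rank_h1 for r in results])
            stat = np.array([r.p_h1 for r in results])
        elif hypothesis == "H2":
            fdr = np.array([r.fdr_h2 for r in results])
            rank = np.array([r.rank_h2 for r in results])
            stat = np.array([r.p_h2 for r in results])
        else:
            raise ValueError(f"unknown hypothesis {hypothesis!r}")
        table = pd.DataFrame(
            {
                "cdt_id": [r.cdt_id for r in results],
                "statistic": stat,
                "p_or_z": fdr,
                "significant": fdr <= alpha,
                "rank": rank,
            }
        ).sort_values(["rank", "cdt_id"], kind="mergesort").reset_index(drop=True)
        return MethodReport(method=method, params=params, table=table)

    view = GeneSetView.from_inputs(kb, profile)

    if method == "ora":
        N = len(view.background)
        de_in_bg = [g for g in view.background if g in de_by_id]
        n = len(de_in_bg)
        stats = []
        for cdt, targets in view.targets.items():
            M = len(targets)
            x = sum(1 for g in targets if g in de_by_id)
            p = ora_pvalue(N, M, n, x)
            stats.append((cdt, float(x), p))
        return _pvalue_report(method, params, stats, [], alpha)

    if method in ("ks", "wilcoxon"):
        de_ids = set(de_by_id)
        stats = []
        skipped = []
        for cdt, targets in view.targets.items():
            hit_ids = [g for g in targets if g in de_ids]
            miss_ids = [g for g in de_ids if g not in set(targets)]
            if not hit_ids or not miss_ids:
                skipped.append(cdt)
                continue
            hits = [de_by_id[g].log_fc for g in hit_ids]
            miss = [de_by_id[g].log_fc for g in miss_ids]
            if method == "ks":
                d, p = ks_test(hits, miss)
                stats.append((cdt, d, p))
            else:
                w, p = wilcoxon_ranksum(hits, miss)
                stats.append((cdt, w, p))
        return _pvalue_report(method, params, stats, skipped, alpha)

    if method == "gsea":
        nperm = int(params.get("nperm", DEFAULT_NPERM))
        min_size = int(params.get("min_size", DEFAULT_MIN_SIZE))
        scores = profile.records.set_index("gene_id")["log_fc"]
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        stats = []
        skipped = []
        for j, (cdt, targets) in enumerate(view.targets.items()):
            sub = int(np.random.SeedSequence(entropy=ss.entropy, spawn_key=(j,)).generate_state(1)[0])
            res = gsea_preranked(scores, targets, nperm=nperm, min_size=min_size, seed=sub)
            if res is None:
                skipped.append(cdt)
                continue
            es, p = res
            stats.append((cdt, es, p))
        return _pvalue_report(method, params, stats, skipped, alpha)

    # ipa_like / ipa_cdt_like: activation z-score ranking, |z| descending
    rows = []
    skipped = []
    for cdt, targets in view.targets.items():
        edges = [
            (e.weight, e.sign, de_by_id[e.gene_id].sign)
            for e in kb.edges
            if e.cdt_id == cdt and e.gene_id in de_by_id
        ]
        z = ipa_zscore(edges)
        if z is None:
            skipped.append(cdt)
            continue
        rows.append((cdt, z))
    if not rows:
        return MethodReport(method=method, params=params, not_tested=sorted(skipped))
    ids = [r[0] for r in rows]
    z = np.array([r[1] for r in rows])
    ranks = rankdata(-np.abs(z), method="average")
    table = pd.DataFrame(
        {
            "cdt_id": ids,
            "statistic": z,
            "p_or_z": z,
            "significant": np.abs(z) >= 2,
            "rank": ranks,
        }
    ).sort_values(["rank", "cdt_id"], kind="mergesort").reset_index(drop=True)
    return MethodReport(method=method, params=params, table=table, not_tested=sorted(skipped))
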
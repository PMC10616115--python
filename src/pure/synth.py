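"""Synthetic knowledge bases and DE profiles.

The generator emulates the generative story behind the two directional
hypotheses: a single "true" CDT is perturbed, so each of its target genes
becomes differentially expressed with the sign implied by the signed edge
(H1) or the opposite sign (H2 — the CDT is lacking), independently flipped
with probability ``agreement_noise``; unrelated genes become DE at a small
background rate with a random sign.  DE magnitudes sit strictly above the
|log FC| > 0.6 / p < 0.05 selection thresholds and non-DE values strictly
below/above, so threshold behaviour is deterministic in tests.

A single global seed derives per-replicate substreams by counter, so any
replicate is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import benchmark, comparators, core
from .de import DEProfile, select_de_genes
from .kb import Edge, KnowledgeBase


@dataclass
class SimulationConfig:
    """Conditions for one simulated experiment.

    Defaults describe a small but structured screen: 50 candidate CDTs
    over 200 genes, 20–60 signed edges per CDT (curated chemicals
    typically carry tens to hundreds of expression edges) with an even
    activation/inhibition mix, a noiseless true perturbation, and a 2%
    background DE rate.  The edge-count floor keeps a noiseless
    perturbation decisively detectable: even at the pessimistic chance
    support fraction of ~0.75 among unrelated edges, a 20-edge true CDT
    has raw p below 0.005, so its BH-adjusted value cannot saturate into
    a field-wide tie.  ``logfc_magnitude`` gives the (location, scale)
    of the log-normal excess above the fold-change cut for DE genes;
    ``de_p_value_beta`` the Beta shapes for DE and non-DE p-values within
    their respective admissible intervals.
    """

    n_cdts: int = 50
    n_genes: int = 200
    edges_per_cdt: tuple[int, int] = (20, 60)
    activation_fraction: float = 0.5
    true_cdt_hypothesis: Literal["H1", "H2"] = "H1"
    agreement_noise: float = 0.0
    background_de_rate: float = 0.02
    logfc_magnitude: tuple[float, float] = (-0.5, 0.6)
    de_p_value_beta: tuple[tuple[float, float], tuple[float, float]] = (
        (0.5, 3.0),
        (1.0, 1.0),
    )
    logfc_cut: float = 0.6
    p_cut: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cdts < 2:
            raise ValueError("n_cdts must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.edges_per_cdt
        if lo < 1 or hi < lo:
            raise ValueError("edges_per_cdt must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValueError("edges_per_cdt max cannot exceed n_genes")
        for name in ("activation_fraction", "agreement_noise", "background_de_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.true_cdt_hypothesis not in ("H1", "H2"):
            raise ValueError("true_cdt_hypothesis must be 'H1' or 'H2'")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng_for(cfg: SimulationConfig, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,))
    )


def generate_kb(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> KnowledgeBase:
    """Draw a synthetic signed KB: per CDT an edge count uniform on the
    configured range, targets sampled without replacement, each edge
    activation with probability ``activation_fraction``."""
    rng = rng if rng is not None else _rng_for(cfg, 0)
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    lo, hi = cfg.edges_per_cdt
    edges: list[Edge] = []
    names: dict[str, str] = {}
    for j in range(1, cfg.n_cdts + 1):
        cdt = f"CDT{j:03d}"
        names[cdt] = f"compound-{j:03d}"
        n_edges = int(rng.integers(lo, hi + 1))
        targets = rng.choice(cfg.n_genes, size=n_edges, replace=False)
        for t in targets:
            sign = 1 if rng.random() < cfg.activation_fraction else -1
            edges.append(
                Edge(
                    cdt_id=cdt,
                    gene_id=genes[int(t)],
                    sign=sign,
                    organism="synthetic",
                    provenance="synth",
                )
            )
    return KnowledgeBase(
        edges=sorted(edges, key=lambda e: e.key), cdt_names=names, organism="synthetic"
    )


def _draw_de_stats(rng, n, cfg) -> tuple[np.ndarray, np.ndarray]:
    """|log FC| strictly above the cut and p strictly below the cut."""
    mu, sigma = cfg.logfc_magnitude
    a, b = cfg.de_p_value_beta[0]
    lfc = cfg.logfc_cut + rng.lognormal(mean=mu, sigma=sigma, size=n)
    p = cfg.p_cut * np.clip(rng.beta(a, b, size=n), 1e-12, 1 - 1e-12)
    return lfc, p


def _draw_null_stats(rng, n, cfg) -> tuple[np.ndarray, np.ndarray]:
    """|log FC| at or below the cut and p at or above the cut."""
    a, b = cfg.de_p_value_beta[1]
    lfc = cfg.logfc_cut * rng.random(size=n)
    p = cfg.p_cut + (1 - cfg.p_cut) * np.clip(rng.beta(a, b, size=n), 0.0, 1 - 1e-12)
    return lfc, p


def generate_profile(
    kb: KnowledgeBase,
    true_cdt: str,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> DEProfile:
    """Simulate the DE table caused by perturbing ``true_cdt``.

    Under H1 each target's DE sign equals its edge sign; under H2 it is
    opposed; either way it is flipped independently with probability
    ``agreement_noise``.  Non-target genes are DE with probability
    ``background_de_rate`` and a uniform random sign; all remaining genes
    receive sub-threshold statistics.
    """
    if true_cdt not in kb.cdt_names and true_cdt not in {e.cdt_id for e in kb.edges}:
        raise ValueError(f"true CDT {true_cdt!r} not present in the knowledge base")
    rng = rng if rng is not None else _rng_for(cfg, 1)
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    target_sign: dict[str, int] = {}
    for e in kb.edges_of(true_cdt):
        implied = e.sign if cfg.true_cdt_hypothesis == "H1" else -e.sign
        target_sign.setdefault(e.gene_id, implied)
    # independent per-gene contradiction of the implied direction
    for g in list(target_sign):
        if rng.random() < cfg.agreement_noise:
            target_sign[g] = -target_sign[g]

    rows = []
    non_targets = [g for g in genes if g not in target_sign]
    bg_de = {g for g in non_targets if rng.random() < cfg.background_de_rate}

    n_t = len(target_sign)
    t_lfc, t_p = _draw_de_stats(rng, n_t, cfg)
    for (g, s), lfc, p in zip(sorted(target_sign.items()), t_lfc, t_p):
        rows.append({"gene_id": g, "log_fc": s * lfc, "p_value": p})
    b_lfc, b_p = _draw_de_stats(rng, len(bg_de), cfg)
    for g, lfc, p in zip(sorted(bg_de), b_lfc, b_p):
        s = 1 if rng.random() < 0.5 else -1
        rows.append({"gene_id": g, "log_fc": s * lfc, "p_value": p})
    null_genes = [g for g in non_targets if g not in bg_de]
    n_lfc, n_p = _draw_null_stats(rng, len(null_genes), cfg)
    for g, lfc, p in zip(null_genes, n_lfc, n_p):
        s = 1 if rng.random() < 0.5 else -1
        rows.append({"gene_id": g, "log_fc": s * lfc, "p_value": p})

    df = (
        pd.DataFrame(rows, columns=["gene_id", "log_fc", "p_value"])
        .sort_values("gene_id", kind="mergesort")
        .reset_index(drop=True)
    )
    return DEProfile(
        records=df,
        logfc_cut=cfg.logfc_cut,
        p_cut=cfg.p_cut,
        meta={
            "true_cdt": true_cdt,
            "hypothesis": cfg.true_cdt_hypothesis,
            "n_targets_de": n_t,
            "n_background_de": len(bg_de),
        },
    )


def simulate_experiment(
    cfg: SimulationConfig, replicate: int = 0
) -> tuple[KnowledgeBase, DEProfile, str]:
    """One replicate: KB + profile + true CDT, on its own substream."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(replicate,))
    )
    kb = generate_kb(cfg, rng)
    true_cdt = kb.cdt_ids[int(rng.integers(0, len(kb.cdt_ids)))]
    profile = generate_profile(kb, true_cdt, cfg, rng)
    return kb, profile, true_cdt


def recovery_experiment(
    cfg: SimulationConfig,
    n_replicates: int,
    methods: Sequence[str] = ("pure",),
    method_params: Optional[dict[str, dict]] = None,
) -> pd.DataFrame:
    """Run the recovery benchmark: per replicate generate (KB, profile),
    run each method, and record the true CDT's rank and the false-positive
    count.  PURE is evaluated under the simulated hypothesis."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    method_params = method_params or {}
    rows: list[benchmark.EvaluationRow] = []
    for rep in range(n_replicates):
        kb, profile, true_cdt = simulate_experiment(cfg, replicate=rep)
        record = benchmark.ExperimentRecord(
            experiment_id=f"rep{rep:03d}",
            true_cdt_id=true_cdt,
            hypothesis=cfg.true_cdt_hypothesis,
        )
        for m in methods:
            params = dict(method_params.get(m, {}))
            if m == "pure":
                params.setdefault("hypothesis", cfg.true_cdt_hypothesis)
            record.reports[m] = comparators.run_method(
                m, kb, profile, params=params, seed=(cfg.seed * 100_003 + rep) % (2**31 - 1)
            )
        rows.extend(benchmark.evaluate_experiment(record))
    return benchmark.rows_to_frame(rows)
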
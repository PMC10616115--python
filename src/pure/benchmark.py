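"""Evaluation machinery for comparing upstream-regulator methods.

Given per-method :class:`~pure.comparators.MethodReport` objects and a
known true CDT per experiment, this module extracts the rank of the true
CDT (with the average-rank tie convention), imputes a rank of
``n_significant + 1`` when the true CDT is absent from a report, counts
false positives, aggregates mean ± sd across experiments, and compares
methods with two-sided Wilcoxon tests (both paired signed-rank and
unpaired rank-sum variants, since either convention is defensible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .comparators import MethodReport


@dataclass
class ExperimentRecord:
    """One benchmark experiment: a known perturbation and the reports of
    every method run on its DE profile."""

    experiment_id: str
    true_cdt_id: str
    hypothesis: Literal["H1", "H2"]
    reports: dict[str, MethodReport] = field(default_factory=dict)


@dataclass
class EvaluationRow:
    """Per (experiment, method) outcome."""

    experiment_id: str
    method: str
    rank_of_true: float
    true_found: bool
    n_significant: int
    false_positives: int

    def __post_init__(self) -> None:
        if not self.true_found and self.rank_of_true != self.n_significant + 1:
            raise ValueError(
                "missing true CDT must carry the imputed rank n_significant + 1"
            )


def rank_of_true(report: MethodReport, true_cdt: str) -> tuple[float, bool]:
    """The true CDT's average-rank in the report; when it is absent from
    the ranked list the imputed rank (significant count + 1) applies."""
    r = report.rank_of(true_cdt)
    if r is None:
        return float(report.n_significant + 1), False
    return r, True


def count_false_positives(report: MethodReport, true_cdt: str) -> int:
    """Significant CDTs other than the true one."""
    if not len(report.table):
        return 0
    sig = report.table.loc[report.table["significant"], "cdt_id"]
    n = len(sig)
    if true_cdt in set(sig):
        n -= 1
    return n


def evaluate_experiment(record: ExperimentRecord) -> list[EvaluationRow]:
    rows = []
    for method, report in sorted(record.reports.items()):
        rank, found = rank_of_true(report, record.true_cdt_id)
        rows.append(
            EvaluationRow(
                experiment_id=record.experiment_id,
                method=method,
                rank_of_true=rank,
                true_found=found,
                n_significant=report.n_significant,
                false_positives=count_false_positives(report, record.true_cdt_id),
            )
        )
    return rows


def rows_to_frame(rows: Sequence[EvaluationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "experiment_id": r.experiment_id,
                "method": r.method,
                "rank_of_true": r.rank_of_true,
                "true_found": r.true_found,
                "n_significant": r.n_significant,
                "false_positives": r.false_positives,
            }
            for r in rows
        ]
    )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Report-style rounding (0.05 → up), as in printed summary tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate(
    frame: pd.DataFrame,
    value: str = "rank_of_true",
) -> pd.DataFrame:
    """Per-method arithmetic mean and sample standard deviation of a
    value column; a single experiment yields sd 0 with ``sd_defined``
    False.  ``mean_1dp`` carries the one-decimal display value."""
    if not len(frame):
        raise ValueError("aggregate requires at least one experiment row")
    out = []
    for method, grp in frame.groupby("method", sort=True):
        vals = grp[value].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        sd_defined = vals.size > 1
        sd = float(np.std(vals, ddof=1)) if sd_defined else 0.0
        out.append(
            {
                "method": method,
                "n": int(vals.size),
                "mean": mean,
                "sd": sd,
                "sd_defined": sd_defined,
                "mean_1dp": round_half_up(mean, 1),
                "sd_1dp": round_half_up(sd, 1),
            }
        )
    return pd.DataFrame(out)


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by complete permutation enumeration.

    Pooled midranks make the null distribution exact under ties; the
    two-sided p is the fraction of group assignments whose rank-sum
    deviates from its mean at least as much as the observed one.
    """
    from itertools import combinations

    from scipy.stats import rankdata as _rankdata

    pooled = np.concatenate([a, b])
    ranks = _rankdata(pooled, method="average")
    n1 = a.size
    w_obs = float(ranks[:n1].sum())
    mean_w = ranks.sum() * n1 / ranks.size
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for idx in combinations(range(ranks.size), n1):
        w = float(ranks[list(idx)].sum())
        if abs(w - mean_w) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def compare_methods(
    ranks_a: Sequence[float],
    ranks_b: Sequence[float],
    variant: Literal["unpaired", "paired"] = "unpaired",
) -> float:
    """Two-sided Wilcoxon comparison of two methods' per-experiment values.

    ``unpaired`` is the rank-sum (Mann–Whitney) test: a full permutation
    enumeration (midranks, so ties are handled exactly) when both groups
    have at most 8 values, the normal approximation with tie correction
    otherwise.  ``paired`` is the signed-rank test over per-experiment
    differences (all-zero differences → p = 1).  Missing ranks must be
    imputed beforehand.
    """
    a = np.asarray(list(ranks_a), dtype=float)
    b = np.asarray(list(ranks_b), dtype=float)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty rank vectors")
    if variant == "unpaired":
        if a.size <= 8 and b.size <= 8:
            return _exact_ranksum_p(a, b)
        return float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    if variant == "paired":
        d = a - b
        if np.all(d == 0):
            return 1.0
        return float(
            wilcoxon(a, b, alternative="two-sided", zero_method="zsplit", method="auto").pvalue
        )
    raise ValueError(f"unknown variant {variant!r}")


def compare_methods_all(
    frame: pd.DataFrame,
    reference: str = "pure",
    value: str = "rank_of_true",
) -> pd.DataFrame:
    """Reference-vs-each-other-method comparison table, both variants."""
    wide = frame.pivot(index="experiment_id", columns="method", values=value)
    if reference not in wide.columns:
        raise ValueError(f"reference method {reference!r} absent from rows")
    out = []
    for method in wide.columns:
        if method == reference:
            continue
        sub = wide[[reference, method]].dropna()
        out.append(
            {
                "method": method,
                "value": value,
                "n": len(sub),
                "p_unpaired": compare_methods(sub[reference], sub[method], "unpaired"),
                "p_paired": compare_methods(sub[reference], sub[method], "paired"),
            }
        )
    return pd.DataFrame(out)
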
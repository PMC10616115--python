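"""Reference benchmark results shipped with the package.

``reference_benchmark.tsv`` records, for each of the 16 public expression
experiments used in PURE's original evaluation (GEO accession, organism,
administered/target CDT, tested hypothesis), the rank PURE assigned to
the true CDT and the number of CDTs PURE reported as significant.  The
per-experiment values are inputs; summary statistics are always
recomputed from them with :mod:`pure.benchmark`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import benchmark


def load_reference_benchmark() -> pd.DataFrame:
    """Load the per-experiment reference evaluation table."""
    with resources.files("pure.data").joinpath("reference_benchmark.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def reference_summary() -> dict[str, float]:
    """Recompute the headline PURE summary statistics from the
    per-experiment reference values (mean rank of the true CDT and mean
    significant-CDT count, per hypothesis, at report precision)."""
    df = load_reference_benchmark()
    out: dict[str, float] = {}
    for hyp, grp in df.groupby("hypothesis"):
        frame = pd.DataFrame(
            {
                "method": "pure",
                "experiment_id": grp["experiment_id"],
                "rank_of_true": grp["pure_rank_of_true"],
                "n_significant": grp["pure_n_significant"],
            }
        )
        agg_rank = benchmark.aggregate(frame, value="rank_of_true").iloc[0]
        agg_cnt = benchmark.aggregate(frame, value="n_significant").iloc[0]
        if hyp == "H1":
            out["mean_rank_h1"] = float(agg_rank["mean_1dp"])
            out["mean_significant_h1"] = float(agg_cnt["mean_1dp"])
            out["n_h1"] = int(agg_rank["n"])
        else:
            out["mean_rank_h2"] = float(agg_rank["mean"])
            out["mean_significant_h2"] = float(agg_cnt["mean"])
            out["n_h2"] = int(agg_rank["n"])
    return out
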
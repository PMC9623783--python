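"""Published reference statistics packaged with the library.

Two small tables from a US Holstein type-trait genomic evaluation ship as
CSV fixtures: per-year-group counts of genotyped animals receiving direct
(GEBV) versus indirect (IGP) predictions, and the 18-trait validation table
(standardized genetic trend, regression intercept/slope/R^2 and absolute-
difference summaries by sex). They anchor the partition arithmetic and the
trend-correlation computations against printed values.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .population import share_percent

__all__ = [
    "load_partition_counts",
    "load_type_trait_table",
    "partition_shares",
    "type_trait_summary",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("igpipe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_partition_counts() -> pd.DataFrame:
    """Genotyped-animal counts per year group (IGP by sex, and GEBV)."""
    return _read("holstein_partition_counts.csv")


def load_type_trait_table() -> pd.DataFrame:
    """Per-trait validation statistics for 18 linear type traits.

    Columns: dg (standardized genetic trend), b0/b1/r2/mean/max by sex.
    b0, dg, mean and max are in genetic-SD units; b1 and r2 are unitless.
    """
    return _read("holstein_type_traits.csv")


def partition_shares() -> pd.DataFrame:
    """GEBV/IGP shares (integer percent) recomputed from the printed counts."""
    counts = load_partition_counts()
    total = counts["n_igp_total"] + counts["n_gebv"]
    return pd.DataFrame(
        {
            "year_group": counts["year_group"],
            "n_genotyped": total,
            "gebv_share": [share_percent(g, t) for g, t in zip(counts["n_gebv"], total)],
            "igp_share": [share_percent(i, t) for i, t in zip(counts["n_igp_total"], total)],
        }
    )


def type_trait_summary() -> dict:
    """Mean/SD rows and trend correlations recomputed from the trait table.

    Means and SDs are rounded to the column's printed precision (2 dp for
    b0/b1/mean/max/dg, 3 dp for r2); correlations of dg with each statistic
    to 2 dp.
    """
    tab = load_type_trait_table()
    out = {"mean": {}, "sd": {}, "trend_correlation": {}}
    for col in tab.columns[1:]:
        dec = 3 if col.startswith("r2") else 2
        vals = tab[col].to_numpy(dtype=float)
        out["mean"][col] = round(float(vals.mean()), dec)
        out["sd"][col] = round(float(vals.std(ddof=1)), dec)
        if col != "dg":
            out["trend_correlation"][col] = round(float(np.corrcoef(tab["dg"], vals)[0, 1]), 2)
    return out
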
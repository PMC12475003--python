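"""Ranked candidate table and bubble-plot export.

Proteins are ordered by decreasing ANOSIM R, ties broken by decreasing effect
JSD, then by ascending protein identifier — a stable total order, so the
ranking is reproducible and invariant to input row order.  Untestable proteins
follow all testable proteins and carry no rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def rank_proteins(stats: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks 1..N over testable proteins by (R desc, effect JSD desc, id asc).

    ``stats`` needs columns protein_id, anosim_r, effect_jsd, testable_flag
    (plus any statistic columns, which are carried through).  Untestable rows
    are placed after all testable rows with rank NaN.
    """
    df = stats.copy()
    df["_key_r"] = df["anosim_r"].where(df["testable_flag"], -np.inf)
    df["_key_j"] = df["effect_jsd"].where(df["testable_flag"], -np.inf)
    df = df.sort_values(
        by=["testable_flag", "_key_r", "_key_j", "protein_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).drop(columns=["_key_r", "_key_j"])
    n_testable = int(df["testable_flag"].sum())
    rank = np.full(len(df), np.nan)
    rank[:n_testable] = np.arange(1, n_testable + 1)
    df["rank"] = rank
    return df.reset_index(drop=True)


def candidate_table(ranked: pd.DataFrame, r_cutoff: float) -> pd.DataFrame:
    """Testable records with R >= cutoff, rank order preserved."""
    mask = ranked["testable_flag"] & (ranked["anosim_r"] >= r_cutoff)
    return ranked.loc[mask].reset_index(drop=True)


def bubbleplot_table(
    ranked: pd.DataFrame, groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Plot-ready records: x = RPS, y = RDC, size = effect JSD, optional group tag.

    On a categorical fraction axis the x column is empty (NaN) while y and
    size stay populated.
    """
    df = ranked.loc[ranked["testable_flag"]]
    out = pd.DataFrame(
        {
            "protein_id": df["protein_id"],
            "x_relative_fraction_shift": df["relative_fraction_shift"],
            "y_relative_distribution_change": df["relative_distribution_change"],
            "size_effect_jsd": df["effect_jsd"],
        }
    )
    if groups is not None:
        out["group"] = [groups.get(p, "") for p in out["protein_id"]]
    return out.reset_index(drop=True)


def median_rank_by_group(
    ranked: pd.DataFrame, groups: dict[str, str]
) -> pd.Series:
    """Median rank per annotated protein group (smaller = stronger candidates)."""
    df = ranked.loc[ranked["testable_flag"], ["protein_id", "rank"]].copy()
    df["group"] = [groups.get(p) for p in df["protein_id"]]
    return df.dropna(subset=["group"]).groupby("group")["rank"].median()
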
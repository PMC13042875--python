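"""Relative Specificity Score (RSS) for regulon-cell-group association.

For a regulon and a target cell group,
``rss = (mean activity in target - mean activity in the pooled complement)
/ max activity over all cells``; higher values indicate greater
specificity. A regulon whose maximum activity is 0 scores 0, keeping the
table totally ordered.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def regulon_rss(
    activity: pd.DataFrame, group: pd.Series, target_group: str
) -> pd.DataFrame:
    """RSS table for one target group, sorted descending by rss.

    Parameters
    ----------
    activity
        Regulons x cells nonnegative activity matrix.
    group
        Per-cell group label aligned with the activity columns.
    target_group
        Group whose specificity is scored against the pooled complement.
    """
    group = pd.Series(group).reindex(activity.columns)
    if group.isna().any():
        raise ValueError("group labels missing for some cells")
    in_target = (group == target_group).to_numpy()
    if not in_target.any():
        raise ValueError(f"target group {target_group!r} has no cells")
    if in_target.all():
        raise ValueError("no cells outside the target group")
    A = activity.to_numpy(dtype=float)
    if np.any(A < 0):
        raise ValueError("activities must be nonnegative")

    target = A[:, in_target].mean(axis=1)
    other = A[:, ~in_target].mean(axis=1)
    mx = A.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = np.where(mx > 0, (target - other) / np.where(mx > 0, mx, 1.0), 0.0)
    table = pd.DataFrame(
        {
            "regulon": activity.index,
            "target_activity": target,
            "other_activity": other,
            "max_activity": mx,
            "rss": rss,
        }
    )
    return (
        table.sort_values(["rss", "regulon"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def top_specific_regulons(table: pd.DataFrame, k: int) -> list:
    """Top-k regulons by rss, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        warnings.warn(
            f"k={k} exceeds the {len(table)} regulons; returning the full list"
        )
        k = len(table)
    ordered = table.sort_values(
        ["rss", "regulon"], ascending=[False, True], kind="mergesort"
    )
    return ordered["regulon"].head(k).tolist()
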
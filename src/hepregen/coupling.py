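"""Dynamic time warping and pathway-zonation trajectory coupling.

DTW is computed with the symmetric step pattern on the local cost
c(i,j) = |a_i - b_j|, no window constraint and no path-length
normalization; smaller distances mean more similar trajectories. For the
coupling ranking, every series is z-normalized first (pathway activities
and zone proportions live on different scales), each pathway is compared
with the three zone-proportion series, and pathways are ranked by the mean
of the three distances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def z_normalize(values: np.ndarray) -> np.ndarray:
    """Z-score a series; an sd-0 series maps to all zeros with a warning."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        warnings.warn("zero-variance series z-normalized to all zeros")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def dtw_distance(a, b, z_normalize_input: bool = True) -> float:
    """Dynamic time warping distance between two series.

    Recurrence: D(i,j) = |a_i - b_j| + min(D(i-1,j), D(i,j-1), D(i-1,j-1)),
    with cumulative first row/column boundaries; the distance is D(m,n).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty series")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series must be finite")
    if z_normalize_input:
        a, b = z_normalize(a), z_normalize(b)
    cost = np.abs(a[:, None] - b[None, :])
    D = np.empty_like(cost)
    D[0, 0] = cost[0, 0]
    D[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    D[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    for i in range(1, a.size):
        for j in range(1, b.size):
            D[i, j] = cost[i, j] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[-1, -1])


def couple_pathways_to_zonation(
    pathway_profiles: pd.DataFrame,
    zone_series: pd.DataFrame,
    z_normalize_input: bool = True,
    aggregate: str = "min",
) -> pd.DataFrame:
    """Rank pathways by temporal coupling with the zone-proportion series.

    Both inputs have rows = series and columns = samples in timecourse
    order. Per pathway, DTW is computed against each of the three zone
    series and the per-zone distances are combined into one aggregate:
    ``"min"`` (default) scores a pathway by its closest zone — the three
    zone proportions are complementary (they sum to 1), so a pathway
    tracking one zone is necessarily anti-correlated with the others and a
    mean would penalize exactly the strongest couplings — while ``"mean"``
    averages the three. The table is sorted ascending by aggregate with
    lexicographic tie-break, and ranks are 1..n.
    """
    if aggregate not in ("min", "mean"):
        raise ValueError("aggregate must be 'min' or 'mean'")
    zones = ["Zone1", "Zone2", "Zone3"]
    missing = [z for z in zones if z not in zone_series.index]
    if missing:
        raise ValueError(f"zone series missing: {missing}")
    if list(pathway_profiles.columns) != list(zone_series.columns):
        raise ValueError(
            "sample order mismatch between pathway profiles "
            f"{list(pathway_profiles.columns)} and zone series "
            f"{list(zone_series.columns)}"
        )
    rows = []
    for name, profile in pathway_profiles.iterrows():
        d = {
            f"dtw_{z.lower()}": dtw_distance(
                profile.to_numpy(), zone_series.loc[z].to_numpy(),
                z_normalize_input=z_normalize_input,
            )
            for z in zones
        }
        d["pathway"] = name
        per_zone = [d[f"dtw_{z.lower()}"] for z in zones]
        d["aggregate"] = float(min(per_zone) if aggregate == "min" else np.mean(per_zone))
        rows.append(d)
    table = pd.DataFrame(rows).sort_values(
        ["aggregate", "pathway"], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    cols = ["pathway", "dtw_zone1", "dtw_zone2", "dtw_zone3", "aggregate", "rank"]
    return table[cols].reset_index(drop=True)
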
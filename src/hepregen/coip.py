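"""Stepwise Co-IP-MS filtering for high-confidence AFP interactors.

The pipeline starts from quantified protein tables (one per pull-down
experiment, with IgG control replicates) and applies, in order:

1. quality control — keep records with >= 2 unique peptides, search score
   >= 30 and sequence coverage >= 5%;
2. specificity — keep records with fold change over the mean IgG intensity
   strictly above ``fc_min`` AND experimental intensity strictly above the
   mean IgG intensity + ``sd_mult`` standard deviations (per-protein IgG
   replicates when at least two exist, table-wide IgG distribution
   otherwise); a zero IgG mean passes the fold-change rule by convention
   (infinite enrichment);
3. contaminants — drop flagged records and listed ids;
4. abundance — keep records whose iBAQ share of the post-contaminant table
   is at least ``ibaq_pct_min`` percent.

Zero iBAQ_IgG values are imputed with half the table-wide minimum nonzero
value before log2(iBAQ/iBAQ_IgG) is formed. Consensus interactors are the
intersection of the survivors of two experiments, with the two log2 fold
changes and log2 iBAQ ratios averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ProteinTable


@dataclass
class FilterStep:
    step: str
    n_in: int
    n_out: int
    removed: list


@dataclass
class FilterReport:
    steps: list = field(default_factory=list)
    consensus: pd.DataFrame | None = None

    def removed_by_step(self) -> dict:
        return {s.step: list(s.removed) for s in self.steps}


def _as_df(table) -> pd.DataFrame:
    df = table.df if isinstance(table, ProteinTable) else table
    if df["protein_id"].duplicated().any():
        raise ValueError("duplicate protein_ids in table")
    return df.copy()


def _igg_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns if c.startswith("intensity_igg")]


def impute_and_log_ratio(table) -> pd.DataFrame:
    """Impute zero iBAQ_IgG with half the minimum nonzero value and add
    ``log2_ibaq_ratio`` = log2(iBAQ / imputed iBAQ_IgG)."""
    df = _as_df(table)
    nonzero = df.loc[df["ibaq_igg"] > 0, "ibaq_igg"]
    if nonzero.empty:
        raise ValueError("all ibaq_igg values are zero; imputation undefined")
    half_min = nonzero.min() / 2.0
    df["ibaq_igg_imputed"] = df["ibaq_igg"].where(df["ibaq_igg"] > 0, half_min)
    df["log2_ibaq_ratio"] = np.log2(df["ibaq_exp"] / df["ibaq_igg_imputed"])
    return df


def filter_high_confidence(
    table,
    contaminants=(),
    fc_min: float = 4.0,
    sd_mult: float = 3.0,
    ibaq_pct_min: float = 0.1,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the four sequential filters; every step is logged.

    Returns the surviving records (with ``fc``, ``log2_fc`` and
    ``ibaq_pct`` columns added) and a :class:`FilterReport` with one entry
    per step.
    """
    df = _as_df(table)
    if df.empty:
        raise ValueError("empty protein table")
    igg_cols = _igg_columns(df)
    if not igg_cols:
        raise ValueError("no IgG intensity replicate columns found")
    numeric = df[["intensity_exp", "ibaq_exp", "ibaq_igg"] + igg_cols]
    if (numeric.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    if "log2_ibaq_ratio" not in df.columns:
        df = impute_and_log_ratio(df)
    report = FilterReport()

    def log_step(name: str, kept: pd.DataFrame, prev: pd.DataFrame):
        removed = sorted(set(prev["protein_id"]) - set(kept["protein_id"]))
        report.steps.append(FilterStep(name, len(prev), len(kept), removed))

    # 1. quality control
    qc = df[
        (df["unique_peptides"] >= 2)
        & (df["score"] >= 30.0)
        & (df["coverage_pct"] >= 5.0)
    ]
    log_step("quality", qc, df)

    # 2. specificity vs IgG controls
    igg = qc[igg_cols].to_numpy(dtype=float)
    igg_mean = igg.mean(axis=1)
    with np.errstate(divide="ignore"):
        fc = np.where(igg_mean > 0, qc["intensity_exp"] / np.where(igg_mean > 0, igg_mean, 1.0), np.inf)
    pass_fc = fc > fc_min  # zero IgG mean -> fc = inf -> passes by convention
    if igg.shape[1] >= 2:
        mu, sd = igg.mean(axis=1), igg.std(axis=1, ddof=1)
    else:
        pooled = df[igg_cols].to_numpy(dtype=float).ravel()
        mu = igg.mean(axis=1)
        sd = np.full(len(qc), pooled.std(ddof=1))
    pass_int = qc["intensity_exp"].to_numpy() > mu + sd_mult * sd
    spec = qc[pass_fc & pass_int].copy()
    spec["fc"] = fc[pass_fc & pass_int]
    with np.errstate(divide="ignore"):
        spec["log2_fc"] = np.log2(spec["fc"])
    log_step("specificity", spec, qc)

    # 3. contaminants
    contaminants = set(contaminants)
    clean = spec[
        ~spec["contaminant"].astype(bool)
        & ~spec["protein_id"].isin(contaminants)
    ]
    log_step("contaminants", clean, spec)

    # 4. abundance (iBAQ share of the post-contaminant table)
    total = clean["ibaq_exp"].sum()
    clean = clean.copy()
    clean["ibaq_pct"] = 100.0 * clean["ibaq_exp"] / total if total > 0 else 0.0
    final = clean[clean["ibaq_pct"] >= ibaq_pct_min]
    log_step("abundance", final, clean)

    return final.reset_index(drop=True), report


def consensus_interactors(ctl: pd.DataFrame, oe: pd.DataFrame) -> FilterReport:
    """Intersect two filtered tables and average their log2 statistics.

    Both inputs must carry ``log2_fc`` and ``log2_ibaq_ratio`` (as produced
    by :func:`filter_high_confidence`). An empty intersection is allowed
    but warned about.
    """
    for name, df in (("ctl", ctl), ("oe", oe)):
        for col in ("log2_fc", "log2_ibaq_ratio"):
            if col not in df.columns:
                raise ValueError(f"{name} table lacks {col!r}")
    merged = ctl.merge(oe, on="protein_id", suffixes=("_ctl", "_oe"))
    if merged.empty:
        warnings.warn("empty consensus: no protein survived in both experiments")
    consensus = pd.DataFrame(
        {
            "protein_id": merged["protein_id"],
            "mean_log2_fc": (merged["log2_fc_ctl"] + merged["log2_fc_oe"]) / 2.0,
            "mean_log2_ibaq_ratio": (
                merged["log2_ibaq_ratio_ctl"] + merged["log2_ibaq_ratio_oe"]
            )
            / 2.0,
        }
    ).sort_values("protein_id", kind="mergesort").reset_index(drop=True)
    return FilterReport(steps=[], consensus=consensus)
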
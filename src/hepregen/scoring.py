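"""Gene-set scoring, cycling-cell calling, rank-sum DE, temporal clustering,
and construction of the reprogramming signature (ARS).

The module score follows the binned-control scheme used throughout
single-cell analysis: genes are binned by average expression, each signature
gene draws control genes from its own bin, and a cell's score is the mean
signature expression minus the mean control expression. Cycling cells are
called by thresholding a cell-cycle module score at its mean plus three
standard deviations. The ARS is the union of group-wise upregulated DEGs
(log2FC > 1, BH-adjusted p < 0.05) and genes assigned by fuzzy c-means to a
temporal cluster peaking early after transplantation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty-name gene set."""

    name: str
    genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))


def _values(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def normalize_expression(adata: ad.AnnData) -> ad.AnnData:
    """Library-size normalize raw counts to 10,000 per cell, then log(1+x).

    Raises if any cell has zero total counts (naming it) or if the matrix is
    already flagged as log-normalized.
    """
    if adata.uns.get("log_normalized", False):
        raise ValueError("matrix is already log-normalized; refusing to re-normalize")
    X = _values(adata)
    if np.any(X < 0):
        raise ValueError("raw counts must be nonnegative")
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts: {list(adata.obs_names[zero[:5]])}"
        )
    out = adata.copy()
    out.X = np.log1p(X * (1e4 / totals[:, None]))
    out.uns["log_normalized"] = True
    return out


def module_score(
    adata: ad.AnnData,
    signature: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    Genes are ranked by average expression across cells and cut into
    ``n_bins`` equal-frequency bins. For each signature gene, ``n_ctrl``
    control genes are sampled from the non-signature genes of its bin
    (without replacement when the pool is large enough, with replacement
    otherwise; an empty pool falls back to the nearest-ranked non-signature
    genes). Excluding the signature from its own control pool keeps the
    score an unbiased contrast even when the signature dominates a bin. The
    score is the mean expression of the signature genes minus the mean of
    the pooled controls.
    """
    if not adata.uns.get("log_normalized", False):
        raise ValueError("module_score expects a log-normalized matrix")
    genes = pd.Index(adata.var_names)
    present = [g for g in signature.genes if g in genes]
    missing = signature.genes - set(present)
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)} gene(s) absent from "
            "the matrix were dropped"
        )
    X = _values(adata)
    avg = pd.Series(X.mean(axis=0), index=genes)
    n_bins_eff = min(n_bins, len(genes))
    bins = pd.qcut(avg.rank(method="first"), n_bins_eff, labels=False)

    rng = np.random.default_rng(seed)
    sig_set = set(present)
    rank = avg.rank(method="first")
    ctrl: list[str] = []
    for g in sorted(present):
        pool = [m for m in genes[bins == bins[g]] if m not in sig_set]
        if not pool:  # bin fully occupied by the signature: nearest-ranked genes
            others = [m for m in genes if m not in sig_set]
            others.sort(key=lambda m: (abs(rank[m] - rank[g]), m))
            pool = others[:n_ctrl]
        replace = len(pool) < n_ctrl
        ctrl.extend(rng.choice(pool, size=n_ctrl, replace=replace))

    sig_mean = X[:, genes.get_indexer(present)].mean(axis=1)
    ctrl_mean = X[:, genes.get_indexer(ctrl)].mean(axis=1)
    return pd.Series(sig_mean - ctrl_mean, index=adata.obs_names, name=signature.name)


def classify_cycling(scores: pd.Series) -> pd.Series:
    """Flag cells whose score strictly exceeds mean + 3 sample standard deviations.

    With all-identical scores the threshold equals the mean and no cell is
    flagged.
    """
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 cells to estimate a threshold")
    threshold = scores.mean() + 3.0 * scores.std(ddof=1)
    return (scores > threshold).rename("cycling")


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration for small tie-free groups,
    normal approximation with tie correction (no continuity) otherwise."""
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    ties = len(np.unique(pooled)) < pooled.size
    if min(a.size, b.size) <= 10 and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.pvalue)


def rank_sum_de(adata: ad.AnnData, cells_a, cells_b) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two cell groups.

    log2FC reverses log1p before averaging and adds a pseudocount of 1;
    p-values are BH-adjusted across all tested genes; ``pct_a``/``pct_b``
    are the detection (> 0) fractions.
    """
    if not adata.uns.get("log_normalized", False):
        raise ValueError("rank_sum_de expects a log-normalized matrix")
    cells_a, cells_b = list(cells_a), list(cells_b)
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    if set(cells_a) & set(cells_b):
        raise ValueError("groups overlap")
    idx = pd.Index(adata.obs_names)
    A = _values(adata)[idx.get_indexer(cells_a), :]
    B = _values(adata)[idx.get_indexer(cells_b), :]

    pvals = np.array([_wilcoxon(A[:, j], B[:, j]) for j in range(A.shape[1])])
    lfc = np.log2(
        (np.expm1(A).mean(axis=0) + 1.0) / (np.expm1(B).mean(axis=0) + 1.0)
    )
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "log2_fc": lfc,
            "p_value": pvals,
            "adj_p": adj,
            "pct_a": (A > 0).mean(axis=0),
            "pct_b": (B > 0).mean(axis=0),
        }
    ).set_index("gene")


def _fuzzy_cmeans(
    X: np.ndarray, k: int, m: float, rng: np.random.Generator,
    tol: float = 1e-6, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray]:
    """Classic fuzzy c-means (Euclidean, fuzzifier m) on rows of X."""
    n = X.shape[0]
    u = rng.dirichlet(np.ones(k), size=n)  # n x k memberships
    for _ in range(max_iter):
        um = u ** m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        d = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
        zero = d < 1e-12
        u_new = np.empty_like(u)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-2.0 / (m - 1.0))
            u_new = inv / inv.sum(axis=1)[:, None]
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u_new[rows_zero] = 0.0
            u_new[rows_zero, np.argmax(zero[rows_zero], axis=1)] = 1.0
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    um = u ** m
    centroids = (um.T @ X) / um.sum(axis=0)[:, None]
    return centroids, u


def temporal_up_genes(
    sample_profiles: pd.DataFrame,
    k: int = 4,
    m: float = 2.0,
    seed: int = 0,
    baseline: str = "R0_0W",
    early: tuple = ("R1_1W", "R1_3W"),
    late: str = "R1_12W",
) -> GeneSignature:
    """Genes assigned to an early-upregulated temporal cluster.

    Each gene's timepoint profile is z-scored, clustered by seeded fuzzy
    c-means, and a cluster counts as transplant-upregulated iff its centroid
    at both early timepoints exceeds its centroids at the baseline and at
    the late timepoint. Genes whose maximal membership falls in such a
    cluster are returned. Constant profiles are dropped with a warning.
    """
    if sample_profiles.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    if k < 1:
        raise ValueError("k must be >= 1")
    for col in (baseline, *early, late):
        if col not in sample_profiles.columns:
            raise ValueError(f"timepoint {col!r} missing from profiles")
    X = sample_profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} constant profile(s) dropped before z-scoring"
        )
    if not keep.any():
        return GeneSignature("temporal_up", frozenset())
    names = sample_profiles.index[keep]
    Z = (X[keep] - X[keep].mean(axis=1)[:, None]) / sd[keep][:, None]

    rng = np.random.default_rng(seed)
    centroids, u = _fuzzy_cmeans(Z, k, m, rng)

    cols = pd.Index(sample_profiles.columns)
    i_base, i_late = cols.get_loc(baseline), cols.get_loc(late)
    i_early = [cols.get_loc(e) for e in early]
    up = np.array(
        [
            all(c[i] > c[i_base] and c[i] > c[i_late] for i in i_early)
            for c in centroids
        ]
    )
    assign = np.argmax(u, axis=1)
    genes = frozenset(names[up[assign]])
    return GeneSignature("temporal_up", genes)


def derive_ars(
    de: pd.DataFrame,
    temporal: GeneSignature,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> GeneSignature:
    """ARS = upregulated DEGs (log2FC > lfc_min, adj_p < alpha, strict) ∪
    temporally upregulated genes."""
    degs = frozenset(de.index[(de["log2_fc"] > lfc_min) & (de["adj_p"] < alpha)])
    genes = degs | temporal.genes
    if not genes:
        warnings.warn("ARS is empty under the given thresholds")
    return GeneSignature("ARS", genes)
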
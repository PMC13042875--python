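"""Weighted co-expression network math: soft-threshold adjacency,
topological overlap (TOM), module eigengene / kME, and anchor-centric
sub-network extraction.

The network is unsigned: a_ij = |cor(g_i, g_j)|^beta with zero diagonal.
TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
TOM_ii = 1, so "directly connected to the anchor" filters use off-diagonal
entries. The module eigengene is the first principal component over cells
of the z-scored module submatrix, sign-oriented so its average correlation
with the module genes is nonnegative; kME(g) is the Pearson correlation of
gene g with the eigengene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd


@dataclass
class NetworkModule:
    """A co-expression module with eigengene, kME and TOM edge weights."""

    name: str
    genes: list
    eigengene: pd.Series | None = None
    kme: pd.Series | None = None
    tom_edges: pd.DataFrame | None = field(default=None, repr=False)
    anchor: str | None = None
    anchor_rank: int | None = None
    top_genes: list | None = None


def _dense(adata: ad.AnnData, genes) -> np.ndarray:
    X = adata[:, list(genes)].X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    return X.astype(float)


def soft_adjacency(adata: ad.AnnData, genes, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |Pearson cor|^beta, zero diagonal.

    Zero-variance genes are dropped with a warning; fewer than two
    surviving genes is an error.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing}")
    if adata.n_obs < 3:
        raise ValueError("need at least 3 cells")
    X = _dense(adata, genes)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"zero-variance gene(s) dropped: {[g for g, k in zip(genes, keep) if not k]}"
        )
    genes = [g for g, k in zip(genes, keep) if k]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    corr = np.corrcoef(X[:, keep], rowvar=False)
    A = np.abs(corr) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=genes, columns=genes)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric zero-diagonal adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity sum_u a_iu; TOM_ii = 1.
    """
    A = adjacency.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(A - A.T)) > 1e-9:
        raise ValueError("adjacency is not symmetric")
    if np.any((A < 0) | (A > 1)):
        raise ValueError("adjacency values must lie in [0, 1]")
    if np.max(np.abs(np.diag(A))) > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=1)
    shared = A @ A  # diagonal of A is zero, so u = i, j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def module_eigengene_kme(
    adata: ad.AnnData, module_genes
) -> tuple[pd.Series, pd.Series]:
    """Module eigengene (unit-norm, over cells) and kME for every gene.

    Zero-variance module genes are dropped; the eigengene sign is oriented
    so its average correlation with the module genes is nonnegative.
    """
    module_genes = [g for g in module_genes if g in adata.var_names]
    if len(module_genes) < 2:
        raise ValueError("need at least 2 module genes present in the matrix")
    M = _dense(adata, module_genes)
    sd = M.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"zero-variance module gene(s) dropped: "
            f"{[g for g, k in zip(module_genes, keep) if not k]}"
        )
    if not keep.any():
        raise ValueError("all module genes have zero variance")
    M = M[:, keep]
    Z = (M - M.mean(axis=0)) / M.std(axis=0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigengene = U[:, 0]
    # orient: average correlation with module genes >= 0
    corrs = np.array([np.corrcoef(eigengene, Z[:, j])[0, 1] for j in range(Z.shape[1])])
    if corrs.mean() < 0:
        eigengene = -eigengene
    eigengene = eigengene / np.linalg.norm(eigengene)
    eig = pd.Series(eigengene, index=adata.obs_names, name="eigengene")

    X = _dense(adata, adata.var_names)
    sd_all = X.std(axis=0)
    centered = X - X.mean(axis=0)
    e_c = eigengene - eigengene.mean()
    denom = np.linalg.norm(e_c) * np.linalg.norm(centered, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kme = np.where(denom > 0, centered.T @ e_c / np.where(denom > 0, denom, 1.0), 0.0)
    return eig, pd.Series(kme, index=adata.var_names, name="kme")


def extract_anchor_subnetwork(
    module: NetworkModule,
    anchor: str,
    kme_min: float = 0.25,
    tom_min: float = 0.025,
    top_n: int = 10,
) -> NetworkModule:
    """Anchor-centric sub-network: keep module genes with kME strictly above
    ``kme_min`` AND TOM weight to the anchor strictly above ``tom_min``.

    The anchor is always retained; its kME rank among module genes
    (descending kME, lexicographic tie-break) is reported, and the top
    ``top_n`` genes by kME are flagged for display.
    """
    if anchor not in module.genes:
        raise ValueError(f"anchor {anchor!r} is not in the module")
    if module.kme is None or module.tom_edges is None:
        raise ValueError("module must carry kme and tom_edges")
    kme = module.kme
    tom = module.tom_edges

    ranking = sorted(module.genes, key=lambda g: (-kme.get(g, -np.inf), g))
    anchor_rank = ranking.index(anchor) + 1

    kept = [
        g
        for g in module.genes
        if g == anchor
        or (
            kme.get(g, -np.inf) > kme_min
            and g in tom.columns
            and anchor in tom.index
            and tom.loc[anchor, g] > tom_min
        )
    ]
    kept_sorted = sorted(kept, key=lambda g: (-kme.get(g, -np.inf), g))
    sub_tom = tom.loc[
        [g for g in kept_sorted if g in tom.index],
        [g for g in kept_sorted if g in tom.columns],
    ]
    return NetworkModule(
        name=f"{module.name}:{anchor}",
        genes=kept_sorted,
        eigengene=module.eigengene,
        kme=kme[kme.index.isin(kept_sorted)],
        tom_edges=sub_tom,
        anchor=anchor,
        anchor_rank=anchor_rank,
        top_genes=kept_sorted[:top_n],
    )
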
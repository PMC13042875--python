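"""Text-format IO: Matrix Market expression bundles, GMT signatures,
TSV tables, and zonation model serialization (JSON + xgboost JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import io as spio
from scipy import sparse
from sklearn.cross_decomposition import PLSRegression

from .scoring import GeneSignature
from .zonation import ZonationModel

_CELL_META_COLS = ("sample", "group", "timepoint", "layer")


def write_expression(adata: ad.AnnData, outdir) -> None:
    """Write an expression bundle: matrix.mtx (genes x cells), genes.tsv,
    cells.tsv with sample/group/timepoint (and layer when present)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sparse.csr_matrix(X.T if not sparse.issparse(X) else X.T)
    spio.mmwrite(outdir / "matrix.mtx", mat)
    pd.Series(adata.var_names, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    meta = pd.DataFrame({"cell_id": adata.obs_names})
    for col in _CELL_META_COLS:
        if col in adata.obs:
            meta[col] = adata.obs[col].to_numpy()
    meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    (outdir / "flags.json").write_text(
        json.dumps({"log_normalized": bool(adata.uns.get("log_normalized", False))})
    )


def read_expression(indir) -> ad.AnnData:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").tocsr().T  # back to cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].astype(str)
    meta = pd.read_csv(indir / "cells.tsv", sep="\t").set_index("cell_id")
    meta.index = meta.index.astype(str)
    adata = ad.AnnData(
        X=np.asarray(mat.todense(), dtype=float),
        obs=meta,
        var=pd.DataFrame(index=genes),
    )
    flags = indir / "flags.json"
    adata.uns["log_normalized"] = (
        json.loads(flags.read_text()).get("log_normalized", False)
        if flags.exists()
        else False
    )
    return adata


def read_gmt(path) -> list:
    """Read signatures from a GMT file (name, description, genes...)."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sigs.append(GeneSignature(parts[0], frozenset(parts[2:])))
    return sigs


def write_gmt(signatures, path) -> None:
    lines = [
        "\t".join([s.name, "hepregen"] + sorted(s.genes)) for s in signatures
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Series x samples TSV, columns in timecourse order."""
    profiles.to_csv(path, sep="\t", index_label="name")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="name")


def save_zonation_model(model: ZonationModel, outdir) -> None:
    """Serialize a zonation model to a versioned all-text bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "kind": model.kind,
        "features": list(model.features),
        "cv_auc": model.cv_auc,
    }
    if model.kind == "plsr":
        p = model.params
        pls: PLSRegression = p["pls"]
        meta["plsr"] = {
            "mu": p["mu"].tolist(),
            "sd": p["sd"].tolist(),
            "y_mean": p["y_mean"],
            "coef": np.asarray(pls.coef_).tolist(),
            "x_mean": pls._x_mean.tolist(),
            "intercept": np.asarray(pls.intercept_).tolist(),
        }
    elif model.kind == "classifier":
        model.params["clf"].get_booster().save_model(str(outdir / "booster.json"))
    else:
        raise ValueError(f"unknown model kind {model.kind!r}")
    (outdir / "model.json").write_text(json.dumps(meta, indent=1))
    if model.training_summary is not None:
        model.training_summary.to_csv(outdir / "cv_summary.tsv", sep="\t", index=False)


class _LinearPLSR:
    """Prediction-only stand-in for a deserialized PLSR fit."""

    def __init__(self, coef, x_mean, intercept):
        self.coef_ = np.asarray(coef)
        self._x_mean = np.asarray(x_mean)
        self.intercept_ = np.asarray(intercept)

    def predict(self, X):
        return (X - self._x_mean) @ self.coef_.T + self.intercept_


def load_zonation_model(indir) -> ZonationModel:
    indir = Path(indir)
    meta = json.loads((indir / "model.json").read_text())
    summary = None
    cv_path = indir / "cv_summary.tsv"
    if cv_path.exists():
        summary = pd.read_csv(cv_path, sep="\t")
    if meta["kind"] == "plsr":
        p = meta["plsr"]
        params = {
            "mu": np.asarray(p["mu"]),
            "sd": np.asarray(p["sd"]),
            "y_mean": p["y_mean"],
            "pls": _LinearPLSR(p["coef"], p["x_mean"], p["intercept"]),
        }
    else:
        clf = xgb.XGBClassifier()
        clf.load_model(str(indir / "booster.json"))
        params = {"clf": clf}
    return ZonationModel(
        kind=meta["kind"],
        features=meta["features"],
        params=params,
        cv_auc=meta.get("cv_auc"),
        training_summary=summary,
    )
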
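"""Hepatocyte zonation: PLSR coordinate, attribution-based marker selection,
eight-layer gradient-boosted classifier, and zone-proportion time series.

Layers follow the convention that layer 1 is pericentral and layer 8
periportal; for comparison with zonation staining, layers are grouped as
L1-L3 = Zone3 (central vein), L4-L6 = Zone2, L7-L8 = Zone1 (periportal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .simulate import LayeredReference

#: Deterministic grouping of lobule layers into staining-comparable zones.
ZONE_OF_LAYER = {1: "Zone3", 2: "Zone3", 3: "Zone3",
                 4: "Zone2", 5: "Zone2", 6: "Zone2",
                 7: "Zone1", 8: "Zone1"}

LAYERS = tuple(range(1, 9))

_XGB_DEFAULTS = dict(
    n_estimators=150,
    max_depth=3,
    learning_rate=0.2,
    tree_method="hist",
    n_jobs=1,
    eval_metric="mlogloss",
)


@dataclass
class ZonationModel:
    """A fitted zonation model (PLSR coordinate or 8-layer classifier)."""

    kind: str  # "plsr" | "classifier"
    features: list
    params: dict = field(default_factory=dict, repr=False)
    cv_auc: float | None = None
    training_summary: pd.DataFrame | None = None


@dataclass
class ZoneAssignment:
    """Per-cell predicted layer, zone, and class probabilities."""

    layer: pd.Series
    zone: pd.Series
    probabilities: pd.DataFrame  # cells x L1..L8, rows sum to 1


def layer_to_zone(layer: int) -> str:
    return ZONE_OF_LAYER[int(layer)]


def _matrix(adata: ad.AnnData, features) -> np.ndarray:
    missing = [f for f in features if f not in adata.var_names]
    if missing:
        raise ValueError(f"features absent from the matrix: {missing}")
    X = adata[:, list(features)].X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    return X.astype(float)


def fit_plsr_zonation(
    ref: LayeredReference, markers, n_components: int = 2
) -> ZonationModel:
    """Fit the PLSR zonation coordinate on a layered reference.

    Predictors are z-scored marker expression; the response is the centered
    layer index; the model is fitted by NIPALS to ``n_components`` latent
    components. Zero-variance markers are dropped with a warning.
    """
    markers = list(markers)
    adata = ref.expression
    X = _matrix(adata, markers)
    y = ref.layer.to_numpy(dtype=float)
    if set(np.unique(y)) != set(LAYERS):
        warnings.warn("reference does not span all 8 layers")

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"zero-variance marker(s) dropped: {[m for m, k in zip(markers, keep) if not k]}"
        )
    if not keep.any():
        raise ValueError("all markers have zero variance")
    markers = [m for m, k in zip(markers, keep) if k]
    X, sd = X[:, keep], sd[keep]
    mu = X.mean(axis=0)
    Z = (X - mu) / sd

    y_mean = y.mean()
    pls = PLSRegression(n_components=min(n_components, len(markers)), scale=False)
    pls.fit(Z, y - y_mean)
    return ZonationModel(
        kind="plsr",
        features=markers,
        params={"mu": mu, "sd": sd, "y_mean": y_mean, "pls": pls},
    )


def zonation_scores(
    model: ZonationModel, adata: ad.AnnData
) -> tuple[pd.Series, pd.Series]:
    """Per-cell zonation coordinate (clamped to [1, 8]) and per-sample
    dispersion (sample sd of coordinates; NaN for samples with < 2 cells)."""
    if model.kind != "plsr":
        raise ValueError("zonation_scores requires a PLSR model")
    p = model.params
    Z = (_matrix(adata, model.features) - p["mu"]) / p["sd"]
    coord = p["pls"].predict(Z).ravel() + p["y_mean"]
    coord = np.clip(coord, 1.0, 8.0)
    scores = pd.Series(coord, index=adata.obs_names, name="zonation_score")
    samples = adata.obs["sample"] if "sample" in adata.obs else pd.Series(
        "all", index=adata.obs_names
    )
    dispersion = scores.groupby(samples, observed=True).agg(
        lambda s: s.std(ddof=1) if len(s) > 1 else np.nan
    )
    return scores, dispersion.rename("dispersion")


def _fit_xgb(X: np.ndarray, y: np.ndarray, seed: int, weights=None) -> xgb.XGBClassifier:
    clf = xgb.XGBClassifier(random_state=seed, **_XGB_DEFAULTS)
    clf.fit(X, y, sample_weight=weights)
    return clf


def select_marker_features(
    ref: LayeredReference, candidates, k: int = 4, seed: int = 0
) -> list:
    """Rank candidate markers by mean absolute additive attribution.

    A preliminary multiclass gradient-boosted classifier is fitted on all
    candidates and per-feature tree-based additive attributions (SHAP-style
    contributions) are averaged over cells and classes; the top-k genes are
    returned, ties broken lexicographically.
    """
    candidates = list(candidates)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidates")
    adata = ref.expression
    y = ref.layer.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training is degenerate: a single layer is present")
    X = _matrix(adata, candidates)
    clf = _fit_xgb(X, y - 1, seed)
    contribs = clf.get_booster().predict(
        xgb.DMatrix(X, feature_names=candidates), pred_contribs=True
    )
    # multiclass: (n_cells, n_classes, n_features + bias)
    attr = np.abs(contribs[..., :-1]).mean(axis=tuple(range(contribs.ndim - 1)))
    order = sorted(zip(candidates, attr), key=lambda t: (-t[1], t[0]))
    return [g for g, _ in order[:k]]


def train_layer_classifier(
    ref: LayeredReference, features, n_folds: int = 5, seed: int = 0
) -> ZonationModel:
    """Train the eight-layer classifier with stratified cross-validation.

    Per-class sample weights w_c = N / (8 N_c) counter class imbalance;
    cv_auc is the mean over folds of the macro one-vs-rest multiclass AUC;
    the final model is refit on all cells. Cells are sorted by identifier
    before splitting so the metric is invariant to input order.
    """
    features = list(features)
    adata = ref.expression
    order = np.argsort(adata.obs_names)
    X = _matrix(adata, features)[order]
    y = ref.layer.to_numpy(dtype=int)[order]
    classes, counts = np.unique(y, return_counts=True)
    if set(classes) != set(LAYERS):
        raise ValueError(f"training data must contain all 8 layers; found {list(classes)}")
    if counts.min() < n_folds:
        raise ValueError("each layer needs at least n_folds cells")

    n = y.size
    w_of_class = {c: n / (len(classes) * m) for c, m in zip(classes, counts)}
    weights = np.array([w_of_class[c] for c in y])

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf = _fit_xgb(X[tr], y[tr] - 1, seed, weights[tr])
        proba = clf.predict_proba(X[te])
        aucs.append(
            roc_auc_score(
                y[te] - 1, proba, multi_class="ovr", average="macro",
                labels=np.arange(8),
            )
        )
    final = _fit_xgb(X, y - 1, seed, weights)
    summary = pd.DataFrame({"fold": np.arange(1, n_folds + 1), "macro_ovr_auc": aucs})
    return ZonationModel(
        kind="classifier",
        features=features,
        params={"clf": final},
        cv_auc=float(np.mean(aucs)),
        training_summary=summary,
    )


def predict_layers_and_zones(model: ZonationModel, adata: ad.AnnData) -> ZoneAssignment:
    """Predict per-cell layers (argmax probability, ties to the lowest layer)
    and group them into zones."""
    if model.kind != "classifier":
        raise ValueError("predict_layers_and_zones requires a classifier model")
    X = _matrix(adata, model.features)
    proba = model.params["clf"].predict_proba(X)
    layer = proba.argmax(axis=1) + 1  # np.argmax takes the first (lowest) maximum
    layers = pd.Series(layer, index=adata.obs_names, name="layer")
    zones = layers.map(ZONE_OF_LAYER).rename("zone")
    probs = pd.DataFrame(
        proba, index=adata.obs_names, columns=[f"L{i}" for i in LAYERS]
    )
    return ZoneAssignment(layer=layers, zone=zones, probabilities=probs)


def zone_proportion_series(assignments: dict, sample_order) -> pd.DataFrame:
    """Per-sample zone proportions as three ordered series.

    ``assignments`` maps sample name to a per-cell zone label sequence; the
    result has rows Zone1/Zone2/Zone3 and one column per sample in
    ``sample_order``. A zone absent from a sample gets proportion 0.
    """
    sample_order = list(sample_order)
    unknown = [s for s in sample_order if s not in assignments]
    if unknown:
        raise ValueError(f"unknown sample(s) in order list: {unknown}")
    out = pd.DataFrame(
        0.0, index=["Zone1", "Zone2", "Zone3"], columns=sample_order
    )
    for s in sample_order:
        zones = pd.Series(list(assignments[s]))
        if zones.empty:
            raise ValueError(f"sample {s!r} has no assigned cells")
        frac = zones.value_counts(normalize=True)
        for z in out.index:
            out.loc[z, s] = frac.get(z, 0.0)
    return out
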
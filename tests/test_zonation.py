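"""PLSR coordinate, feature attribution, layer classifier, zone grouping."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

import hepregen as hg
from hepregen import scoring as sc
from hepregen import zonation as zon


@pytest.fixture(scope="module")
def noiseless_ref():
    ref = hg.simulate_zonated_reference(
        hg.SimConfig(seed=1, n_cells_per_layer=150, noise_sd=0.0)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = sc.normalize_expression(ref.expression)
    return hg.LayeredReference(norm, ref.marker_truth, ref.candidate_markers)


class TestPLSR:
    def test_recovers_planted_layer_order(self, noiseless_ref):
        model = zon.fit_plsr_zonation(noiseless_ref, noiseless_ref.candidate_markers)
        coords, _ = zon.zonation_scores(model, noiseless_ref.expression)
        rho = spearmanr(coords, noiseless_ref.layer)[0]
        assert rho >= 0.99

    def test_single_component_suffices_on_rank_one_signal(self, noiseless_ref):
        m1 = zon.fit_plsr_zonation(noiseless_ref, list(hg.simulate.STRONG_MARKER_TRUTH), 1)
        m2 = zon.fit_plsr_zonation(noiseless_ref, list(hg.simulate.STRONG_MARKER_TRUTH), 2)
        c1, _ = zon.zonation_scores(m1, noiseless_ref.expression)
        c2, _ = zon.zonation_scores(m2, noiseless_ref.expression)
        assert spearmanr(c1, c2)[0] > 0.999

    def test_permuted_labels_destroy_signal(self, noiseless_ref):
        # train on permuted labels, evaluate on held-out cells: predictions
        # and held-out permuted labels are independent, so rho ~ 0
        rng = np.random.default_rng(0)
        adata = noiseless_ref.expression.copy()
        perm_layer = rng.permutation(noiseless_ref.layer.to_numpy())
        adata.obs["layer"] = perm_layer
        half = adata.n_obs // 2
        idx = rng.permutation(adata.n_obs)
        train, test = adata[idx[:half]].copy(), adata[idx[half:]].copy()
        model = zon.fit_plsr_zonation(
            hg.LayeredReference(train, {}, []), noiseless_ref.candidate_markers
        )
        coords, _ = zon.zonation_scores(model, test)
        assert abs(spearmanr(coords, test.obs["layer"])[0]) < 0.1

    def test_missing_marker_listed(self, noiseless_ref):
        with pytest.raises(ValueError, match="Nope"):
            zon.fit_plsr_zonation(noiseless_ref, ["Glul", "Nope"])

    def test_rescaled_predictor_invariance(self, noiseless_ref):
        markers = list(hg.simulate.STRONG_MARKER_TRUTH)
        base = zon.fit_plsr_zonation(noiseless_ref, markers)
        c_base, _ = zon.zonation_scores(base, noiseless_ref.expression)
        scaled = noiseless_ref.expression.copy()
        j = list(scaled.var_names).index("Glul")
        scaled.X[:, j] = scaled.X[:, j] * 10.0 + 5.0
        ref2 = hg.LayeredReference(scaled, {}, [])
        m2 = zon.fit_plsr_zonation(ref2, markers)
        c2, _ = zon.zonation_scores(m2, scaled)
        np.testing.assert_allclose(c_base, c2, atol=1e-8)


class TestZonationScores:
    def test_dispersion_reflects_layer_spread(self, noiseless_ref):
        model = zon.fit_plsr_zonation(noiseless_ref, noiseless_ref.candidate_markers)
        adata = noiseless_ref.expression.copy()
        wide = adata.obs_names[adata.obs["layer"].isin(range(1, 9))][:400]
        narrow = adata.obs_names[adata.obs["layer"].isin([4, 5])][:200]
        adata.obs["sample"] = "other"
        adata.obs.loc[wide, "sample"] = "wide"
        adata.obs.loc[narrow, "sample"] = "narrow"
        _, disp = zon.zonation_scores(model, adata)
        assert disp["wide"] > disp["narrow"]

    def test_coordinates_clamped_to_layer_range(self, noiseless_ref):
        model = zon.fit_plsr_zonation(noiseless_ref, noiseless_ref.candidate_markers)
        extreme = noiseless_ref.expression.copy()
        extreme.X = extreme.X * 3.0  # push predictions beyond the training range
        coords, _ = zon.zonation_scores(model, extreme)
        assert coords.max() <= 8.0 and coords.min() >= 1.0

    def test_small_sample_dispersion_missing(self, noiseless_ref):
        model = zon.fit_plsr_zonation(noiseless_ref, noiseless_ref.candidate_markers)
        adata = noiseless_ref.expression[:3].copy()
        adata.obs["sample"] = ["solo", "pair", "pair"]
        _, disp = zon.zonation_scores(model, adata)
        assert np.isnan(disp["solo"]) and np.isfinite(disp["pair"])


class TestFeatureSelection:
    def test_recovers_planted_informative_markers(self, reference_norm):
        feats = zon.select_marker_features(
            reference_norm, reference_norm.candidate_markers, k=4, seed=0
        )
        assert set(feats) == {"Cyp2f2", "Cyp2e1", "Glul", "Ass1"}

    def test_k_equals_all_returns_everything(self, reference_norm):
        feats = zon.select_marker_features(
            reference_norm, reference_norm.candidate_markers, k=18, seed=0
        )
        assert set(feats) == set(reference_norm.candidate_markers)

    def test_seed_stability(self, reference_norm):
        a = zon.select_marker_features(reference_norm, reference_norm.candidate_markers, 4, seed=0)
        b = zon.select_marker_features(reference_norm, reference_norm.candidate_markers, 4, seed=123)
        assert set(a) == set(b)

    def test_single_layer_training_rejected(self, reference_norm):
        sub = reference_norm.expression[reference_norm.layer == 3].copy()
        ref = hg.LayeredReference(sub, {}, [])
        with pytest.raises(ValueError, match="single layer"):
            zon.select_marker_features(ref, reference_norm.candidate_markers, 4)


class TestLayerClassifier:
    FEATURES = ["Cyp2f2", "Cyp2e1", "Glul", "Ass1"]

    def test_cv_auc_on_planted_gradients(self, reference_norm):
        model = zon.train_layer_classifier(reference_norm, self.FEATURES, seed=0)
        assert model.cv_auc >= 0.95
        assert len(model.training_summary) == 5

    def test_shuffled_labels_score_at_chance(self, reference_norm):
        rng = np.random.default_rng(0)
        shuffled = reference_norm.expression.copy()
        shuffled.obs["layer"] = rng.permutation(reference_norm.layer.to_numpy())
        model = zon.train_layer_classifier(
            hg.LayeredReference(shuffled, {}, []), self.FEATURES, seed=0
        )
        assert abs(model.cv_auc - 0.5) < 0.05

    def test_cv_auc_invariant_to_cell_order(self, reference_norm):
        model_a = zon.train_layer_classifier(reference_norm, self.FEATURES, seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(reference_norm.expression.n_obs)
        shuffled = reference_norm.expression[perm].copy()
        model_b = zon.train_layer_classifier(
            hg.LayeredReference(shuffled, {}, []), self.FEATURES, seed=0
        )
        assert model_a.cv_auc == pytest.approx(model_b.cv_auc, abs=1e-12)

    def test_cv_auc_degrades_with_noise(self):
        aucs = []
        for noise in (0.2, 0.6, 1.2):
            ref = hg.simulate_zonated_reference(
                hg.SimConfig(seed=3, n_cells_per_layer=80, noise_sd=noise)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                norm = sc.normalize_expression(ref.expression)
            model = zon.train_layer_classifier(
                hg.LayeredReference(norm, {}, []), self.FEATURES, seed=0
            )
            aucs.append(model.cv_auc)
        assert aucs[0] > aucs[1] > aucs[2]

    def test_missing_layer_rejected(self, reference_norm):
        sub = reference_norm.expression[reference_norm.layer != 5].copy()
        with pytest.raises(ValueError, match="8 layers"):
            zon.train_layer_classifier(hg.LayeredReference(sub, {}, []), self.FEATURES)


class TestZoneGrouping:
    def test_grouping_map_is_total_and_exact(self):
        expected = {1: "Zone3", 2: "Zone3", 3: "Zone3",
                    4: "Zone2", 5: "Zone2", 6: "Zone2",
                    7: "Zone1", 8: "Zone1"}
        for layer, zone in expected.items():
            assert zon.layer_to_zone(layer) == zone

    def test_argmax_tie_breaks_to_lowest_layer(self, reference_norm):
        class TieClassifier:
            def predict_proba(self, X):
                p = np.zeros((len(X), 8))
                p[:, 2] = p[:, 3] = 0.5  # tie between layers 3 and 4
                return p

        model = zon.ZonationModel(
            kind="classifier", features=self.FEATURES if hasattr(self, "FEATURES") else
            ["Cyp2f2", "Cyp2e1", "Glul", "Ass1"],
            params={"clf": TieClassifier()},
        )
        assign = zon.predict_layers_and_zones(model, reference_norm.expression[:5])
        assert (assign.layer == 3).all()
        assert (assign.zone == "Zone3").all()

    def test_prediction_round_trip_on_reference(self, reference_norm):
        feats = ["Cyp2f2", "Cyp2e1", "Glul", "Ass1"]
        model = zon.train_layer_classifier(reference_norm, feats, seed=0)
        assign = zon.predict_layers_and_zones(model, reference_norm.expression)
        np.testing.assert_allclose(assign.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert (assign.zone == assign.layer.map(zon.ZONE_OF_LAYER)).all()
        true_zone = reference_norm.layer.map(zon.ZONE_OF_LAYER)
        assert (assign.zone.to_numpy() == true_zone.to_numpy()).mean() > 0.9


class TestZoneProportions:
    def test_single_zone_sample(self):
        out = zon.zone_proportion_series({"s": ["Zone1"] * 10}, ["s"])
        assert out["s"].tolist() == [1.0, 0.0, 0.0]

    def test_proportion_arithmetic(self):
        zones = ["Zone1"] * 2 + ["Zone2"] * 3 + ["Zone3"] * 5
        out = zon.zone_proportion_series({"s": zones}, ["s"])
        assert out["s"].tolist() == [0.2, 0.3, 0.5]
        assert out["s"].sum() == pytest.approx(1.0)

    def test_order_preserved_and_unknown_sample_rejected(self):
        assignments = {"a": ["Zone1"], "b": ["Zone2"], "c": ["Zone3"]}
        out = zon.zone_proportion_series(assignments, ["c", "a", "b"])
        assert list(out.columns) == ["c", "a", "b"]
        with pytest.raises(ValueError, match="unknown"):
            zon.zone_proportion_series(assignments, ["a", "zzz"])
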
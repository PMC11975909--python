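"""Phenotype classifier tests: splits, balanced weighting, kNN baseline,
boosted-tree final model, whole-dataset binning, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen import phenosorter as psrt
from phenoscreen import quantification as quant
from phenoscreen import synthetic as syn
from conftest import make_layout_row


def _gaussian_set(n_per_class=200, sep=4.0, sd=0.5, seed=0, d=5,
                  weights=None) -> psrt.LabeledSet:
    rng = np.random.default_rng(seed)
    sizes = weights or [n_per_class, n_per_class]
    xs, ys = [], []
    for i, n in enumerate(sizes):
        mu = np.zeros(d)
        mu[0] = i * sep
        xs.append(rng.normal(mu, sd, size=(n, d)))
        ys.append([f"c{i}"] * n)
    x = np.vstack(xs)
    y = np.concatenate(ys)
    return psrt.LabeledSet(np.arange(len(y)), x, y)


class TestSplit:
    def test_80_20_counts(self):
        data = _gaussian_set(50)
        tr, te = psrt.split(data, psrt.SplitSpec(seed=1))
        assert len(tr) == 80 and len(te) == 20

    def test_stratified_split_preserves_proportions(self):
        data = _gaussian_set(seed=2, weights=[90, 10])
        tr, te = psrt.split(data, psrt.SplitSpec(seed=0, stratified=True))
        te_counts = pd.Series(te.labels).value_counts()
        assert te_counts["c0"] == 18 and te_counts["c1"] == 2

    def test_same_seed_identical_partition(self):
        data = _gaussian_set(30)
        tr1, te1 = psrt.split(data, psrt.SplitSpec(seed=7))
        tr2, te2 = psrt.split(data, psrt.SplitSpec(seed=7))
        np.testing.assert_array_equal(tr1.cell_ids, tr2.cell_ids)
        np.testing.assert_array_equal(te1.cell_ids, te2.cell_ids)

    def test_disjoint_and_exhaustive(self):
        data = _gaussian_set(33)
        tr, te = psrt.split(data, psrt.SplitSpec(seed=3))
        ids_tr, ids_te = set(tr.cell_ids), set(te.cell_ids)
        assert not ids_tr & ids_te
        assert ids_tr | ids_te == set(data.cell_ids)

    def test_singleton_class_rejected_under_stratification(self):
        data = _gaussian_set(seed=4, weights=[10, 1])
        with pytest.raises(ValueError, match="stratified"):
            psrt.split(data, psrt.SplitSpec(stratified=True))


class TestBaselineKNN:
    def test_k1_returns_training_label_for_training_point(self):
        data = _gaussian_set(20, seed=5)
        model = psrt.train_baseline(data, k=1)
        pred = model.predict(data.embeddings[:5])
        np.testing.assert_array_equal(pred, data.labels[:5])

    def test_separated_gaussians_high_heldout_accuracy(self):
        data = _gaussian_set(200, sep=4.0, sd=0.5, seed=6)
        tr, te = psrt.split(data, psrt.SplitSpec(seed=0))
        model = psrt.train_baseline(tr, k=15)
        m = psrt.evaluate(model, te)
        assert m["balanced_accuracy"] >= 0.95

    def test_balanced_weighting_lifts_minority_recall(self):
        # 10:1 imbalance with overlapping classes
        data = _gaussian_set(seed=7, weights=[400, 40], sep=1.5, sd=1.0)
        tr, te = psrt.split(data, psrt.SplitSpec(seed=0))
        rec = {}
        for balanced in (True, False):
            model = psrt.train_baseline(tr, k=15, balanced=balanced)
            m = psrt.evaluate(model, te)
            rec[balanced] = m["per_class"]["c1"]["recall"]
        assert rec[True] > rec[False]

    def test_expected_class_weight_mass_equal_across_classes(self):
        data = _gaussian_set(seed=8, weights=[300, 60])
        model = psrt.train_baseline(data, k=5)
        counts = pd.Series(data.labels).value_counts()
        masses = {c: model.class_weights[c] * counts[c] for c in model.classes}
        assert masses["c0"] == pytest.approx(masses["c1"])

    def test_invalid_k_rejected(self):
        data = _gaussian_set(10)
        with pytest.raises(ValueError):
            psrt.train_baseline(data, k=0)
        with pytest.raises(ValueError):
            psrt.train_baseline(data, k=100)


class TestFinalModel:
    def test_boosted_trees_at_least_match_baseline(self):
        data = _gaussian_set(200, sep=4.0, sd=0.5, seed=9)
        tr, te = psrt.split(data, psrt.SplitSpec(seed=0))
        base = psrt.evaluate(psrt.train_baseline(tr, k=15), te)
        final = psrt.evaluate(psrt.train_final(tr, seed=0), te)
        assert final["balanced_accuracy"] >= base["balanced_accuracy"] - 1e-9

    def test_pure_noise_labels_score_at_chance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, size=(400, 6))
        y = rng.choice(["a", "b"], size=400)
        data = psrt.LabeledSet(np.arange(400), x, y)
        tr, te = psrt.split(data, psrt.SplitSpec(seed=0))
        m = psrt.evaluate(psrt.train_final(tr, seed=0), te)
        # chance level 0.5; binomial 99.9% band at n_test = 80
        assert abs(m["balanced_accuracy"] - 0.5) < 0.2

    def test_same_seed_identical_predictions(self):
        data = _gaussian_set(100, seed=11)
        tr, _ = psrt.split(data, psrt.SplitSpec(seed=0))
        p1 = psrt.train_final(tr, seed=3).predict(data.embeddings)
        p2 = psrt.train_final(tr, seed=3).predict(data.embeddings)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_degenerates_to_constant_with_warning(self):
        data = _gaussian_set(20, seed=12, weights=[20])
        with pytest.warns(UserWarning, match="single-class"):
            model = psrt.train_final(data)
        pred = model.predict(np.zeros((3, 5)))
        assert list(pred) == ["c0"] * 3


class TestClassifyAll:
    def test_training_points_recovered_in_separable_case(self):
        data = _gaussian_set(100, sep=5.0, sd=0.3, seed=13)
        model = psrt.train_final(data, seed=0)
        pred = psrt.classify_all(model, data.embeddings)
        assert (pred == data.labels).mean() > 0.999

    def test_empty_input_gives_empty_output(self):
        data = _gaussian_set(20, seed=14)
        model = psrt.train_final(data, seed=0)
        assert len(psrt.classify_all(model, np.zeros((0, 5)))) == 0

    def test_unfitted_model_raises(self):
        model = psrt.ClassifierModel(kind="knn", classes=["a"], class_weights={})
        with pytest.raises(psrt.NotFittedError):
            model.predict(np.zeros((1, 5)))

    def test_no_test_set_leakage_by_id(self):
        data = _gaussian_set(50, seed=15)
        tr, te = psrt.split(data, psrt.SplitSpec(seed=0))
        assert not set(tr.cell_ids) & set(te.cell_ids)
        psrt.evaluate(psrt.train_final(tr, seed=0), te)  # metrics from te only


class TestSerialization:
    def test_xgboost_round_trip_preserves_predictions(self, tmp_path):
        data = _gaussian_set(100, seed=20)
        model = psrt.train_final(data, seed=0)
        psrt.save_model(model, tmp_path / "m")
        loaded = psrt.load_model(tmp_path / "m")
        np.testing.assert_array_equal(model.predict(data.embeddings),
                                      loaded.predict(data.embeddings))
        assert loaded.version == model.version

    def test_knn_round_trip_preserves_predictions(self, tmp_path):
        data = _gaussian_set(60, seed=21)
        model = psrt.train_baseline(data, k=5)
        psrt.save_model(model, tmp_path / "k")
        loaded = psrt.load_model(tmp_path / "k")
        np.testing.assert_array_equal(model.predict(data.embeddings),
                                      loaded.predict(data.embeddings))


class TestGeneratorCells:
    def test_heldout_balanced_accuracy_on_generator_truth(self, training_data):
        """Full model set on segmented+matched generator cells."""
        cells, emb = training_data
        model_set = psrt.train_model_set(cells, emb, seed=1)
        for fam in ("size", "actin", "annexin", "fragment"):
            assert model_set.metrics[fam]["balanced_accuracy"] >= 0.9, fam

    def test_wellwise_fraction_recovery_correlates_with_truth(
            self, training_data, render_params, seg_params):
        """Classifier-derived small-round fractions track truth fractions
        across wells with varying composition (r >= 0.95 over 50 wells)."""
        from phenoscreen import pipeline as pl

        cells, emb = training_data
        model_set = psrt.train_model_set(cells, emb, families=("size",), seed=1)
        rng = np.random.default_rng(0)
        truth_fracs, est_fracs = [], []
        for w in range(50):
            p_large = rng.uniform(0.1, 0.7)
            spec = syn.EffectSpec(baseline=syn.PhenotypeBaseline(
                large_frac=p_large), donor_sd=0.0)
            truth = syn.simulate_well(make_layout_row(well=f"W{w}"), spec, 30,
                                      seed=500 + w)
            _, det, e = pl.process_well(
                truth, syn.RenderParams(field_px=384), seg_params,
                seed=600 + w)
            labels = model_set.classify(e)
            est = (labels["size_class"] == "small_round").mean()
            truth_fracs.append(truth.realized_fractions()["small_round"])
            est_fracs.append(est)
        r = np.corrcoef(truth_fracs, est_fracs)[0, 1]
        assert r >= 0.95
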
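import warnings

import numpy as np
import pandas as pd
import pytest

from seedspectra.classify import (BandSelection, ConfusionMatrix,
                                  SubspaceLdaEnsemble, cross_validate,
                                  metrics, predict_lda, select_bands_osp,
                                  selection_frequency, split_train_test,
                                  train_lda)
from seedspectra.features import FeatureTable
from seedspectra.synthetic import make_cohort


def _table(x: np.ndarray, y, names=None) -> FeatureTable:
    names = names or [f"p{i}" for i in range(x.shape[1])]
    frame = pd.DataFrame(x, columns=names)
    frame.insert(0, "accession", y)
    return FeatureTable(frame=frame, predictor_names=names,
                        class_labels=np.asarray(y))


def _gaussian_two_class(rng, n=200, d=2, sep=10.0):
    x = rng.normal(0, 1, (n, d))
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    x[y == "b"] += sep
    return _table(x, y)


class TestSplit:
    def test_80_20_sizes(self, rng):
        table = _gaussian_two_class(rng, n=100)
        tr, te = split_train_test(table, 0.2, seed=0)
        assert len(tr.frame) == 80 and len(te.frame) == 20

    def test_same_seed_same_split(self, rng):
        table = _gaussian_two_class(rng)
        a = split_train_test(table, 0.2, seed=3)[1].frame
        b = split_train_test(table, 0.2, seed=3)[1].frame
        pd.testing.assert_frame_equal(a, b)

    def test_zero_fraction_errors(self, rng):
        with pytest.raises(ValueError):
            split_train_test(_gaussian_two_class(rng), 0.0, seed=0)

    def test_singleton_class_forced_to_train(self, rng):
        x = rng.normal(0, 1, (21, 3))
        y = ["a"] * 10 + ["b"] * 10 + ["solo"]
        with pytest.warns(UserWarning, match="single"):
            tr, te = split_train_test(_table(x, y), 0.2, seed=0)
        assert "solo" in tr.class_labels
        assert "solo" not in te.class_labels


class TestTrainLda:
    def test_separable_classes_high_accuracy(self, rng):
        table = _gaussian_two_class(rng, n=200, sep=10.0)
        tr, te = split_train_test(table, 0.2, seed=0)
        model = train_lda(tr)
        acc = (predict_lda(model, te) == te.class_labels).mean()
        assert acc >= 0.99

    def test_identical_distributions_chance_level(self, rng):
        x = rng.normal(0, 1, (400, 5))
        y = np.array(["a", "b", "c", "d"] * 100)
        table = _table(x, y)
        tr, te = split_train_test(table, 0.25, seed=0)
        acc = (predict_lda(train_lda(tr), te) == te.class_labels).mean()
        assert abs(acc - 0.25) <= 0.1

    def test_informative_predictor_has_top_importance(self, rng):
        n = 300
        x = rng.normal(0, 1, (n, 51))
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        x[y == "b", 17] += 6.0  # single informative predictor
        model = train_lda(_table(x, y))
        assert int(np.argmax(model.delta_importance)) == 17

    def test_zero_variance_predictor_dropped(self, rng):
        x = rng.normal(0, 1, (40, 3))
        x[:, 1] = 7.0
        y = ["a"] * 20 + ["b"] * 20
        with pytest.warns(UserWarning, match="zero-variance"):
            model = train_lda(_table(x, y))
        assert "p1" not in model.predictor_names

    def test_matches_sklearn_fisher_direction(self, rng):
        """Cross-check: on spherical two-class data the discriminant direction
        agrees with scikit-learn's LDA coefficient direction."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        x = rng.normal(0, 1, (400, 4))
        y = np.array(["a"] * 200 + ["b"] * 200)
        x[y == "b"] += [1.0, 2.0, -1.0, 0.5]
        model = train_lda(_table(x, y), regularization=1e-12)
        ours = model.precision @ (model.class_means[0] - model.class_means[1])
        ours /= np.linalg.norm(ours)
        sk = LinearDiscriminantAnalysis().fit((x - x.mean(0)) / x.std(0), y)
        theirs = sk.coef_[0] / np.linalg.norm(sk.coef_[0])
        assert abs(abs(np.dot(ours, theirs))) >= 0.999

    def test_model_json_roundtrip(self, rng, tmp_path):
        from seedspectra.classify import LdaModel
        table = _gaussian_two_class(rng)
        model = train_lda(table)
        model.to_json(tmp_path / "m.json")
        back = LdaModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.precision, model.precision)
        assert back.class_names == model.class_names


class TestCrossValidate:
    def test_separable_data_perfect_mean(self, rng):
        table = _gaussian_two_class(rng, n=100, sep=8.0)
        res = cross_validate(table, k=5, seed=0)
        assert res["summary"]["accuracy"]["mean"] == 1.0

    def test_same_seed_identical_results(self, rng):
        table = _gaussian_two_class(rng, n=60, sep=2.0)
        a = cross_validate(table, k=5, seed=1)
        b = cross_validate(table, k=5, seed=1)
        assert a["folds"] == b["folds"]

    def test_k_below_two_errors(self, rng):
        with pytest.raises(ValueError):
            cross_validate(_gaussian_two_class(rng), k=1, seed=0)

    def test_cv_close_to_single_split_on_separable(self, rng):
        table = _gaussian_two_class(rng, n=100, sep=8.0)
        res = cross_validate(table, k=5, seed=0)
        tr, te = split_train_test(table, 0.2, seed=0)
        single = (predict_lda(train_lda(tr), te) == te.class_labels).mean()
        assert res["summary"]["accuracy"]["mean"] >= single - 0.02


class TestMetrics:
    def test_diagonal_matrix_all_ones(self):
        cm = ConfusionMatrix(counts=np.diag([4, 6, 5]),
                             class_names=["a", "b", "c"])
        assert metrics(cm) == {"accuracy": 1.0, "precision": 1.0,
                               "recall": 1.0, "f1": 1.0}

    def test_binary_hand_example(self):
        # TP=3, FN=1 / FP=1, TN=5
        cm = ConfusionMatrix(counts=np.array([[3, 1], [1, 5]]),
                             class_names=["pos", "neg"])
        out = metrics(cm, average="binary")
        assert out == pytest.approx({"accuracy": 0.8, "precision": 0.75,
                                     "recall": 0.75, "f1": 0.75})

    def test_degenerate_single_prediction_macro(self):
        cm = ConfusionMatrix(counts=np.array([[5, 0], [5, 0]]),
                             class_names=["a", "b"])
        with pytest.warns(UserWarning, match="never predicted"):
            out = metrics(cm)
        assert out["accuracy"] == pytest.approx(0.5)
        assert out["f1"] == pytest.approx(1.0 / 3.0)

    def test_micro_accuracy_is_trace_over_sum(self, rng):
        for _ in range(20):
            c = rng.integers(0, 30, (4, 4))
            if c.sum() == 0:
                continue
            cm = ConfusionMatrix(counts=c, class_names=list("abcd"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = metrics(cm)
            assert out["accuracy"] == pytest.approx(np.trace(c) / c.sum())


class TestOspBandSelection:
    def _rank2(self, rng, n_pix=400, n_bands=60, i=5, j=40):
        u, v = rng.normal(0, 1, (2, n_pix))
        x = np.zeros((n_pix, n_bands))
        for b in range(n_bands):
            a1, a2 = rng.uniform(0, 0.45, 2)
            x[:, b] = a1 * u + a2 * v
        x[:, i] = u
        x[:, j] = v
        return x

    def test_rank2_selects_generating_bands(self, rng):
        x = self._rank2(rng)
        sel = select_bands_osp(x, n_bands=2, pixel_fraction=0.5, seed=0)
        assert sorted(sel.selected_indices) == [5, 40]

    def test_selection_stops_when_span_exhausted(self, rng):
        x = self._rank2(rng)
        sel = select_bands_osp(x, n_bands=10, pixel_fraction=0.5, seed=0)
        assert len(sel.selected_indices) == 2  # residual hits zero

    def test_duplicate_band_selected_once(self, rng):
        x = rng.normal(0, 1, (200, 10))
        x[:, 7] = x[:, 3]
        sel = select_bands_osp(x, n_bands=5, pixel_fraction=1.0, seed=0)
        assert not ({3, 7} <= set(sel.selected_indices))

    def test_residual_norms_non_increasing(self, rng):
        x = rng.normal(0, 1, (300, 20)) @ rng.normal(0, 1, (20, 20))
        sel = select_bands_osp(x, n_bands=8, pixel_fraction=0.5, seed=0)
        norms = sel.residual_norms
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_invalid_count_errors(self, rng):
        with pytest.raises(ValueError):
            select_bands_osp(rng.normal(0, 1, (10, 5)), n_bands=0)


class TestSelectionFrequency:
    def test_identical_selections_count_all(self):
        sels = [BandSelection([1, 5, 9], [3, 2, 1])] * 5
        out = selection_frequency(sels, n_total=12)
        assert out["frequency"][1] == 5
        assert out["bands_in_every_selection"] == [1, 5, 9]

    def test_disjoint_selections_all_once(self):
        sels = [BandSelection([0, 1], [1, 1]), BandSelection([2, 3], [1, 1])]
        out = selection_frequency(sels, n_total=4)
        assert out["bands_selected_more_than_once"] == []
        assert out["bands_in_every_selection"] == []

    def test_signal_bands_found_in_every_member(self, rng):
        """Cohort where three bands carry all class structure."""
        sels = []
        for acc in range(5):
            r = np.random.default_rng(acc)
            n = 150
            base = r.normal(0, 0.02, (n, 30))
            drivers = r.normal(0, 1, (n, 3))
            base[:, 4] += drivers[:, 0]
            base[:, 12] += drivers[:, 1]
            base[:, 25] += drivers[:, 2]
            sels.append(select_bands_osp(base, n_bands=3, pixel_fraction=1.0,
                                         seed=acc))
        out = selection_frequency(sels, n_total=30)
        assert out["bands_in_every_selection"] == [4, 12, 25]


def test_cohort_lda_strong_vs_null():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        strong = make_cohort(10, 20, class_effect=1.0, seed=0)
        res = cross_validate(strong, k=5, seed=0)
        assert res["summary"]["accuracy"]["mean"] >= 0.95
        null = make_cohort(10, 20, class_effect=0.0, seed=1)
        res0 = cross_validate(null, k=5, seed=0)
        assert abs(res0["summary"]["accuracy"]["mean"] - 0.1) <= 0.1


def test_subspace_ensemble_on_separable_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = make_cohort(5, 12, class_effect=1.0, seed=2)
        tr, te = split_train_test(table, 0.25, seed=0)
        ens = SubspaceLdaEnsemble(n_members=15, seed=0).fit(tr)
        acc = (ens.predict(te) == te.class_labels.astype(str)).mean()
    assert acc >= 0.9
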
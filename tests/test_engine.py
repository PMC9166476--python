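"""Perturbation engine: nets, training, splitting, perturbation contract."""

import numpy as np
import pandas as pd
import pytest

from statepert import engine, gem_io
from statepert.engine import ClassifierConfig, GeneratorConfig
from statepert.gem_io import ExpressionMatrix
from statepert.nn import MLP, softmax_cross_entropy


@pytest.fixture(scope="module")
def split_cohort(request):
    small = request.getfixturevalue("small_cohort")
    cfg, gem, labels, truth = small
    tr, trl, he, hel = engine.split_train_heldout(
        gem, labels, cfg.n_heldout_per_class, seed=cfg.seed)
    tri = gem_io.impute_missing(tr, tr)
    hei = gem_io.impute_missing(he, tr)
    return cfg, truth, tri, trl, hei, hel


@pytest.fixture(scope="module")
def trained_classifier(split_cohort):
    cfg, truth, tri, trl, hei, hel = split_cohort
    clf = engine.train_classifier(
        tri, trl, ClassifierConfig(epochs=150), seed=0)
    return clf


class TestMLPGradients:
    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = MLP((5, 7, 3), rng)
        x = rng.normal(size=(4, 5))
        y = np.array([0, 2, 1, 0])

        logits, caches = net.forward(x)
        _, d_logits = softmax_cross_entropy(logits, y)
        d_x, grads = net.backward(d_logits, caches)

        def loss_at(w, idx, delta):
            orig = w.flat[idx]
            w.flat[idx] = orig + delta
            out, _ = net.forward(x)
            l, _ = softmax_cross_entropy(out, y)
            w.flat[idx] = orig
            return l

        eps = 1e-6
        for p, g in zip(net.params, grads):
            for idx in [0, p.size // 2, p.size - 1]:
                num = (loss_at(p, idx, eps) - loss_at(p, idx, -eps)) / (2 * eps)
                assert num == pytest.approx(g.flat[idx], abs=1e-5)

        # input gradient too (needed for adversarial training)
        for idx in [0, 7]:
            xp, xm = x.copy(), x.copy()
            xp.flat[idx] += eps
            xm.flat[idx] -= eps
            lp, _ = softmax_cross_entropy(net.forward(xp)[0], y)
            lm, _ = softmax_cross_entropy(net.forward(xm)[0], y)
            assert (lp - lm) / (2 * eps) == pytest.approx(d_x.flat[idx],
                                                          abs=1e-5)


class TestSplit:
    def test_partition_with_exact_heldout_counts(self, small_cohort):
        cfg, gem, labels, truth = small_cohort
        tr, trl, he, hel = engine.split_train_heldout(gem, labels, 5, seed=2)
        assert len(hel) == 5 * len(cfg.classes)
        assert hel.value_counts().eq(5).all()
        assert set(tr.sample_ids) | set(he.sample_ids) == set(gem.sample_ids)
        assert not set(tr.sample_ids) & set(he.sample_ids)

    def test_deterministic_under_seed(self, small_cohort):
        _, gem, labels, _ = small_cohort
        a = engine.split_train_heldout(gem, labels, 3, seed=9)
        b = engine.split_train_heldout(gem, labels, 3, seed=9)
        assert a[2].sample_ids == b[2].sample_ids

    def test_class_too_small_names_class(self, small_cohort):
        _, gem, labels, _ = small_cohort
        with pytest.raises(ValueError, match="normal-gtex"):
            engine.split_train_heldout(gem, labels, 20, seed=0)


class TestClassifier:
    def test_heldout_accuracy_high_on_synthetic(self, split_cohort,
                                                trained_classifier):
        """Tumor stages separate cleanly even at this reduced scale; any
        residual confusion is confined to the two normal sources, whose
        only difference is the subtle batch offset."""
        cfg, truth, tri, trl, hei, hel = split_cohort
        acc = engine.classifier_accuracy(trained_classifier, hei, hel)
        assert acc >= 0.8
        pred = trained_classifier.predict(hei)
        normals = {"normal-tcga", "normal-gtex"}
        for true, p in zip(hel, pred):
            if true != p:
                assert {true, p} <= normals, (true, p)

    def test_probabilities_normalized(self, split_cohort,
                                      trained_classifier):
        *_, hei, hel = split_cohort
        proba = trained_classifier.predict_proba(hei)
        assert (proba >= 0).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_shuffled_labels_give_chance_accuracy(self, split_cohort):
        cfg, truth, tri, trl, hei, hel = split_cohort
        rng = np.random.default_rng(5)
        shuffled = pd.Series(rng.permutation(trl.to_numpy()),
                             index=trl.index)
        clf = engine.train_classifier(tri, shuffled,
                                      ClassifierConfig(epochs=100), seed=0)
        acc = engine.classifier_accuracy(clf, hei, hel)
        n = len(hel)
        chance = 1 / 6
        assert acc <= chance + 3 * np.sqrt(chance * (1 - chance) / n)

    def test_single_class_rejected(self, split_cohort):
        cfg, truth, tri, trl, *_ = split_cohort
        one = trl[trl == "tumor-s1"]
        with pytest.raises(ValueError, match="two classes"):
            engine.train_classifier(tri.select_samples(list(one.index)),
                                    one, seed=0)

    def test_missing_values_rejected(self, small_cohort):
        cfg, gem, labels, _ = small_cohort
        assert np.isnan(gem.values).any()
        with pytest.raises(ValueError, match="impute"):
            engine.train_classifier(gem, labels, seed=0)

    def test_accuracy_arithmetic(self, split_cohort, trained_classifier):
        *_, hei, hel = split_cohort
        pred = trained_classifier.predict(hei)
        expect = np.mean([p == t for p, t in zip(pred, hel)])
        acc = engine.classifier_accuracy(trained_classifier, hei, hel)
        assert acc == pytest.approx(expect)

    def test_unknown_label_rejected(self, split_cohort, trained_classifier):
        *_, hei, hel = split_cohort
        bad = hel.copy()
        bad.iloc[0] = "martian"
        with pytest.raises(ValueError, match="martian"):
            engine.classifier_accuracy(trained_classifier, hei, bad)


@pytest.fixture(scope="module")
def trained_generator(split_cohort, trained_classifier):
    return engine.train_generator(
        trained_classifier, split_cohort[2], split_cohort[3],
        "normal-gtex", GeneratorConfig(epochs=300), seed=0)


class TestGenerator:
    def test_training_samples_reach_target(self, split_cohort,
                                           trained_classifier,
                                           trained_generator):
        cfg, truth, tri, trl, *_ = split_cohort
        res = engine.perturb(trained_generator, tri)
        acc = engine.perturbation_accuracy(trained_classifier,
                                           res.perturbed, "normal-gtex")
        assert acc >= 0.99

    def test_perturbation_matrix_contract(self, split_cohort,
                                          trained_generator):
        *_, hei, hel = split_cohort
        res = engine.perturb(trained_generator, hei)
        assert res.perturbations.gene_ids == hei.gene_ids
        assert res.perturbations.sample_ids == hei.sample_ids
        np.testing.assert_allclose(
            res.perturbed.values - hei.values, res.perturbations.values,
            atol=1e-6)

    def test_planted_up_gene_gets_negative_perturbation(self, split_cohort,
                                                        trained_generator):
        cfg, truth, tri, trl, hei, hel = split_cohort
        res = engine.perturb(trained_generator, hei)
        s1 = [s for s in hei.sample_ids if hel[s] == "tumor-s1"]
        up = sorted(truth.per_class["tumor-s1"].up)
        mean_p = res.perturbations.data.loc[up, s1].to_numpy().mean()
        assert mean_p < -0.5  # tumor-up ⇒ expression must decrease

    def test_magnitude_penalty_shrinks_perturbations(self, split_cohort,
                                                     trained_classifier):
        cfg, truth, tri, trl, hei, hel = split_cohort
        small = engine.train_generator(
            trained_classifier, tri, trl, "normal-gtex",
            GeneratorConfig(epochs=120, lambda_magnitude=0.01), seed=0)
        large = engine.train_generator(
            trained_classifier, tri, trl, "normal-gtex",
            GeneratorConfig(epochs=120, lambda_magnitude=100.0), seed=0)
        p_small = np.abs(engine.perturb(small, hei).perturbations.values)
        p_large = np.abs(engine.perturb(large, hei).perturbations.values)
        assert p_large.mean() < p_small.mean()

    def test_target_class_samples_need_less_perturbation(self, split_cohort,
                                                         trained_generator):
        *_, hei, hel = split_cohort
        res = engine.perturb(trained_generator, hei)
        p = res.perturbations.data
        gtex = [s for s in p.columns if hel[s] == "normal-gtex"]
        tumor = [s for s in p.columns if hel[s].startswith("tumor")]
        assert p[gtex].abs().mean().mean() < p[tumor].abs().mean().mean()

    def test_deterministic_under_seed(self, split_cohort,
                                      trained_classifier):
        cfg, truth, tri, trl, hei, hel = split_cohort
        cfg_g = GeneratorConfig(epochs=30)
        a = engine.train_generator(trained_classifier, tri, trl,
                                   "normal-gtex", cfg_g, seed=3)
        b = engine.train_generator(trained_classifier, tri, trl,
                                   "normal-gtex", cfg_g, seed=3)
        pa = engine.perturb(a, hei).perturbations.values
        pb = engine.perturb(b, hei).perturbations.values
        np.testing.assert_array_equal(pa, pb)

    def test_absent_target_class_rejected(self, split_cohort,
                                          trained_classifier):
        cfg, truth, tri, trl, *_ = split_cohort
        with pytest.raises(ValueError, match="nonexistent"):
            engine.train_generator(trained_classifier, tri, trl,
                                   "nonexistent", seed=0)


class TestTargetMean:
    def test_matches_hand_mean_and_skips_missing(self):
        gem = ExpressionMatrix(pd.DataFrame(
            [[1.0, 3.0, 100.0], [np.nan, 4.0, 100.0]],
            index=["g1", "g2"], columns=["a", "b", "c"]))
        labels = pd.Series({"a": "t", "b": "t", "c": "other"})
        mu = engine.target_mean(gem, labels, "t")
        assert mu["g1"] == 2.0
        assert mu["g2"] == 4.0  # missing excluded per gene

    def test_empty_target_class_rejected(self, small_cohort):
        _, gem, labels, _ = small_cohort
        with pytest.raises(ValueError, match="ghost"):
            engine.target_mean(gem, labels, "ghost")

    def test_perturbed_mean_approaches_target_mean(self, split_cohort,
                                                   trained_classifier):
        cfg, truth, tri, trl, hei, hel = split_cohort
        gen = engine.train_generator(trained_classifier, tri, trl,
                                     "normal-gtex",
                                     GeneratorConfig(epochs=300), seed=0)
        res = engine.perturb(gen, hei)
        mu_t = engine.target_mean(tri, trl, "normal-gtex")
        xp_mean = res.perturbed.data.mean(axis=1)
        assert (xp_mean - mu_t).abs().mean() < cfg.noise_sd


class TestCheckpoints:
    def test_classifier_round_trip(self, split_cohort, trained_classifier,
                                   tmp_path):
        *_, hei, hel = split_cohort
        path = tmp_path / "clf.npz"
        engine.save_classifier(trained_classifier, path)
        back = engine.load_classifier(path)
        np.testing.assert_array_equal(back.predict_proba(hei),
                                      trained_classifier.predict_proba(hei))

    def test_generator_round_trip(self, split_cohort, trained_classifier,
                                  tmp_path):
        cfg, truth, tri, trl, hei, hel = split_cohort
        gen = engine.train_generator(trained_classifier, tri, trl,
                                     "normal-gtex",
                                     GeneratorConfig(epochs=20), seed=1)
        path = tmp_path / "gen.npz"
        engine.save_generator(gen, path)
        back = engine.load_generator(path)
        assert back.target_class == "normal-gtex"
        np.testing.assert_array_equal(
            engine.perturb(back, hei).perturbations.values,
            engine.perturb(gen, hei).perturbations.values)

    def test_wrong_kind_rejected(self, split_cohort, trained_classifier,
                                 tmp_path):
        path = tmp_path / "clf.npz"
        engine.save_classifier(trained_classifier, path)
        with pytest.raises(ValueError, match="generator"):
            engine.load_generator(path)
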
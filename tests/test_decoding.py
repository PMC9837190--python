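"""The masked KLD loss, evaluation metrics, activations, chance model
and classical baselines."""
import numpy as np
import pytest

from popdecode.decoding import (DecoderSpec, baseline_classifiers, binarize,
                                evaluate_metrics, kld_loss, kld_loss_batch,
                                predict_activations, fold_metrics,
                                train_decoder)
from popdecode.labeling import DNK, NO, YES, WindowSampleSet, make_fold_plan
from popdecode.nn import backward, softmax_cross_entropy


class TestKLDLoss:
    def test_dnk_character_contributes_zero(self):
        pred = np.full((4, 3), 1 / 3)
        truth = np.array([YES, NO, NO, DNK])
        with_dnk = kld_loss(pred, truth)
        # replacing the DNK row by any prediction changes nothing
        pred2 = pred.copy()
        pred2[3] = [0.98, 0.01, 0.01]
        assert kld_loss(pred2, truth) == pytest.approx(with_dnk)
        all_dnk = kld_loss(pred, np.full(4, DNK))
        assert all_dnk == 0.0

    def test_one_hot_prediction_zero_loss(self):
        pred = np.zeros((4, 3))
        truth = np.array([YES, NO, YES, NO])
        pred[np.arange(4), truth] = 1.0
        assert kld_loss(pred, truth) == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_gives_ln2(self):
        pred = np.tile([0.5, 0.25, 0.25], (4, 1))
        truth = np.array([YES, DNK, DNK, DNK])
        # only the first character contributes: ln 2 / 4
        assert kld_loss(pred, truth) == pytest.approx(np.log(2) / 4)

    def test_malformed_shapes_rejected(self):
        with pytest.raises(ValueError):
            kld_loss(np.ones((4, 2)), np.zeros(4, dtype=int))

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=(6, 4))
        truths = rng.integers(0, 3, size=(6, 4))
        batch = kld_loss_batch(probs, truths)
        single = [kld_loss(probs[i], truths[i]) for i in range(6)]
        assert np.allclose(batch, single)


class TestMetrics:
    def test_formula_arithmetic(self):
        truth = np.array([[YES]] * 3 + [[NO]] * 7)
        pred = np.array([[True]] * 2 + [[False]] + [[True]] + [[False]] * 6)
        rep = evaluate_metrics(pred, truth)
        d = rep.per_character[0]
        assert (d["TP"], d["TN"], d["FP"], d["FN"]) == (2, 6, 1, 1)
        assert d["accuracy"] == pytest.approx(0.8)
        assert d["recall"] == pytest.approx(2 / 3)
        assert d["precision"] == pytest.approx(2 / 3)
        assert d["f1"] == pytest.approx(2 / 3)

    def test_constant_no_predictor_at_20pct_prevalence(self):
        truth = np.array([[YES]] * 20 + [[NO]] * 80)
        pred = np.zeros((100, 1), dtype=bool)
        rep = evaluate_metrics(pred, truth)
        assert rep.per_character[0]["accuracy"] == pytest.approx(0.80)
        assert rep.per_character[0]["f1"] == 0.0

    def test_perfect_predictor(self):
        rng = np.random.default_rng(1)
        truth = rng.choice([YES, NO], size=(50, 4)).astype(np.int8)
        rep = evaluate_metrics(truth == YES, truth)
        for d in rep.per_character:
            assert d["accuracy"] == d["recall"] == d["precision"] == 1.0
            assert d["f1"] == 1.0

    def test_dnk_excluded_from_counts(self):
        truth = np.array([[YES], [DNK], [NO], [DNK]])
        pred = np.array([[True], [True], [False], [False]])
        d = evaluate_metrics(pred, truth).per_character[0]
        assert d["TP"] + d["TN"] + d["FP"] + d["FN"] == 2

    def test_metric_identities_from_confusion(self):
        rng = np.random.default_rng(2)
        truth = rng.choice([YES, NO], size=(200, 2), p=[0.2, 0.8]
                           ).astype(np.int8)
        pred = rng.random((200, 2)) < 0.3
        for d in evaluate_metrics(pred, truth).per_character:
            tp, tn, fp, fn = d["TP"], d["TN"], d["FP"], d["FN"]
            assert d["accuracy"] == pytest.approx(
                (tp + tn) / (tp + tn + fp + fn))
            if tp:
                assert d["f1"] == pytest.approx(
                    2 / (1 / d["recall"] + 1 / d["precision"]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics(np.zeros((0, 4), dtype=bool),
                             np.zeros((0, 4), dtype=np.int8))


class TestActivations:
    def test_binarize_threshold_is_strict(self):
        acts = np.array([[0.6, 0.5, 0.49, 0.51]])
        assert np.array_equal(binarize(acts),
                              [[True, False, False, True]])

    def test_fold_average_is_arithmetic_mean(self, movie_data,
                                             trained_lstm):
        x = movie_data["samples"].x[:32]
        per_fold = predict_activations(trained_lstm, x,
                                       average_folds=False)
        avg = predict_activations(trained_lstm, x, average_folds=True)
        assert np.allclose(avg, per_fold.mean(axis=0))
        assert np.all((avg >= 0) & (avg <= 1))

    def test_unit_mismatch_raises(self, movie_data, trained_lstm):
        x = movie_data["samples"].x[:4]
        with pytest.raises(ValueError, match="missing"):
            predict_activations(trained_lstm, x[:, :, :5],
                                unit_ids=np.arange(5))


class TestTraining:
    def test_decoder_beats_chance_on_tuned_data(self, movie_data,
                                                trained_lstm):
        rep = fold_metrics(trained_lstm, movie_data["samples"],
                                movie_data["plan"])[0]
        f1 = [d["f1"] for d in rep.per_character]
        assert min(f1) > 0.5      # prevalence-level chance F1 is ~0.15

    def test_training_is_deterministic(self, movie_data):
        spec = DecoderSpec(architecture="lstm", hidden=8, fc_hidden=8,
                           max_epochs=1, batch_size=256,
                           learning_rate=3e-3, seed=5)
        sub = WindowSampleSet(movie_data["samples"].x[:600],
                              movie_data["samples"].y[:600],
                              movie_data["samples"].frame_times[:600],
                              movie_data["samples"].unit_ids, 0)
        plan = make_fold_plan(600, seed=2)
        a = train_decoder(sub, spec, plan, folds=[0])
        b = train_decoder(sub, spec, plan, folds=[0])
        xa = predict_activations(a, sub.x[:20])
        xb = predict_activations(b, sub.x[:20])
        assert np.array_equal(xa, xb)

    def test_dnk_character_has_no_gradient(self):
        """A (sample, character) pair labelled DNK contributes exactly
        zero gradient through its score row; other rows still learn."""
        from popdecode.nn import Tensor
        rng = np.random.default_rng(0)
        logits = Tensor(rng.normal(size=(3, 4, 3)), requires_grad=True)
        labels = np.array([[DNK, YES, NO, NO],
                           [NO, DNK, DNK, YES],
                           [YES, NO, NO, NO]])
        mask = (labels != DNK).astype(float)
        loss = softmax_cross_entropy(logits, labels, mask)
        backward(loss)
        g = logits.grad
        assert not np.any(g[0, 0]) and not np.any(g[1, 1:3])
        assert np.all(np.any(g[2], axis=-1))
        assert np.any(g[0, 1:])


class TestArchitectureConsistency:
    def test_both_architectures_decode_a_single_tuned_unit(self):
        """On linearly decodable data (one strongly tuned unit, strong
        size modulation) both architectures reach F1 >= 0.9 for the
        tuned character and agree to within 0.1."""
        from popdecode.preprocess import bin_and_resample, \
            filter_low_rate_units
        from popdecode.synthetic import (PopulationSpec, TimelineConfig,
                                         UnitSpec,
                                         generate_character_timeline,
                                         simulate_spikes)
        from popdecode.labeling import build_frame_labels, \
            make_window_samples

        cfg = TimelineConfig(prevalence=0.15, duration_s=600.0,
                             size_beta=(5.0, 1.5))
        tl = generate_character_timeline(cfg, 3)
        pop = PopulationSpec(units=[UnitSpec(0, "occipital", "L", 0, 5.0,
                                             np.array([6.0, 1, 1, 1]))])
        spk = filter_low_rate_units(simulate_spikes(tl, pop, 4))
        ws = make_window_samples(bin_and_resample(spk),
                                 build_frame_labels(tl))
        plan = make_fold_plan(ws.n_samples, 0)
        f1s = {}
        for arch, kw in [("lstm", dict(hidden=12, fc_hidden=12)),
                         ("cnn", dict(channels=(4, 8), kernel=(3, 1),
                                      cnn_pools=((2, 1), (3, 1)),
                                      fc_hidden=16))]:
            spec = DecoderSpec(architecture=arch, max_epochs=8,
                               batch_size=128, learning_rate=5e-3,
                               seed=5, **kw)
            dec = train_decoder(ws, spec, plan, folds=[0])
            rep = fold_metrics(dec, ws, plan)[0]
            f1s[arch] = rep.per_character[0]["f1"]
        assert f1s["lstm"] >= 0.9
        assert f1s["cnn"] >= 0.9
        assert abs(f1s["lstm"] - f1s["cnn"]) < 0.1


class TestBaselines:
    @staticmethod
    def _label_samples(seed, n=4000, q=0.2):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random((n, 4)) < q, YES, NO).astype(np.int8)
        x = rng.normal(size=(n, 6, 4)).astype(np.float32)
        return WindowSampleSet(x, y, np.arange(n, dtype=float),
                               np.arange(4), 0)

    def test_nb_prior_f1_approx_prevalence(self):
        samples = self._label_samples(3)
        plan = make_fold_plan(samples.n_samples, seed=1)
        rep = baseline_classifiers(samples, plan, seed=0,
                                   methods=("nb_prior",))["nb_prior"]
        for d in rep.per_character:
            assert d["f1"] == pytest.approx(0.2, abs=0.05)

    def test_linear_methods_deterministic(self, movie_data):
        sub = WindowSampleSet(movie_data["samples"].x[:800],
                              movie_data["samples"].y[:800],
                              movie_data["samples"].frame_times[:800],
                              movie_data["samples"].unit_ids, 0)
        plan = make_fold_plan(800, seed=4)
        a = baseline_classifiers(sub, plan, seed=0, folds=[0],
                                 methods=("logreg", "linear_svm"))
        b = baseline_classifiers(sub, plan, seed=0, folds=[0],
                                 methods=("logreg", "linear_svm"))
        for m in ("logreg", "linear_svm"):
            assert a[m].macro == b[m].macro

    def test_deep_decoder_beats_nb_prior(self, movie_data, trained_lstm):
        rep = fold_metrics(trained_lstm, movie_data["samples"],
                                movie_data["plan"])[0]
        nb = baseline_classifiers(movie_data["samples"],
                                  movie_data["plan"], seed=0, folds=[0],
                                  methods=("nb_prior",))["nb_prior"]
        assert rep.macro["f1"] > 2 * nb.macro["f1"]
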
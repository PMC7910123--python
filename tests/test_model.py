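"""Model construction, cost-sensitive losses, training, decision rules."""

import dataclasses

import numpy as np
import pytest

from rnnlr._autodiff import Tensor
from rnnlr.model import (CostMatrix, LatentRegulator, ModelConfig, RNNLRModel,
                         RNNLRResults, expected_cost, training_loss)
from rnnlr.nn import softmax_probs
from rnnlr.sequences import PaddedSequenceSet

from conftest import quick_model_config


def _dataset(n=30, F=6, S=4, seed=0, n_classes=3):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, n)
    seqs = rng.normal(size=(n, 3, F)) * 0.3 + labels[:, None, None] * 0.2
    statics = rng.normal(size=(n, S))
    return PaddedSequenceSet(seqs, statics, np.ones((n, 3), bool), labels,
                             [f"p{i}" for i in range(n)],
                             [f"f{i}" for i in range(F)],
                             [f"s{i}" for i in range(S)])


class TestCostMatrix:
    def test_default_structure(self):
        c = CostMatrix.default().c
        assert np.array_equal(np.diag(c), np.zeros(3))
        assert c[1, 0] == c[1, 2] == c[2, 0] == c[2, 1] == 200.0
        assert c[0, 1] == c[0, 2] == 1.0

    def test_class_weights_are_row_means(self):
        w = CostMatrix.default().class_weights()
        assert np.allclose(w, [1.0, 200.0, 200.0])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            CostMatrix(np.ones((3, 3)))


class TestExpectedCost:
    def test_one_hot_on_truth_is_free(self):
        assert expected_cost([0.0, 1.0, 0.0], 1, CostMatrix.default()) == 0.0

    def test_uniform_probs_true_ahe(self):
        # (c(1,0) + 0 + c(1,2)) / 3 = (200 + 200) / 3
        val = expected_cost(np.full(3, 1 / 3), 1, CostMatrix.default())
        assert val == pytest.approx(400 / 3)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.dirichlet(np.ones(3))
            k = rng.integers(0, 3)
            c = rng.uniform(0, 10, (3, 3))
            np.fill_diagonal(c, 0.0)
            cost = CostMatrix(c)
            brute = sum(c[k, i] * p[i] for i in range(3))
            assert expected_cost(p, k, cost) == pytest.approx(brute)


class TestTrainingLoss:
    def _logits(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, n)
        return Tensor(rng.normal(size=(n, 3)), requires_grad=True), labels

    def test_uniform_costs_reduce_to_plain_cross_entropy(self):
        logits, labels = self._logits()
        uniform = CostMatrix(np.ones((3, 3)) - np.eye(3))
        loss = training_loss(logits, labels, uniform, "weighted_ce")
        probs = softmax_probs(logits).data
        ce = -np.mean(np.log(probs[np.arange(len(labels)), labels]))
        assert float(loss.data) == pytest.approx(ce)

    def test_perfect_predictions_cost_nothing(self):
        labels = np.array([0, 1, 2])
        logits = Tensor(np.eye(3) * 60.0)  # saturated softmax ~ one-hot
        for mode in ("weighted_ce", "expected_cost"):
            loss = training_loss(logits, labels, CostMatrix.default(), mode)
            assert float(loss.data) == pytest.approx(0.0, abs=1e-8)

    def test_doubling_a_cost_row_doubles_its_contribution(self):
        logits, _ = self._logits()
        labels = np.full(8, 1)  # all AHE
        base = training_loss(logits, labels, CostMatrix.default(200.0),
                             "weighted_ce")
        double = training_loss(logits, labels, CostMatrix(
            CostMatrix.default(200.0).c * 2), "weighted_ce")
        assert float(double.data) == pytest.approx(2 * float(base.data))

    def test_expected_cost_mode_matches_rowwise_oracle(self):
        logits, labels = self._logits(seed=2)
        cost = CostMatrix.default()
        loss = training_loss(logits, labels, cost, "expected_cost")
        probs = softmax_probs(logits).data
        brute = np.mean([expected_cost(probs[i], labels[i], cost)
                         for i in range(len(labels))])
        assert float(loss.data) == pytest.approx(brute)


class TestModelStructure:
    def test_init_deterministic_per_seed(self):
        ds = _dataset()
        a = RNNLRModel(ds, quick_model_config())
        b = RNNLRModel(ds, quick_model_config())
        for name in a.params:
            assert np.array_equal(a.params[name].data, b.params[name].data)
        c = RNNLRModel(ds, quick_model_config(seed=1))
        assert not np.array_equal(a.params["Wx0"].data, c.params["Wx0"].data)

    def test_embedding_and_head_dimensions(self):
        ds = _dataset(F=9, S=5)
        m = RNNLRModel(ds, quick_model_config())
        r = m.config.latent_size
        assert m.params["Wproj"].shape == (m.config.units_per_layer, r * r)
        assert m.params["H"].shape == (r, r)
        # head consumes flatten(D) + flatten(D@H) + statics
        assert m.params["Wd1"].shape == (r * r + r * r + 5, 128)

    def test_probabilities_are_simplex_rows(self):
        ds = _dataset()
        m = RNNLRModel(ds, quick_model_config())
        probs = m.predict_proba(ds)
        assert probs.min() >= 0
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_probabilities_shift_invariant(self):
        logits = np.random.default_rng(0).normal(size=(5, 3))
        a = softmax_probs(Tensor(logits)).data
        b = softmax_probs(Tensor(logits + 7.3)).data
        assert np.allclose(a, b)

    def test_equal_logits_give_uniform_probabilities(self):
        p = softmax_probs(Tensor(np.full((2, 3), 1.7))).data
        assert np.allclose(p, 1 / 3)

    def test_mask_aware_recurrence_ignores_leading_pads(self):
        ds = _dataset(n=10)
        ds.pad_mask[:, 0] = False
        ds.sequences[:, 0, :] = 0.0
        m = RNNLRModel(ds, quick_model_config(mask_aware=True))
        base = m.predict_proba(ds)
        # changing a padded slot's content must not change the output
        ds.sequences[:, 0, :] = 5.0
        assert np.allclose(m.predict_proba(ds), base)


class TestTraining:
    def test_zero_learning_rate_freezes_all_parameters(self):
        ds = _dataset()
        m = RNNLRModel(ds, quick_model_config(
            learning_rate=0.0, epochs=3, weight_decay=0.0))
        before = {k: t.data.copy() for k, t in m.params.items()}
        m.fit()
        for k, t in m.params.items():
            assert np.array_equal(before[k], t.data)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_decreases_over_training(self, seed):
        ds = _dataset(n=60, seed=seed)
        res = RNNLRModel(ds, quick_model_config(epochs=15, seed=seed)).fit()
        h = res.history
        assert h.train_loss.iloc[-1] < h.train_loss.iloc[0]

    def test_latent_regulator_trace_converges(self):
        ds = _dataset(n=40)
        res = RNNLRModel(ds, quick_model_config(epochs=12)).fit()
        assert np.isfinite(res.latent.deltas).all()
        assert res.latent.i_min is not None
        assert res.latent.deltas[res.latent.i_min - 1] < res.config.tolerance

    def test_single_class_labels_rejected(self):
        ds = _dataset()
        ds.labels[:] = 1
        with pytest.raises(ValueError, match="single class"):
            RNNLRModel(ds, quick_model_config()).fit()

    def test_frozen_regulator_stays_zero(self):
        ds = _dataset(n=40)
        res = RNNLRModel(ds, quick_model_config(
            epochs=5, use_latent_regulator=False)).fit()
        assert np.all(res.latent.H == 0.0)

    def test_fit_deterministic_per_seed(self):
        ds = _dataset(n=40)
        r1 = RNNLRModel(ds, quick_model_config(epochs=4)).fit()
        r2 = RNNLRModel(ds, quick_model_config(epochs=4)).fit()
        assert np.array_equal(r1.latent.H, r2.latent.H)
        assert r1.history.train_loss.tolist() == r2.history.train_loss.tolist()


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        ds = _dataset(n=40)
        return RNNLRModel(ds, quick_model_config(epochs=5)).fit(), ds

    def test_argmax_rule(self, fitted):
        res, ds = fitted
        labels, probs = res.predict(ds)
        assert np.array_equal(labels, probs.argmax(axis=1))

    def test_min_expected_cost_matches_brute_force(self, fitted):
        res, ds = fitted
        labels, probs = res.predict(ds, decision_rule="min_expected_cost")
        c = res.cost.c
        for i in range(len(ds)):
            decision_costs = [sum(probs[i, k] * c[k, j] for k in range(3))
                              for j in range(3)]
            assert labels[i] == int(np.argmin(decision_costs))

    def test_uniform_probabilities_pick_cheapest_column(self):
        # default costs: column sums are (400, 201, 201) -> AHE (index 1) wins
        probs = np.full((1, 3), 1 / 3)
        c = CostMatrix.default().c
        assert int((probs @ c).argmin()) == 1

    def test_inference_is_repeatable(self, fitted):
        res, ds = fitted
        a = res.class_probabilities(ds)
        b = res.class_probabilities(ds)
        assert np.array_equal(a, b)

    def test_checkpoint_round_trip(self, tmp_path, fitted):
        res, ds = fitted
        path = tmp_path / "model.npz"
        res.save(path)
        back = RNNLRResults.load(path)
        assert np.allclose(back.class_probabilities(ds),
                           res.class_probabilities(ds))
        assert back.latent.deltas == pytest.approx(res.latent.deltas)

    def test_summary_mentions_convergence_and_weights(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "latent regulator" in text
        assert "200.0" in text
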
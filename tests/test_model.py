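"""Network architecture, gradients, training mechanics, ensembling.

Architecture-shape checks run at full size (cheap); training mechanics use
a scaled-down configuration so the whole file stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from pihelix.encode import MAX_LEN, Pssm, encode
from pihelix.fixtures import synth_dataset
from pihelix.model import (
    ModelConfig,
    build_model,
    cv_train,
    ensemble_predict,
    load_weights,
    make_folds,
    prepare_sample,
    save_weights,
    train_fold,
)

TINY = ModelConfig(
    conv_windows=(3, 5), conv_filters=4, dense1=8, lstm_units=6, dense2=8,
    epochs=2, batch_size=4, dropout=0.0, recurrent_dropout=0.0,
)


def make_samples(n, seed=0, pi_rate=0.1, lengths=(30, 50)):
    ds = synth_dataset(n, pi_rate=pi_rate, length_range=lengths, seed=seed)
    out = []
    for i, rec in enumerate(ds):
        enc = encode(rec["sequence"], Pssm(np.asarray(rec["pssm"], float), rec["sequence"]), seed=seed + i)
        out.append(prepare_sample(enc, rec["labels"]))
    return out


class TestArchitecture:
    def test_full_size_layer_shapes(self):
        net = build_model(ModelConfig())
        shapes = net.layer_shapes()
        assert shapes["concat"] == (700, 192)
        assert shapes["output"] == (700, 4)
        for k in (3, 5, 7):
            assert shapes[f"conv{k}"] == (700, 64)

    def test_forward_output_shape_and_simplex(self):
        net = build_model(ModelConfig())
        x = np.random.default_rng(0).random((MAX_LEN, 40))
        probs, _ = net.forward(x)
        assert probs.shape == (700, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self):
        net = build_model(TINY, seed=0)
        x = np.random.default_rng(1).random((2, 30, 40))
        p1, _ = net.forward(x, train=False)
        p2, _ = net.forward(x, train=False)
        assert np.array_equal(p1, p2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(out_classes=3)
        with pytest.raises(ValueError):
            ModelConfig(conv_windows=(2, 4))

    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(
            conv_windows=(3,), conv_filters=3, dense1=5, lstm_units=4, dense2=5,
            dropout=0.0, recurrent_dropout=0.0, n_features=6,
        )
        net = build_model(cfg, seed=1, dtype=np.float64)
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
        rng = np.random.default_rng(0)
        B, T = 2, 8
        x = rng.random((B, T, 6))
        y = np.zeros((B, T, 4))
        for b in range(B):
            for t in range(T):
                y[b, t, rng.integers(4)] = 1
        w = rng.random((B, T))

        def loss_only():
            probs, _ = net.forward(x, train=True, rng=np.random.default_rng(5))
            return float(-(w * (y * np.log(probs + 1e-9)).sum(axis=2)).sum() / w.sum())

        _, grads, _ = net.loss_and_grads(x, y, w, np.random.default_rng(5))
        for key, g in grads.items():
            ga = np.asarray(g, float)
            for _ in range(2):
                idx = tuple(rng.integers(s) for s in ga.shape)
                eps = 1e-6
                orig = net.params[key][idx]
                net.params[key][idx] = orig + eps
                lp = loss_only()
                net.params[key][idx] = orig - eps
                lm = loss_only()
                net.params[key][idx] = orig
                num = (lp - lm) / (2 * eps)
                assert ga[idx] == pytest.approx(num, abs=max(1e-7, 1e-4 * abs(num)))


class TestTraining:
    def test_pad_labels_do_not_affect_loss(self):
        net = build_model(TINY, seed=2)
        rng = np.random.default_rng(3)
        B, T = 3, 20
        x = rng.random((B, T, 40)).astype(np.float32)
        y = np.zeros((B, T, 4), np.float32)
        y[..., 1] = 1
        w = np.ones((B, T), np.float32)
        w[:, 15:] = 0.0  # padded tail
        loss1, _, _ = net.loss_and_grads(x, y, w, np.random.default_rng(7))
        y2 = y.copy()
        y2[:, 15:] = 0
        y2[:, 15:, 3] = 1  # permute pad-row labels
        loss2, _, _ = net.loss_and_grads(x, y2, w, np.random.default_rng(7))
        assert loss1 == pytest.approx(loss2, abs=1e-7)

    def test_fixed_seed_reproduces_first_epoch_loss(self):
        samples = make_samples(6, seed=4)
        cfg = TINY
        h1 = train_fold(build_model(cfg, seed=5), samples, [], cfg, seed=9)[1]
        h2 = train_fold(build_model(cfg, seed=5), samples, [], cfg, seed=9)[1]
        assert h1["loss"][0] == h2["loss"][0]

    def test_no_pi_in_validation_warns_and_scores_zero(self):
        train = make_samples(6, seed=4)
        val = make_samples(2, seed=5, pi_rate=0.0)
        with pytest.warns(UserWarning, match="no pi-helical"):
            _, hist = train_fold(build_model(TINY, seed=0), train, val, TINY, seed=1)
        assert all(v == 0.0 for v in hist["val_pi_f1"])

    def test_best_epoch_weights_returned(self):
        samples = make_samples(8, seed=6)
        cfg = TINY
        net = build_model(cfg, seed=3)
        weights, hist = train_fold(net, samples, samples[:4], cfg, seed=2)
        net.set_weights(weights)
        from pihelix.model import _pi_f1

        assert _pi_f1(net, samples[:4]) == pytest.approx(max(hist["val_pi_f1"]), abs=1e-12)


class TestFolds:
    def test_fold_sizes_and_count(self):
        samples = make_samples(25, seed=7)
        folds = make_folds(samples, 10, seed=0)
        assert len(folds) == 10
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
        assert sorted(i for f in folds for i in f) == list(range(25))

    def test_pi_balance_across_folds(self):
        samples = make_samples(100, seed=8, pi_rate=0.08)
        folds = make_folds(samples, 10, seed=1)
        totals = [sum(int(samples[i]["is_pi"].sum()) for i in f) for f in folds]
        assert max(totals) / max(1, min(totals)) <= 1.5

    def test_too_few_sequences_raises(self):
        samples = make_samples(5, seed=9)
        with pytest.raises(ValueError):
            make_folds(samples, 10)

    def test_cv_returns_one_weight_set_per_fold(self):
        cfg = ModelConfig(
            conv_windows=(3,), conv_filters=2, dense1=4, lstm_units=3, dense2=4,
            epochs=1, batch_size=8, dropout=0.0, recurrent_dropout=0.0, folds=10,
        )
        samples = make_samples(12, seed=10, lengths=(20, 30))
        weight_sets = cv_train(samples, cfg, seed=0)
        assert len(weight_sets) == 10


class TestEnsemble:
    def _encoded(self, seed=0):
        ds = synth_dataset(1, pi_rate=0.1, length_range=(40, 40), seed=seed)[0]
        return encode(ds["sequence"], Pssm(np.asarray(ds["pssm"], float), ds["sequence"]), seed=seed)

    def test_single_member_equals_model(self):
        net = build_model(TINY, seed=1)
        enc = self._encoded()
        direct, _ = net.forward(enc.matrix[enc.mask].astype(np.float32))
        res = ensemble_predict([net.get_weights()], enc, TINY)
        assert np.allclose(res.probabilities, direct, atol=1e-7)

    def test_identical_members_equal_single(self):
        net = build_model(TINY, seed=1)
        enc = self._encoded(1)
        w = net.get_weights()
        one = ensemble_predict([w], enc, TINY)
        three = ensemble_predict([w, w, w], enc, TINY)
        assert np.allclose(one.probabilities, three.probabilities, atol=1e-7)

    def test_rows_sum_to_one_and_strip_pads(self):
        nets = [build_model(TINY, seed=s) for s in range(3)]
        enc = self._encoded(2)
        res = ensemble_predict([n.get_weights() for n in nets], enc, TINY)
        assert res.probabilities.shape == (40, 4)
        assert len(res.labels4) == 40
        assert np.allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_labels_match_argmax(self):
        net = build_model(TINY, seed=4)
        enc = self._encoded(3)
        res = ensemble_predict([net.get_weights()], enc, TINY)
        for i, lab in enumerate(res.labels4):
            assert "EHIC"[res.probabilities[i].argmax()] == lab

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            ensemble_predict([], self._encoded())

    def test_weight_checkpoint_roundtrip(self, tmp_path):
        net = build_model(TINY, seed=5)
        path = tmp_path / "w.npz"
        save_weights(net.get_weights(), path)
        loaded = load_weights(path)
        net2 = build_model(TINY, seed=99)
        net2.set_weights(loaded)
        x = np.random.default_rng(0).random((10, 40)).astype(np.float32)
        p1, _ = net.forward(x)
        p2, _ = net2.forward(x)
        assert np.array_equal(p1, p2)
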
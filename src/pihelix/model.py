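"""Cascaded convolutional/recurrent network for 4-state prediction.

Architecture: a 700 x 40 encoded sequence enters three parallel 1-D
convolutions (window lengths 3, 5, 7; 64 tanh filters each, length-
preserving), each branch is batch-normalized, the branches are
concatenated to 700 x 192, passed through a position-wise dense layer
(200, ReLU), two bidirectional LSTM layers (200 units per direction,
dropout and recurrent dropout 0.5), another dense layer (200, ReLU) and a
4-way softmax, yielding per-residue probabilities over (E, H, I, C).

Training uses Adam (lr 3e-4) on weighted categorical cross-entropy:
padded positions carry weight 0 and pi-helical positions weight 5 to
counter the extreme class imbalance.  Model selection within a
cross-validation fold is by the validation F1 of the pi class; the final
predictor averages the class probabilities of the per-fold models.

The network is implemented directly on NumPy (forward and analytic
backward passes, float32).  All layers are length-agnostic: the canonical
frame is 700 rows, but training batches are packed to their true sequence
lengths, which is equivalent under the zero-weighted padding and much
cheaper on CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .encode import MAX_LEN, EncodedSample
from .evaluate import CLASSES, f1

__all__ = [
    "ModelConfig",
    "PredictionResult",
    "SequenceClassifierNet",
    "build_model",
    "prepare_sample",
    "train_fold",
    "make_folds",
    "cv_train",
    "ensemble_predict",
]

_CLS_IDX = {c: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class ModelConfig:
    conv_windows: tuple[int, ...] = (3, 5, 7)
    conv_filters: int = 64
    dense1: int = 200
    lstm_units: int = 200
    dropout: float = 0.5
    recurrent_dropout: float = 0.5
    dense2: int = 200
    out_classes: int = 4
    lr: float = 0.0003
    epochs: int = 50
    batch_size: int = 16
    class_weight_pi: float = 5.0
    folds: int = 10
    n_features: int = 40

    def __post_init__(self):
        if self.out_classes != 4:
            raise ValueError("the predictor is defined over 4 output classes")
        for name in ("conv_filters", "dense1", "lstm_units", "dense2", "epochs", "batch_size", "folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not all(w % 2 == 1 for w in self.conv_windows):
            raise ValueError("conv windows must be odd for length-preserving output")


@dataclass
class PredictionResult:
    """Per-residue class probabilities (rows sum to 1) and argmax labels."""

    probabilities: np.ndarray  # (L, 4) over CLASSES order (E, H, I, C)
    labels4: str


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _orthogonal(rng, n, m):
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return (q[:n, :m] if q.shape == (max(n, m), min(n, m)) else q.T[:n, :m]).astype(np.float32)


def _lstm_recurrent_init(rng, h):
    blocks = [_orthogonal(rng, h, h) for _ in range(4)]
    return np.concatenate(blocks, axis=1)


class SequenceClassifierNet:
    """NumPy implementation of the conv/biLSTM sequence labeller."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, np.ndarray] = {}
        for k in c.conv_windows:
            p[f"conv{k}_W"] = _glorot(rng, (k * c.n_features, c.conv_filters))
            p[f"conv{k}_b"] = np.zeros(c.conv_filters, self.dtype)
            p[f"bn{k}_gamma"] = np.ones(c.conv_filters, self.dtype)
            p[f"bn{k}_beta"] = np.zeros(c.conv_filters, self.dtype)
        concat = c.conv_filters * len(c.conv_windows)
        p["dense1_W"] = _glorot(rng, (concat, c.dense1))
        p["dense1_b"] = np.zeros(c.dense1, self.dtype)
        h = c.lstm_units
        for layer, in_dim in ((1, c.dense1), (2, 2 * h)):
            for d in ("f", "b"):
                p[f"lstm{layer}{d}_W"] = _glorot(rng, (in_dim, 4 * h))
                p[f"lstm{layer}{d}_U"] = _lstm_recurrent_init(rng, h)
                bias = np.zeros(4 * h, self.dtype)
                bias[h : 2 * h] = 1.0  # unit forget-gate bias
                p[f"lstm{layer}{d}_b"] = bias
        p["dense2_W"] = _glorot(rng, (2 * h, c.dense2))
        p["dense2_b"] = np.zeros(c.dense2, self.dtype)
        p["out_W"] = _glorot(rng, (c.dense2, c.out_classes))
        p["out_b"] = np.zeros(c.out_classes, self.dtype)
        self.params = p
        # batch-norm running statistics (not trained by gradient)
        self.bn_state = {
            f"bn{k}_{s}": (np.zeros if s == "mean" else np.ones)(c.conv_filters, self.dtype)
            for k in c.conv_windows
            for s in ("mean", "var")
        }
        self.bn_momentum = 0.99
        self.bn_eps = 1e-3

    # -- weights ----------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        w = {k: v.copy() for k, v in self.params.items()}
        w.update({f"state_{k}": v.copy() for k, v in self.bn_state.items()})
        return w

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            if k not in weights:
                raise ValueError(f"missing weight {k!r}")
            if weights[k].shape != self.params[k].shape:
                raise ValueError(f"weight {k!r}: shape {weights[k].shape} != {self.params[k].shape}")
            self.params[k] = weights[k].astype(self.dtype).copy()
        for k in self.bn_state:
            sk = f"state_{k}"
            if sk in weights:
                self.bn_state[k] = weights[sk].astype(self.dtype).copy()

    def layer_shapes(self, T: int = MAX_LEN) -> dict[str, tuple[int, int]]:
        c = self.config
        return {
            **{f"conv{k}": (T, c.conv_filters) for k in c.conv_windows},
            "concat": (T, c.conv_filters * len(c.conv_windows)),
            "dense1": (T, c.dense1),
            "bilstm1": (T, 2 * c.lstm_units),
            "bilstm2": (T, 2 * c.lstm_units),
            "dense2": (T, c.dense2),
            "output": (T, c.out_classes),
        }

    # -- layer primitives --------------------------------------------------

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        B, T, F = x.shape
        pad = k // 2
        xp = np.zeros((B, T + 2 * pad, F), x.dtype)
        xp[:, pad : pad + T] = x
        return np.concatenate([xp[:, j : j + T] for j in range(k)], axis=2)

    @staticmethod
    def _col2im(dcol: np.ndarray, k: int, T: int, F: int) -> np.ndarray:
        B = dcol.shape[0]
        pad = k // 2
        dxp = np.zeros((B, T + 2 * pad, F), dcol.dtype)
        for j in range(k):
            dxp[:, j : j + T] += dcol[:, :, j * F : (j + 1) * F]
        return dxp[:, pad : pad + T]

    def _bn_forward(self, x, k, train):
        g = self.params[f"bn{k}_gamma"]
        b = self.params[f"bn{k}_beta"]
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.bn_momentum
            self.bn_state[f"bn{k}_mean"] = (m * self.bn_state[f"bn{k}_mean"] + (1 - m) * mean).astype(self.dtype)
            self.bn_state[f"bn{k}_var"] = (m * self.bn_state[f"bn{k}_var"] + (1 - m) * var).astype(self.dtype)
        else:
            mean = self.bn_state[f"bn{k}_mean"]
            var = self.bn_state[f"bn{k}_var"]
        inv = 1.0 / np.sqrt(var + self.bn_eps)
        xhat = (x - mean) * inv
        return g * xhat + b, (xhat, inv, g)

    @staticmethod
    def _bn_backward(dy, cache):
        xhat, inv, g = cache
        n = dy.shape[0] * dy.shape[1]
        dgamma = (dy * xhat).sum(axis=(0, 1))
        dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * g
        dx = inv / n * (n * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        return dx.astype(dy.dtype), dgamma.astype(dy.dtype), dbeta.astype(dy.dtype)

    def _lstm_forward(self, x, prefix, train, rng):
        """One direction; x already time-reversed for the backward direction."""
        W = self.params[f"{prefix}_W"]
        U = self.params[f"{prefix}_U"]
        b = self.params[f"{prefix}_b"]
        B, T, D = x.shape
        H = U.shape[0]
        c = self.config
        if train and c.dropout > 0:
            dmask = (rng.random((B, 1, D)) >= c.dropout).astype(self.dtype) / (1 - c.dropout)
        else:
            dmask = np.ones((B, 1, D), self.dtype)
        if train and c.recurrent_dropout > 0:
            rmask = (rng.random((B, H)) >= c.recurrent_dropout).astype(self.dtype) / (1 - c.recurrent_dropout)
        else:
            rmask = np.ones((B, H), self.dtype)
        xd = x * dmask
        zx = (xd.reshape(B * T, D) @ W).reshape(B, T, 4 * H) + b
        hs = np.empty((B, T, H), self.dtype)
        cs = np.empty((B, T, H), self.dtype)
        gates = np.empty((B, T, 4 * H), self.dtype)
        h = np.zeros((B, H), self.dtype)
        cc = np.zeros((B, H), self.dtype)
        for t in range(T):
            z = zx[:, t] + (h * rmask) @ U
            i = _sigmoid(z[:, :H])
            fgate = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            cc = fgate * cc + i * g
            h = o * np.tanh(cc)
            hs[:, t] = h
            cs[:, t] = cc
            gates[:, t, :H] = i
            gates[:, t, H : 2 * H] = fgate
            gates[:, t, 2 * H : 3 * H] = g
            gates[:, t, 3 * H :] = o
        cache = (xd, dmask, rmask, hs, cs, gates)
        return hs, cache

    def _lstm_backward(self, dh_out, prefix, cache, grads):
        W = self.params[f"{prefix}_W"]
        U = self.params[f"{prefix}_U"]
        xd, dmask, rmask, hs, cs, gates = cache
        B, T, D = xd.shape
        H = hs.shape[2]
        dz_all = np.empty((B, T, 4 * H), self.dtype)
        dU = np.zeros_like(U)
        dh = np.zeros((B, H), self.dtype)
        dc = np.zeros((B, H), self.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh + dh_out[:, t]
            i = gates[:, t, :H]
            fgate = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            cc = cs[:, t]
            tanh_c = np.tanh(cc)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c * tanh_c)
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), self.dtype)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), self.dtype)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * fgate * (1 - fgate),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            ).astype(self.dtype)
            dz_all[:, t] = dz
            dU += (h_prev * rmask).T @ dz
            dh = ((dz @ U.T) * rmask).astype(self.dtype)
            dc = dc * fgate
        dW = xd.reshape(B * T, D).T @ dz_all.reshape(B * T, 4 * H)
        db = dz_all.sum(axis=(0, 1))
        dx = ((dz_all.reshape(B * T, 4 * H) @ W.T).reshape(B, T, D) * dmask).astype(self.dtype)
        grads[f"{prefix}_W"] = dW.astype(self.dtype)
        grads[f"{prefix}_U"] = dU.astype(self.dtype)
        grads[f"{prefix}_b"] = db.astype(self.dtype)
        return dx

    def _bilstm_forward(self, x, layer, train, rng):
        hf, cache_f = self._lstm_forward(x, f"lstm{layer}f", train, rng)
        hb_rev, cache_b = self._lstm_forward(x[:, ::-1], f"lstm{layer}b", train, rng)
        out = np.concatenate([hf, hb_rev[:, ::-1]], axis=2)
        return out, (cache_f, cache_b)

    def _bilstm_backward(self, dout, layer, cache, grads):
        H = self.config.lstm_units
        cache_f, cache_b = cache
        dx_f = self._lstm_backward(np.ascontiguousarray(dout[:, :, :H]), f"lstm{layer}f", cache_f, grads)
        dx_b_rev = self._lstm_backward(
            np.ascontiguousarray(dout[:, ::-1, H:]), f"lstm{layer}b", cache_b, grads
        )
        return dx_f + dx_b_rev[:, ::-1]

    # -- full network ------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng: Optional[np.random.Generator] = None):
        """Class probabilities (B, T, 4) and the cache for backprop."""
        if rng is None:
            rng = np.random.default_rng(0)
        x = np.asarray(x, self.dtype)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        c = self.config
        cache: dict = {"x": x, "squeeze": squeeze}
        branches = []
        for k in c.conv_windows:
            col = self._im2col(x, k)
            z = col @ self.params[f"conv{k}_W"] + self.params[f"conv{k}_b"]
            a = np.tanh(z)
            bn, bn_cache = self._bn_forward(a, k, train)
            cache[f"conv{k}"] = (col, a, bn_cache)
            branches.append(bn.astype(self.dtype))
        concat = np.concatenate(branches, axis=2)
        z1 = concat @ self.params["dense1_W"] + self.params["dense1_b"]
        a1 = np.maximum(z1, 0).astype(self.dtype)
        cache["concat"] = concat
        cache["a1"] = a1
        l1, cache["bilstm1"] = self._bilstm_forward(a1, 1, train, rng)
        l2, cache["bilstm2"] = self._bilstm_forward(l1, 2, train, rng)
        cache["l1"] = l1
        cache["l2"] = l2
        z2 = l2 @ self.params["dense2_W"] + self.params["dense2_b"]
        a2 = np.maximum(z2, 0).astype(self.dtype)
        cache["a2"] = a2
        logits = a2 @ self.params["out_W"] + self.params["out_b"]
        logits -= logits.max(axis=2, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=2, keepdims=True)
        cache["probs"] = probs
        return (probs[0] if squeeze else probs), cache

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients for all parameters given d(loss)/d(logits)."""
        c = self.config
        grads: dict[str, np.ndarray] = {}
        a2 = cache["a2"]
        B, T, _ = a2.shape
        dlogits = np.asarray(dlogits, self.dtype)
        if dlogits.ndim == 2:
            dlogits = dlogits[None]
        grads["out_W"] = a2.reshape(B * T, -1).T @ dlogits.reshape(B * T, -1)
        grads["out_b"] = dlogits.sum(axis=(0, 1))
        da2 = dlogits @ self.params["out_W"].T
        dz2 = (da2 * (a2 > 0)).astype(self.dtype)
        l2 = cache["l2"]
        grads["dense2_W"] = l2.reshape(B * T, -1).T @ dz2.reshape(B * T, -1)
        grads["dense2_b"] = dz2.sum(axis=(0, 1))
        dl2 = (dz2 @ self.params["dense2_W"].T).astype(self.dtype)
        dl1 = self._bilstm_backward(dl2, 2, cache["bilstm2"], grads)
        da1 = self._bilstm_backward(dl1, 1, cache["bilstm1"], grads)
        a1 = cache["a1"]
        dz1 = (da1 * (a1 > 0)).astype(self.dtype)
        concat = cache["concat"]
        grads["dense1_W"] = concat.reshape(B * T, -1).T @ dz1.reshape(B * T, -1)
        grads["dense1_b"] = dz1.sum(axis=(0, 1))
        dconcat = (dz1 @ self.params["dense1_W"].T).astype(self.dtype)
        F = c.conv_filters
        nfeat = c.n_features
        for bi, k in enumerate(c.conv_windows):
            col, a, bn_cache = cache[f"conv{k}"]
            dbn = dconcat[:, :, bi * F : (bi + 1) * F]
            da, dgamma, dbeta = self._bn_backward(dbn, bn_cache)
            grads[f"bn{k}_gamma"] = dgamma
            grads[f"bn{k}_beta"] = dbeta
            dz = (da * (1 - a * a)).astype(self.dtype)
            grads[f"conv{k}_W"] = col.reshape(B * T, -1).T @ dz.reshape(B * T, -1)
            grads[f"conv{k}_b"] = dz.sum(axis=(0, 1))
        return grads

    def loss_and_grads(self, x, y, w, rng):
        """Weighted categorical cross-entropy and its parameter gradients."""
        probs, cache = self.forward(x, train=True, rng=rng)
        if probs.ndim == 2:
            probs = probs[None]
        y = np.asarray(y, self.dtype)
        w = np.asarray(w, self.dtype)
        if y.ndim == 2:
            y = y[None]
        if w.ndim == 1:
            w = w[None]
        wsum = float(w.sum())
        if wsum == 0:
            raise ValueError("all-zero loss weights")
        eps = 1e-9
        loss = float(-(w * (y * np.log(probs + eps)).sum(axis=2)).sum() / wsum)
        dlogits = ((probs - y) * w[:, :, None] / wsum).astype(self.dtype)
        grads = self.backward(cache, dlogits)
        return loss, grads, probs


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0, dtype=np.float32) -> SequenceClassifierNet:
    """Construct the network (weights initialized from ``seed``)."""
    return SequenceClassifierNet(config, seed=seed, dtype=dtype)


# --------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-7
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            params[k] -= (lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)).astype(np.float32)


def prepare_sample(encoded: EncodedSample, labels4: str) -> dict:
    """Pack an encoded sample with aligned targets and loss weights.

    Targets are one-hot over (E, H, I, C); weights are 0 on padding,
    ``class_weight_pi`` is applied at training time on 'I' positions.
    """
    L = int(encoded.mask.sum())
    if len(labels4) != L:
        raise ValueError(f"labels length {len(labels4)} != sequence length {L}")
    y = np.zeros((MAX_LEN, 4), np.float32)
    w = np.zeros(MAX_LEN, np.float32)
    is_pi = np.zeros(MAX_LEN, bool)
    off = encoded.pad_offset
    for i, lab in enumerate(labels4):
        y[off + i, _CLS_IDX[lab]] = 1.0
        w[off + i] = 1.0
        is_pi[off + i] = lab == "I"
    return {
        "x": encoded.matrix.astype(np.float32),
        "y": y,
        "w": w,
        "mask": encoded.mask.copy(),
        "is_pi": is_pi,
        "labels4": labels4,
    }


def _pack_batch(samples: Sequence[dict], class_weight_pi: float):
    """Crop each sample to its real rows and pad to the batch maximum.

    Zero-weight padding makes this equivalent to training on the full
    700-row frames, at a fraction of the recurrent-layer cost.
    """
    lengths = [int(s["mask"].sum()) for s in samples]
    Tmax = max(lengths)
    B = len(samples)
    nfeat = samples[0]["x"].shape[1]
    x = np.zeros((B, Tmax, nfeat), np.float32)
    y = np.zeros((B, Tmax, 4), np.float32)
    w = np.zeros((B, Tmax), np.float32)
    for bi, (s, L) in enumerate(zip(samples, lengths)):
        rows = s["mask"]
        x[bi, :L] = s["x"][rows]
        y[bi, :L] = s["y"][rows]
        w[bi, :L] = s["w"][rows] * np.where(s["is_pi"][rows], class_weight_pi, 1.0)
    return x, y, w


def _pi_f1(model: SequenceClassifierNet, samples: Sequence[dict], batch_size: int = 16) -> float:
    """F1 of the pi class over all masked residues (inference mode)."""
    tp = fp = fn = 0
    for start in range(0, len(samples), batch_size):
        batch = samples[start : start + batch_size]
        x, y, w = _pack_batch(batch, 1.0)
        probs, _ = model.forward(x, train=False)
        real = w > 0
        pred_pi = (probs.argmax(axis=2) == _CLS_IDX["I"]) & real
        true_pi = (y.argmax(axis=2) == _CLS_IDX["I"]) & real
        tp += int(np.sum(pred_pi & true_pi))
        fp += int(np.sum(pred_pi & ~true_pi))
        fn += int(np.sum(~pred_pi & true_pi))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    sens = tp / (tp + fn)
    return f1(prec, sens)


def train_fold(
    model: SequenceClassifierNet,
    train_samples: Sequence[dict],
    val_samples: Sequence[dict],
    config: Optional[ModelConfig] = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict]:
    """Train one cross-validation fold and return the best-epoch weights.

    After each epoch the pi-class F1 on the validation set is computed and
    the weights of the best epoch are returned together with the history.
    """
    config = config or model.config
    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, config.lr)
    if val_samples and not any(s["is_pi"].any() for s in val_samples):
        warnings.warn("validation set contains no pi-helical residues; F1 defined as 0")
    history = {"loss": [], "val_pi_f1": []}
    best_f1 = -1.0
    best_weights = model.get_weights()
    order = np.arange(len(train_samples))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            x, y, w = _pack_batch(batch, config.class_weight_pi)
            loss, grads, _ = model.loss_and_grads(x, y, w, rng)
            opt.step(model.params, grads)
            losses.append(loss)
        val_f1 = _pi_f1(model, val_samples) if val_samples else _pi_f1(model, train_samples)
        history["loss"].append(float(np.mean(losses)))
        history["val_pi_f1"].append(val_f1)
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_weights = model.get_weights()
    return best_weights, history


def make_folds(samples: Sequence[dict], n_folds: int, seed: int = 0) -> list[list[int]]:
    """Equally-sized folds balanced in per-fold pi-residue totals.

    Sequences are assigned greedily (largest pi count first, random
    tie-breaking) to the fold with the smallest running pi total among the
    folds that still have capacity; fold sizes differ by at most one.
    """
    n = len(samples)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} sequences, got {n}")
    rng = np.random.default_rng(seed)
    pi_counts = np.array([int(s["is_pi"].sum()) for s in samples])
    order = np.lexsort((rng.random(n), -pi_counts))
    cap = [n // n_folds + (1 if i < n % n_folds else 0) for i in range(n_folds)]
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    totals = np.zeros(n_folds)
    for idx in order:
        open_folds = [i for i in range(n_folds) if len(folds[i]) < cap[i]]
        target = min(open_folds, key=lambda i: (totals[i], len(folds[i])))
        folds[target].append(int(idx))
        totals[target] += pi_counts[idx]
    return folds


def cv_train(
    samples: Sequence[dict],
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> list[dict[str, np.ndarray]]:
    """Cross-validated training: one selected weight set per fold."""
    folds = make_folds(samples, config.folds, seed)
    weight_sets = []
    for fi, val_idx in enumerate(folds):
        val = [samples[i] for i in val_idx]
        train = [samples[i] for f2, fold in enumerate(folds) if f2 != fi for i in fold]
        model = build_model(config, seed=seed + fi)
        weights, _ = train_fold(model, train, val, config, seed=seed * 1000 + fi)
        weight_sets.append(weights)
    return weight_sets


def save_weights(weights: dict[str, np.ndarray], path) -> None:
    """Save a weight set as an ``.npz`` checkpoint."""
    np.savez(path, **weights)


def load_weights(path) -> dict[str, np.ndarray]:
    """Load a weight set saved by :func:`save_weights`."""
    with np.load(path) as data:
        return {k: data[k].copy() for k in data.files}


def ensemble_predict(
    weight_sets: Sequence[dict[str, np.ndarray]],
    encoded: EncodedSample,
    config: ModelConfig = ModelConfig(),
) -> PredictionResult:
    """Average member probabilities and call the argmax label per residue.

    Pad rows are stripped; ties in the argmax resolve to the first class in
    (E, H, I, C) order.
    """
    if not weight_sets:
        raise ValueError("need at least one weight set")
    model = build_model(config)
    x = encoded.matrix[encoded.mask].astype(np.float32)
    acc = None
    for weights in weight_sets:
        model.set_weights(weights)
        probs, _ = model.forward(x, train=False)
        acc = probs if acc is None else acc + probs
    probs = acc / len(weight_sets)
    labels = "".join(CLASSES[i] for i in probs.argmax(axis=1))
    return PredictionResult(probabilities=probs, labels4=labels)
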
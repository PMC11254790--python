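"""Compact two-convolution 1D network for closed-set subject identification.

Architecture: conv(16 kernels, size 3) + ReLU → max-pool(2) → conv(32, 3)
+ ReLU → max-pool(2) → flatten → dense(100) + ReLU → dropout(0.2) →
dense(n_classes) + softmax.  Trained with Adam (lr 0.001), batch size 32,
categorical cross-entropy, up to 500 epochs with early stopping on
validation loss and best-weights restoration.

The network is implemented directly in numpy — forward pass, analytic
backpropagation and the Adam update — which keeps it dependency-free,
fully seeded and bit-reproducible on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import BeatDataset

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedClassifier",
    "build_model",
    "count_parameters",
    "train",
]


@dataclass(frozen=True)
class ModelSpec:
    """Hyper-parameters of the two-conv architecture."""

    input_len: int = 150
    conv1_kernels: int = 16
    conv2_kernels: int = 32
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 100
    dropout_rate: float = 0.2
    n_classes: int = 2
    padding: str = "valid"  # or "same"
    per_beat_zscore: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        for v in (self.input_len, self.conv1_kernels, self.conv2_kernels,
                  self.kernel_size, self.pool_size, self.dense_units):
            if v < 1:
                raise ValueError("all size parameters must be positive")

    def feature_lengths(self) -> list[int]:
        """Sequence lengths after conv1, pool1, conv2, pool2."""
        def conv_out(n: int) -> int:
            if self.padding == "valid":
                out = n - self.kernel_size + 1
            else:
                out = n
            if out < 1:
                raise ValueError(
                    f"input_len {self.input_len} too short for two conv+pool stages"
                )
            return out

        l1 = conv_out(self.input_len)
        p1 = l1 // self.pool_size
        if p1 < 1:
            raise ValueError("input too short to survive pooling")
        l2 = conv_out(p1)
        p2 = l2 // self.pool_size
        if p2 < 1:
            raise ValueError("input too short to survive pooling")
        return [l1, p1, l2, p2]

    @property
    def flatten_width(self) -> int:
        return self.feature_lengths()[-1] * self.conv2_kernels


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) sliding windows."""
    B, L, C = x.shape
    Lo = L - k + 1
    return np.concatenate([x[:, j:j + Lo, :] for j in range(k)], axis=2)


class _Network:
    """Weights and forward/backward passes; private to this module."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        spec.feature_lengths()  # validates the geometry
        k, c1, c2 = spec.kernel_size, spec.conv1_kernels, spec.conv2_kernels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {
            "W1": _glorot(rng, (k * 1, c1), k * 1, c1),
            "b1": np.zeros(c1),
            "W2": _glorot(rng, (k * c1, c2), k * c1, c2),
            "b2": np.zeros(c2),
            "W3": _glorot(rng, (spec.flatten_width, spec.dense_units),
                          spec.flatten_width, spec.dense_units),
            "b3": np.zeros(spec.dense_units),
            "W4": _glorot(rng, (spec.dense_units, spec.n_classes),
                          spec.dense_units, spec.n_classes),
            "b4": np.zeros(spec.n_classes),
        }

    # -- layer helpers ------------------------------------------------------

    def _conv(self, x: np.ndarray, W: np.ndarray, b: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
        k = self.spec.kernel_size
        if self.spec.padding == "same":
            pad = (k - 1) // 2, k - 1 - (k - 1) // 2
            x = np.pad(x, ((0, 0), pad, (0, 0)))
        cols = _im2col(x, k)
        return cols @ W + b, cols

    def _pool(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        p = self.spec.pool_size
        B, L, C = x.shape
        Lo = L // p
        xt = x[:, : Lo * p, :].reshape(B, Lo, p, C)
        amax = np.argmax(xt, axis=2)
        return np.take_along_axis(xt, amax[:, :, None, :], axis=2)[:, :, 0, :], amax, L

    def forward(self, X: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None) -> dict:
        """X: (B, input_len) beat matrix -> cache with probabilities."""
        spec = self.spec
        p = self.params
        x0 = X[:, :, None]
        z1, cols1 = self._conv(x0, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        m1, amax1, L1 = self._pool(a1)
        z2, cols2 = self._conv(m1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        m2, amax2, L2 = self._pool(a2)
        flat = m2.reshape(X.shape[0], -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        if train and spec.dropout_rate > 0:
            mask = (dropout_rng.random(a3.shape) >= spec.dropout_rate) / (
                1.0 - spec.dropout_rate
            )
            d3 = a3 * mask
        else:
            mask = None
            d3 = a3
        z4 = d3 @ p["W4"] + p["b4"]
        z4 = z4 - z4.max(axis=1, keepdims=True)
        e = np.exp(z4)
        probs = e / e.sum(axis=1, keepdims=True)
        return {
            "x0": x0, "cols1": cols1, "z1": z1, "amax1": amax1, "L1": L1,
            "m1": m1, "cols2": cols2, "z2": z2, "amax2": amax2, "L2": L2,
            "flat": flat, "z3": z3, "mask": mask, "d3": d3, "probs": probs,
        }

    def _unpool(self, g: np.ndarray, amax: np.ndarray, L: int) -> np.ndarray:
        p = self.spec.pool_size
        B, Lo, C = g.shape
        out = np.zeros((B, Lo, p, C))
        np.put_along_axis(out, amax[:, :, None, :], g[:, :, None, :], axis=2)
        out = out.reshape(B, Lo * p, C)
        if Lo * p < L:
            out = np.pad(out, ((0, 0), (0, L - Lo * p), (0, 0)))
        return out

    def _conv_backward(self, g: np.ndarray, cols: np.ndarray, W: np.ndarray,
                       in_shape: tuple[int, int, int]
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        B, Lo, _ = g.shape
        kC = W.shape[0]
        gW = cols.reshape(B * Lo, kC).T @ g.reshape(B * Lo, -1)
        gb = g.sum(axis=(0, 1))
        dcols = g @ W.T  # (B, Lo, k*C)
        k = self.spec.kernel_size
        C = in_shape[2]
        if self.spec.padding == "same":
            pad_l = (k - 1) // 2
            padded = np.zeros((B, in_shape[1] + k - 1, C))
        else:
            pad_l = 0
            padded = np.zeros(in_shape)
        for j in range(k):
            padded[:, j:j + Lo, :] += dcols[:, :, j * C:(j + 1) * C]
        if self.spec.padding == "same":
            dx = padded[:, pad_l:pad_l + in_shape[1], :]
        else:
            dx = padded
        return dx, gW, gb

    def backward(self, cache: dict, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean categorical cross-entropy w.r.t. all weights."""
        p = self.params
        B = Y.shape[0]
        g4 = (cache["probs"] - Y) / B
        gW4 = cache["d3"].T @ g4
        gb4 = g4.sum(axis=0)
        g3 = g4 @ p["W4"].T
        if cache["mask"] is not None:
            g3 = g3 * cache["mask"]
        g3 = g3 * (cache["z3"] > 0)
        gW3 = cache["flat"].T @ g3
        gb3 = g3.sum(axis=0)
        gflat = g3 @ p["W3"].T
        gm2 = gflat.reshape(cache["x0"].shape[0], -1, self.spec.conv2_kernels)
        ga2 = self._unpool(gm2, cache["amax2"], cache["L2"])
        gz2 = ga2 * (cache["z2"] > 0)
        gm1, gW2, gb2 = self._conv_backward(
            gz2, cache["cols2"], p["W2"], cache["m1"].shape
        )
        ga1 = self._unpool(gm1, cache["amax1"], cache["L1"])
        gz1 = ga1 * (cache["z1"] > 0)
        _, gW1, gb1 = self._conv_backward(
            gz1, cache["cols1"], p["W1"], cache["x0"].shape
        )
        return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
                "W3": gW3, "b3": gb3, "W4": gW4, "b4": gb4}

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in snap.items()}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0) -> _Network:
    """Instantiate the network with seeded Glorot-uniform weights."""
    return _Network(spec, seed=seed)


def layer_summary(model: _Network) -> list[tuple[str, dict]]:
    """Inspectable layer sequence with the shapes the spec implies."""
    s = model.spec
    l1, p1, l2, p2 = s.feature_lengths()
    return [
        ("conv1d", {"kernels": s.conv1_kernels, "kernel_size": s.kernel_size,
                    "activation": "relu", "out_len": l1}),
        ("maxpool1d", {"pool_size": s.pool_size, "out_len": p1}),
        ("conv1d", {"kernels": s.conv2_kernels, "kernel_size": s.kernel_size,
                    "activation": "relu", "out_len": l2}),
        ("maxpool1d", {"pool_size": s.pool_size, "out_len": p2}),
        ("flatten", {"width": s.flatten_width}),
        ("dense", {"units": s.dense_units, "activation": "relu"}),
        ("dropout", {"rate": s.dropout_rate}),
        ("dense", {"units": s.n_classes, "activation": "softmax"}),
    ]


def count_parameters(model: _Network) -> int:
    """Total trainable scalar parameters."""
    return int(sum(v.size for v in model.params.values()))


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def _one_hot(labels: np.ndarray, label_order: list[str]) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(label_order)}
    Y = np.zeros((labels.size, len(label_order)))
    for i, lab in enumerate(labels):
        Y[i, index[str(lab)]] = 1.0
    return Y


@dataclass
class TrainedClassifier:
    """A fitted network plus its label order and training history."""

    spec: ModelSpec
    network: _Network
    label_order: list[str]
    history: dict[str, list[float]] = field(default_factory=dict)

    def save(self, directory) -> None:
        """Persist spec, label order and history as JSON, weights as npz."""
        import dataclasses
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "spec.json").write_text(
            json.dumps(dataclasses.asdict(self.spec), indent=2)
        )
        (directory / "label_order.json").write_text(json.dumps(self.label_order))
        (directory / "history.json").write_text(json.dumps(self.history))
        np.savez(directory / "weights.npz", **self.network.params)

    @classmethod
    def load(cls, directory) -> "TrainedClassifier":
        import json
        from pathlib import Path

        directory = Path(directory)
        spec = ModelSpec(**json.loads((directory / "spec.json").read_text()))
        net = _Network(spec, seed=0)
        with np.load(directory / "weights.npz") as data:
            net.params = {k: data[k].copy() for k in data.files}
        return cls(
            spec=spec,
            network=net,
            label_order=json.loads((directory / "label_order.json").read_text()),
            history=json.loads((directory / "history.json").read_text()),
        )

    def _prep(self, beats: np.ndarray) -> np.ndarray:
        X = np.asarray(beats, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.input_len:
            raise ValueError(
                f"beat vectors must have length {self.spec.input_len}, got {X.shape[1]}"
            )
        return _zscore(X) if self.spec.per_beat_zscore else X

    def predict_proba(self, beats: np.ndarray) -> np.ndarray:
        X = self._prep(beats)
        return self.network.forward(X, train=False)["probs"]

    def predict(self, beats: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(beats)
        idx = np.argmax(probs, axis=1)  # ties -> lowest class index
        return np.array([self.label_order[i] for i in idx], dtype=object)


def _loss_acc(net: _Network, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    probs = net.forward(X, train=False)["probs"]
    eps = 1e-12
    loss = float(-np.mean(np.sum(Y * np.log(probs + eps), axis=1)))
    acc = float(np.mean(np.argmax(probs, 1) == np.argmax(Y, 1)))
    return loss, acc


def train(
    model: _Network,
    train_ds: BeatDataset,
    val_ds: BeatDataset,
    cfg: TrainConfig | None = None,
) -> TrainedClassifier:
    """Fit the network on a training split with early stopping.

    Label order is the sorted training label set; a validation label absent
    from it violates the closed-set contract and raises.  The weights of the
    best validation-loss epoch are restored before returning.
    """
    cfg = cfg or TrainConfig()
    spec = model.spec
    label_order = train_ds.classes
    if len(label_order) != spec.n_classes:
        raise ValueError(
            f"model built for {spec.n_classes} classes but training set has "
            f"{len(label_order)}"
        )
    extra = set(map(str, val_ds.labels)) - set(label_order)
    if extra:
        raise ValueError(f"validation labels not present in training set: {sorted(extra)}")

    Xtr = np.asarray(train_ds.beats, dtype=float)
    Xva = np.asarray(val_ds.beats, dtype=float)
    if spec.per_beat_zscore:
        Xtr, Xva = _zscore(Xtr), _zscore(Xva)
    Ytr = _one_hot(train_ds.labels, label_order)
    Yva = _one_hot(val_ds.labels, label_order)

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate)
    history: dict[str, list[float]] = {
        "loss": [], "acc": [], "val_loss": [], "val_acc": []
    }
    best_loss = np.inf
    best_snap = model.snapshot()
    since_best = 0
    n = Xtr.shape[0]
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            cache = model.forward(Xtr[idx], train=True, dropout_rng=rng)
            grads = model.backward(cache, Ytr[idx])
            opt.step(model.params, grads)
        tr_loss, tr_acc = _loss_acc(model, Xtr, Ytr)
        va_loss, va_acc = _loss_acc(model, Xva, Yva)
        history["loss"].append(tr_loss)
        history["acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        if va_loss < best_loss:
            best_loss = va_loss
            best_snap = model.snapshot()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.restore(best_snap)
    return TrainedClassifier(
        spec=spec, network=model, label_order=label_order, history=history
    )
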
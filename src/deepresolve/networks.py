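"""Small convolutional networks over one-hot DNA, plus the feature-space contract.

The architectures interpreted here are deliberately tiny — one convolutional
layer (each filter a candidate motif detector), max-pooling, one fully
connected hidden layer and sigmoid task outputs — so the networks are
implemented directly in NumPy: im2col convolution, ReLU, non-overlapping
local (or global) max-pooling, dense head, binary cross-entropy with Adam.
Everything is float32 and seeded, so training is bit-reproducible on one
machine.

:class:`FeatureSpaceHandle` is the contract the interpretation engine needs:
forward scores and analytic gradients with respect to a free-valued
intermediate feature map ``H`` of shape (K, W), where K is the channel
(filter) count and W the pooled spatial width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ArchSpec:
    """Architecture: conv(n_filters x filter_len) -> pool -> FC -> sigmoid(s)."""

    n_filters: int = 32
    filter_len: int = 8
    pool: str = "local"          # "local" (non-overlapping, width=stride) or "global"
    pool_stride: int = 4
    fc_units: int = 64
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if min(self.n_filters, self.filter_len, self.fc_units, self.n_outputs) < 1:
            raise ValueError("all architecture counts must be >= 1")
        if self.pool not in ("local", "global"):
            raise ValueError(f"unknown pooling {self.pool!r}")

    def conv_positions(self, seq_len: int) -> int:
        if self.filter_len > seq_len:
            raise ValueError(
                f"filter_len {self.filter_len} exceeds sequence length {seq_len}")
        return seq_len - self.filter_len + 1

    def pooled_width(self, seq_len: int) -> int:
        """Spatial width W of the post-pooling feature map."""
        if self.pool == "global":
            return 1
        w = self.conv_positions(seq_len) // self.pool_stride
        if w < 1:
            raise ValueError(
                f"pool stride {self.pool_stride} incompatible with length {seq_len}")
        return w


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ConvNet:
    """A trainable one-conv-layer network over 4xL one-hot inputs.

    Parameters are plain float32 arrays:
    ``Wc`` (K, 4, F) conv filters, ``bc`` (K,), ``W2`` (W*K, fc) dense,
    ``b2``, ``W3`` (fc, C) output, ``b3``. The flattened feature-map order is
    spatial-major (W, K), fixed so the feature-space handle can map a (K, W)
    map onto the dense head.
    """

    def __init__(self, arch: ArchSpec, seq_len: int, seed: int = 0):
        self.arch = arch
        self.seq_len = seq_len
        self.W = arch.pooled_width(seq_len)
        self.K = arch.n_filters
        rng = np.random.default_rng(seed)
        F, K, D, H, C = (arch.filter_len, arch.n_filters,
                         self.W * arch.n_filters, arch.fc_units, arch.n_outputs)
        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)
        self.params = {
            "Wc": he((K, 4, F), 4 * F), "bc": np.zeros(K, dtype=np.float32),
            "W2": he((D, H), D), "b2": np.zeros(H, dtype=np.float32),
            "W3": he((H, C), H), "b3": np.zeros(C, dtype=np.float32),
        }
        self.training_meta: dict = {"seed": seed}

    # ---------------- forward passes -----------------

    def _conv_relu(self, X: np.ndarray) -> np.ndarray:
        """(N, 4, L) one-hot -> (N, P, K) post-ReLU conv activations."""
        F = self.arch.filter_len
        cols = sliding_window_view(X, F, axis=2)          # (N, 4, P, F)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3))  # (N, P, 4, F)
        N, P = cols.shape[:2]
        Wc = self.params["Wc"].reshape(self.K, -1)        # (K, 4F)
        Z = cols.reshape(N, P, -1) @ Wc.T + self.params["bc"]
        self._cache_cols = cols.reshape(N, P, -1)
        self._cache_Z = Z
        return _relu(Z)

    def _pool(self, A: np.ndarray) -> np.ndarray:
        """(N, P, K) -> (N, W, K) max pool; stores argmax for backprop."""
        if self.arch.pool == "global":
            self._cache_pool_arg = np.argmax(A, axis=1)   # (N, K)
            return A.max(axis=1, keepdims=True)
        s = self.arch.pool_stride
        N, P, K = A.shape
        w = self.W
        Aw = A[:, : w * s].reshape(N, w, s, K)
        self._cache_pool_arg = np.argmax(Aw, axis=2)      # (N, W, K)
        return Aw.max(axis=2)

    def pooled_activations(self, X: np.ndarray,
                           batch_size: int = 2048) -> np.ndarray:
        """Feature maps of a batch: (N, K, W) post-pooling activations."""
        out = []
        for i in range(0, X.shape[0], batch_size):
            pooled = self._pool(self._conv_relu(X[i: i + batch_size]))
            out.append(pooled.transpose(0, 2, 1))
        return np.concatenate(out, axis=0)

    def head_scores(self, flat: np.ndarray, dropout: float = 0.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
        """Dense head on flattened (N, W*K) feature maps -> (N, C) logits.

        ``dropout`` applies inverted dropout to the hidden layer (training
        only; inference passes 0).
        """
        z = flat @ self.params["W2"] + self.params["b2"]
        h = _relu(z)
        if dropout > 0.0:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
            self._cache_mask = mask.astype(np.float32)
        else:
            self._cache_mask = None
        self._cache_z2 = z
        self._cache_h = h
        self._cache_flat = flat
        return h @ self.params["W3"] + self.params["b3"]

    def forward(self, X: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Pre-sigmoid class scores S for a one-hot batch, shape (N, C)."""
        pooled = self._pool(self._conv_relu(X))           # (N, W, K)
        self._cache_pooled = pooled
        return self.head_scores(pooled.reshape(X.shape[0], -1),
                                dropout=dropout, rng=rng)

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = [
            _sigmoid(self.forward(X[i: i + batch_size]))
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    # ---------------- backward -----------------

    def _backward(self, X: np.ndarray, dS: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss given dLoss/dScores (N, C)."""
        p = self.params
        h, flat = self._cache_h, self._cache_flat
        g = {}
        g["W3"] = h.T @ dS
        g["b3"] = dS.sum(axis=0)
        dh = dS @ p["W3"].T
        if self._cache_mask is not None:
            dh = dh * self._cache_mask
        dh = dh * (self._cache_z2 > 0)
        g["W2"] = flat.T @ dh
        g["b2"] = dh.sum(axis=0)
        dflat = dh @ p["W2"].T                            # (N, W*K)
        N = X.shape[0]
        dpool = dflat.reshape(N, self.W, self.K)
        # route pooled gradients back to argmax conv positions
        Z = self._cache_Z
        dA = np.zeros_like(Z)                             # (N, P, K)
        if self.arch.pool == "global":
            np.put_along_axis(dA, self._cache_pool_arg[:, None, :],
                              dpool, axis=1)
        else:
            s = self.arch.pool_stride
            arg = self._cache_pool_arg                    # (N, W, K)
            dAw = dA[:, : self.W * s].reshape(N, self.W, s, self.K)
            np.put_along_axis(dAw, arg[:, :, None, :], dpool[:, :, None, :],
                              axis=2)                     # windows disjoint
        dZ = dA * (Z > 0)                                 # (N, P, K)
        cols = self._cache_cols                           # (N, P, 4F)
        P = Z.shape[1]
        g["Wc"] = (dZ.reshape(N * P, self.K).T
                   @ cols.reshape(N * P, -1)).reshape(p["Wc"].shape)
        g["bc"] = dZ.sum(axis=(0, 1))
        return g

    # ---------------- persistence -----------------

    def conv_filters(self) -> np.ndarray:
        """The learned filters as an (n_filters, 4, filter_len) array."""
        return self.params["Wc"].copy()

    def save(self, path) -> None:
        np.savez(str(path), seq_len=self.seq_len, **self.params)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"arch": asdict(self.arch), "seq_len": self.seq_len,
                       "training_meta": self.training_meta}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ConvNet":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        model = cls(ArchSpec(**meta["arch"]), meta["seq_len"])
        data = np.load(str(path))
        for k in model.params:
            model.params[k] = data[k]
        model.training_meta = meta.get("training_meta", {})
        return model


def build_model(arch: ArchSpec, seq_len: int, seed: int = 0) -> ConvNet:
    """Deterministically initialize an untrained network for *seq_len* inputs."""
    return ConvNet(arch, seq_len, seed=seed)


@dataclass
class TrainingResult:
    """A trained network with its held-out evaluation."""

    model: ConvNet
    auc: np.ndarray              # per-output held-out AUC
    losses: list = field(default_factory=list)
    test_idx: np.ndarray | None = None

    def summary(self) -> str:
        aucs = ", ".join(f"{a:.3f}" for a in np.atleast_1d(self.auc))
        a = self.model.arch
        return (f"ConvNet({a.n_filters}x{a.filter_len}bp, pool={a.pool}, "
                f"fc={a.fc_units}, outputs={a.n_outputs}) "
                f"held-out AUC: {aucs}")


def _bce_grad(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over the batch and its score gradient."""
    p = _sigmoid(scores)
    eps = 1e-7
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    return float(loss), (p - y) / scores.size


def train(model: ConvNet, data, holdout_frac: float = 0.2, epochs: int = 10,
          batch_size: int = 128, lr: float = 1e-3, dropout: float = 0.5,
          seed: int = 0, verbose: bool = False) -> TrainingResult:
    """Train with Adam on binary cross-entropy; report held-out per-class AUC.

    The train/test split is deterministic in *seed*. Hidden-layer dropout
    (default 0.5) regularizes against memorization, which this benchmark's
    dense head is otherwise prone to. Raises if any held-out label column is
    single-class (its AUC would be undefined).
    """
    X = data.one_hot_matrix()
    y = data.labels.astype(np.float32)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if y.shape[1] != model.arch.n_outputs:
        raise ValueError(
            f"labels have {y.shape[1]} columns, model has {model.arch.n_outputs}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    n_test = int(round(holdout_frac * X.shape[0]))
    test_idx, train_idx = order[:n_test], order[n_test:]
    y_test = y[test_idx]
    if n_test and any(len(np.unique(y_test[:, c])) < 2 for c in range(y.shape[1])):
        raise ValueError("held-out split is single-class for some output; "
                         "AUC undefined — enlarge the dataset or holdout")

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    b1, b2m, eps = 0.9, 0.999, 1e-8
    t = 0
    losses = []
    for epoch in range(epochs):
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(perm), batch_size):
            idx = perm[i: i + batch_size]
            scores = model.forward(X[idx], dropout=dropout, rng=rng)
            loss, dS = _bce_grad(scores, y[idx])
            grads = model._backward(X[idx], dS)
            t += 1
            for k, gk in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * gk
                v[k] = b2m * v[k] + (1 - b2m) * gk * gk
                mhat = m[k] / (1 - b1 ** t)
                vhat = v[k] / (1 - b2m ** t)
                model.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs} loss={losses[-1]:.4f}")

    if n_test:
        p = model.predict_proba(X[test_idx])
        auc = np.array([roc_auc_score(y_test[:, c], p[:, c])
                        for c in range(y.shape[1])])
    else:
        auc = np.full(y.shape[1], np.nan)
    model.training_meta.update({"train_seed": seed, "epochs": epochs,
                                "auc": [float(a) for a in auc]})
    return TrainingResult(model=model, auc=auc, losses=losses, test_idx=test_idx)


class FeatureSpaceHandle:
    """Scores and gradients as functions of a free (K, W) feature map.

    ``H`` replaces the post-pooling activations; only the dense head is
    evaluated, so gradients are analytic (ReLU subgradient at the hidden
    layer). ``H`` is unconstrained real-valued even though actual pooled
    activations are nonnegative — negative entries are meaningful to the
    interpretation (features whose presence argues *against* a class).
    """

    LAYERS = ("post_pool",)

    def __init__(self, model: ConvNet, layer: str = "post_pool"):
        if layer not in self.LAYERS:
            raise ValueError(
                f"unknown layer {layer!r}; available: {list(self.LAYERS)}")
        self.model = model
        self.layer = layer
        self.K = model.K
        self.W = model.W
        self.n_outputs = model.arch.n_outputs

    def _flatten(self, H: np.ndarray) -> np.ndarray:
        H = np.asarray(H, dtype=np.float64)
        if H.shape != (self.K, self.W):
            raise ValueError(f"H must have shape {(self.K, self.W)}")
        return H.T.reshape(1, -1)          # spatial-major, matching training

    def forward_from(self, H: np.ndarray) -> np.ndarray:
        """All pre-sigmoid class scores for feature map ``H``; shape (C,)."""
        p = self.model.params
        h = _relu(self._flatten(H) @ p["W2"] + p["b2"])
        return (h @ p["W3"] + p["b3"])[0]

    def score(self, H: np.ndarray, c: int) -> float:
        return float(self.forward_from(H)[c])

    def grad(self, H: np.ndarray, c: int) -> np.ndarray:
        """dS_c/dH, shape (K, W)."""
        p = self.model.params
        flat = self._flatten(H)
        h = _relu(flat @ p["W2"] + p["b2"])
        dh = p["W3"][:, c] * (h[0] > 0)
        dflat = p["W2"] @ dh                              # (W*K,)
        return dflat.reshape(self.W, self.K).T

    def activation_maps(self, X: np.ndarray) -> np.ndarray:
        """Actual pooled feature maps of inputs X, shape (N, K, W)."""
        return self.model.pooled_activations(X)


def feature_space(model: ConvNet, layer: str = "post_pool") -> FeatureSpaceHandle:
    """Handle onto the layer between pooling and the fully connected head."""
    return FeatureSpaceHandle(model, layer)
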
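"""Graph-convolutional and convolutional classifiers, implemented in numpy.

The graph convolution uses the renormalised propagation operator

    L_sym = D~^{-1/2} (A + I) D~^{-1/2},   D~_ii = sum_j (A + I)_ij,

and the layer rule  X_{k+1} = sigma(L_sym X_k W_k + b_k)  with a per-node,
per-feature bias matrix b_k of shape (m, out). Three architectures are
provided, all trained with categorical cross-entropy:

* ``vn_gcn``    — two graph convolutions (widths 32, 8) on the 73-node
                  virtual-node graph, flatten (584), dense, softmax;
* ``tinas_gcn`` — the same widths on the bare 64-node PLV graph
                  (flatten 512);
* ``cnn_fc``    — 2x2 convolution (1->32 channels), 2x2 max-pool, 2x2
                  depthwise convolution, 2x2 max-pool, flatten (7200),
                  dense, softmax, consuming the 64x64 PLV matrix as an
                  image. The second convolution is depthwise (channel-wise),
                  the only reading under which its parameter count is
                  2*2*32 + 32 = 160.

Hidden layers use a leaky ReLU (slope 0.01). Because the graph models see
only non-negative inputs (operator entries, all-ones features), a plain
ReLU network here has an absorbing all-dead state that one large early
optimiser step can reach; the leak makes that state recoverable without
otherwise changing the architecture.

Models are small enough (<= 0.8 M parameters) that forward, backprop and
Adam are implemented directly on numpy arrays; training is deterministic
for a fixed seed and thread count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedOperator",
    "GraphConvLayer",
    "ModelSpec",
    "TrainConfig",
    "degree_matrix",
    "laplacian",
    "renormalized_operator",
    "gcn_forward",
    "build_model",
    "count_parameters",
    "train",
    "predict",
    "GCNClassifier",
    "CNNFCClassifier",
]

MODEL_NAMES = ("vn_gcn", "tinas_gcn", "cnn_fc")


# ---------------------------------------------------------------- operators


def degree_matrix(A: np.ndarray) -> np.ndarray:
    """Diagonal degree vector D_ii = sum_j A_ij of a square matrix."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return A.sum(axis=1)


def laplacian(A: np.ndarray) -> np.ndarray:
    """Combinatorial graph Laplacian L = D - A."""
    d = degree_matrix(A)
    return np.diag(d) - np.asarray(A, dtype=float)


@dataclass(frozen=True)
class NormalizedOperator:
    """Renormalised propagation operator L_sym = D~^{-1/2}(A+I)D~^{-1/2}."""

    L_sym: np.ndarray

    @property
    def m(self) -> int:
        return self.L_sym.shape[0]


def renormalized_operator(A: np.ndarray) -> NormalizedOperator:
    """Symmetric renormalised operator of a non-negative adjacency.

    Adding the identity before normalising guarantees positive degrees, so
    the operator is defined for any non-negative A (including A = 0, where
    it is the identity). Its spectral radius is at most 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0):
        raise ValueError("adjacency must be non-negative")
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    return NormalizedOperator(L_sym=At / np.sqrt(np.outer(d, d)))


# ----------------------------------------------------------- layer + forward


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, _LEAK * x)


#: Hidden-layer leak. The graph models see only non-negative inputs
#: (operator entries and all-ones features), so a plain ReLU network can be
#: driven into an all-dead, unrecoverable state by one large early update;
#: the small leak keeps gradients flowing.
_LEAK = 0.01

_ACTIVATIONS = {"relu": _relu, "leaky_relu": _leaky_relu, "identity": lambda x: x}


@dataclass(frozen=True)
class GraphConvLayer:
    """One graph-convolution layer: X -> sigma(L_sym X W + b).

    W is (in, out); b is the per-node bias matrix (m, out).
    """

    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    def apply(self, op: NormalizedOperator, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"feature dim {X.shape[1]} does not match W in-dim {self.W.shape[0]}"
            )
        if self.b.shape != (op.m, self.W.shape[1]):
            raise ValueError("bias must be (m, out)")
        return _ACTIVATIONS[self.activation](op.L_sym @ X @ self.W + self.b)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gcn_forward(
    op: NormalizedOperator,
    X: np.ndarray,
    layers: "list[GraphConvLayer]",
    dense_W: np.ndarray,
    dense_b: np.ndarray,
) -> np.ndarray:
    """Reference single-sample forward pass: graph convolutions, flatten,
    dense map to class scores, softmax. Returns the probability vector."""
    H = np.asarray(X, dtype=float)
    for layer in layers:
        H = layer.apply(op, H)
    flat = H.reshape(-1)
    if flat.shape[0] != dense_W.shape[0]:
        raise ValueError(
            f"flatten length {flat.shape[0]} does not match dense in-dim {dense_W.shape[0]}"
        )
    return _softmax(flat @ dense_W + dense_b)


# ------------------------------------------------------------------- models


@dataclass(frozen=True)
class ModelSpec:
    """Named architecture specification.

    ``m`` is the node count for the GCN variants (73 with virtual nodes on
    the full montage, 64 without) or the image side for ``cnn_fc``.
    """

    name: str
    m: int
    n_classes: int = 109
    feature_dim: int = 32
    hidden: tuple = (32, 8)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")


def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(np.float32)


class GCNClassifier:
    """Two graph convolutions -> flatten -> dense -> softmax.

    Consumes precomputed renormalised operators, one (m, m) matrix per
    sample; the node-feature input is the all-ones (m, N) matrix, which is
    exploited analytically in the first layer (L X is constant across
    feature columns).
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.name not in ("vn_gcn", "tinas_gcn"):
            raise ValueError("GCNClassifier builds vn_gcn / tinas_gcn specs")
        self.spec = spec
        rng = np.random.default_rng(seed)
        m, N, (h1, h2), C = spec.m, spec.feature_dim, spec.hidden, spec.n_classes
        # Per-node biases start small but non-zero: the all-ones node features
        # make the pre-bias first-layer output rank one with strictly positive
        # node sums, so zero biases occasionally leave every hidden unit on the
        # dead side of the ReLU and the network can never escape uniform output.
        self.params = {
            "W1": _glorot(rng, (N, h1)),
            "b1": rng.uniform(-0.1, 0.1, (m, h1)).astype(np.float32),
            "W2": _glorot(rng, (h1, h2)),
            "b2": rng.uniform(-0.1, 0.1, (m, h2)).astype(np.float32),
            "Wd": _glorot(rng, (m * h2, C)),
            "bd": np.zeros(C, dtype=np.float32),
        }

    # -- architecture bookkeeping -------------------------------------------
    @property
    def flatten_length(self) -> int:
        return self.spec.m * self.spec.hidden[1]

    def layer_shapes(self) -> dict:
        m, (h1, h2), C = self.spec.m, self.spec.hidden, self.spec.n_classes
        return {
            "graph_conv_1": (m, h1),
            "graph_conv_2": (m, h2),
            "flatten": (m * h2, 1),
            "dense": (C, 1),
            "softmax": (C, 1),
        }

    def parameter_breakdown(self) -> dict:
        p = self.params
        return {
            "graph_conv_1": int(p["W1"].size + p["b1"].size),
            "graph_conv_2": int(p["W2"].size + p["b2"].size),
            "dense": int(p["Wd"].size + p["bd"].size),
        }

    # -- compute ------------------------------------------------------------
    def _forward(self, L: np.ndarray, need_cache: bool = False):
        p = self.params
        L = np.ascontiguousarray(L, dtype=p["W1"].dtype)
        S = L.sum(axis=2)  # (B, m): L @ ones has identical columns
        Z1 = S[:, :, None] * p["W1"].sum(axis=0)[None, None, :] + p["b1"]
        H1 = _leaky_relu(Z1)
        M1 = np.matmul(L, H1)  # (B, m, h1)
        Z2 = M1 @ p["W2"] + p["b2"]
        H2 = _leaky_relu(Z2)
        F = H2.reshape(L.shape[0], -1)
        logits = F @ p["Wd"] + p["bd"]
        probs = _softmax(logits)
        if need_cache:
            return probs, (L, S, Z1, H1, M1, Z2, F)
        return probs

    def predict_proba(self, L: np.ndarray) -> np.ndarray:
        return self._forward(L)

    def loss_and_grads(self, L: np.ndarray, y: np.ndarray):
        p = self.params
        B = L.shape[0]
        probs, (L32, S, Z1, H1, M1, Z2, F) = self._forward(L, need_cache=True)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {}
        grads["Wd"] = F.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dH2 = (dlogits @ p["Wd"].T).reshape(Z2.shape)
        dZ2 = dH2 * np.where(Z2 > 0, 1.0, _LEAK)
        grads["b2"] = dZ2.sum(axis=0)
        grads["W2"] = np.einsum("bmf,bmo->fo", M1, dZ2)
        dM1 = dZ2 @ p["W2"].T
        dH1 = np.matmul(L32, dM1)  # L_sym is symmetric
        dZ1 = dH1 * np.where(Z1 > 0, 1.0, _LEAK)
        grads["b1"] = dZ1.sum(axis=0)
        gw1_row = np.einsum("bm,bmo->o", S, dZ1)
        grads["W1"] = np.broadcast_to(gw1_row, p["W1"].shape).copy()
        return loss, grads

    def as_reference_layers(self):
        """Float64 views of the conv layers for the reference forward pass."""
        p = self.params
        return [
            GraphConvLayer(W=p["W1"].astype(float), b=p["b1"].astype(float), activation="leaky_relu"),
            GraphConvLayer(W=p["W2"].astype(float), b=p["b2"].astype(float), activation="leaky_relu"),
        ]


class CNNFCClassifier:
    """CNN on the 64 x 64 PLV matrix treated as a one-channel image."""

    SIDE = 64

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.name != "cnn_fc":
            raise ValueError("CNNFCClassifier builds the cnn_fc spec")
        if spec.m != self.SIDE:
            raise ValueError("cnn_fc consumes a 64 x 64 connectivity image")
        self.spec = spec
        rng = np.random.default_rng(seed)
        C = spec.n_classes
        self.params = {
            "w1": _glorot(rng, (2, 2, 1, 32)).reshape(2, 2, 32),
            "c1": np.zeros(32, dtype=np.float32),
            "w2": _glorot(rng, (2, 2, 32)),
            "c2": np.zeros(32, dtype=np.float32),
            "Wd": _glorot(rng, (7200, C)),
            "bd": np.zeros(C, dtype=np.float32),
        }

    @property
    def flatten_length(self) -> int:
        return 7200

    def layer_shapes(self) -> dict:
        C = self.spec.n_classes
        return {
            "conv_1": (63, 63, 32),
            "pool_1": (31, 31, 32),
            "conv_2": (30, 30, 32),
            "pool_2": (15, 15, 32),
            "flatten": (7200, 1),
            "dense": (C, 1),
            "softmax": (C, 1),
        }

    def parameter_breakdown(self) -> dict:
        p = self.params
        return {
            "conv_1": int(p["w1"].size + p["c1"].size),
            "conv_2": int(p["w2"].size + p["c2"].size),
            "dense": int(p["Wd"].size + p["bd"].size),
        }

    @staticmethod
    def _pool(x: np.ndarray):
        """2x2 max pool, stride 2; odd trailing row/column dropped."""
        B, H, W, C = x.shape
        h, w = H // 2, W // 2
        crop = x[:, : 2 * h, : 2 * w, :].reshape(B, h, 2, w, 2, C)
        pooled = crop.max(axis=(2, 4))
        return pooled, crop

    def _forward(self, x: np.ndarray, need_cache: bool = False):
        p = self.params
        x = np.ascontiguousarray(x, dtype=p["Wd"].dtype)
        B = x.shape[0]
        # conv 1: 2x2, single input channel -> 32 channels, valid, stride 1
        z1 = p["c1"][None, None, None, :] + sum(
            p["w1"][di, dj][None, None, None, :]
            * x[:, di : di + 63, dj : dj + 63, None]
            for di in range(2)
            for dj in range(2)
        )
        h1 = _relu(z1)
        p1, crop1 = self._pool(h1)  # (B,31,31,32)
        # conv 2: depthwise 2x2 over the 32 channels
        z2 = p["c2"][None, None, None, :] + sum(
            p["w2"][di, dj][None, None, None, :] * p1[:, di : di + 30, dj : dj + 30, :]
            for di in range(2)
            for dj in range(2)
        )
        h2 = _relu(z2)
        p2, crop2 = self._pool(h2)  # (B,15,15,32)
        F = p2.reshape(B, -1)
        logits = F @ p["Wd"] + p["bd"]
        probs = _softmax(logits)
        if need_cache:
            return probs, (x, z1, crop1, p1, z2, crop2, p2, F)
        return probs

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x)

    @staticmethod
    def _pool_backward(dpool: np.ndarray, crop: np.ndarray, pooled: np.ndarray, out_hw: tuple):
        """Route gradients to the max positions (ties split the gradient)."""
        B, h, _, w, _, C = crop.shape
        mask = crop == pooled[:, :, None, :, None, :]
        mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        dcrop = mask * dpool[:, :, None, :, None, :]
        dx = np.zeros((B, out_hw[0], out_hw[1], C), dtype=dpool.dtype)
        dx[:, : 2 * h, : 2 * w, :] = dcrop.reshape(B, 2 * h, 2 * w, C)
        return dx

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        p = self.params
        B = x.shape[0]
        probs, (x32, z1, crop1, p1, z2, crop2, p2, F) = self._forward(x, need_cache=True)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {}
        grads["Wd"] = F.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dp2 = (dlogits @ p["Wd"].T).reshape(p2.shape)
        dh2 = self._pool_backward(dp2, crop2, p2, (30, 30))
        dz2 = dh2 * (z2 > 0)
        grads["c2"] = dz2.sum(axis=(0, 1, 2))
        grads["w2"] = np.stack(
            [
                np.stack(
                    [
                        (p1[:, di : di + 30, dj : dj + 30, :] * dz2).sum(axis=(0, 1, 2))
                        for dj in range(2)
                    ]
                )
                for di in range(2)
            ]
        )
        dp1 = np.zeros_like(p1)
        for di in range(2):
            for dj in range(2):
                dp1[:, di : di + 30, dj : dj + 30, :] += dz2 * p["w2"][di, dj][None, None, None, :]
        dh1 = self._pool_backward(dp1, crop1, p1, (63, 63))
        dz1 = dh1 * (z1 > 0)
        grads["c1"] = dz1.sum(axis=(0, 1, 2))
        grads["w1"] = np.stack(
            [
                np.stack(
                    [
                        (x32[:, di : di + 63, dj : dj + 63, None] * dz1).sum(axis=(0, 1, 2))
                        for dj in range(2)
                    ]
                )
                for di in range(2)
            ]
        )
        return loss, grads


def build_model(spec: "ModelSpec | str", n_classes: int = 109, m: "int | None" = None, seed: int = 0):
    """Instantiate one of the three named architectures.

    Accepts a full ModelSpec or just a name; for names, ``m`` defaults to 73
    (vn_gcn: 64 channels + 8 local + 1 global virtual node) or 64.
    """
    if isinstance(spec, str):
        default_m = {"vn_gcn": 73, "tinas_gcn": 64, "cnn_fc": 64}
        if spec not in default_m:
            raise ValueError(f"unknown model {spec!r}")
        spec = ModelSpec(name=spec, m=m if m is not None else default_m[spec], n_classes=n_classes)
    if spec.name == "cnn_fc":
        return CNNFCClassifier(spec, seed=seed)
    return GCNClassifier(spec, seed=seed)


def count_parameters(model) -> int:
    """Exact number of trainable scalars."""
    return int(sum(v.size for v in model.params.values()))


def kilo(count: int) -> float:
    """Parameter count rounded to 0.1 k, the table-reporting convention."""
    return round(count / 1000.0, 1)


# ----------------------------------------------------------------- training


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam on categorical cross-entropy)."""

    learning_rate: float = 3e-3
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def train(model, inputs: np.ndarray, labels: np.ndarray, cfg: TrainConfig) -> dict:
    """Fit a model in place by mini-batch Adam on cross-entropy.

    Returns a history dict with per-epoch mean loss and training accuracy.
    Deterministic for a fixed config seed (single-threaded execution).
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training needs at least two classes")
    if labels.max() >= model.spec.n_classes:
        raise ValueError("label exceeds the model's class count")
    n = inputs.shape[0]
    history = {"loss": [], "accuracy": []}
    if cfg.epochs == 0:
        return history
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, lr=cfg.learning_rate)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        hits = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(inputs[idx], labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at step {opt.t}; lr={cfg.learning_rate}, "
                    f"batch={cfg.batch_size} — inspect inputs/learning rate"
                )
            opt.step(model.params, grads)
            losses.append(loss * idx.size)
            probs = model.predict_proba(inputs[idx])
            hits += int((probs.argmax(axis=1) == labels[idx]).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(hits / n)
    return history


def predict(model, inputs: np.ndarray):
    """Predicted labels and probability vectors for a batch of inputs."""
    probs = model.predict_proba(inputs)
    return probs.argmax(axis=1), probs
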
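"""Graph-convolutional encoding of similarity networks.

A similarity network with weighted adjacency A is propagated through the
symmetric degree-normalized operator

    S = D^{-1/2} A D^{-1/2},      D_ii = sum_j A_ij,

the normalization underlying the symmetric normalized Laplacian
L_sym = I - S.  A GCN layer is H^(l+1) = sigma(S H^(l) W^(l)); the diagonal
of a cosine similarity network already equals 1, so self-loops are built in
and no A + I augmentation is applied.

Because node labels are not available at encoding time, the encoder trains
as a graph autoencoder: an inner-product decoder sigmoid(h_i . h_j) is fit
by mean binary cross-entropy against the adjacency min-max rescaled to
[0, 1].  An ``objective="untrained"`` mode (random fixed weights, pure
propagation) is kept for ablation.  Everything is dense numpy with
full-batch Adam — networks here are small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._errors import DataError
from .networks import SimilarityNetwork

_ACTIVATIONS = ("relu", "identity", "tanh")


@dataclass
class NormalizedOperator:
    """The propagation operator S = D^{-1/2} A D^{-1/2} with its degrees."""

    matrix: np.ndarray
    degrees: np.ndarray

    def __post_init__(self):
        if not np.all(self.degrees > 0):
            raise DataError("non-positive degree in normalized operator")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise DataError("normalized operator not symmetric")

    @property
    def laplacian(self) -> np.ndarray:
        """Symmetric normalized Laplacian L_sym = I - S."""
        return np.eye(self.matrix.shape[0]) - self.matrix


@dataclass
class EmbeddingMatrix:
    """Node embeddings H^(l): one row of coordinates per network node."""

    node_ids: list[str]
    values: np.ndarray
    layer: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.node_ids):
            raise DataError(
                f"embedding shape {self.values.shape} does not match "
                f"{len(self.node_ids)} node ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite embedding values")


@dataclass
class EncoderConfig:
    """Hyperparameters of the network encoder.

    None of these are dictated by the method itself; the defaults are a
    conventional small two-layer GCN.
    """

    hidden_dim: int = 128
    embedding_dim: int = 64
    activation: str = "tanh"
    epochs: int = 200
    learning_rate: float = 0.01
    objective: str = "autoencoder"  # or "untrained"
    init_features: str = "adjacency"  # or "identity"
    seed: int = 0


def degree_vector(net: SimilarityNetwork) -> np.ndarray:
    """Weighted degrees d_i = sum_j A_ij (the diagonal self-similarity counts).

    Raises if any degree is non-positive: the inverse square root in the
    normalization would be undefined.
    """
    deg = net.adjacency.sum(axis=1)
    if np.any(deg <= 0):
        bad = [net.node_ids[i] for i in np.nonzero(deg <= 0)[0]]
        raise DataError(f"non-positive weighted degree for node(s): {bad[:5]}")
    return deg


def normalized_operator(net: SimilarityNetwork) -> NormalizedOperator:
    """S = D^{-1/2} A D^{-1/2}; ``.laplacian`` gives L_sym = I - S."""
    deg = degree_vector(net)
    inv_sqrt = 1.0 / np.sqrt(deg)
    S = net.adjacency * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    return NormalizedOperator(S, deg)


def _activate(x: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "identity":
        return x
    if name == "tanh":
        return np.tanh(x)
    raise DataError(f"unknown activation {name!r}; choose from {_ACTIVATIONS}")


def gcn_layer(
    S: NormalizedOperator | np.ndarray,
    H: EmbeddingMatrix | np.ndarray,
    W: np.ndarray,
    activation: str = "tanh",
) -> np.ndarray | EmbeddingMatrix:
    """One propagation step sigma(S H W).

    Accepts either raw arrays (returns an array) or the wrapped types
    (returns an ``EmbeddingMatrix`` with the layer index incremented).
    """
    S_mat = S.matrix if isinstance(S, NormalizedOperator) else np.asarray(S, float)
    wrapped = isinstance(H, EmbeddingMatrix)
    H_mat = H.values if wrapped else np.asarray(H, float)
    W = np.asarray(W, dtype=float)
    n = S_mat.shape[0]
    if S_mat.shape != (n, n) or H_mat.shape[0] != n or H_mat.shape[1] != W.shape[0]:
        raise DataError(
            f"shape mismatch in GCN layer: S {S_mat.shape}, "
            f"H {H_mat.shape}, W {W.shape}"
        )
    out = _activate(S_mat @ H_mat @ W, activation)
    if wrapped:
        return EmbeddingMatrix(list(H.node_ids), out, layer=H.layer + 1)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GCNEncoder(BaseEstimator, TransformerMixin):
    """Two-layer graph-convolutional autoencoder over a dense adjacency.

    ``fit(A)`` takes the symmetric weighted adjacency matrix itself (the
    graph is the sample), trains the layer weights against the inner-product
    reconstruction of A, and stores per-node embeddings in ``embedding_``.
    ``transform(A)`` re-runs the forward pass with the trained weights.

    Parameters
    ----------
    hidden_dim, embedding_dim : int
        Widths of the hidden and output layers.
    activation : str
        Nonlinearity between layers ("relu", "tanh", "identity"); the output
        layer is always linear so embeddings keep full range.
    epochs, learning_rate : training schedule (full-batch Adam).
    objective : {"autoencoder", "untrained"}
        "untrained" skips optimization: pure propagation with the random
        initial weights.
    init_features : {"adjacency", "identity"}
        Initial node features H^(0): each node's similarity profile (the
        adjacency row) or a one-hot indicator.
    random_state : int
        Seeds weight initialization; fixed seed gives bit-reproducible fits.
    """

    def __init__(
        self,
        hidden_dim: int = 128,
        embedding_dim: int = 64,
        activation: str = "tanh",
        epochs: int = 200,
        learning_rate: float = 0.01,
        objective: str = "autoencoder",
        init_features: str = "adjacency",
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.embedding_dim = embedding_dim
        self.activation = activation
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.objective = objective
        self.init_features = init_features
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _initial_features(self, A: np.ndarray) -> np.ndarray:
        if self.init_features == "adjacency":
            return A.copy()
        if self.init_features == "identity":
            return np.eye(A.shape[0])
        raise DataError(f"unknown init_features {self.init_features!r}")

    def _forward(self, S: np.ndarray, X: np.ndarray):
        SX = S @ X
        pre1 = SX @ self.weights_[0]
        H1 = _activate(pre1, self.activation)
        Z = (S @ H1) @ self.weights_[1]
        return SX, pre1, H1, Z

    def fit(self, A, y=None):
        A = np.asarray(A, dtype=float)
        n = A.shape[0]
        if A.ndim != 2 or A.shape[1] != n:
            raise DataError(f"adjacency must be square, got {A.shape}")
        if n < 2:
            raise DataError("network must have at least 2 nodes")
        if self.objective not in ("autoencoder", "untrained"):
            raise DataError(f"unknown objective {self.objective!r}")
        net = SimilarityNetwork([str(i) for i in range(n)], A)
        S = normalized_operator(net).matrix
        X = self._initial_features(A)

        rng = np.random.default_rng(self.random_state)
        d_in = X.shape[1]
        self.weights_ = [
            _glorot(rng, d_in, self.hidden_dim),
            _glorot(rng, self.hidden_dim, self.embedding_dim),
        ]
        self.operator_ = S
        self.loss_history_: list[float] = []

        if self.objective == "autoencoder" and self.epochs > 0:
            self._train(S, X, A)

        _, _, _, Z = self._forward(S, X)
        self.embedding_ = Z
        self.n_features_in_ = n
        return self

    def _train(self, S: np.ndarray, X: np.ndarray, A: np.ndarray) -> None:
        # reconstruction target: adjacency rescaled to [0, 1]
        lo, hi = A.min(), A.max()
        T = np.full_like(A, 0.5) if hi == lo else (A - lo) / (hi - lo)
        n = A.shape[0]
        lr = self.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m = [np.zeros_like(w) for w in self.weights_]
        v = [np.zeros_like(w) for w in self.weights_]
        for t in range(1, self.epochs + 1):
            SX, pre1, H1, Z = self._forward(S, X)
            logits = Z @ Z.T
            # stable BCE on logits
            loss = float(
                np.mean(np.clip(logits, 0, None) - logits * T
                        + np.log1p(np.exp(-np.abs(logits))))
            )
            if not np.isfinite(loss):
                raise DataError(
                    "GCN training loss became non-finite; "
                    "try a smaller learning rate"
                )
            self.loss_history_.append(loss)
            P = 1.0 / (1.0 + np.exp(-logits))
            G = (P - T) / (n * n)          # symmetric
            dZ = 2.0 * (G @ Z)
            SH1 = S @ H1
            dW1 = SH1.T @ dZ
            dH1 = S @ (dZ @ self.weights_[1].T)
            if self.activation == "relu":
                dpre1 = dH1 * (pre1 > 0)
            elif self.activation == "tanh":
                dpre1 = dH1 * (1.0 - np.tanh(pre1) ** 2)
            else:
                dpre1 = dH1
            dW0 = SX.T @ dpre1
            for i, g in enumerate((dW0, dW1)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                self.weights_[i] -= lr * mhat / (np.sqrt(vhat) + eps)

    def transform(self, A=None) -> np.ndarray:
        """Embeddings for ``A`` under the trained weights (default: the
        fitted graph's stored embeddings)."""
        if not hasattr(self, "weights_"):
            raise DataError("GCNEncoder is not fitted")
        if A is None:
            return self.embedding_
        A = np.asarray(A, dtype=float)
        net = SimilarityNetwork([str(i) for i in range(A.shape[0])], A)
        S = normalized_operator(net).matrix
        X = self._initial_features(A)
        if X.shape[1] != self.weights_[0].shape[0]:
            raise DataError(
                f"feature width {X.shape[1]} does not match fitted input "
                f"width {self.weights_[0].shape[0]}"
            )
        return self._forward(S, X)[3]

    def fit_transform(self, A, y=None) -> np.ndarray:
        return self.fit(A).embedding_


def encode_network(net: SimilarityNetwork, config: EncoderConfig | None = None) -> EmbeddingMatrix:
    """Encode a similarity network into per-node embeddings.

    Thin wrapper building a :class:`GCNEncoder` from ``config`` and running
    it on the network's adjacency; deterministic for a fixed config seed.
    """
    config = config or EncoderConfig()
    enc = GCNEncoder(
        hidden_dim=config.hidden_dim,
        embedding_dim=config.embedding_dim,
        activation=config.activation,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        objective=config.objective,
        init_features=config.init_features,
        random_state=config.seed,
    )
    Z = enc.fit_transform(net.adjacency)
    return EmbeddingMatrix(list(net.node_ids), Z, layer=2)


def write_embeddings(emb: EmbeddingMatrix, path) -> None:
    import pandas as pd

    cols = [f"e{i}" for i in range(emb.values.shape[1])]
    pd.DataFrame(emb.values, index=emb.node_ids, columns=cols).rename_axis(
        "node_id"
    ).to_csv(path, sep="\t", float_format="%.12g")


def read_embeddings(path) -> EmbeddingMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return EmbeddingMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))
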
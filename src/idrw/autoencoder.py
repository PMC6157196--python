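"""Single-hidden-layer tied-weight denoising autoencoder for feature ranking.

The encoder maps a masking-corrupted input x~ to y = sigmoid(W x~ + b); the
decoder reconstructs z = sigmoid(W^T y + b_dec) with the transposed encoder
weights (tied).  Training minimizes the squared reconstruction error
L = ||x - z||^2 / 2 of the *clean* input by plain minibatch SGD.  After
training, each input feature (pathway) is scored by the mean of its encoder
weight column; large-magnitude scores mark features the code layer relies on.

Activities are real-valued rather than confined to [0, 1]; the sigmoid
decoder is kept as the reference formulation, with ``decoder="linear"``
available when faithful reconstruction matters more than ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .ranking import FeatureRanking, RankedFeature

log = logging.getLogger(__name__)


@dataclass
class DAModel:
    W: np.ndarray                 # hidden(p) x input(d)
    b: np.ndarray                 # hidden bias, length p
    b_dec: np.ndarray             # decoder bias, length d
    corruption_rate: float
    decoder: str = "sigmoid"      # {"sigmoid", "linear"}
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        p, d = self.W.shape
        if self.b.shape != (p,) or self.b_dec.shape != (d,):
            raise ValueError("bias shapes inconsistent with W")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0, 1]")
        if self.decoder not in ("sigmoid", "linear"):
            raise ValueError(f"unknown decoder {self.decoder!r}")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_input(self) -> int:
        return self.W.shape[1]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def corrupt(x: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Masking noise: each coordinate is independently zeroed with probability rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("corruption rate must be in [0, 1]")
    if rate == 0.0:
        return np.array(x, dtype=float, copy=True)
    keep = rng.random(np.shape(x)) >= rate
    return np.asarray(x, dtype=float) * keep


def forward(model: DAModel, x_tilde: np.ndarray):
    """Encode/decode a single vector or a (batch, d) matrix; returns (y, z)."""
    x_tilde = np.atleast_2d(np.asarray(x_tilde, dtype=float))
    y = sigmoid(x_tilde @ model.W.T + model.b)
    pre = y @ model.W + model.b_dec
    z = sigmoid(pre) if model.decoder == "sigmoid" else pre
    if x_tilde.shape[0] == 1:
        return y[0], z[0]
    return y, z


def loss_and_grads(model: DAModel, x: np.ndarray, x_tilde: np.ndarray):
    """Mean reconstruction loss over the batch and its analytic gradients.

    Backprop with tied weights: the gradient of W collects both the decoder
    term (through W^T) and the encoder term (through W).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_tilde = np.atleast_2d(np.asarray(x_tilde, dtype=float))
    n = x.shape[0]
    y = sigmoid(x_tilde @ model.W.T + model.b)        # (n, p)
    pre = y @ model.W + model.b_dec                   # (n, d)
    z = sigmoid(pre) if model.decoder == "sigmoid" else pre
    loss = float(((x - z) ** 2).sum(axis=1).mean() / 2.0)

    dz = (z - x)                                      # dL/dz, (n, d)
    if model.decoder == "sigmoid":
        dz = dz * z * (1.0 - z)                       # through decoder sigmoid
    dy = dz @ model.W.T                               # (n, p)
    dh = dy * y * (1.0 - y)                           # through encoder sigmoid
    gW = (dh.T @ x_tilde + y.T @ dz) / n              # tied: encoder + decoder parts
    gb = dh.mean(axis=0)
    gb_dec = dz.mean(axis=0)
    return loss, gW, gb, gb_dec


def init_model(n_input: int, hidden: int, corruption: float, seed: int,
               decoder: str = "sigmoid") -> DAModel:
    """Glorot-uniform weight initialization with a seeded generator."""
    rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (hidden + n_input))
    W = rng.uniform(-limit, limit, size=(hidden, n_input))
    return DAModel(W, np.zeros(hidden), np.zeros(n_input), corruption, decoder)


def train(X: np.ndarray, hidden: int = 200, corruption: float = 0.1,
          lr: float = 0.01, epochs: int = 500, batch_size: int = 32,
          seed: int = 0, decoder: str = "sigmoid") -> DAModel:
    """Train the denoising autoencoder on rows of X (samples x features).

    Deterministic given ``seed``: initialization, shuffling and corruption all
    draw from one seeded generator.  Raises on a non-finite loss.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be samples x features")
    n, d = X.shape
    model = init_model(d, hidden, corruption, seed, decoder)
    rng = np.random.default_rng(seed + 1)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = X[order[start:start + batch_size]]
            x_tilde = corrupt(batch, corruption, rng)
            loss, gW, gb, gb_dec = loss_and_grads(model, batch, x_tilde)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.W -= lr * gW
            model.b -= lr * gb
            model.b_dec -= lr * gb_dec
            epoch_loss += loss * batch.shape[0]
        model.loss_trace.append(epoch_loss / n)
    return model


def rank_by_da(model: DAModel, feature_ids: list[str],
               signed: bool = False) -> FeatureRanking:
    """Rank input features by the mean encoder weight of their input node.

    Default order is descending |mean weight| (magnitude of influence on the
    code layer); ``signed=True`` orders by the raw signed mean instead.  Ties
    break lexicographically by feature id.
    """
    if len(feature_ids) != model.n_input:
        raise ValueError("feature_ids length must equal the model input size")
    scores = model.W.mean(axis=0)
    key = scores if signed else np.abs(scores)
    order = sorted(range(len(feature_ids)), key=lambda j: (-key[j], feature_ids[j]))
    entries = [RankedFeature(feature_ids[j], float(scores[j]), rank)
               for rank, j in enumerate(order, start=1)]
    return FeatureRanking(entries, "da")


def save_model(model: DAModel, prefix) -> None:
    """Write W, b, b_dec as TSVs plus a JSON sidecar of hyperparameters."""
    prefix = str(prefix)
    np.savetxt(prefix + ".W.tsv", model.W, delimiter="\t")
    np.savetxt(prefix + ".b.tsv", model.b, delimiter="\t")
    np.savetxt(prefix + ".b_dec.tsv", model.b_dec, delimiter="\t")
    with open(prefix + ".json", "w") as fh:
        json.dump({"corruption_rate": model.corruption_rate,
                   "decoder": model.decoder,
                   "n_hidden": model.n_hidden,
                   "n_input": model.n_input,
                   "loss_trace": model.loss_trace}, fh, indent=2)


def load_model(prefix) -> DAModel:
    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    W = np.atleast_2d(np.loadtxt(prefix + ".W.tsv", delimiter="\t"))
    b = np.atleast_1d(np.loadtxt(prefix + ".b.tsv", delimiter="\t"))
    b_dec = np.atleast_1d(np.loadtxt(prefix + ".b_dec.tsv", delimiter="\t"))
    return DAModel(W, b, b_dec, meta["corruption_rate"], meta["decoder"],
                   meta.get("loss_trace", []))
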
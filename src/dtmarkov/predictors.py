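"""Covariate-to-score mappings: constant, linear, and neural-network.

Each predictor maps a covariate vector (assumed pre-scaled to [0,1]) to one
pre-link score per competing destination; :func:`dtmarkov.core.link` then
turns the scores into a transition-probability row.  All three families are
trained through the same interface: a list of parameter arrays, a forward
``scores`` pass, and an analytic ``backward`` pass accumulating gradients
with respect to every parameter.

The default network is a single shared-trunk multilayer perceptron with
two hidden layers of 50 units and swish activation, emitting all N
destination scores jointly so the competing transitions of one row are
modeled together.  Fully separate per-destination networks are available
via ``shared_trunk=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .core import ProbabilityRow, link

__all__ = [
    "AnnArchitecture",
    "Predictor",
    "ConstantPredictor",
    "LinearPredictor",
    "NeuralPredictor",
    "make_predictor",
    "predict_row",
    "save_predictor",
    "load_predictor",
]


@dataclass(frozen=True)
class AnnArchitecture:
    """Hidden-layer widths and activation of the neural predictor."""

    hidden_sizes: tuple = (50, 50)
    activation: str = "swish"
    shared_trunk: bool = True

    def __post_init__(self):
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        if self.activation != "swish":
            raise ValueError("only the swish activation is supported")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


def _swish(x):
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s, s


def _swish_grad(z, s):
    # d/dz [z*sigmoid(z)] = sigmoid(z) * (1 + z*(1 - sigmoid(z)))
    return s * (1.0 + z * (1.0 - s))


class Predictor:
    """Base class: a parameterized map from covariates to scores."""

    kind: str

    def __init__(self, n_destinations: int, n_covariates: int):
        if n_destinations < 1:
            raise ValueError("need at least one destination")
        if n_covariates < 0:
            raise ValueError("negative covariate dimension")
        self.n_destinations = int(n_destinations)
        self.n_covariates = int(n_covariates)
        self.params: List[np.ndarray] = []

    # -- parameter plumbing -------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def flat_params(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params])

    def set_flat_params(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.size}")
        if not np.all(np.isfinite(theta)):
            raise ValueError("parameters must be finite")
        pos = 0
        for p in self.params:
            p[...] = theta[pos:pos + p.size].reshape(p.shape)
            pos += p.size

    # -- forward / backward -------------------------------------------------
    def scores(self, X: np.ndarray) -> np.ndarray:
        """Score matrix (n, N) for a batch of covariate rows (n, d)."""
        raise NotImplementedError

    def backward(self, X: np.ndarray, grad_scores: np.ndarray) -> List[np.ndarray]:
        """Gradients of ``sum_i g_i . s_i`` w.r.t. each parameter array,
        where ``grad_scores`` holds the upstream gradients ``g_i``.
        Must be called after ``scores`` on the same batch."""
        raise NotImplementedError


class ConstantPredictor(Predictor):
    """One score per destination, independent of covariates."""

    kind = "constant"

    def __init__(self, n_destinations: int, n_covariates: int = 0):
        super().__init__(n_destinations, n_covariates)
        self.params = [np.zeros(n_destinations)]

    def scores(self, X):
        X = np.asarray(X, dtype=float)
        return np.broadcast_to(self.params[0], (X.shape[0], self.n_destinations)).copy()

    def backward(self, X, grad_scores):
        return [grad_scores.sum(axis=0)]


class LinearPredictor(Predictor):
    """Affine map ``s = x W + b`` with an intercept per destination.

    The intercept makes the constant family a nested special case
    (zero weights), so likelihood-ratio style comparisons are well-posed.
    """

    kind = "linear"

    def __init__(self, n_destinations: int, n_covariates: int):
        super().__init__(n_destinations, n_covariates)
        self.params = [np.zeros((n_covariates, n_destinations)), np.zeros(n_destinations)]

    def scores(self, X):
        X = np.asarray(X, dtype=float)
        self._X = X
        return X @ self.params[0] + self.params[1]

    def backward(self, X, grad_scores):
        return [np.asarray(X, dtype=float).T @ grad_scores, grad_scores.sum(axis=0)]


class _MLP:
    """Plain fully-connected trunk with swish hidden activations."""

    def __init__(self, sizes, rng):
        self.sizes = list(sizes)
        self.params = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot-uniform
            self.params.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))

    def forward(self, X):
        h = X
        cache = []
        n_layers = len(self.sizes) - 1
        for layer in range(n_layers):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            z = h @ W + b
            if layer < n_layers - 1:
                a, s = _swish(z)
                cache.append((h, z, s))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        self._cache = cache
        return h

    def backward(self, grad_out):
        grads = [None] * len(self.params)
        g = grad_out
        n_layers = len(self.sizes) - 1
        for layer in reversed(range(n_layers)):
            h, z, s = self._cache[layer]
            grads[2 * layer] = h.T @ g
            grads[2 * layer + 1] = g.sum(axis=0)
            if layer > 0:
                g = g @ self.params[2 * layer].T
                h_prev, z_prev, s_prev = self._cache[layer - 1]
                g = g * _swish_grad(z_prev, s_prev)
        return grads


class NeuralPredictor(Predictor):
    """Multilayer-perceptron scores, 2x50 swish by default."""

    kind = "ann"

    def __init__(self, n_destinations: int, n_covariates: int,
                 architecture: Optional[AnnArchitecture] = None, seed: int = 0):
        super().__init__(n_destinations, n_covariates)
        self.architecture = architecture or AnnArchitecture()
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        hidden = self.architecture.hidden_sizes
        if self.architecture.shared_trunk:
            self._nets = [_MLP([n_covariates, *hidden, n_destinations], rng)]
        else:
            self._nets = [_MLP([n_covariates, *hidden, 1], rng) for _ in range(n_destinations)]
        self.params = [p for net in self._nets for p in net.params]

    def scores(self, X):
        X = np.asarray(X, dtype=float)
        if self.architecture.shared_trunk:
            return self._nets[0].forward(X)
        return np.concatenate([net.forward(X) for net in self._nets], axis=1)

    def backward(self, X, grad_scores):
        if self.architecture.shared_trunk:
            return self._nets[0].backward(grad_scores)
        grads = []
        for col, net in enumerate(self._nets):
            grads.extend(net.backward(grad_scores[:, col:col + 1]))
        return grads


_KINDS = {"constant": ConstantPredictor, "linear": LinearPredictor, "ann": NeuralPredictor}


def make_predictor(kind: str, n_destinations: int, n_covariates: int,
                   architecture: Optional[AnnArchitecture] = None,
                   seed: int = 0) -> Predictor:
    """Factory with the initialization contract: constant and linear start
    at zero scores (uniform outcome probabilities); the network uses
    fan-based random initialization reproducible under ``seed``."""
    if kind not in _KINDS:
        raise ValueError(f"unknown predictor kind {kind!r}; choose from {sorted(_KINDS)}")
    if kind == "ann":
        return NeuralPredictor(n_destinations, n_covariates, architecture, seed)
    return _KINDS[kind](n_destinations, n_covariates)


def init_parameters(kind: str, n_destinations: int, n_covariates: int,
                    architecture: Optional[AnnArchitecture] = None,
                    seed: int = 0) -> np.ndarray:
    """Initial flat parameter vector for a predictor of the given shape."""
    return make_predictor(kind, n_destinations, n_covariates, architecture, seed).flat_params()


def predict_row(predictor: Predictor, covariates) -> ProbabilityRow:
    """Transition-probability row for a single covariate vector."""
    x = np.atleast_1d(np.asarray(covariates, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    if predictor.kind != "constant" and x.size != predictor.n_covariates:
        raise ValueError(
            f"predictor expects {predictor.n_covariates} covariates, got {x.size}"
        )
    return link(predictor.scores(x[None, :])[0])


def save_predictor(predictor: Predictor, path) -> None:
    """Flat parameter vector plus a JSON sidecar describing the layout."""
    path = Path(path)
    meta = {
        "kind": predictor.kind,
        "n_destinations": predictor.n_destinations,
        "n_covariates": predictor.n_covariates,
        "shapes": [list(p.shape) for p in predictor.params],
        "params": predictor.flat_params().tolist(),
    }
    if predictor.kind == "ann":
        meta["architecture"] = {
            "hidden_sizes": list(predictor.architecture.hidden_sizes),
            "activation": predictor.architecture.activation,
            "shared_trunk": predictor.architecture.shared_trunk,
        }
        meta["seed"] = predictor.seed
    path.write_text(json.dumps(meta))


def load_predictor(path) -> Predictor:
    meta = json.loads(Path(path).read_text())
    arch = None
    if meta["kind"] == "ann":
        a = meta.get("architecture", {})
        arch = AnnArchitecture(tuple(a.get("hidden_sizes", (50, 50))),
                               a.get("activation", "swish"),
                               a.get("shared_trunk", True))
    pred = make_predictor(meta["kind"], meta["n_destinations"], meta["n_covariates"],
                          arch, meta.get("seed", 0))
    pred.set_flat_params(np.asarray(meta["params"]))
    return pred
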
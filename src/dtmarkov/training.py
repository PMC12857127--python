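"""Minibatch likelihood maximization with ADAM.

The negative log-likelihood of the censored transition data is minimized
by ADAM over minibatches of individuals.  One *iteration* is one optimizer
step on one minibatch; the minibatch loss is the mean per-individual
negative log-likelihood, so the learning rate is batch-size invariant.

The default learning rate (1e-2) is chosen so that the constant and linear
models reach their optima within the default 500-step budget on the
reference simulation (see docs/methods.md); it is configurable, as are all
other protocol knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np

from .core import ObservationSet
from .likelihood import dataset_negloglik, loglik_and_score_grad
from .predictors import Predictor

__all__ = ["TrainConfig", "TrainResult", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Protocol for one training run.

    batch_size : individuals per minibatch (default 128)
    iterations : optimizer steps (default 500)
    learning_rate : ADAM step size (default 1e-2)
    weight_decay : optional L2 penalty coefficient (default 0, off)
    seed : RNG seed for batch shuffling
    shuffle : reshuffle individuals at every pass through the data
    log_every : emit a log line every this many steps (0 = silent)
    """

    batch_size: int = 128
    iterations: int = 500
    learning_rate: float = 1e-2
    weight_decay: float = 0.0
    seed: int = 0
    shuffle: bool = True
    log_every: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")


@dataclass
class TrainResult:
    """Fitted parameters, per-step loss trace, and final full-data NLL."""

    params: np.ndarray
    loss_trace: List[float]
    final_negloglik: float
    config: TrainConfig

    def to_dict(self):
        return {
            "params": self.params.tolist(),
            "loss_trace": list(self.loss_trace),
            "final_negloglik": self.final_negloglik,
            "config": asdict(self.config),
        }


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def train(predictor: Predictor, obs_set: ObservationSet,
          config: Optional[TrainConfig] = None,
          logger=None) -> TrainResult:
    """Run ``config.iterations`` ADAM steps of minibatch NLL minimization.

    Deterministic under a fixed config seed (given a deterministically
    initialized predictor).  Raises if the loss turns non-finite, reporting
    the step at which it happened.
    """
    config = config or TrainConfig()
    n = len(obs_set)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(predictor.params, config.learning_rate,
                config.beta1, config.beta2, config.eps)

    order = rng.permutation(n) if config.shuffle else np.arange(n)
    pos = 0
    trace: List[float] = []
    for step in range(1, config.iterations + 1):
        if pos + config.batch_size > n:
            order = rng.permutation(n) if config.shuffle else np.arange(n)
            pos = 0
        idx = order[pos:pos + config.batch_size]
        pos += config.batch_size

        batch = obs_set.subset(idx)
        scores = predictor.scores(batch.covariates)
        ll, g_scores = loglik_and_score_grad(scores, batch)
        loss = float(-ll.mean())
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite minibatch loss at step {step}; "
                f"last finite losses: {trace[-5:]}"
            )
        grads = predictor.backward(batch.covariates, -g_scores / len(idx))
        if config.weight_decay > 0:
            loss += 0.5 * config.weight_decay * sum(
                float(np.sum(np.square(p))) for p in predictor.params)
            grads = [g + config.weight_decay * p
                     for g, p in zip(grads, predictor.params)]
        opt.step(predictor.params, grads)
        trace.append(loss)
        if logger is not None and config.log_every and step % config.log_every == 0:
            logger.info("step %d  batch NLL %.6f", step, loss)

    final = dataset_negloglik(predictor, obs_set)
    return TrainResult(predictor.flat_params(), trace, final, config)
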
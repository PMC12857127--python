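"""Synthetic censored transition data with known ground truth.

The generator emulates a three-state star model: every individual starts
in the transient state 1 and eventually moves to one of two absorbing
states (2 or 3).  Per-individual transition probabilities are nonlinear
functions of two covariates drawn uniformly on a truncated unit square:

    g12(x1, x2) = 1/4 * (0.5*x1^3/(x1^3 + 0.027)
                         + 5*x2*(x2 - 0.9)*(x2 - 0.8) + 0.05)
    g13(x1, x2) = 2/3 * (exp(x1^3 + 2*x1 - 4)
                         + 5*x2*(x2 - 0.9)*(x2 - 0.8) + 0.15)

with the stay probability by complement.  The shared cubic term makes the
second covariate's effect non-monotone.  A dataset-level proportional
error (one Normal(0, sd) draw per transition, shared by all individuals)
perturbs the curves; the perturbed probabilities are both the sampling
distribution and the recorded "true" per-individual probabilities.

Event times are the number of per-interval trials until the first
transition — geometric with success probability lambda12 + lambda13 — and
the drawn destination is the conditional category.  Observations are then
censored: with probability ``right_censor_prob`` the individual is
right-censored at ``max(k* - Poisson(1), 0)``; otherwise the event is
reported only within the interval ``(max(k* - s1, 0), k* + s2]`` with
``s1, s2 ~ Poisson(1)`` independent (degenerate intervals widen to
``(k*-1, k*]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import EXACT, INTERVAL, Observation, ObservationSet, TransitionStructure

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_g12",
    "default_g13",
    "truth_probs",
    "apply_proportional_noise",
    "sample_transition_time",
    "censor",
    "generate_dataset",
]


def default_g12(x1, x2):
    """Hill-type rise in the first covariate plus a non-monotone cubic."""
    return 0.25 * (0.5 * x1**3 / (x1**3 + 0.027)
                   + 5.0 * x2 * (x2 - 0.9) * (x2 - 0.8) + 0.05)


def default_g13(x1, x2):
    """Exponential rise in the first covariate plus the same cubic."""
    return (2.0 / 3.0) * (np.exp(x1**3 + 2.0 * x1 - 4.0)
                          + 5.0 * x2 * (x2 - 0.9) * (x2 - 0.8) + 0.15)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_individuals: int = 1000
    covariate_low: float = 0.02
    covariate_high: float = 0.98
    noise_sd: float = 0.05
    poisson_rate: float = 1.0
    right_censor_prob: float = 0.5
    right_censor_poisson_rate: float = 1.0
    max_time: int = 10_000
    seed: int = 0
    truth_functions: Tuple[Callable, Callable] = (default_g12, default_g13)

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0.0 <= self.covariate_low < self.covariate_high <= 1.0):
            raise ValueError("need 0 <= covariate_low < covariate_high <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 <= self.right_censor_prob <= 1.0):
            raise ValueError("right_censor_prob must be a probability")
        if self.max_time < 1:
            raise ValueError("max_time must be >= 1")


@dataclass
class SimulatedDataset:
    """Observations plus the per-individual generating probabilities."""

    observations: List[Observation]
    truth: pd.DataFrame  # columns: id, g12, g13, lam12, lam13, lam11
    config: SimulationConfig
    seed: int
    structure: TransitionStructure = field(
        default_factory=lambda: TransitionStructure.star((1, 2, 3)))

    def observation_set(self) -> ObservationSet:
        return ObservationSet(self.observations, self.structure)

    @property
    def truth_lambdas(self) -> np.ndarray:
        """(n, 3) array of true (lam11, lam12, lam13) rows."""
        return self.truth[["lam11", "lam12", "lam13"]].to_numpy()


def truth_probs(phi, config: Optional[SimulationConfig] = None):
    """Noise-free (lam12, lam13, lam11) at one covariate point."""
    config = config or SimulationConfig()
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (2,):
        raise ValueError("expected a 2-vector of covariates")
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError(f"covariates must lie in [0,1], got {phi}")
    g12f, g13f = config.truth_functions
    l12 = float(g12f(phi[0], phi[1]))
    l13 = float(g13f(phi[0], phi[1]))
    return l12, l13, 1.0 - (l12 + l13)


def apply_proportional_noise(g12, g13, eps):
    """Scale each transition curve by ``1 + eps`` (one draw per transition,
    shared over individuals), then clip to keep a valid probability row."""
    l12 = np.clip(np.asarray(g12, dtype=float) * (1.0 + eps[0]), 0.0, None)
    l13 = np.clip(np.asarray(g13, dtype=float) * (1.0 + eps[1]), 0.0, None)
    total = l12 + l13
    # rescale any row pushed over the simplex boundary by a pathological draw
    scale = np.where(total > 1.0 - 1e-9, (1.0 - 1e-9) / np.maximum(total, 1e-300), 1.0)
    l12 = l12 * scale
    l13 = l13 * scale
    return l12, l13, 1.0 - (l12 + l13)


def sample_transition_time(lam12: float, lam13: float, rng,
                           max_time: int = 10_000):
    """Repeated categorical trials until the first transition.

    Returns ``(destination_state, k_star, truncated)`` with destination 2
    or 3 and ``k_star >= 1`` the trial on which the transition occurred.
    Individuals that never transition within ``max_time`` trials are
    flagged truncated.
    """
    total = lam12 + lam13
    for k in range(1, int(max_time) + 1):
        u = rng.uniform()
        if u < lam12:
            return 2, k, False
        if u < total:
            return 3, k, False
    return None, int(max_time), True


def censor(k_star: int, destination: int, rng, config: SimulationConfig,
           individual_id=None, covariates=None) -> Observation:
    """Apply the right/interval censoring mechanism to one event time."""
    if k_star < 1:
        raise ValueError("transition times start at 1")
    if rng.uniform() < config.right_censor_prob:
        c = max(int(k_star) - int(rng.poisson(config.right_censor_poisson_rate)), 0)
        return Observation(individual_id, 0, 0, None, EXACT, c,
                           covariates=covariates if covariates is not None else np.zeros(2))
    s1 = int(rng.poisson(config.poisson_rate))
    s2 = int(rng.poisson(config.poisson_rate))
    k1 = max(int(k_star) - s1, 0)
    k2 = int(k_star) + s2
    if k1 >= k2:  # degenerate (s1 = s2 = 0): widen to (k*-1, k*]
        k1, k2 = int(k_star) - 1, int(k_star)
    return Observation(individual_id, 0, 1, destination - 1, INTERVAL,
                       None, k1, k2,
                       covariates=covariates if covariates is not None else np.zeros(2))


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one full dataset: covariates, dataset-level noise, event times,
    censoring, and the ground-truth probability table."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    phi = rng.uniform(config.covariate_low, config.covariate_high, size=(n, 2))
    g12f, g13f = config.truth_functions
    g12v = np.asarray(g12f(phi[:, 0], phi[:, 1]), dtype=float)
    g13v = np.asarray(g13f(phi[:, 0], phi[:, 1]), dtype=float)
    eps = rng.normal(0.0, config.noise_sd, size=2)
    l12, l13, l11 = apply_proportional_noise(g12v, g13v, eps)

    total = l12 + l13
    # number of trials until the first transition is geometric(total);
    # the destination is the conditional Bernoulli split — an exact,
    # vectorized equivalent of repeated categorical draws
    positive = total > 0
    kstar = np.full(n, config.max_time, dtype=np.int64)
    kstar[positive] = rng.geometric(total[positive])
    truncated = ~positive | (kstar > config.max_time)
    kstar = np.minimum(kstar, config.max_time)
    u = rng.uniform(size=n)
    dest_state = np.where(u < np.divide(l12, total, out=np.full(n, 0.5), where=positive), 2, 3)

    censored = rng.uniform(size=n) < config.right_censor_prob
    censor_sub = rng.poisson(config.right_censor_poisson_rate, size=n)
    s1 = rng.poisson(config.poisson_rate, size=n)
    s2 = rng.poisson(config.poisson_rate, size=n)

    observations = []
    for i in range(n):
        if truncated[i]:
            observations.append(Observation(i, 0, 0, None, EXACT,
                                            int(config.max_time), covariates=phi[i]))
        elif censored[i]:
            c = max(int(kstar[i]) - int(censor_sub[i]), 0)
            observations.append(Observation(i, 0, 0, None, EXACT, c, covariates=phi[i]))
        else:
            k1 = max(int(kstar[i]) - int(s1[i]), 0)
            k2 = int(kstar[i]) + int(s2[i])
            if k1 >= k2:
                k1, k2 = int(kstar[i]) - 1, int(kstar[i])
            observations.append(Observation(i, 0, 1, int(dest_state[i]) - 1,
                                            INTERVAL, None, k1, k2, covariates=phi[i]))

    truth = pd.DataFrame({
        "id": np.arange(n),
        "phi1": phi[:, 0], "phi2": phi[:, 1],
        "g12": g12v, "g13": g13v,
        "lam12": l12, "lam13": l13, "lam11": l11,
    })
    return SimulatedDataset(observations, truth, config, config.seed)
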
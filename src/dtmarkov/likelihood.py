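"""Log-likelihood contributions for censored discrete-time transition data.

Conventions
-----------
With per-interval transition probabilities ``lambda_n`` and stay
probability ``q = 1 - sum(lambda)``:

* ``survival(row, k) = q**k`` — no transition in the first ``k`` intervals.
* An exact record contributes ``alpha*log(lambda_dest) + k*log(q)``;
  right-censored records (``alpha = 0``) contribute survival only.
* An interval record ``(k1, k2]`` with destination ``d`` contributes
  ``log sum_{k=k1+1..k2} lambda_d * q**(k-1)``, the probability that the
  first transition lands on ``d`` at some time in the interval.  The sum
  telescopes to ``log(lambda_d) + log(q**k1 - q**k2) - log(1-q)``, which in
  the single-risk case reduces exactly to the survival-difference closed
  form ``log((1-lambda)**k1 - (1-lambda)**k2)``.

All accumulation is done in the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .core import ObservationSet, Observation, ProbabilityRow, TransitionStructure, link_rows

__all__ = [
    "LikelihoodContext",
    "survival",
    "loglik_exact",
    "loglik_interval",
    "dataset_negloglik",
    "loglik_and_score_grad",
]


@dataclass(frozen=True)
class LikelihoodContext:
    """Plumbing for likelihood evaluation against one structure."""

    structure: TransitionStructure
    horizon: Optional[int] = None

    def __post_init__(self):
        if self.horizon is not None and self.horizon < 1:
            raise ValueError("horizon must be >= 1 when given")


def survival(row: ProbabilityRow, k: int) -> float:
    """Probability of no transition in the first ``k`` intervals: ``q**k``."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return row.stay ** int(k)


def _dest_column(row: ProbabilityRow, obs: Observation,
                 structure: Optional[TransitionStructure]) -> int:
    if structure is not None:
        return structure.destination_column(obs.destination_state)
    d = int(obs.destination_state)
    if not (0 <= d < row.n_destinations):
        raise ValueError(f"destination column {d} out of range")
    return d


def loglik_exact(row: ProbabilityRow, obs: Observation,
                 structure: Optional[TransitionStructure] = None) -> float:
    """Log-likelihood of an exact-time record.

    ``alpha*log(lambda_dest) + k_star*log(q)``.  Without a structure, the
    observation's destination is taken as a 0-based destination column.
    A degenerate event probability (``lambda_dest = 0``) yields ``-inf``.
    """
    if obs.time_kind != "exact":
        raise ValueError("loglik_exact requires an exact-time observation")
    q = row.stay
    out = obs.k_star * np.log(q) if obs.k_star > 0 else 0.0
    if obs.event:
        lam_d = row.lambdas[_dest_column(row, obs, structure)]
        with np.errstate(divide="ignore"):
            out += np.log(lam_d)
    return float(out)


def loglik_interval(row: ProbabilityRow, obs: Observation,
                    structure: Optional[TransitionStructure] = None) -> float:
    """Log-likelihood of an interval-censored event over ``(k1, k2]``.

    Computed through the telescoped closed form; returns ``-inf`` when the
    interval carries no probability mass.
    """
    if obs.time_kind != "interval":
        raise ValueError("loglik_interval requires an interval observation")
    if obs.event != 1:
        raise ValueError("interval records carry an observed event")
    lam_d = row.lambdas[_dest_column(row, obs, structure)]
    q = row.stay
    if lam_d == 0.0:
        return float("-inf")
    # log(q^k1 - q^k2) = k1*log q + log(1 - q^(k2-k1)), log(1-q) = log(sum lam)
    logq = np.log(q)
    width = obs.k2 - obs.k1
    log_mass = obs.k1 * logq + np.log(-np.expm1(width * logq))
    return float(np.log(lam_d) + log_mass - np.log(row.lambdas.sum()))


def _scores_for(predictor, obs_set: ObservationSet) -> np.ndarray:
    if obs_set.n_covariates != predictor.n_covariates and predictor.kind != "constant":
        raise ValueError(
            f"predictor expects {predictor.n_covariates} covariates, data has {obs_set.n_covariates}"
        )
    return predictor.scores(obs_set.covariates)


def dataset_negloglik(predictor, obs_set: ObservationSet) -> float:
    """Joint negative log-likelihood: minus the sum of the per-individual
    contributions under the rows produced by the predictor."""
    ll, _ = loglik_and_score_grad(_scores_for(predictor, obs_set), obs_set, want_grad=False)
    return float(-ll.sum())


def loglik_and_score_grad(scores: np.ndarray, obs: ObservationSet,
                          want_grad: bool = True):
    """Per-observation log-likelihood and its gradient w.r.t. the scores.

    The gradient is analytic, exploiting the multinomial-logit Jacobian
    ``d lambda_n / d s_j = lambda_n (1[n=j] - lambda_j)`` and
    ``d q / d s_j = -q lambda_j``.  Returns ``(loglik (n,), grad (n, N))``;
    ``grad`` is None when ``want_grad`` is false.
    """
    scores = np.asarray(scores, dtype=float)
    n, N = scores.shape
    lam, q = link_rows(scores)
    with np.errstate(divide="ignore"):
        logq = np.log(q)  # -inf for fully saturated rows; caught by the trainer
    loglam = scores + logq[:, None]

    ll = np.zeros(n)
    grad = np.zeros((n, N)) if want_grad else None

    exact = ~obs.is_interval
    if exact.any():
        idx = np.where(exact)[0]
        k = obs.k_star[idx].astype(float)
        ll[idx] = k * logq[idx]
        if want_grad:
            grad[idx] = -k[:, None] * lam[idx]
        ev = idx[obs.event[idx] == 1]
        if ev.size:
            d = obs.dest[ev]
            ll[ev] += loglam[ev, d]
            if want_grad:
                grad[ev] -= lam[ev]
                grad[ev, d] += 1.0

    if obs.is_interval.any():
        idx = np.where(obs.is_interval)[0]
        d = obs.dest[idx]
        k1 = obs.k1[idx].astype(float)
        width = (obs.k2[idx] - obs.k1[idx]).astype(float)
        lq = logq[idx]
        # interval mass: lam_d * q^k1 * (1 - q^width) / (1 - q)
        log_one_minus_qw = np.log(-np.expm1(width * lq))
        # log(1-q) = log(sum lam) computed from the scores, robust when q -> 1
        log_sum_lam = logsumexp(scores[idx], axis=1) + lq
        ll[idx] = loglam[idx, d] + k1 * lq + log_one_minus_qw - log_sum_lam
        if want_grad:
            qw = np.exp(width * lq)
            qv = q[idx]
            c = 1.0 + k1 - width * qw / (1.0 - qw) + qv / (1.0 - qv)
            grad[idx] = -c[:, None] * lam[idx]
            grad[idx, d] += 1.0
    return ll, grad
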
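"""Model evaluation: state occupation, Brier scores, per-transition MSE,
validation likelihood, and pairwise model comparisons.

State-occupation probabilities follow from the Chapman-Kolmogorov
relation ``pi(t) = pi0 @ P^t``.  The Brier score at a horizon ``t`` is the
squared distance between the predicted occupation vector and the observed
(one-hot) state.  For interval-censored observations the score is averaged
over the candidate transition times in the half-open interval, so the
``1/(t2 - t1)`` normalizer is an exact mean.  Right-censored individuals
whose censoring time precedes the horizon have an unknown state there and
are excluded from the average by default (set ``include_unknown`` to score
them as still occupying the origin state instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import ObservationSet, TransitionStructure, link_rows
from .likelihood import dataset_negloglik

__all__ = [
    "occupation",
    "brier_individual",
    "brier_interval",
    "brier_score",
    "mse_transitions",
    "EvaluationReport",
    "evaluate_predictor",
    "DeltaReport",
    "compare_models",
]

BRIER_HORIZON = 5


def occupation(P: np.ndarray, pi0: np.ndarray, t: int) -> np.ndarray:
    """State-occupation vector ``pi0 @ P^t`` by repeated multiplication."""
    P = np.asarray(P, dtype=float)
    pi = np.asarray(pi0, dtype=float).copy()
    if t < 0:
        raise ValueError("t must be nonnegative")
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8) or np.any(P < -1e-12):
        raise ValueError("P must be row-stochastic")
    if not np.isclose(pi.sum(), 1.0) or np.any(pi < 0):
        raise ValueError("pi0 must be a probability vector")
    for _ in range(int(t)):
        pi = pi @ P
    return pi


def brier_individual(pi: np.ndarray, observed_state: int) -> float:
    """Squared distance between predicted occupation and the one-hot
    observed state, summed over states."""
    pi = np.asarray(pi, dtype=float)
    target = np.zeros_like(pi)
    target[observed_state] = 1.0
    return float(np.sum((pi - target) ** 2))


def brier_interval(P: np.ndarray, pi0: np.ndarray, interval, destination: int,
                   horizon: int = BRIER_HORIZON) -> float:
    """Mean Brier score over the candidate transition times of an interval.

    For each candidate time ``k`` in ``(t1, t2]`` the observed state at the
    horizon is the destination if ``k <= horizon`` and the origin
    otherwise; the mean over the ``t2 - t1`` candidates is returned.
    """
    t1, t2 = interval
    if t1 >= t2:
        raise ValueError("interval must satisfy t1 < t2")
    pi = occupation(P, pi0, horizon)
    origin = int(np.argmax(np.asarray(pi0)))
    total = 0.0
    for k in range(t1 + 1, t2 + 1):
        observed = destination if k <= horizon else origin
        total += brier_individual(pi, observed)
    return total / (t2 - t1)


def _occupations_at(lam: np.ndarray, stay: np.ndarray,
                    structure: TransitionStructure, horizon: int) -> np.ndarray:
    """Occupation vectors at the horizon for a batch of star-model rows."""
    n = lam.shape[0]
    S = structure.n_states
    pi = np.zeros((n, S))
    pi[:, structure.origin] = 1.0
    for _ in range(horizon):
        nxt = pi.copy()
        at_origin = pi[:, structure.origin]
        nxt[:, structure.origin] = at_origin * stay
        for col, state in enumerate(structure.destinations):
            nxt[:, state] += at_origin * lam[:, col]
        pi = nxt
    return pi


def brier_score(predictor, obs_set: ObservationSet,
                horizon: int = BRIER_HORIZON,
                include_unknown: bool = False) -> float:
    """Mean Brier score at the horizon over the evaluable individuals."""
    structure = obs_set.structure
    lam, stay = link_rows(predictor.scores(obs_set.covariates))
    pi = _occupations_at(lam, stay, structure, horizon)
    scores: List[float] = []
    for i in range(len(obs_set)):
        if not obs_set.is_interval[i]:
            if obs_set.event[i] == 1:
                state = (structure.destinations[obs_set.dest[i]]
                         if obs_set.k_star[i] <= horizon else structure.origin)
                scores.append(brier_individual(pi[i], state))
            elif obs_set.k_star[i] >= horizon:
                scores.append(brier_individual(pi[i], structure.origin))
            elif include_unknown:
                scores.append(brier_individual(pi[i], structure.origin))
        else:
            k1, k2 = int(obs_set.k1[i]), int(obs_set.k2[i])
            dest_state = structure.destinations[obs_set.dest[i]]
            total = 0.0
            for k in range(k1 + 1, k2 + 1):
                observed = dest_state if k <= horizon else structure.origin
                total += brier_individual(pi[i], observed)
            scores.append(total / (k2 - k1))
    if not scores:
        raise ValueError("no individuals with a known state at the horizon")
    return float(np.mean(scores))


def mse_transitions(predictor, covariates: np.ndarray,
                    truth_lambdas: np.ndarray) -> Dict[str, float]:
    """Mean squared error of predicted vs. true per-individual
    probabilities, per transition (stay row first)."""
    truth = np.asarray(truth_lambdas, dtype=float)
    if truth.shape[0] != np.asarray(covariates).shape[0]:
        raise ValueError("truth and covariates are misaligned")
    lam, stay = link_rows(predictor.scores(np.asarray(covariates, dtype=float)))
    pred = np.column_stack([stay, lam])
    if pred.shape != truth.shape:
        raise ValueError(f"expected truth shaped {pred.shape}, got {truth.shape}")
    errs = np.mean((pred - truth) ** 2, axis=0)
    keys = ["lam11"] + [f"lam1{j}" for j in range(2, truth.shape[1] + 1)]
    return {k: float(e) for k, e in zip(keys, errs)}


@dataclass
class EvaluationReport:
    """Validation metrics for one fitted model on one dataset."""

    negloglik: float
    brier: float
    mse_per_transition: Dict[str, float] = field(default_factory=dict)
    n_individuals: int = 0
    horizon: int = BRIER_HORIZON

    def to_dict(self):
        return {
            "negloglik": self.negloglik,
            "brier": self.brier,
            "mse_per_transition": dict(self.mse_per_transition),
            "n_individuals": self.n_individuals,
            "horizon": self.horizon,
        }


def evaluate_predictor(predictor, obs_set: ObservationSet,
                       truth_lambdas: Optional[np.ndarray] = None,
                       horizon: int = BRIER_HORIZON) -> EvaluationReport:
    """Joint validation NLL, Brier score, and (with simulation truth)
    per-transition MSE for one fitted predictor."""
    mse = {}
    if truth_lambdas is not None:
        mse = mse_transitions(predictor, obs_set.covariates, truth_lambdas)
    return EvaluationReport(
        negloglik=dataset_negloglik(predictor, obs_set),
        brier=brier_score(predictor, obs_set, horizon=horizon),
        mse_per_transition=mse,
        n_individuals=len(obs_set),
        horizon=horizon,
    )


@dataclass
class DeltaReport:
    """Reference-minus-ANN metric differences across replicate datasets.

    Positive values mean the ANN performed better on that metric.
    """

    table: pd.DataFrame  # rows: metric; columns: median, lo, hi per reference

    def to_csv(self, path):
        self.table.to_csv(path)


def _metric_values(report: EvaluationReport) -> Dict[str, float]:
    out = {"loss": report.negloglik, "brier": report.brier}
    out.update({f"mse_{k}": v for k, v in report.mse_per_transition.items()})
    return out


def compare_models(replicate_reports: List[Dict[str, EvaluationReport]],
                   ann_key: str = "ann",
                   percentiles=(2.5, 97.5)) -> DeltaReport:
    """Pairwise differences (reference model minus ANN) per metric.

    ``replicate_reports`` holds one dict of reports per replicate dataset,
    all computed on identical validation data within a replicate.  Reports
    the across-replicate median and the given percentile interval.
    """
    if not replicate_reports:
        raise ValueError("no replicate reports")
    keys = set(replicate_reports[0])
    for rep in replicate_reports:
        if set(rep) != keys:
            raise ValueError("replicates cover different model sets")
    if ann_key not in keys:
        raise ValueError(f"no {ann_key!r} report to compare against")
    refs = sorted(keys - {ann_key})
    rows = {}
    metrics = list(_metric_values(replicate_reports[0][ann_key]))
    for ref in refs:
        for metric in metrics:
            deltas = [
                _metric_values(rep[ref])[metric] - _metric_values(rep[ann_key])[metric]
                for rep in replicate_reports
            ]
            rows[(ref, metric)] = {
                "median": float(np.median(deltas)),
                f"p{percentiles[0]}": float(np.percentile(deltas, percentiles[0])),
                f"p{percentiles[1]}": float(np.percentile(deltas, percentiles[1])),
                "n_replicates": len(deltas),
            }
    table = pd.DataFrame(rows).T
    table.index.names = ["reference", "metric"]
    return DeltaReport(table)
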
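"""Core domain types for discrete-time multi-state Markov models.

A model describes the movement of individuals between a finite set of
states in discrete time.  One row of the transition matrix — the row of a
single transient *origin* state — is modeled at a time: the probability
``lambda_mn`` of moving from origin ``m`` to destination ``n`` within one
time interval, for each of ``N`` competing destinations, together with the
complementary probability ``1 - sum(lambda)`` of remaining in ``m``.

The mapping from unconstrained real-valued scores to a valid probability
row is the multinomial-logistic link with the stay category's score pinned
at zero; with a single destination it reduces to the ordinary sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TransitionStructure",
    "Observation",
    "ObservationSet",
    "ProbabilityRow",
    "link",
    "realize_matrix",
]

EXACT = "exact"
INTERVAL = "interval"


@dataclass(frozen=True)
class TransitionStructure:
    """The state space and which transitions are possible.

    Parameters
    ----------
    state_labels : sequence
        Ordered, user-facing labels for the states.  Internally states are
        addressed by 0-based index.
    origin : int
        Index of the transient origin state whose row is being modeled.
    destinations : sequence of int
        Ordered indices of the ``N >= 1`` states reachable from the origin.
        Their order fixes the order of probability rows and score vectors.
    absorbing : sequence of bool, optional
        Flag per state.  Defaults to every non-origin state absorbing
        (the star topology).
    """

    state_labels: tuple
    origin: int
    destinations: tuple
    absorbing: tuple = ()

    def __post_init__(self):
        labels = tuple(self.state_labels)
        dests = tuple(int(d) for d in self.destinations)
        object.__setattr__(self, "state_labels", labels)
        object.__setattr__(self, "destinations", dests)
        S = len(labels)
        if len(set(labels)) != S:
            raise ValueError("state labels must be unique")
        if not (0 <= self.origin < S):
            raise ValueError(f"origin index {self.origin} out of range for {S} states")
        if len(dests) < 1:
            raise ValueError("need at least one destination state (N >= 1)")
        if self.origin in dests:
            raise ValueError("origin state cannot be its own destination")
        if any(not (0 <= d < S) for d in dests):
            raise ValueError("destination index out of range")
        if len(set(dests)) != len(dests):
            raise ValueError("destination indices must be unique")
        if not self.absorbing:
            absorbing = tuple(i != self.origin for i in range(S))
        else:
            absorbing = tuple(bool(a) for a in self.absorbing)
            if len(absorbing) != S:
                raise ValueError("absorbing flags must match number of states")
            if absorbing[self.origin]:
                raise ValueError("origin state cannot be absorbing")
        object.__setattr__(self, "absorbing", absorbing)

    @classmethod
    def star(cls, state_labels: Sequence) -> "TransitionStructure":
        """Star topology: first label is the transient origin, all other
        states are absorbing destinations."""
        labels = tuple(state_labels)
        return cls(labels, 0, tuple(range(1, len(labels))))

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_destinations(self) -> int:
        return len(self.destinations)

    def destination_column(self, state_index: int) -> int:
        """Column (0..N-1) of a destination state in probability rows."""
        try:
            return self.destinations.index(state_index)
        except ValueError:
            raise ValueError(
                f"state {state_index} is not a destination of this structure"
            ) from None

    def label_index(self, label) -> int:
        return self.state_labels.index(label)


@dataclass(frozen=True)
class ProbabilityRow:
    """One origin-state row of transition probabilities.

    ``lambdas[n]`` is the probability of moving to the n-th destination in
    one interval; ``stay`` is the derived probability ``1 - sum(lambdas)``
    of remaining, so the full row sums to one exactly.
    """

    lambdas: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        if lam.ndim != 1 or lam.size < 1:
            raise ValueError("lambdas must be a vector of length N >= 1")
        if not np.all(np.isfinite(lam)):
            raise ValueError("transition probabilities must be finite")
        if np.any(lam < 0) or np.any(lam >= 1):
            raise ValueError("each transition probability must lie in [0, 1)")
        if lam.sum() >= 1:
            raise ValueError("total transition probability must be < 1")

    @property
    def stay(self) -> float:
        return 1.0 - float(self.lambdas.sum())

    @property
    def n_destinations(self) -> int:
        return self.lambdas.size


@dataclass
class Observation:
    """One individual's transition record.

    Either an exact discrete time ``k_star`` (a transition or a
    right-censoring time) or a half-open interval ``(k1, k2]`` of possible
    transition times is recorded.  Right-censored records (``event=0``)
    always carry an exact censoring time and no destination.
    """

    individual_id: object
    origin_state: int
    event: int
    destination_state: Optional[int] = None
    time_kind: str = EXACT
    k_star: Optional[int] = None
    k1: Optional[int] = None
    k2: Optional[int] = None
    covariates: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.covariates = np.atleast_1d(np.asarray(self.covariates, dtype=float))
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")
        if self.time_kind not in (EXACT, INTERVAL):
            raise ValueError(f"unknown time_kind {self.time_kind!r}")
        if self.event == 1 and self.destination_state is None:
            raise ValueError("an observed event requires a destination state")
        if self.event == 0:
            if self.time_kind != EXACT:
                raise ValueError("right-censored records must carry an exact time")
            if self.destination_state is not None:
                raise ValueError("right-censored records carry no destination")
        if self.time_kind == EXACT:
            if self.k_star is None or self.k_star < 0:
                raise ValueError("exact records need a nonnegative integer k_star")
            self.k_star = int(self.k_star)
        else:
            if self.k1 is None or self.k2 is None:
                raise ValueError("interval records need bounds k1 < k2")
            self.k1, self.k2 = int(self.k1), int(self.k2)
            if not (0 <= self.k1 < self.k2):
                raise ValueError(f"interval bounds must satisfy 0 <= k1 < k2, got ({self.k1}, {self.k2}]")


class ObservationSet:
    """Column-wise view of a list of observations for vectorized work.

    Destination states are re-expressed as 0-based columns in the
    structure's destination order; ``dest`` is -1 for censored records.
    """

    def __init__(self, observations: Sequence[Observation], structure: TransitionStructure):
        obs = list(observations)
        if not obs:
            raise ValueError("empty dataset")
        d = obs[0].covariates.size
        for i, o in enumerate(obs):
            if o.covariates.size != d:
                raise ValueError(
                    f"covariate length mismatch at record {i}: {o.covariates.size} != {d}"
                )
            if o.origin_state != structure.origin:
                raise ValueError(
                    f"record {i} has origin state {o.origin_state}, structure expects {structure.origin}"
                )
        self.structure = structure
        self.observations = obs
        self.ids = [o.individual_id for o in obs]
        self.covariates = np.array([o.covariates for o in obs], dtype=float)
        self.event = np.array([o.event for o in obs], dtype=np.int64)
        self.is_interval = np.array([o.time_kind == INTERVAL for o in obs])
        self.dest = np.array(
            [structure.destination_column(o.destination_state) if o.event else -1 for o in obs],
            dtype=np.int64,
        )
        self.k_star = np.array([o.k_star if o.k_star is not None else 0 for o in obs], dtype=np.int64)
        self.k1 = np.array([o.k1 if o.k1 is not None else 0 for o in obs], dtype=np.int64)
        self.k2 = np.array([o.k2 if o.k2 is not None else 0 for o in obs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx) -> "ObservationSet":
        out = object.__new__(ObservationSet)
        out.structure = self.structure
        idx = np.asarray(idx)
        out.observations = [self.observations[i] for i in idx]
        out.ids = [self.ids[i] for i in idx]
        for name in ("covariates", "event", "is_interval", "dest", "k_star", "k1", "k2"):
            setattr(out, name, getattr(self, name)[idx])
        return out


def link(scores) -> ProbabilityRow:
    """Map unconstrained scores to a transition-probability row.

    ``lambda_n = exp(s_n) / (1 + sum_j exp(s_j))`` with the stay
    probability ``1 / (1 + sum_j exp(s_j))``.  Stabilized by shifting all
    scores (including the implicit zero of the stay category) by their
    maximum before exponentiation, so rows sum to one even for large
    score magnitudes.  With ``N = 1`` this is the logistic function.
    """
    s = np.atleast_1d(np.asarray(scores, dtype=float))
    if s.ndim != 1 or s.size < 1:
        raise ValueError("scores must be a vector of length N >= 1")
    if not np.all(np.isfinite(s)):
        raise ValueError(f"scores must be finite, got {scores!r}")
    m = max(0.0, float(s.max()))
    num = np.exp(s - m)
    denom = np.exp(-m) + num.sum()
    lam = num / denom
    # guard the open-interval invariant against rounding at huge scores
    total = lam.sum()
    if total >= 1.0 or np.any(lam >= 1.0):
        lam = lam * ((1.0 - 1e-15) / total)
    return ProbabilityRow(lam)


def link_rows(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized link for an (n, N) score matrix.

    Returns ``(lam, stay)`` with ``lam`` shaped (n, N) and ``stay`` (n,).
    """
    s = np.asarray(scores, dtype=float)
    m = np.maximum(0.0, s.max(axis=1))
    num = np.exp(s - m[:, None])
    denom = np.exp(-m) + num.sum(axis=1)
    return num / denom[:, None], np.exp(-m) / denom


def realize_matrix(structure: TransitionStructure, row: ProbabilityRow) -> np.ndarray:
    """Build the full square transition matrix implied by one modeled row.

    The origin row carries the stay probability and the destination
    probabilities in structure order; absorbing rows are unit vectors;
    transitions not in the structure have probability zero.
    """
    if row.n_destinations != structure.n_destinations:
        raise ValueError(
            f"row has {row.n_destinations} destinations, structure expects {structure.n_destinations}"
        )
    S = structure.n_states
    P = np.zeros((S, S))
    P[structure.origin, structure.origin] = row.stay
    for col, state in enumerate(structure.destinations):
        P[structure.origin, state] = row.lambdas[col]
    for s in range(S):
        if s == structure.origin:
            continue
        if structure.absorbing[s]:
            P[s, s] = 1.0
        else:
            P[s, s] = 1.0  # unmodeled non-absorbing rows default to staying put
    return P
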
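"""Model/Results interface over the discrete-time Markov framework.

:class:`DiscreteMarkovModel` bundles a transition structure, a dataset of
censored transition records, and a choice of covariate mapping
(constant / linear / neural network).  Its :meth:`fit` runs minibatch
likelihood maximization and returns a :class:`MarkovResults` carrying the
fitted parameters, the loss trace, validation metrics, prediction and
plotting helpers, and a text summary.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Observation, ObservationSet, TransitionStructure, link_rows, realize_matrix
from .evaluate import BRIER_HORIZON, EvaluationReport, evaluate_predictor, occupation
from .likelihood import dataset_negloglik
from .predictors import AnnArchitecture, make_predictor, predict_row, save_predictor
from .training import TrainConfig, TrainResult, train

__all__ = ["DiscreteMarkovModel", "MarkovResults"]


class DiscreteMarkovModel:
    """A one-origin-row discrete-time Markov model with covariate effects.

    Parameters
    ----------
    observations : sequence of Observation or ObservationSet
    structure : TransitionStructure, optional
        Defaults to a star over the states seen in the data when given a
        plain list of observations with a 3-state layout; required
        otherwise.
    predictor : {"constant", "linear", "ann"}
    architecture : AnnArchitecture, optional
        Network layout for the "ann" predictor (default two hidden layers
        of 50 with swish).
    seed : int
        Seed for the network's parameter initialization.
    """

    def __init__(self, observations, structure: Optional[TransitionStructure] = None,
                 predictor: str = "ann",
                 architecture: Optional[AnnArchitecture] = None,
                 seed: int = 0):
        if isinstance(observations, ObservationSet):
            self.data = observations
            self.structure = observations.structure
        else:
            if structure is None:
                raise ValueError("a TransitionStructure is required with a list of observations")
            self.structure = structure
            self.data = ObservationSet(observations, structure)
        self.predictor_kind = predictor
        self.architecture = architecture
        self.seed = int(seed)
        self.predictor = make_predictor(
            predictor, self.structure.n_destinations, self.data.n_covariates,
            architecture, seed)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, structure: TransitionStructure,
                       covariate_columns: Sequence[str], **kwargs) -> "DiscreteMarkovModel":
        """Build from a long-format frame (see :mod:`dtmarkov.io` for the
        column conventions)."""
        from .io import observations_from_frame
        obs = observations_from_frame(frame, covariate_columns)
        return cls(obs, structure, **kwargs)

    def fit(self, config: Optional[TrainConfig] = None, logger=None) -> "MarkovResults":
        """Train the predictor and wrap the outcome in a results object."""
        result = train(self.predictor, self.data, config, logger=logger)
        return MarkovResults(self, result)

    def negloglik(self, params: Optional[np.ndarray] = None) -> float:
        if params is not None:
            self.predictor.set_flat_params(params)
        return dataset_negloglik(self.predictor, self.data)


class MarkovResults:
    """Fitted-model container with estimates, diagnostics, and predictions."""

    def __init__(self, model: DiscreteMarkovModel, train_result: TrainResult):
        self.model = model
        self.train_result = train_result
        self.params = train_result.params
        self.loss_trace = train_result.loss_trace
        self.nll = train_result.final_negloglik
        self.config = train_result.config

    # -- prediction ---------------------------------------------------------
    def predict(self, covariates) -> pd.DataFrame:
        """Per-row transition probabilities (stay column first)."""
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        lam, stay = link_rows(self.model.predictor.scores(X))
        structure = self.model.structure
        cols = {f"stay_{structure.state_labels[structure.origin]}": stay}
        for col, state in enumerate(structure.destinations):
            cols[f"to_{structure.state_labels[state]}"] = lam[:, col]
        return pd.DataFrame(cols)

    def transition_matrix(self, covariates) -> np.ndarray:
        """Full square transition matrix for one covariate vector."""
        row = predict_row(self.model.predictor, covariates)
        return realize_matrix(self.model.structure, row)

    def occupation(self, covariates, t: int, pi0=None) -> np.ndarray:
        """State occupation ``pi0 @ P^t`` for one covariate vector."""
        P = self.transition_matrix(covariates)
        if pi0 is None:
            pi0 = np.zeros(self.model.structure.n_states)
            pi0[self.model.structure.origin] = 1.0
        return occupation(P, pi0, t)

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, obs_set: ObservationSet,
                 truth_lambdas: Optional[np.ndarray] = None,
                 horizon: int = BRIER_HORIZON) -> EvaluationReport:
        """Validation NLL, Brier score, and (with truth) per-transition MSE."""
        return evaluate_predictor(self.model.predictor, obs_set,
                                  truth_lambdas, horizon=horizon)

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        model = self.model
        lines = [
            "Discrete-time Markov model results",
            "=" * 50,
            f"states:            {model.structure.state_labels}",
            f"origin state:      {model.structure.state_labels[model.structure.origin]}",
            f"predictor:         {model.predictor_kind}",
            f"parameters:        {model.predictor.n_params}",
            f"observations:      {len(model.data)}",
            f"events:            {int(model.data.event.sum())}",
            f"right censored:    {int((model.data.event == 0).sum())}",
            f"iterations:        {self.config.iterations}",
            f"learning rate:     {self.config.learning_rate}",
            f"batch size:        {self.config.batch_size}",
            f"seed:              {self.config.seed}",
            f"final NLL:         {self.nll:.4f}",
            f"first/last batch NLL: {self.loss_trace[0]:.4f} / {self.loss_trace[-1]:.4f}",
        ]
        if model.predictor_kind == "constant":
            lam, stay = link_rows(model.predictor.scores(np.zeros((1, model.data.n_covariates))))
            lines.append("fitted row:        stay={:.4f}, ".format(stay[0]) +
                         ", ".join(f"lam->{model.structure.state_labels[s]}={lam[0, c]:.4f}"
                                   for c, s in enumerate(model.structure.destinations)))
        return "\n".join(lines)

    def save(self, path) -> None:
        save_predictor(self.model.predictor, path)

    # -- plotting -----------------------------------------------------------
    def plot_predictions(self, covariates, truth_lambdas, ax=None):
        """Predicted-vs-true scatter per transition (identity line in red)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        truth = np.asarray(truth_lambdas, dtype=float)
        pred = self.predict(covariates).to_numpy()
        k = truth.shape[1]
        if ax is None:
            _, axes = plt.subplots(1, k, figsize=(4 * k, 4))
        else:
            axes = np.atleast_1d(ax)
        names = ["stay"] + [f"to {self.model.structure.state_labels[s]}"
                            for s in self.model.structure.destinations]
        for j in range(k):
            a = axes[j]
            a.scatter(truth[:, j], pred[:, j], s=4, alpha=0.4)
            lim = [0, max(truth[:, j].max(), pred[:, j].max()) * 1.05]
            a.plot(lim, lim, color="red", lw=1)
            a.set_xlabel(f"true {names[j]}")
            a.set_ylabel(f"predicted {names[j]}")
        return axes
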
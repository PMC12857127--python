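# Methods

## Model

The package models one row of a discrete-time Markov transition matrix:
a transient origin state with `N >= 1` competing destinations. Rows are
statistically independent given the covariates, so multi-row systems are
composed from separately fitted row models. Time is a dimensionless
integer index (the sampling interval is fixed at one model unit; calendar
time must be discretized upstream, and the chosen step recorded with the
run). The Markov assumption — the next state depends only on the current
state — is taken as given, not tested; if it is doubtful for a dataset,
the previous state can be added as a covariate.

Scores from the covariate mapping pass through a multinomial-logistic
link with the stay category pinned at score zero, which guarantees
`0 <= lambda_n < 1` and `sum_n lambda_n < 1` for any finite scores. The
link is evaluated with a max-shift before exponentiation; at score
magnitudes where a probability would round to exactly 1 in float64
(|s| > ~36) the row is nudged inside the open simplex by a factor
`1 - 1e-15`.

## Likelihood conventions

The survival function is parameterized so that "no transition in the
first k intervals" has probability `q^k`, `q = 1 - sum_n lambda_n`.

* Right-censored at `k*` (event indicator 0): contribution `k* log q`.
  Censoring at 0 contributes nothing.
* Exact observed event at `k*`: `log lambda_dest + k* log q`.
* Event inside `(k1, k2]`: the sum over candidate times `k = k1+1 .. k2`
  of `lambda_dest * q^(k-1)`. The per-term exponent `k-1` is chosen so the
  sum telescopes exactly to the single-risk survival-difference closed
  form `(1-lambda)^k1 - (1-lambda)^k2`, and so that a width-one interval
  `(k-1, k]` carries exactly the geometric first-transition probability
  `lambda_dest * q^(k-1)` used by the data generator. The sum is computed
  in closed form in the log domain (`k1 log q + log(1 - q^(k2-k1))
  - log(1-q)`, with `log(1-q)` taken as `logsumexp(scores) + log q` so it
  stays finite when `q -> 1`).

Note the deliberate asymmetry: the exact-event contribution uses the
exponent `k*` while the interval terms use `k-1`. The interval convention
is the one that is internally consistent with both the closed form and
the generator; the exact-event convention follows the standard
discrete-time form `alpha log lambda + k* log q`. The simulator never
emits exact-time events (events are always interval-censored, censoring
times are always exact), so the asymmetry does not affect the simulation
study. Left censoring and left truncation are out of scope.

Degenerate cases: an event assigned to a zero-probability destination, or
an interval carrying zero mass, yields `-inf` rather than an exception at
the likelihood level; the trainer aborts with the step index if a batch
loss turns non-finite.

## Predictors

* constant — one free score per destination; covariates ignored.
* linear — affine scores `x W + b`. The intercept is included even though
  the plain form would be `x . theta` alone: without it the constant
  model is not nested inside the linear family, and nestedness makes the
  loss comparisons between families interpretable.
* ann — a single shared-trunk perceptron, two hidden layers of 50 swish
  units (`swish(x) = x * sigmoid(x)`), `N` linear outputs. Sharing the
  trunk models the competing transitions of a row jointly and roughly
  halves the parameters at this scale; fully separate per-destination
  networks are available through `AnnArchitecture(shared_trunk=False)`.
  Weights are Glorot-uniform at a given seed; biases start at zero.
  Deeper or wider defaults were not adopted: at the demonstrated problem
  size the 2x50 network already saturates the achievable validation loss.

Constant and linear models initialize at zero scores, i.e. uniform
probabilities over outcomes. Gradients for all three families are
analytic (hand-written backpropagation through the link and the network)
and are tested against central finite differences at relative tolerance
1e-5.

## Training protocol

ADAM (beta1 0.9, beta2 0.999, eps 1e-8) on minibatches of 128
individuals, 500 steps by default, shuffling individuals at every pass.
The minibatch loss is the mean per-individual negative log-likelihood;
since ADAM normalizes step sizes by gradient scale, mean versus sum only
matters through the epsilon term. "Iterations" means optimizer steps, not
epochs.

The default learning rate is 1e-2. It was chosen from training-loss
convergence diagnostics on the reference simulation: at the conventional
1e-3 the constant model is still several hundred nats short of its
optimum after 500 steps, while at 1e-2 it reaches its optimum within the
budget and the linear model comes close; rates of 3e-2 and above visibly
destabilize the network fit. The network itself does not fully converge
within 500 steps at any stable rate — with the default protocol it
remains a few tens of nats above its long-run training optimum — which is
the price of the fixed small step budget; raise `iterations` for a fully
converged network. No early stopping; weight decay is available
(`weight_decay`) but off by default, since L2 regularization at this
problem size simply pulls the network back to the linear solution.

Runs are deterministic given the config seed and the predictor's
initialization seed.

## Synthetic-data generator

The generator emulates a registry-like cohort on a three-state star:
everyone starts in state 1; states 2 and 3 absorb. Defaults are the study
conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| covariate_low/high | 0.02 / 0.98 | truncated-uniform covariate support |
| noise_sd | 0.05 | sd of the dataset-level proportional error |
| poisson_rate | 1 | interval half-width draws `s1, s2 ~ Poisson(1)` |
| right_censor_prob | 0.5 | chance an individual is right-censored |
| right_censor_poisson_rate | 1 | censor time `max(k* - Poisson(1), 0)` |
| max_time | 10000 | hard cap; capped individuals recorded censored |

The truth curves combine a Hill-type term, an exponential term, and a
shared non-monotone cubic in the second covariate (see
`dtmarkov.simulate`); they keep `lambda_12 + lambda_13 <= 1` on the whole
unit square. The proportional error is drawn once per transition per
dataset and shared by all individuals; `N(0, 0.05)` is read as standard
deviation 0.05. After scaling, rows are clipped back onto the simplex
(nonnegative, total at most `1 - 1e-9`) and the stay probability is
recomputed by complement. The *noise-applied* probabilities are used both
to sample the data and as the recorded per-individual truth for MSE
evaluation, since they are what actually generated each individual's
outcomes.

Event times count repeated categorical trials until the first transition;
the vectorized path draws the trial count from the exactly equivalent
geometric distribution and the destination from the conditional split.
Degenerate intervals (`s1 = s2 = 0`) widen to `(k*-1, k*]`, the unique
width-one interval containing `k*`; interval lower bounds and censoring
times clip at 0.

Two features of the mechanism are *informative* and deliberately ignored
by the likelihood, exactly as in the estimator being studied: the
interval endpoints and the subtracted censoring times both depend on the
true event time. All three model families therefore share an
unremovable bias on this generator, and the study's headline quantities
are the *differences* between models on identical validation data, which
cancel the shared component. Passing tests show the estimator ranks the
families correctly under these conditions; they do not certify absolute
calibration under informative censoring, nor behavior under covariate
correlation or model misspecification beyond the simulated kind.

## Evaluation

* Validation loss: the same interval-censored joint negative
  log-likelihood used in training, summed over individuals.
* Per-transition MSE: mean squared difference between predicted and
  generating per-individual probabilities, reported for the stay
  probability and each destination.
* Brier score at `t = 5`: squared distance between the predicted
  occupation `pi0 P_i^t` and the observed one-hot state, averaged over
  individuals. Interval-censored individuals are averaged over their
  `t2 - t1` candidate transition times in `(t1, t2]` (a candidate at or
  before the horizon counts as absorbed, later candidates as still in the
  origin), making the printed normalizer an exact mean. Right-censored
  individuals whose censoring time precedes the horizon have an unknown
  state there and are excluded by default (`include_unknown=True` scores
  them as still at the origin instead); censored at or after the horizon
  they count as occupying the origin state.

The replicate study driver (`dtmarkov.study`) generates independent
train(3000)/validation(1000) pairs from per-replicate child seeds,
fits all three families with the shared protocol, and reports the median
and 2.5/97.5 percentile of each reference-minus-ANN difference across
replicates. The scripted reproduction uses 5 replicates — enough for a
stable sign and rough magnitude of every difference at desk scale, though
the across-replicate spread of the linear-versus-ANN loss difference in
particular is large relative to its median, so that metric is the
noisiest of the ten.

## Known limitations

* One modeled origin row per model object; multi-hop trajectories are
  composed, not jointly fitted.
* No time-varying covariates, no left censoring or truncation.
* The likelihood treats interval endpoints and censoring times as
  non-informative; under mechanisms where they encode the event time (as
  in the generator) absolute probability estimates are biased for every
  family, and only model comparisons are unbiased.
* The Brier exclusion rule for early-censored individuals conditions the
  scored subpopulation on censoring, a mild selection effect switchable
  via `include_unknown`.
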
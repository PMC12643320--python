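# Methods

`srtrace` models trial-by-trial reaction times (RTs) in graph sequence
learning tasks: a participant watches a stream of stimuli generated by a
random walk on a hidden 15-node graph and responds to each one; RTs speed up
for transitions the participant has come to expect.  The package asks *which
learning rule* produces those expectations, by fitting competing trial-level
learners to RT sequences and by testing model-agnostic sequence signatures.

## Task structure and graphs

All stimulus graphs are connected, undirected and 4-regular on 15 nodes, so
every edge has the same one-step transition probability (0.25) under a random
walk.  Three families are provided:

* **modular** — three 5-cliques minus one internal edge, joined in a ring by
  three cross-cluster edges.  Matched one-step probabilities with unmatched
  multi-step structure is what makes this graph diagnostic: any RT difference
  between within- and cross-cluster transitions must reflect predictions that
  integrate more than one step.
* **lattice** — a ring lattice with edges at circular distances 1 and 2.
* **random** — uniformly sampled connected 4-regular graphs, resampled per
  subject.

Published descriptions of this task family under-determine the exact lattice
and random topologies; the constructions above preserve the matched-degree
property the cross-cluster analyses rely on, and both are configurable.
A session is one stage of 1500 random-walk
trials; subjects perform two stages with counterbalanced order.  Node
indices are 0-based in memory and 1-based in files.

## Learners

Each learner maps the node sequence to a per-trial expectancy of the upcoming
node, read from its state *before* that trial is observed.

* **Recency** — a vector `W` (init 1/15) updated as
  `W <- (1-a) W + a onehot(s_t)`: exponentially recency-weighted node
  frequencies, unconditional on the predecessor.
* **One-step** — a transition matrix `T` (init 1/15) with row decay
  `T[s_prev,:] *= (1-a)` then `T[s_prev,s_t] += a`.
* **SR-TD(lambda)** — the successor representation
  `M = T + g T^2 + g^2 T^3 + ...` (one-step-ahead convention, equal to
  `T (I - g T)^{-1}`), learned by temporal-difference updates with a dutch
  eligibility trace:

      e[s_prev] <- (1-a) e[s_prev] + 1
      delta      = onehot(s_t) + g M[s_t,:] - M[s_prev,:]
      M[s',:]   += a e[s'] delta   for every state s'
      e         <- g l e

  The trace is incremented *before* the update, so the current transition is
  itself trace-weighted.  `lambda = 0` is pure bootstrapping (only the
  predecessor updates); `lambda = 1` is Monte-Carlo-like trace learning.
  `M` is initialized at the SR of the uniform transition matrix (every entry
  `1/(15(1-g))`) and is never renormalized during learning; the behavioral
  readout is `M[s_prev,s_t] / sum(M[s_prev,:])`.
* **Static SR** — the SR of the empirical transition matrix of the entire
  observed sequence; a no-learning yardstick.
* **Trace-only Hebbian (lambda = 1 reference)** — when the trace decays by
  exactly `g`, successive bootstrap terms telescope away, so an equivalent
  update needs no error vector at all: increment the trace, apply forgetting
  `M[s_prev,:] *= (1-a)`, credit the observed node `M[:,s_t] += a e`, decay
  `e <- g e`.  Its fixed point is the SR up to a small row rescaling from the
  dutch increment, which the normalized readout removes.  The telescoping
  identity is exact at a frozen `M` up to a `g^(steps-to-end)` boundary term;
  `learners.bootstrap_cancellation_terms` verifies it numerically.  Several
  trace-only variants exist with distinct transients; this one is the
  package's reference choice and is used for signature simulations, not for
  subject fitting.

Numerical guard: if any `|M|` entry exceeds 1e3 during a likelihood
evaluation the parameter point is rejected (large `a*g*l` combinations can
diverge).  The hot forward passes are numba-compiled (`_kernels`); a
stateful pure-Python implementation in `learners` serves as the tested
reference.

## Observation model

RTs follow a shifted log-normal: `log(rt_t - shift) ~ N(mu_t, sigma^2)`, with
`shift = shift_frac * min(valid rt)` per subject and

    mu_t = mu0 + beta_trial * trial + target_offsets + beta_A * A_t
         [+ beta_W * W_t] + beta_ntrials * r_ntrials + beta_lag10 * r_lag10

where `A_t` is the higher-order learner's expectancy, `W_t` the recency
expectancy (combined models only), `trial` is rescaled to [0,1] within stage,
motor-target category 1 is absorbed into `mu0` with offsets for categories
2–15, and the nuisance regressors are trials-since-last-occurrence of the
current node and `log(1 + count in the last 10 trials)` (the `+1` keeps zero
counts finite).  Nuisance regressors are z-scored within session so their
weights are comparable across subjects (configurable off).  A combined
model's recency term reads `W[s_t]` — the recency vector is indexed by the
upcoming node only.  The baseline model carries no node-prediction terms at
all.

Incorrect trials and RTs below 30 ms are excluded from the likelihood but
still advance learner state; the first 500 trials of each stage equilibrate
the learner and contribute no likelihood, which removes sensitivity to the
initialization of `M`.

## Hierarchical estimation

Session-level parameters live on an unconstrained scale (logit for rates,
discount, trace decay and shift fraction; log for sigma; identity otherwise)
with a population Gaussian prior whose covariance is fixed at the identity.
EM alternates MAP fits per session with a least-squares update of the group
mean and the stage-difference coefficients (covariate −1/+1 for first/second
stage), stopping when the group mean moves less than 1e-3 (max 50
iterations).  MAP fits are multi-start L-BFGS; because the linear
coefficients have a closed-form ridge solution given the learner block, the
optimizer searches only 4–6 nonlinear coordinates.  Warm starts carry MAP
vectors across EM iterations.

Model evidence per session is the Laplace approximation
`NLML = negLogPost(theta_map) − (d/2) log 2π + ½ log det H`, with `H` a
finite-difference Hessian of the full objective (positive definiteness is
checked; non-PD fits are flagged and eigenvalue-clipped).  Laplace is exact
for conjugate Gaussian problems, which the tests use as an oracle.  Model
scores add one NLL unit per group-level parameter (the AIC/2 convention;
the per-parameter unit is configurable) divided equally between sessions, and
models are compared by paired one-sided t-tests on per-session scores.

Caveats: the shift parameter sits against the `rt > shift` support boundary,
so its Laplace SD is unreliable (a generic property of threshold parameters
in shifted distributions); and Laplace error can break exact EM monotonicity
in occasional iterations — both are tested at the rates observed rather than
asserted exactly.

## Sequence signatures

Trace and bootstrap updating leave distinct fingerprints that need no model
fit.  In `SXTST` (all of S, X, T distinct), a trace learner strengthens
S→T at the moment T appears after S's trace was set — so the closing S→T is
faster than in the recency-matched control `X1X2TST` (the fillers may
coincide; only S-recency is broken).  In `BTSBST`, a bootstrap learner
chains the earlier B→T prediction into S via the S→B backup — faster closing
S→T than in `XTSBST`.  Windows are matched on the raw node sequence
(excluded trials still drive perception) but a match is dropped when its
final RT is invalid; a window matching a test template is never counted as a
control.  Contrasts are fit on RT in ms with `statsmodels` MixedLM: fixed
effects for the indicator and motor targets, random intercept and slope by
subject, and a graphset variance component when several graph instances are
present (statsmodels has no fully crossed random effects; the nested
approximation is flagged, with fallbacks to random intercepts and then OLS).

Two caveats found in simulation: SR-TD(1) itself shows a *transient*
bootstrap effect because cancellation only lands on the following trial, so
the bootstrap-free Hebbian learner is the clean trace agent; and both
contrasts carry a small selection confound (conditioning on a repeated
window element selects locally lingering walks), which shrinks like `g^3`
versus `g` for the direct effects — demonstration agents therefore use
`g = 0.5`, learning rate 0.25, expectancy weight −3 and sigma 0.1 on random
graphs, where the direct effects dominate at a few dozen simulated subjects.

The novel-cluster analysis residualizes log RTs against a baseline model
(trial and motor terms only), finds the first and second nodes after each
cross-cluster transition on the modular graph, and fits
`resid ~ C(lag, Sum) + cluster_step` with a random `cluster_step` slope by
subject, where lag (trials since that node last occurred) is capped at 100
and effects-coded.  An SR predicts a negative `cluster_step` effect (second
entry faster); a pure recency learner does not.

## Synthetic cohorts

`synth.simulate_cohort` draws session parameters from the group Gaussian on
the unconstrained scale, simulates walks and RTs through the exact
observation model above (so generator and fitter share one definition of
`mu_t`), assigns a seeded random node→motor-category bijection per subject,
and injects contamination: incorrect trials keep their RT but are flagged
(3% default), fast guesses are uniform on (1, 30) ms (0.5% default); both
rates are placeholders exercising the preprocessing rules, as realistic rates
are not established.  Default group means — baseline 6.0 log-ms over a
250 ms shift, practice slope −0.15, expectancy weights −2.0 (SR) and −1.0
(recency), learning rates 0.15, discount 0.8, trace decay 0.7, sigma 0.2 —
are values at which a 40-subject, 1500-trial recovery study is informative
while staying in the range human fits report; between-subject SDs are
0.5–0.8 on the unconstrained scale.  The generator reproduces the
statistical structure the analysis assumes and nothing more: no residual
autocorrelation, no fatigue beyond the practice slope, no lapse process — so
green tests certify the machinery and the logic of the analyses, not the fit
of the model family to real humans.

## Study sizes and numerical choices

Test-suite studies run at desk scale, chosen so the full suite completes in
minutes: recovery uses 40 sessions × 10 replicate cohorts (subject-level
Pearson r ≥ 0.5 for the six learner parameters in ≥ 9/10), the
free-vs-fixed-lambda comparison 12 sessions × 10 cohorts, model
identification 10 sessions × 3 cohorts, signatures 24 agents × 3 replicate
cohorts with majority voting (the selection confound above makes single
replicates borderline at this n).  SR-TD convergence is checked on
2×10^5-step walks at `a = 0.02` with `M` time-averaged over the final half —
the time average suppresses the `O(sqrt(a))` steady-state fluctuation around
the fixed point, which at this learning rate would otherwise exceed the
0.05 error bound without any actual bias (error falls to ~0.01 at
`a = 0.005`).  All randomness flows from explicit seeds through
`io.derive_seed(master, label)`; reports serialize floats at 10 significant
digits.

## Known limitations

* Real-data features the generator omits (above) mean parameter-recovery
  results bound what fits to human data can show, not guarantee it.
* Crossed random effects (subject × graphset) are approximated as nested
  variance components.
* The AIC share per group parameter and the stage-coefficient scope (all
  parameters) follow one reading of under-specified conventions; both are
  explicit options in the code.
* The iterated one-step (model-based SR) learner family is deliberately out
  of scope.
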
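# srtrace

Trial-by-trial successor-representation learning analysis of serial reaction
times on graph walks.

## What this is for

In graph sequence learning tasks, people respond to a stream of stimuli
generated by a random walk on a hidden graph, and their reaction times (RTs)
speed up on transitions they have learned to expect.  Block-averaged RTs are
known to track the *successor representation* (SR) — the discounted future
state-occupancy matrix M = T + γT² + γ²T³ + … = T(I − γT)⁻¹ — but averages
cannot say *how* that long-run prediction is learned trial by trial.  The
candidate mechanisms have distinct transient dynamics: TD bootstrapping
(SR-TD(0)) chains one-step backups, eligibility traces (SR-TD(1), or an
equivalent trace-only Hebbian rule) broadcast each encounter to recently
visited states, and SR-TD(λ) interpolates between them via a dutch trace

    e[s₋] ← (1−α)e[s₋] + 1
    δ     = 𝟙(s) + γM[s,:] − M[s₋,:]
    M     ← M + α e δᵀ
    e     ← γλ e

This package is for computational cognitive modelers who want to run that
analysis end to end on trial tables, or to study its statistical behavior on
synthetic data where the true learning rule is known.  It provides:

* the three 15-node, 4-regular stimulus graph families (modular / lattice /
  random) and random-walk sequence generation;
* trial-level learners: recency (unconditional exponential frequency
  vector), one-step transition, SR-TD(λ), static (no-learning) SR, a
  trace-only Hebbian λ=1 reference, and closed-form SR oracles;
* a shifted log-normal RT likelihood, log(rt − shift) ~ N(μₜ, σ²), where μₜ
  combines the learner's expectancy of the upcoming node with practice,
  motor-target and recency-nuisance terms;
* hierarchical fitting (EM with per-session MAP under an identity-covariance
  Gaussian prior on an unconstrained scale), Laplace-approximated marginal
  likelihoods, AIC-penalized scores and paired model comparisons;
* model-agnostic sequence signatures: the SXTST-vs-X₁X₂TST trace contrast,
  the BTSBST-vs-XTSBST bootstrap contrast, and the first-vs-second
  cluster-entry analysis on the modular graph;
* a synthetic-cohort generator that mirrors the observation model exactly
  and writes truth records for parameter- and model-recovery studies.

## Worked example

Simulate a small cohort of combined recency + SR-TD(λ) learners, fit the
recency-only and combined models hierarchically, compare them, and run the
trace signature:

```python
from srtrace import hierarchical as hier, rt_model, signatures, synth

spec = synth.CohortSpec(n_subjects=8, stages_per_subject=1, n_trials=1500, seed=7)
trials, truth = synth.simulate_cohort(spec)
sessions = rt_model.sessions_from_table(rt_model.preprocess(trials))

opts = hier.FitOptions(n_restarts=2, em_max_iter=6, seed=1)
scores = {}
for model_id in ("recency", "combined_sr_td"):
    result = hier.em_fit(rt_model.MODELS[model_id], sessions, opts)
    scores[model_id] = hier.model_score(result, model_id)
    gm = result.group.natural_means()
    print(f"{model_id}: mean score {scores[model_id].per_subject_score.mean():.1f}"
          + (f", group gamma {gm['gamma']:.2f}, lambda {gm['lam']:.2f}"
             if "gamma" in gm else ""))

cmp = hier.compare_models(scores["combined_sr_td"], scores["recency"])
print(f"combined vs recency: t={cmp['t_statistic']:.2f}, "
      f"one-sided p={cmp['one_sided_p']:.4f}, "
      f"mean improvement {cmp['mean_diff']:.2f} NLML units/subject")

res = signatures.signature_contrast(
    signatures.collect_pattern_matches(trials, "trace"), "trace")
print(f"trace signature: {res.effect_estimate:.1f} ms (z={res.z_or_t:.2f}, "
      f"p={res.p:.4g}, n={res.n_obs} windows)")
```

Output (about a minute on one core):

```
recency: mean score 5066.9
combined_sr_td: mean score 4987.6, group gamma 0.76, lambda 0.66
combined vs recency: t=6.27, one-sided p=0.0002, mean improvement 79.24 NLML units/subject
trace signature: -7.7 ms (z=-2.26, p=0.0237, n=1646 windows)
```

Reading this: per-subject scores are AIC-penalized negative log marginal
likelihoods (lower is better), so the combined model's 79-unit mean
improvement — confirmed by the paired t-test — says these RT sequences carry
higher-order SR structure beyond recency, as they should given the
generator.  The recovered group discount γ ≈ 0.76 and trace parameter
λ ≈ 0.66 sit near the generating values (0.80, 0.70).  The trace signature
is the RT difference on the closing S→T of SXTST windows versus
recency-matched controls: −7.7 ms means facilitation, the fingerprint of
trace-based updating.

The same steps are available from a shell: `srtrace simulate`, `srtrace
fit`, `srtrace compare`, `srtrace signatures`, `srtrace recover`, and
`srtrace pipeline --config run.yaml` for the whole sequence on one trial
table.  Trial tables are plain CSV/TSV with columns
`subject,graphset,stage,trial,node,target,rt_ms,correct`.

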
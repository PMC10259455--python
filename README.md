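# discernddm

Simulated social-media sharing experiments with veracity-coupled feedback
("trust"/"distrust" reactions), the discernment statistics used to compare
feedback environments, and a from-scratch hierarchical Bayesian
drift-diffusion model with MCMC fitting, convergence diagnostics,
HDI-based group comparisons, posterior-predictive simulation and parameter
recovery.

## What is in the box

| module | contents |
|---|---|
| `discernddm.synth` | generators for posts, multi-select reaction tables, per-post feedback counts, diffusion-driven sharing trials, belief-accuracy ratings and memory-check exclusions |
| `discernddm.ddm` | four-parameter Wiener diffusion model: defective first-passage density (dual small/large-time series), closed-form choice probability, Euler simulator with Brownian-bridge absorption correction, trial log likelihood |
| `discernddm.inference` | hierarchical Metropolis-within-Gibbs sampler (group means/spreads + subject parameters), Gelman–Rubin diagnostic, highest-density intervals, credible group differences |
| `discernddm.metrics` | button-wise / sharing / veracity-coded discernment, belief error, engagement, partisan post selection by per-post Pearson chi-square, one-sample t and explicit-sums-of-squares ANOVAs |
| `discernddm.pipeline` + `discernddm.cli` | config-driven end-to-end runs: simulate → summarize → fit → diagnose → compare → recovery / posterior-predictive reports, with seeded manifests |

The model's time axis is log-milliseconds: trial tables store
`rt = t0 + decision_time` on that scale, matching non-decision times near
7 (`log(1000 ms) ≈ 6.9`). The diffusion coefficient is fixed at 1 and the
starting point `z` is relative (a fraction of the bound separation `a`).
The upper bound codes the veracity-promoting response (share a true post /
skip a false post).

Generating group values for the two sharing experiments are bundled in
`discernddm.config` (`TABLE1_EXP2`, `TABLE2_EXP3`) along with the published
95% credible intervals used by the recovery report. Group *spreads* are not
published; the defaults (0.2 for drift, 0.35 for bound, 0.15 logit-z,
0.3 for t0) give subject-level heterogeneity consistent with the implied
posterior widths at the reported cohort sizes.

## CLI

```bash
# simulate an experiment (exp2 = five feedback environments, exp3 = three)
discernddm simulate --template exp2 --seed 1 --out runs/exp2

# per-participant discernment + engagement for one trial table
discernddm metrics --trials runs/exp2/trials_trust.csv --out runs/trust_metrics.csv

# hierarchical fit (veracity-coded trials; CSV with participant_id, rt, response)
discernddm fit --trials runs/exp2/trials_trust.csv --out runs/fit_trust --n-chains 5

# convergence + HDI comparison of saved posteriors
discernddm diagnose --posterior runs/fit_trust/posterior.csv
discernddm compare --posterior-a runs/fit_trust/posterior.csv \
                   --posterior-b runs/fit_base/posterior.csv --parameter mu_v

# parameter recovery and the full bundle
discernddm recover --template exp2 --seed 1 --out runs/recovery
discernddm run-all --template exp2 --seed 1 --out runs/full --fast
```

`--fast` shrinks cohorts and the MCMC protocol for smoke runs. Every stage
derives its own child seed from the master seed through a fixed counter
(`discernddm.config.child_seed`), so identical `(config, seed)` pairs give
byte-identical manifests and any stage can be re-run in isolation.

Experiment configs can also be given as YAML (`--config`), mirroring
`ExperimentConfig.to_dict()`: template, cohort sizes per environment, post
counts, generating group parameters per pooled fit group, and the MCMC
protocol.

## Notes on calibration anchors

Reported behavioral group means (button discernment 0.06/0.034/0.099/0.156,
usage rates, sharing discernment 0.18, share rates) are used to calibrate
the generators in closed form, not as reproduction targets: they come from
real participants. In particular, the pure diffusion generator constrains
the mean share rate to ≈ 50% for a near-symmetric starting point, so
observed share rates of 26–36% are not reproducible from the published
diffusion parameters alone — the veracity-coded model is agnostic to the
overall share/skip bias.
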
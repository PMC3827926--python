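# profreg — Dirichlet-process profile regression for case-control data

Epidemiological exposures are usually multi-dimensional — a smoking history
carries intensity, duration, time since cessation and cumulative dose — yet
they are routinely collapsed into a single summary (pack-years) before being
regressed on disease. `profreg` implements **profile regression**: a joint
Bayesian mixture model in which a subject's categorical exposure *profile*
and their binary outcome share one latent cluster allocation, so clusters
are shaped simultaneously by exposure patterns and by risk. It is aimed at
epidemiologists and biostatisticians who want cluster-level and
profile-level risk estimates with honest uncertainty, without assuming
additivity of exposure effects on the log-odds scale.

## The model

For subject $i$ with outcome $y_i\in\{0,1\}$, profile
$x_i=(x_{i1},\dots,x_{iJ})$ (covariate $j$ taking one of $L_j$ categories,
missing values allowed) and fixed-effect confounders $w_i$:

$$p(y_i, x_i \mid \Theta) \;=\; \sum_{c=1}^{\infty} \psi_c\;
p(y_i \mid \theta_c, \beta)\; p(x_i \mid \phi_c)$$

* **weights** — stick-breaking Dirichlet-process prior:
  $\psi_c = V_c \prod_{l<c}(1-V_l)$, $V_c \sim \mathrm{Beta}(1,\alpha)$;
* **response sub-model** — $y_i \sim \mathrm{Bernoulli}(\pi_i)$ with
  $\mathrm{logit}(\pi_i) = \theta_{Z_i} + \beta' w_i$, where $\theta_c$ is
  the cluster log odds of disease;
* **profile sub-model** — $x_{ij} \mid Z_i{=}c \sim
  \mathrm{Multinomial}(1, \phi_{cj})$, covariates independent given the
  cluster.

Inference is by a truncation-free slice MCMC sampler (conjugate Gibbs for
$V$ and $\phi$, Metropolis-within-Gibbs for $\theta$ and $\beta$, missing
profile entries imputed inside the chain). The label-switching-invariant
posterior is summarised by a **dissimilarity matrix** (share of sweeps two
subjects occupy different components), reduced to a representative hard
clustering by PAM with silhouette-selected $k$. Hypothetical
**pseudo-profiles** (partially specified vectors; `NA` entries are
marginalised) are pushed through the posterior to get cluster-averaged
log-odds-ratio densities against a reference profile, plus ordinal
expected-category values for the covariates left unspecified.

## Worked example

```python
import profreg as pr

truth = pr.icare_like_truth()                    # 4 latent clusters, J=4, L=5
data, labels = pr.generate_population(truth, 1500, seed=11)

chain = pr.run_chain(data, pr.PriorSpec(alpha=1.0),
                     pr.SamplerControls(n_sweeps=1200, n_burnin=400, thin=5, seed=12))

D = pr.dissimilarity(chain)
part = pr.representative_partition(D, range(2, 9))
summ = pr.cluster_summaries(chain, part)

heavy = pr.PseudoProfile((4, 4, pr.MISSING, pr.MISSING), "heavy")
ref = pr.PseudoProfile((0, 0, 0, 0), "never-exposed")
d = pr.predictive_log_or(heavy, ref, chain)

pihat = pr.fitted_probabilities(chain, data)
fa = pr.fit_metrics(data.y, pihat)
```

Output of the full script (`N=1500`, truth log ORs `(0, 1.5, 3, 4.5)`):

```
dataset: Dataset(N=1500, J=4, cardinalities=(5, 5, 5, 5), fixed_effects=1, cases=767)
posterior mean K = 5.38
representative clustering: 4 clusters, silhouette 0.994
  cluster 1: n= 384  log OR  0.00  95% CI [ 0.00,  0.00]
  cluster 2: n= 394  log OR  1.76  95% CI [ 1.38,  2.13]
  cluster 3: n= 373  log OR  2.89  95% CI [ 2.57,  3.23]
  cluster 4: n= 349  log OR  4.34  95% CI [ 3.87,  4.81]
pseudo-profile log OR (heavy vs never-exposed): 4.35 (0.26)
expected category of covariate 4 for that profile: 3.77 (0.04)
fit: RMSE 0.402  MAE 0.325  misclassification 0.236
ARI vs hidden labels: 0.998
```

Reading it: the sampler keeps ~5 occupied components; the consensus
clustering recovers the four generative clusters almost exactly (adjusted
Rand index 0.998), with posterior-mean log odds ratios (relative to the
lowest-risk cluster 1) close to the generative values. The pseudo-profile
set to the two heaviest exposure categories with the other covariates
marginalised lands at log OR 4.35 with posterior SD 0.26 — the
"mean (sd)" shape used for predictive scenario tables — and its implied
expected category for the cumulative-dose covariate is 3.77 of a 0–4 scale.
The fit metrics are in-sample logistic-residual summaries usable to compare
any model that emits case probabilities.

## Command line

Every step is also a subcommand (`profreg --help`): `simulate` (synthetic
populations and two ten-binary-covariate benchmark scenarios), `discretize`
(raw exposures → category codes via a JSON bin scheme; the packaged smoking
scheme is `src/profreg/data/smoking_categories.json`), `fit` (chain written
as a versioned directory of text files), `postprocess`, `predict` and
`evaluate`. Example:

```bash
profreg simulate icare-like --n 2000 --seed 1 --out sim/
profreg fit sim/data.csv sim/config.json --out chain/ --seed 2 --alpha 1.0
profreg postprocess chain/ --out post/
profreg evaluate sim/data.csv sim/config.json --chain chain/ --out metrics.csv
```

The concentration parameter (`--alpha`, default 1.0; try 3.6 or 10 for
sensitivity analyses) controls the prior number of occupied clusters,
approximately $\alpha\log(1+N/\alpha)$ (`profreg.expected_clusters`).

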
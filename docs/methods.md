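# Methods

This note records the model, the numerical and design choices behind
`profreg`, and what the synthetic benchmarks do and do not establish.

## Model and priors

The joint density of outcome and profile is an infinite mixture

p(y_i, x_i | Θ) = Σ_c ψ_c · Bernoulli(y_i; expit(θ_c + β′w_i)) · Π_j Multinomial(x_ij; φ_cj),

with stick-breaking weights ψ_c = V_c Π_{l<c}(1−V_l), V_c ~ Beta(1, α).
The concentration α is **fixed** (no hyperprior): it is an analysis choice,
default 1.0, with 3.6 and 10 as conventional sensitivity values; the prior
expectation of the number of occupied clusters is approximately
α·log(1+N/α), exposed as `expected_clusters`. Because the exact
hyperparameters used in comparable analyses are not publicly specified, the
remaining priors are this package's own weakly-informative defaults,
declared in `PriorSpec` and configurable:

| parameter | prior | default | rationale |
|---|---|---|---|
| φ_cj | Dirichlet(a) | a = (1,…,1) | conjugate; flat over the simplex |
| θ_c | Student-t(df, loc, scale) | t(7, 0, 2.5) | heavy-tailed, weakly informative on the log-odds scale |
| β_k | Normal(mean, sd) | N(0, 5) | diffuse for dummy-coded/centred confounders |

θ_c is the cluster log odds of disease *at mean confounder values*: fixed
effects are centred internally (the centring means are stored in the chain
and fitted probabilities are computed on the raw scale). Slopes are
unaffected by centring, and all reported odds-ratio contrasts cancel β′w
exactly. Missing outcomes are rejected at load; missing profile entries are
explicit sentinels (`MISSING = -1`) sampled within the chain.

## Sampler

A dependent-slice scheme keeps the mixture untruncated: u_i ~ U(0, ψ_{Z_i}),
sticks are extended from the prior until the residual mass Π(1−V_l) falls
below min_i u_i (hard cap 10,000 extensions per sweep, which aborts with a
diagnostic rather than silently truncating), and Z_i is resampled among
components with ψ_c > u_i with probability proportional to the data
likelihood. Allocation marginalises missing profile entries; imputation
from the allocated component immediately afterwards makes the pair a joint
draw of (Z, x_mis). V and φ updates are conjugate; θ (per occupied
component) and β (coordinate-wise) use random-walk Metropolis whose scales
adapt by ×/÷1.1 toward an acceptance band of [0.2, 0.5] during burn-in only
and are frozen afterwards, preserving detailed balance for retained sweeps.

Two points proved load-bearing during development and are worth stating as
constraints:

1. **Empty components may only be pruned from the tail.** The stick
   fraction of an interior empty component conditions on the counts of all
   later components; dropping interior empties and compacting indices
   measurably biases the partition law toward too few clusters (prior-only
   pairwise co-clustering 0.59 instead of the exact 0.5 at α=1). The live
   state therefore keeps interior empties; compaction to occupied
   components happens only in the *stored* chain.
2. **Initial states are drawn from the model prior, including the correct
   cluster-to-position label law**: sticks from Beta(1, α) until the
   residual mass is below 1e-9, allocations i.i.d. over the resulting
   weights. Packing clusters into leading stick positions (e.g. labelling a
   partition in order of first appearance) is *not* stationary and inflates
   the early cluster count. With the likelihood disabled the chain
   therefore starts at stationarity, which turns the prior-law tests into
   sensitive drift detectors for kernel bias.

Label-swap moves (default 3 per sweep) exchange the contents (θ, φ) and
members of two components while keeping stick positions fixed, accepted
with probability min{1, (ψ_c/ψ_d)^{n_d−n_c}}; they are applied at sweep end,
just before the slice variables are refreshed, so they act on the
slice-marginal posterior. The recorded joint log likelihood excludes the
allocation mass term Σ log ψ_{Z_i}; this makes it invariant under any
consistent relabelling (checked after every accepted swap) and suitable as
a stability diagnostic.

Default run lengths are 12,000 sweeps with 2,000 burn-in and thinning 10; a
seed is mandatory and chains are bit-reproducible. Chains persist as a
directory of versioned text files (JSON metadata, gzipped CSV allocations,
CSV scalar trace, gzipped JSON-lines component parameters).

## Post-processing

δ_ik = share of retained sweeps allocating i and k to different components.
PAM (classic BUILD + SWAP, deterministic; verified to match the reference R
implementation's objective on fixed inputs) is run on δ for each k in a
range (default 2–20), and k is chosen by maximum average silhouette width,
ties toward smaller k — the selection rule is this package's choice, as is
the "square-error" alternative's omission. Cluster risk is summarised by
the member-averaged θ per sweep (robust to representative clusters
straddling chain components); clusters are reordered by posterior mean log
odds and log OR draws are taken against the lowest-risk (reference)
cluster. A degenerate all-zero dissimilarity collapses to a single cluster
with a warning rather than an error.

## Pseudo-profiles

Allocation of a pseudo-profile at sweep t is restricted to that sweep's
*occupied* components (no residual-stick mass): predictive risk is meant to
reflect fitted clusters, and this is the documented variant. Averaging is
on the **log-odds scale** (λ* = Σ_c p_c θ_c), the cluster-averaged log odds;
log ORs are per-sweep differences against a user-supplied reference profile
(not hard-coded; the all-zeros never-exposed profile in the examples).
Ordinal expected-category values are Σ_c p_c Σ_l l·φ_cjl per sweep,
reported as mean (sd). Densities use a Gaussian KDE with Scott's bandwidth
on a fixed grid (draws ± 3 bandwidths, 256 points) so figures reproduce
exactly. Predictive operations never touch the chain (checksum-verified in
tests). These summaries are associational; no causal reading is intended.

## Fit metrics

On probability-scale residuals y − π̂: RMSE, MAE and misclassification
error with threshold 0.5, a tie at exactly 0.5 counting as predicted
control. For a chain, π̂_i is the posterior mean of expit(θ_{Z_i} + β′w_i)
over retained sweeps — in-sample residuals, labelled as such. The metric
interface accepts any external probability vector, so tree or logistic
comparators can be scored identically without being reimplemented here.

## Synthetic data: what it emulates, what it does not

`icare_like_truth()` mirrors the structure of a large smoking case-control
study: J=4 five-category exposure covariates; K_true=4 clusters with equal
weights; a never-exposed cluster concentrated (0.97) on category 0 and
three exposure clusters with increasing modal categories (modal probability
0.92, consistent with the 0.9–1.0 concentrations typical of well-separated
consensus-cluster profiles); cluster log odds = baseline −2.25 plus log-OR
contrasts (0, 1.5, 3, 4.5), so the log OR span is ~0–4.5 while the sampled
case fraction stays near the ~45–50% of a case-control design; one binary
occupational confounder (p=0.3, β=0.4); MCAR missingness of 0.3% on the
first and last covariates. The exact population case fraction has a closed
form used as a generator oracle.

Two benchmark scenarios over ten binary covariates ship with surrogate
coefficients in versioned JSON (`data/scenario_logistic.json`,
`data/scenario_profiles.json`): a logistic model with two pairwise
interactions (returns the true linear predictor; its population AUC is
checked by exact enumeration of all 2^10 patterns) and a
contrasting-profiles mixture with cluster-specific risks (returns hidden
labels).

What passing these benchmarks does **not** show: real exposure data have
correlated covariates *within* clusters, informative (non-MCAR)
missingness, and far less separated clusters; recovery and coverage results
here are statements about the well-separated regime the generators define.

## Problem sizes and numerical choices

Test and reproduction runs are scaled to desk hardware as package choices:
the recovery study uses 20 replicates of N=2000 at 900 sweeps (300
burn-in, thin 5); the small-sample exactness check enumerates all 203
partitions of N=6 against 50,000 sweeps; prior-law checks average many
short independent chains started at stationarity, with across-chain
standard errors (the cluster count mixes slowly within a chain). Stick
fractions are clipped to (1e-12, 1−1e-12); slice variables floored at
1e-300; Dirichlet draws use gamma normalisation with zero-shape padding for
ragged cardinalities; silhouette ties break toward smaller k; PAM is
deterministic, so partitions are bit-reproducible.

## Known limitations

Continuous or mixed continuous/categorical profiles are out of scope, as
are survival/count outcomes, α hyperpriors, truncated blocked-Gibbs or
variational inference, and alternative consensus-clustering losses. The
cluster-count approximation α·log(1+N/α) is asymptotic: at α=1 its relative
error versus the exact CRP expectation is ~22% at N=10 and ~12% at N=100,
shrinking below 10% only for larger N — tests that compare the two at small
N document this gap rather than hide it.
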
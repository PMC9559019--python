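# Methods

## The estimation problem

A set of p independent SNPs **G** is associated with a continuous outcome
Y. Part of that association flows through K measured mediators M_1 … M_K
(effect sizes b_1 … b_K), but after conditioning on the known mediators a
residual per-SNP direct effect **c** remains. The package assumes this
residual is carried by a single unobserved ("hidden") mediator M_H, so
that **c** = **a**_H · b_H, where **a**_H holds the SNP effects on M_H and
b_H — the estimand — is the hidden mediator's effect on Y. Only a fraction
π_H of the SNPs affect M_H; the rest have a_Hj = 0.

The identifying assumption is that SNP effects on the hidden mediator are
drawn from the same distribution as SNP effects on the known mediators: a
spike-and-slab mixture of a point mass at zero and a Normal(μ_a, σ_a²)
"true effect" component. Because regression estimates carry sampling
error, the estimated vectors a\* and c\* are two-component Gaussian
mixtures — a near-zero-mean noise component and a shifted effect
component — which is what Steps 2–3 exploit.

## The three-step procedure

**Step 1 — mediation regressions.** An initial multiple regression of Y on
all SNPs (plus covariates) orients each SNP so its marginal outcome effect
is non-negative (columns with negative coefficients are recoded
dosage → 2 − dosage). Then each mediator is regressed on all SNPs jointly
(plus covariates and, when a causal order among mediators is declared, its
parent mediators), giving a\*_1 … a\*_K; and Y is regressed on all SNPs,
all mediators and covariates, giving c\* together with estimates of
b_1 … b_K. SNPs whose estimate in any of these vectors falls outside
[Q1 − 3·IQR, Q3 + 3·IQR] (linear-interpolation quartiles) are removed from
every downstream vector. Rank-deficient designs (p ≥ n) are rejected.

All OLS fits use a shared Cholesky solve of the normal equations with
classical standard errors; mediators with identical designs are fitted as
one multi-response solve. The test suite verifies coefficient and SE
agreement with statsmodels to 1e-8.

**Step 2 — two-component EM.** The concatenated a\* (all K mediators,
kept SNPs) and the kept c\* are each fitted with a two-component Gaussian
mixture by EM, with the mixing proportion initialised at 0.5. The
component with smaller |mean| is labelled *noise*, the other *effect*
(ties broken toward the smaller variance). To guard against poor local
optima the fit is repeated 15 times and the run whose effect-component
mean is the median across runs is kept, returning one coherent parameter
set (component-wise medians are available behind a flag).

Initialisation matters more than usual here: the data have a very tight
near-zero cluster (regression noise, sd of order the coefficient standard
error) beside a broad effect cluster, and both generic random starts and
model-based hierarchical initialisation can converge to spurious optima
that split the effect cluster instead. Each of the 15 runs is therefore
itself a small multi-start: EM is started from the exact 1-D 2-means
partition of the sorted values and from five random quantile-cut
partitions (component means/variances from each side of the cut), and the
best log-likelihood within the run wins. Convergence is declared when the
relative change in observed-data log-likelihood drops below 1e-8 (max
1000 iterations); a component variance falling below 1e-10 aborts the run
as degenerate.

**Step 3 — Gibbs sampling for b_H.** The kept c\* values enter the
mixture model

    c_j | z_j = 1  ~  Normal(0, σ1²)           (noise)
    c_j | z_j = 2  ~  Normal(b_H · μ_a, σ2²)   (effect)

with a categorical prior on z_j and a Normal(0, 100) prior on b_H. μ_a is
the effect-component mean of the a\* fit and the z-prior weights are the
component weights of the c\* fit. Both conditionals are exact — z_j is
categorical, and b_H is conjugate Normal with precision
1/100 + m·μ_a²/σ2² and mean precision⁻¹·μ_a·Σ_{z_j=2} c_j/σ2²
(m = #{z_j = 2}) — so the sampler is a plain two-block Gibbs scheme.
b_H starts at 0; z is drawn first in every sweep. The default chain is
30,000 sweeps with 5,000 burn-in. μ_a = 0 is rejected as unidentifiable.

*Where σ1² and σ2² come from.* By default both are the noise/effect
component variances of the **a\*** fit (`variance_source="a_star"`).
Under the decomposition c = a_H·b_H the dispersion of the effect
component of c\* is b_H²·σ_a², so plugging in σ_a² itself makes the
posterior deliberately conservative: its width is governed by the spread
of the SNP-effect distribution rather than shrinking with b_H. This
choice reproduces the conservative interval coverage, the
near-constant-in-b_H interval widths (slightly wider at small b_H) and
the mild downward bias at large b_H that the simulation study exhibits;
taking both variances from the c\* fit instead
(`variance_source="c_star"`) gives sampling-matched, much narrower
intervals and is available as an option. A consequence of the default is
that when no hidden mediator exists the intervals essentially always
include zero, i.e. the empirical type I error is close to 0 rather than
to the nominal 0.1.

*Label-switching adjustment.* When b_H ≈ 0 the c\* distribution is a
single Gaussian and EM may hand the "effect" role a nearly empty
component; the sampler then assigns almost no SNPs to z = 2 and the
posterior collapses to the prior (width ≈ 33). If the initial 90%
quantile interval is wider than 5, the c\* labels are flipped and Step 3
rerun; the result records the flip and the initial width.

Posterior summaries are the median, mean, 90% highest-density interval
(exact shortest window over the sorted draws) and 90% central quantile
interval. A single chain is the default; `gibbs_bh(..., n_chains=k)` runs
independent seeded chains and reports the split-R̂ diagnostic. The Gibbs kernel is numba-compiled when numba is importable,
with a pure-NumPy fallback; all variates are pregenerated from a seeded
`numpy.random.Generator`, so results are reproducible and identical
across the two kernels.

## The synthetic-data generator

The generator emulates the study's base case: n individuals; p SNPs drawn
independently with MAF ~ Uniform(0.1, 0.5) and dosages Binomial(2, MAF)
(Hardy–Weinberg, additive coding, no LD); per-mediator SNP effects from
the spike-and-slab mixture with nonzero probabilities
(0.5, 0.6, 0.8, 0.2, 0.5) for the five known mediators and π_H = 0.8 for
the hidden one, effect distribution Normal(0.2, 0.08²); mediators
M_k = intercept_k + a_kᵀG + ε_k with intercepts (50, 5, 10, 6, 15, 20)
and noise sds (1, 1, 1.5, 1.2, 1, 1); covariates C1 ~ Normal(7, 0.5²),
C2 ~ Normal(4, 0.4²); outcome
Y = 0.4·M1 + 0.2·M2 + 0.3·M3 + 0.2·M4 + 0.4·M5 + b_H·M_H
+ 0.8·C1 − 0.3·C2 + ε with ε ~ Normal(0, 0.2²). The small outcome noise
encodes the assumption that the hidden mediator absorbs essentially all
leftover genetic signal.

Scenario constructors cover the full nine-row study design: varying π_H
(0.3/0.5/1), negative known-mediator effects, sample size (25k/50k), one
or ten known mediators, causal edges among mediators
(child = intercept + aᵀG + coef·parent + noise; cycles rejected), a
two-level effect hierarchy, b_H = 0, and SNP counts 20/40/700. For the
ten-mediator case the per-mediator nuisance parameters (association
probabilities, intercepts, noise sds) recycle the base-case vectors —
only the mediator effect sizes are specified by the study design. The
two-level hierarchy draws a per-mediator centre
Normal(0.2, σ_L1²) and SNP effects Normal(centre, σ_L2²) with
σ_L1 : σ_L2 equal to the stated ratio and σ_L1² + σ_L2² = (0.08)², so the
0:1 ratio reduces bit-for-bit to the flat draw.

What the generator does *not* emulate: linkage disequilibrium, non-additive
genetic effects, binary traits, missing data, population structure, and
winner's-curse-inflated SNP selection. Passing tests therefore demonstrate
correctness of the pipeline under the stated generative model, not
robustness to these real-data complications.

Each replicate draws from one `numpy.random.Generator` seeded from
(master seed, replicate index) via `SeedSequence.spawn`, so replicates are
independent, order-insensitive and bitwise reproducible.

## Evaluation harness

`evaluate_setting` runs the full pipeline over replicated simulations and
reports: coverage (fraction of replicates whose 90% interval contains the
true b_H), empirical power or type I error (fraction whose interval
excludes zero), RMSE and mean bias of the posterior median and mean,
counts of point estimates outside the 1.5×IQR fences, mean interval width
and the number of label flips. Replicates that fail in any stage are
recorded with the error, excluded from metric denominators and counted
separately.

## Problem sizes and numerical defaults

Replicated studies in the tests and the acceptance script run at a desk
scale chosen to keep a full four-scenario study within minutes on one
core: n = 25,000 individuals, 70 SNPs, 200 replicates per scenario, and
chains shortened to 6,000 sweeps / 1,000 burn-in. The study design's own
sample-size variation shows the method is insensitive to n in this range,
and interval summaries stabilise well below 5,000 retained draws; spot
checks at n = 100,000 and p = 500 agree with the reported desk-scale
behaviour. Key defaults: EM runs 15 (6 starts each), EM tolerance 1e-8,
variance floor 1e-10, outlier multiplier 3, flip threshold 5, prior
variance 100, chain 30,000/5,000 at full scale.

## Known limitations

- A single hidden mediator; multiple hidden factors are not decomposed.
- Continuous outcomes only.
- Individual-level data (no summary-statistics / two-sample mode).
- Step-1 estimation uncertainty is not propagated into Step 3 beyond its
  effect on the fitted mixture variances.
- The conservative default for σ1²/σ2² trades power near b_H = 0 for
  coverage; users wanting calibrated (non-conservative) intervals should
  use `variance_source="c_star"` and expect materially lower coverage in
  exchange for nominal-width intervals.
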
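# Methods

This note documents the models implemented in `marshniche`, the choices made
where the procedure was genuinely open, and what the synthetic surveys do
and do not establish about real data.

## Occurrence model

For each species, presence/absence `y_i ∈ {0,1}` in quadrat `i` is modelled
as `P(y_i = 1) = Φ(f_i)`, with the latent suitability `f` given a Gaussian
process prior over environmental space — the quadrat × explanatory-variable
matrix. Natural-marsh niche models use redox potential, RTH and region; the
marsh-age models add age class (MR/AR/NAT).

**Kernel.** Squared-exponential over continuous covariates standardized to
zero mean and unit variance on the training data (prediction reuses the
training scaling, which is what makes transfer to restored marshes
well-defined):

    k(x, x') = σ² exp(−½ Σ_d ((x_d − x'_d)/ℓ_d)²) · Π_c s_c(x, x')

Each categorical covariate `c` (region, age class) contributes `s_c = 1`
when levels match and `exp(−1/ℓ_c²)` otherwise, so levels share statistical
strength rather than being modelled independently. Defaults: ℓ_d = 1
standardized unit, σ² = 1, ℓ_c = 1 (cross-level similarity e⁻¹ ≈ 0.37), a
diagonal jitter of 1e-6.

**Prior mean.** The "flat" latent prior is a constant mean at
`probit(p₀)` with the kernel's stationary variance. By default `p₀` is the
training prevalence, so predictions far from any training data revert to
the species' base rate; `prior_mean_prob=0.5` gives the zero-mean
alternative. Both readings of an uninformative prior are available because
the convention is not identifiable from the procedure alone.

**Inference.** Laplace approximation: Newton iteration on the penalized
log-likelihood locates the latent posterior mode (convergence when the
objective changes by <1e-8, at most 100 iterations, flagged if not
converged), and the negative Hessian there supplies the Gaussian
approximation. Probit quantities use `log_ndtr` throughout, so the ratio
φ/Φ is stable deep in the tails. Predictions use the standard identity
`P(y*=1) ≈ Φ(μ*/√(1+σ*²))` with the Laplace predictive moments. The test
suite checks the whole chain against a long-run MCMC sampler on the exact
model (≤8-point designs, maximum probability error ≤0.05) and against
closed-form properties (label-flip antisymmetry, reversion to the prior).

**Posterior draws.** Every interval in the pipeline is an equal-tailed
percentile interval over draws of the latent field mapped through Φ. Draws
use the joint Gaussian over the prediction points when there are ≤2,000 of
them (the exact Laplace joint, so spatially correlated uncertainty is
preserved in quadrat averages) and independent marginals above that, with
the choice logged. Default 1,000 draws; the reduced desk scale uses 200.

**Hyperparameters.** Optional bounded L-BFGS-B maximization of the Laplace
log marginal likelihood over log-lengthscales and log-variance (≤60
evaluations; bounds ℓ ∈ [0.05, 100] standardized units, σ² ∈ [0.01, 100]).
The optimized kernel is kept only if its marginal likelihood beats the
starting value, and optimizer failure falls back to the initial kernel with
a warning, never an abort. The fixed-default mode (all parameters 1) exists
for exact reproducibility and is the default in the pipeline, since the
original tool's precise initialization rules are not recoverable.

## Analysis stages

**Cross-validation.** Repeated simple random 75/25 splits (default 1,000;
reduced scale 100), refitting on each training part and scoring the holdout
by AUC. Splits are deliberately unstratified, matching the procedure being
reproduced; a split whose training or test part lacks both classes is
redrawn and counted. AUC is computed as the Mann–Whitney concordance via
midranks (ties count ½), which agrees exactly — not just to rounding — with
brute-force pairwise concordance. Species too rare for any valid split
yield a flagged result. Because the grand mean can pool runs or average
per-species means, both are reported.

**Transfer prediction.** Natural-marsh models predict every MR/AR quadrat;
per posterior draw the probabilities are averaged within an age class, and
the median and 2.5/97.5 percentiles across draws summarize expected
occupancy under available environmental conditions alone.

**Age effects at the optimum.** The age-class model's most favourable
conditions are found by searching the *observed* covariate vectors (redox,
RTH, region — with every age substitution considered) for the maximum
latent predictive mean; the search never leaves the sampled environmental
space, consistent with clipping niches by available conditions. All three
age classes are then evaluated at that one fixed environment, so the
contrast isolates the age effect. The posterior mode is the argmax of a
Gaussian KDE over the draws with reflection at 0 and 1 (a finite-draw mode
needs a density estimate; reflection avoids boundary bias), and the
interval is the 2.5/97.5 percentile band.

**Hierarchical partitioning.** The GP is fitted for all 2^k − 1 predictor
subsets; goodness of fit is the in-sample log-likelihood gain over the
prevalence-only null. This deviance-style measure is used because it makes
the Chevan–Sutherland averaging identity exact: each predictor's
independent contribution (the average over hierarchy levels of its mean
marginal gain) sums to the full-model gain to machine precision. A subset
whose fit fails is imputed the null fit and logged.

**Niche surfaces.** Predicted probability over an (RTH, redox) grid, with
cells outside the convex hull of the observed environment masked
(degenerate, collinear clouds fall back to on-segment membership; observed
points are never masked). Recovery tests evaluate the surface argmax on a
grid whose cell size is half the generative niche breadth per axis — the
resolution at which a quadratic optimum is actually identifiable from
Bernoulli occurrences; on finer grids the argmax position is dominated by
sampling noise in the flat region around the optimum.

**Tidal position.** Observed position is the mean/median/IQR of RTH over
occupied quadrats (quantiles by linear interpolation of order statistics,
the type-7 rule). Expected position ranks a class's quadrats by drawn
occurrence probability per posterior draw, takes the top n (n = observed
occupied count; ties broken by quadrat order — a stable, documented rule),
and averages their RTH; the across-draw mean and percentile CI are
reported, and n = 0 yields a flagged, undefined summary. Kruskal–Wallis
uses the standard tie correction; pairwise Mann–Whitney–Wilcoxon tests are
exact for groups ≤50 (scipy's exact null when tie-free; full enumeration of
group assignments when ties are present and tractable) and otherwise use
the normal approximation with tie and continuity corrections.
Benjamini–Hochberg adjusts the ≤3 pairs per species, and compact letters
are maximal cliques of the non-significance graph, so two classes share a
letter exactly when not significantly different.

**Environmental models.** OLS with treatment coding, references NAT and
Essex, so MR/AR coefficients are contrasts against natural marshes;
rank-deficient designs report aliased terms instead of dropping them
silently. Quadrats are pooled (no site random effects), matching the
comparison being reproduced.

## Synthetic surveys

The generator reproduces the survey design: 22 sites (7 MR, 4 AR, 11 NAT)
across Essex, Norfolk and the Humber with class totals 290/249/506
quadrats and ≥30 quadrats per site along elevation-spanning transects. RTH
is Uniform(−0.3, 1.4) on NAT/AR transects and Uniform(−0.6, 1.1) on MR
(realignments sit lower in the tidal frame); redox is linear in RTH at 238
mV per RTH unit on natural marshes, steeper (318) in MRs and flatter (178)
in ARs, with 80 mV Gaussian noise — noise chosen so the slope's standard
error at the natural-marsh sample size is of the order of 15 mV/RTH.

Species occurrence comes from parametric suitability surfaces: latent =
max_latent − ((RTH−opt)/breadth)² − ((redox−opt)/breadth)² + region offset
+ age shift, presence ~ Bernoulli(Φ(latent)). The surface is a quadratic
bell rather than a GP draw precisely so that optima, breadths and age
shifts are exact, recoverable ground truth. The ten default profiles run
from broad-niched pioneers low in the tidal frame to narrow-niched
upper-marsh species (producing the negative range–median correlation
characteristic of natural marshes), with age shifts that depress mid-marsh
perennials and favour annual pioneers on young realignments.

What passing tests on these surveys demonstrate: the pipeline recovers
known optima, age effects, slopes and dominance structure at realistic
sample sizes, with calibrated uncertainty. What they do not demonstrate:
robustness to features absent from the generator — spatial autocorrelation
within transects, dispersal limitation, biotic interactions, measurement
error in elevation and redox, or non-quadratic niche shapes. Real-data
conclusions inherit those caveats.

## Seeding and determinism

A single master seed is split into named per-stage streams (SeedSequence
spawned with a CRC-32 key of the stage name), so any stage reproduces in
isolation. The pipeline manifest records the config hash and a SHA-256
checksum of every output; identical config and seed give byte-identical
tables. Reduced desk-scale defaults (100 CV runs, 200 draws) keep the full
synthetic run at roughly a minute and a half on one CPU; the full scale
(1,000/1,000) is a config change.

## Known limitations

- The Laplace approximation understates skewness of the latent posterior at
  very small sample sizes or extreme prevalence; the MCMC cross-check
  bounds this at ≤0.05 probability error on small designs, not in general.
- The latent-optimum search is restricted to observed covariate vectors by
  design; if the true optimum lies outside the sampled envelope the age
  effects are evaluated at the best *available* conditions.
- Categorical kernel similarity is a single scalar per covariate; regions
  with heterogeneous affinity are not modelled.
- Cross-validation AUC depends on relative occurrence area; comparisons
  across species should consider prevalence, which is reported alongside.
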
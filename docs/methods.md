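# Methods

## Scope and shape

The package reimplements, as a tested pipeline, three linked analyses: (i)
favourability-function species distribution models over a hexagonal grid,
(ii) replicate- and genotype-level seed germination statistics, and (iii)
a PLSR/VIP trait–environment linkage. Real herbarium occurrences and
climate rasters are out of scope; a virtual study system with recorded
truth stands in for them, so correctness claims are about the estimators,
not about any real species' distribution.

## Hexagonal grid and the spatial descriptor

Pointy-top regular hexagons tile the bounding geometry in the raw lon/lat
plane; the apothem is given in km and converted with a configurable
km-per-degree scale (default 111.32, the equatorial value — the source
projection of the original 6 km grid is not recoverable, so the scale is a
parameter rather than a constant). A hexagon belongs to the grid when its
centroid is covered by the geometry; partial overlap at the boundary is
therefore resolved by the centroid rule. Site ids run west→east within
rows, south→north across rows. Occurrence points on a shared hexagon edge
are assigned to the lowest touching site id — an arbitrary but
deterministic tie-break.

The spatial descriptor Ysp is a logistic regression of presence on the
nine cubic polynomial terms of latitude and longitude (Lo, Lo², Lo³, La,
La², La³, LaLo, La²Lo, LaLo²). Coordinates are z-scored before expansion:
cubic terms of raw coordinates span many orders of magnitude and destroy
the IRLS conditioning, and the fitted probabilities are invariant to this
affine rescaling (property-tested to 1e-6). Terms are removed by backward
elimination on AIC — the candidate set is small and fixed, so backward-only
search is sufficient and deterministic. Ysp is defined as the fitted
*probability*, not the linear predictor: it is then bounded in [0, 1] and
directly usable as a covariate whose high values mean "spatially favoured".
With spatially unstructured presence the elimination collapses to (near)
the intercept-only model and Ysp hugs the prevalence.

## The selection cascade

1. **FDR pre-filter.** Per covariate, the Wald p-value of the slope in a
   single-covariate logistic fit; Benjamini–Hochberg step-up at q = 0.05
   (verified against a brute-force step-up oracle). Zero-variance columns
   are excluded beforehand.
2. **Correlation pruning.** While any pair of retained covariates has
   |Pearson r| > 0.8, resolve the most-correlated pair by keeping the
   member with the smaller univariate p (ties: alphabetically first).
3. **Stepwise AIC.** From the full model on the pruned set, repeatedly take
   the single add/drop move with the largest AIC decrease; ties break
   drop-before-add, then alphabetically. AIC = deviance + 2·(parameters
   incl. intercept). The result is locally optimal (tested by exhaustive
   neighbour enumeration).
4. **Wald trimming.** Iteratively refit after dropping the variable with
   the largest Wald p ≥ 0.05 until all remaining p < 0.05; an emptied model
   returns the flagged intercept-only fit (prevalence prediction).
5. **Diagnostics.** Per-variable Wald W = (β̂/SE)² with χ²₁ p-values and
   coefficient signs; VIF per retained variable from OLS of each on the
   others, reported against both the <10 and the stricter <2 conventions.

Logistic fits use IRLS (statsmodels GLM, deviance tolerance 1e-8, max 100
iterations). Separation — non-convergence or |β̂| > 30 — triggers a
ridge-stabilised Newton fallback (L2 penalty 1e-3, intercept unpenalised,
coefficients clipped at |β| ≤ 30) whose fit is flagged; standard errors
then come from the penalised Hessian.

The trend-surface Ysp enters the candidate pool like any covariate, so it
competes in the FDR and correlation filters. On gradient-driven virtual
species Ysp often absorbs a collinear climate layer at the pruning step;
this is the intended behaviour of a spatial descriptor, and the
recovery experiments therefore score the cascade without Ysp in the pool.

**Favourability and evaluation.** F = odds(P)/(n1/n0 + odds(P)), with
F(0) = 0 and F(1) = 1 by continuity, and F ≡ P when n1 = n0 (tested to
1e-12). Classification metrics use the cut F ≥ 0.5, i.e. P at or above the
prevalence — the favourability-natural threshold, adopted because no
explicit threshold is recoverable. AUC uses the Mann–Whitney rank form with
midranks (rank-identical whether computed on P or F, since the transform is
strictly increasing). Favourability classes are counted at cuts 0.2 and
0.8; 0.8 is the established "maximum favourability" cut, 0.2 the
symmetrical lower convention.

## Germination statistics

FGP divides germinated by viable seeds, where viability counts germinated
plus tetrazolium-positive non-germinated — dead seeds do not dilute the
proportion. MGT is the germination-weighted mean day. For the
stratification design (6 scheduled counts spanning a change of incubation
conditions), timing is expressed in section units: MGS = k − Tmod, which
reduces algebraically to the weighted mean of the section index h = i − 1
(property-tested on random count vectors). UG is the base-2 Shannon entropy
of the count distribution (bounded by log₂ of the occupied counts,
invariant to scaling the counts). Dishes where nothing germinated get
missing MGT/MGS/UG — never 0, which would fake perfect synchrony — and are
excluded from level means.

GA sums the 11 level-mean FGPs; GE is the modified Levins evenness
1/(R·Σpⱼ²). GE is reported on (1/R, 1]; GA = 0 makes GE undefined
(missing, flagged). Missing levels are a hard error unless explicitly
imputed as zero (`impute_zero`), because silent imputation changes both
indices' meaning. Level means default to genotype × harvest groups, with
pooled per-genotype means available — the original grouping is ambiguous,
and both are exposed.

Genotype-level means here are arithmetic means over replicates and
harvests. The original analysis used mixed-model adjusted means and Tukey
comparisons; that inference layer is deliberately out of scope, and for
balanced designs (as generated here) arithmetic and adjusted means
coincide. Logit transforms for downstream analysis use the empirical logit
ln((g+0.5)/(n−g+0.5)) for count-backed proportions (finite at 0 and 1) and
a clamped plain logit (ε = 0.005) for GE, which has no underlying count.

## PCA and PLSR

PCA is on z-scored columns (correlation-matrix PCA) of the genotype ×
harvest germination profile (FGP, MGT-or-MGS, UG per treatment level);
missing cells — timing/UG of zero-germination levels — are imputed by
column mean and counted. PC1's sign is fixed to correlate positively with
the mean FGP columns so that PC1 consistently decreases with dormancy
depth across runs.

PLS1 is NIPALS on autoscaled X and y (it reproduces scikit-learn's
`PLSRegression` predictions to machine precision, which serves as the
independent cross-check in the tests, and reduces to OLS at full rank).
The component count minimises the leave-one-out RMSEP, computed by a full
refit per held-out row and reported in original response units; ties go to
fewer components. VIP is Wold's formulation with unit-norm weight vectors,
so Σⱼ VIP²ⱼ = p exactly. The two-stage procedure retains VIP > 1 after a
first fit on all predictors and refits on the retained set. When stage one
retains a single predictor, stage-two VIP is identically 1 and the strict
VIP > 1 rule is vacuous; the simple regressions then fall back to the
stage-two predictor set. No multiplicity correction is applied across the
simple regressions (none was applied originally); all p-values are
reported together so the reader can apply one.

## The virtual study system

Layers are planar gradients in the (z-scored) grid coordinates plus iid
Gaussian noise, standardised; when a target inter-layer correlation matrix
is requested it is imposed exactly by whitening the realised columns and
colouring with the Cholesky factor of the target (a non-positive-definite
target is an error). Default: ~2000 hexagons, 8 layers named after the
bioclimatic variables they caricature, with temperature-like layers
sharing a latitudinal gradient and precipitation-like layers a mixed one,
so natural collinearity exercises the pruning step.

Virtual species draw presence ~ Bernoulli(inverse-logit(η)) with η linear
in the layers for the broad-niche "generalist" (shallow coefficients,
prevalence ≈ 0.5) and with an added quadratic penalty around an optimum
for the narrow-niche "specialist" (prevalence ≈ 0.2). A degenerate
all-presence/all-absence draw is resampled once, then errors.

Germination: dormancy D_g = α + γ·driver_g + ε_g with the dry-season
precipitation layer as driver, γ = −1 (wetter dry season → shallower
dormancy, matching the latitudinal dormancy cline the indices are meant to
detect), α = 0.5, and genotype residual sd 0.45 — chosen so the GA-driver
regression explains R² ≈ 0.8, a strong but noisy field-realistic signal.
Genotypes sit at evenly spaced driver quantiles (sampling across the
range). Per treatment level, P(germinate) = inverse-logit(η_level − D),
with stimuli η encoding cold > warm > no stratification, warmer
alternating regimes > colder, and a nitrate bonus; counts are binomial in
the viable seeds (viability 0.95 of 50 sown), and timing spreads the
germinated seeds multinomially over the scheduled counts with mean and
dispersion increasing in D. Experiment 1 uses the 6-count schedule (days
2, 3, 4 at constant temperature, then 2, 4, 7 days into the alternating
period); experiment 2 uses 2–3-day count intervals out to 28/21/17/14 days
for the four temperature regimes. Defaults: 12 genotypes, 2 harvests
(with a small N(0, 0.1) dormancy shift per harvest), 3 replicates.

Randomness: one integer seed; per-species and per-genotype sub-streams are
derived with fixed offsets (`default_rng([seed, offset])`), so editing one
configuration block does not perturb the draws of another. Identical
(config, seed) → identical CSVs.

What the simulation does **not** emulate: spatially autocorrelated noise
within layers beyond the smooth gradient, sampling bias in occurrences
(every presence cell yields a record), seed-lot ageing, secondary
dormancy, or between-dish micro-environment effects. Passing recovery
tests therefore show the estimators are correct and well-calibrated under
clean sampling, not that the original field estimates are right.

## Problem sizes and recovery studies

The recovery experiments run at desk scale — ~2000 hexagons, 25 seeded
replicates, 12 genotypes × 11 levels × 3 replicates × 2 harvests — sizes
at which every suite completes in about a minute on one core while leaving
the binomial/Bernoulli noise large enough to be a real test. Scored
quantities: cascade success (all 3 informative layers kept, ≤1 of 5 noise
layers admitted) and pooled 95% Wald-CI coverage; two-stage PLSR retention
of 2 known drivers among 8; sign and 20%-band recovery of the implied
GA–driver slope; and the TSS/AUC contrast between the specialist and the
generalist, which reproduces, in sign, the observation that evaluation
metrics are lower for a habitat generalist.

## Known limitations

- The grid is planar; at continental extents hexagon area in km² varies
  with latitude. The geometry is exact in map units only.
- The ridge fallback's standard errors (penalised Hessian) are
  approximate; affected fits carry a flag.
- LOO component selection refits n times per candidate count; fine at
  n ≤ a few hundred rows, not meant for large n.
- GE's clamped logit constant (ε = 0.005) is a convention; values of GE
  within ε of 0 or 1 are compressed.
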
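# Methods

## Synthetic cohort generator

The generator emulates the data structure of a BMI-stratified obesity
cohort with qPCR gene panels, not any particular patient's data.  All
variables — 6 browning genes, 7 inflammatory genes, and 9 clinical
covariates (BMI kg/m², endotoxin EU/mL, glucose mmol/L, insulin pmol/L,
total cholesterol / HDL / TG mmol/L, weight and ideal weight kg) — share a
latent multivariate standard normal vector with a configurable target
correlation matrix, factorised by Cholesky decomposition.  Group
membership (lean n=44, overweight n=49, obese n=63 by default; paired
surgery subcohort n=26) adds per-variable mean offsets on the latent
scale.  Gene latents are multiplied by `noise_sd` (default 0.5) and
exponentiated, giving log-normal, strictly positive relative-expression
values; covariates map linearly onto their natural scales via per-variable
(mean, sd) anchors and are floored at a tiny positive value.

**Correlation contract.** Because expression is exponentiated, the target
correlations hold on the *latent* scale: log-expression for genes, natural
scale for covariates.  Consistency checks therefore correlate
log-expression; raw-scale Pearson correlations of log-normal variables are
attenuated relative to the latent targets (by a factor
σ/√(e^σ²−1) ≈ 0.88 at σ = 0.5), which is also how real right-skewed qPCR
data behave.

**Default correlation structure.** The default target matrix comes from a
three-factor loading model (an adiposity–inflammation axis, a body-size
factor, a lipid factor), chosen so that browning genes correlate ≈ −0.3
with inflammatory genes, ≈ −0.39 with BMI and ≈ −0.33 with endotoxin,
matching the magnitudes such cohorts report.  A factor structure is
positive semi-definite by construction.  User-supplied matrices are
validated (symmetry, unit diagonal, entries in [−1, 1]) and PSD-repaired
by eigenvalue clipping at 1e-8 with diagonal renormalisation; matrices
with an eigenvalue below −1e-6 before repair are rejected, naming the
offending eigenvalue.

**Group and surgery effects.** Default per-group latent shifts place the
covariate group means at values typical of lean/overweight/obese cohorts
(e.g. BMI ≈ 22.1 / 27.3 / 36.4, glucose rising to ≈ 5.9 mmol/L in
obesity), and encode lower browning-gene / higher inflammatory-gene
expression with increasing adiposity.  The paired subcohort starts from a
severely obese baseline; post-minus-pre changes are drawn jointly normal
with mean `surgery_effect` (endotoxin −2 EU/mL, browning genes +0.4,
weight −15 kg, glucose −2.26 mmol/L, ...) and covariance given by the
target correlation on the delta scale — deltas of expression are additive
on the natural scale, since change scores may be negative.

**qPCR plates.** Each sample gets a housekeeping (L19) base Ct ~
N(20, 0.3²); each gene's duplicate wells read
Ct = Ct_L19 − log2(expression) + N(0, 0.15²) per replicate.  With zero
noise the quantification round trip (collapse duplicates → 2^−ΔCt) is
exact by construction.

**What the generator does not emulate:** assay plate layouts and batch
effects, amplification-efficiency differences between primers, depot-level
(Sc vs Om) effect differences (depot is an optional random label only),
drop-out/censoring, and any non-monotone gene regulation.  Passing tests
therefore demonstrate algorithmic correctness and calibration under the
stated generative model, not robustness to those real-data features.

## Normality routing

A sample is *parametric* iff the D'Agostino & Pearson omnibus p ≥ 0.05
and both skewness-z and kurtosis-z lie in (−1.96, 1.96).  Samples with
n < 8 or zero variance route non-parametric with a warning.  The routing
vector is the pooled within-group residuals for group designs and the
differences for paired designs — a deliberate choice, since testing raw
pooled values would confuse between-group shifts with non-normality.
Routing is a pure function of the data, so a fixed dataset always takes
the same branch.

Note that the screen is strict: an exactly normal sample fails it about
8–10% of the time (by design — the omnibus test alone has 5% false
positives and the z-band adds more), in which case the analysis simply
runs the non-parametric branch, which is also calibrated.  Type-I error of
the routed 3-group comparison is verified at 5% ± 3 binomial SE over 1000
null simulations.

Dunn's post-hoc test (after Kruskal–Wallis) uses pooled-rank mean
differences with the standard tie correction; both unadjusted and
Bonferroni-adjusted p-values are reported, with the adjusted value as the
headline, since the number of pairwise looks is the whole point of a
post-hoc.  Two-way ANOVA uses type-II sums of squares (robust to mild
imbalance; identical to the classical decomposition for balanced designs)
and runs unconditionally on the parametric branch, as is conventional for
factorial treatment designs; designs with an empty cell are rejected.

## Correlation designs

Pearson's r with two-tailed p from t = r·√((n−2)/(1−r²)).  Log routing is
per variable (not pairwise): a non-normal variable is natural-log
transformed and must be strictly positive, otherwise the correlation is
rejected naming the variable.  Missing data are handled pairwise-complete,
so each matrix cell carries its own effective n.  Δ-correlations
(post − pre per subject) disable log routing because change scores are
signed.  No multiplicity correction is applied across correlation
matrices; stars mark 0.05/0.01/0.001/0.0001 per cell.

## Interaction inference

Architecture: one hidden layer, 3 sigmoidal units, linear output — the
smallest network that can express non-additive interactions while keeping
the composite-weight read-out interpretable.  Training: full-batch Adam
(learning rate 0.02, max 600 epochs, L2 penalty 1e-4) with early stopping
(patience 60) on the validation fraction; weights restored to the best
validation epoch.  Scaling: predictors and target min–max scaled to [0, 1]
using the *training fraction only* (no information leakage into validation
or test); z-scoring is available as an option.  Splits: 60/20/20 without
replacement, 50 resamples by default.  Seeding: each (target, resample)
pair gets an independent child of a `SeedSequence` keyed by the config
seed and the target's column index, so the full run is reproducible from
(data, seed) and insensitive to evaluation order.

The influence statistic Σ_h w1[i,h]·w2[h] is the standard composite-weight
reading of "signal direction and prediction weight" for a single hidden
layer; it is exact for a linearised network and empirically matches the
sign of monotone planted dependencies in ≥ 90% of seeded runs.  It is
deliberately isolated in one function so alternative read-outs (e.g.
partial derivatives at the data mean) can be substituted.

Ranking and export: edges sort by |W| descending with lexical (source,
target) tie-breaks.  Because cross-sectional co-expression carries no
directional information, the two directions of a pair converge to similar
magnitudes; `rank_interactions(..., undirected=True)` merges them (keeping
the larger-magnitude direction) and is what the planted-edge recovery
benchmark counts, since a planted edge is a gene *pair* in the data.
Influence collapse uses compensated summation (`math.fsum`); the
conservation identity Σ exerted = Σ received = grand sum of W is exact in
real arithmetic, exact in floating point for dyadic inputs, and verified
to 1e-12 relative error on general doubles.

Calibration: on mutually independent genes, the fraction of |W| entries
exceeding the 95th percentile of a label-permutation null (column-wise
shuffles, 3 permutations pooled) stays at the nominal ≈ 5%, well under
10%.

## Pipeline

One structured config (YAML/JSON) with a mandatory seed declares either a
synthetic block or input CSV paths, stage toggles and the ANNi settings.
Stages run in dependency order (data → qpcr → metrics → stats /
correlations → anni).  Every CSV starts with a provenance comment line
(`# adiponet seed=... config=...`); the config hash excludes the output
directory and log level so the same analysis written elsewhere is still
byte-identical.  The manifest lists every file with its SHA-256 and a
digest over the whole set; a failing stage aborts with its name and leaves
a `manifest.partial.json`.

## Problem sizes used in validation

The validation benchmarks use: n = 5000 for generator-consistency checks
(sampling error of r at that size is ≈ 0.014, comfortably inside the 0.05
band), 1000 simulations for type-I calibration (3 binomial SE = 0.021),
n = 150 / 15 genes / 50 resamples / 5 planted edges (weight ±0.8) for
network recovery, 8 genes × 100 samples × 15 resamples with 3 pooled
permutations for null calibration, and a 60-sample, 12-subject demo cohort
with 6 resamples for the end-to-end determinism run.  These sizes give
stable metrics while keeping a full validation run to a few minutes on one
CPU.

## Known limitations

* Perfect-efficiency 2^−ΔCt quantification; no standard-curve or
  multi-reference normalisation.
* The influence statistic linearises the network; strongly non-monotone
  dependencies can yield attenuated or unstable signs (the across-resample
  dispersion matrix flags these).
* Directionality of inferred edges is not identifiable from
  cross-sectional data; directed output is provided for compatibility with
  network tooling, with the undirected merge recommended for evaluation.
* The paired generator couples deltas through the same correlation matrix
  as levels; real pre/post data may have distinct level and change
  correlation structures.
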
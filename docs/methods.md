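# Methods

This note documents the statistical model, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Effect sizes

dARR is the slope of mean heat tolerance against developmental
temperature between two acclimation groups of the same study, species,
tolerance metric and timing; pairs are ordered internally so T2 > T1,
making the value invariant to input order. Temperatures closer than
0.1 °C are treated as duplicates (typically digitization round-off) and
rejected rather than divided by. Fluctuating-temperature treatments are
represented by their mean temperature.

Four sampling-variance routes exist (independent vs. shared-cohort
groups × sd/n vs. se reporting). When one group reports sd and n and the
other only se, the sd is converted to se = sd/√n and the se form is
used — this keeps the pair rather than discarding it. Every row that
admits no variance is written to a rejects table with a machine-readable
reason; nothing is dropped silently.

Designs with m > 2 temperatures expand into the m − 1 adjacent-pair
comparisons. Each interior group feeds two comparisons and stamps a
shared-group identifier on both; an effect may carry up to two such
identifiers (one per endpoint), and the sampling VCV places
r_shared·√(vᵢvⱼ) (default 0.5) wherever two effects' identifier sets
intersect. With consecutive sharing this yields the tridiagonal
1/0.5/0.5 correlation pattern, which is positive definite (smallest
eigenvalue 1 − 1/√2 for a chain of three).

### SD imputation

Missing standard deviations are imputed under the assumption that the
sd-to-mean ratio is constant across studies: the pooled CV is the
arithmetic (unweighted) mean of sd/|mean| over all complete rows, pooled
separately per tolerance metric by default because CT_max and LT50
dispersions live on different scales. Rows reporting only a standard
error are left alone (an se admits a variance directly and cannot be
back-converted without n). The operation is idempotent and flags every
imputed row so sensitivity refits can exclude them.

### Thermal-death-time conversion

Static assays reporting time to knockdown at several test temperatures
are converted to the temperature tolerated for one hour: OLS of
log₁₀(time in hours) on temperature, solved at log₁₀(time) = 0. Base 10
and hours are a package convention (so the 1-h criterion is the root of
the fitted line). The estimate's uncertainty is the delta-method SE of
T\* = −a/b from the OLS coefficient covariance — an explicit assumption,
stored as an se so the variance then flows through the se route. A
warning is raised when T\* falls outside the tested temperature range,
where the inversion extrapolates.

## Nonindependence structures

The phylogenetic correlation matrix comes from a rooted tree: polytomies
are resolved at random (the seed is mandatory and recorded in run
metadata), then Grafen heights are assigned — node height
((descendant tips − 1)/(total tips − 1))^ρ with ρ = 1 by default, tips
at 0, root at 1 — giving an ultrametric unit-depth tree whose
tip-pair correlation is the shared root-to-MRCA path, 1 − height(MRCA).
Tips split at the root are exactly uncorrelated. Species present in the
data but absent from the tree are a hard error listing the offenders;
grafting species onto the tree is the user's job on the newick file.
Species labels are matched after trimming whitespace and converting
spaces to underscores.

Both A and V are validated as symmetric PSD (tolerance 1e−8 relative to
the largest eigenvalue); violations are reported, never repaired.

## The multilevel model

y ~ N(Xβ, Σ) with
Σ = σ²_phylo·Z A Zᵀ + σ²_species·Z Zᵀ + D_obs + V. D_obs is a single
observation-level variance, or one per level of a categorical moderator
("heteroscedastic with zero covariance"): independent variances, no
inner-level correlation. Categorical moderators use cell-means (no
intercept) coding when they are the only fixed term, so each level's
estimate and prediction interval is directly reported; continuous
moderators are mean-centered with an intercept.

Estimation is REML. The restricted log-likelihood includes the
+½log|XᵀX| constant, so values equal the density of orthonormal error
contrasts and match metafor's convention. Variance components are
optimized on the log scale (bounds e⁻³⁰–e¹⁰) by L-BFGS-B from three
deterministic moment-based starts, followed by a Nelder-Mead polish;
components finishing below 1e−8 are reported as exactly 0. If a
candidate Σ fails Cholesky during optimization its eigenvalues are
clipped at 1e−10 for factorization only — reported results always come
from unmodified parameters. Fits are deterministic functions of their
inputs. The implementation reproduces `metafor::rma.mv` (β, SE, all
variance components, restricted log-likelihood) to ~1e−5 on test
instances, and its optimum matches a generic dense optimization of the
contrast likelihood to 1e−6.

Inference: t distributions with df = k − p for coefficients, contrasts
and marginal means; significance convention is a 95% CI excluding zero.
Cluster-based df corrections are out of scope. Prediction intervals add
the summed heterogeneity variance to the squared coefficient SE; under
per-level residual variances the default plugs in the
effect-count-weighted mean of the level variances, and per-level
intervals using each level's own variance are available.

Heterogeneity uses the multilevel "typical" sampling variance
s̄² = (k−1)Σw / ((Σw)² − Σw²), w = 1/v; each component's I² is its
variance over (Σσ² + s̄²), so components sum to the total exactly and
are invariant to common rescaling of all variances.

Marginal means average cell-mean estimates with externally chosen
weights (equal by default — post-stratification), correcting for
unbalanced category representation such as the overabundance of aquatic
species in the literature.

AIC is −2·restricted loglik + 2·(number of variance parameters) and is
comparable only across fits sharing the fixed-effect design; the
comparison function enforces this.

## Bias and sensitivity suite

All refits go through the same REML path as the main analysis, with the
sampling VCV rebuilt per subset. Small-study regressions use the
effect's SE (Egger-style default) or variance as moderator; the time-lag
regression uses grand-mean-centered publication year so the intercept
remains interpretable at the average year. The source-type comparison is
a cell-means fit with a thesis-vs-article contrast, skipped with a
logged reason when one level is absent. Leave-one-out excludes one study
or species per refit (non-convergence is recorded, not fatal). Subset
refits cover initial/persistent timing, exclusion of imputed-variance
effects, a user-supplied risk-of-bias flag (the package only honours the
boolean column), and configurable dARR cutoffs; subsets below 10 effects
are skipped with a logged reason. Funnel export writes per-effect GLS
residuals against SE, with an optional basic plot.

## Synthetic data generator

The generator is the model read generatively: species deviations are
multivariate normal with covariance σ²_phylo·A plus independent
σ²_species; each adjacent-temperature interval adds its own
observation-level deviation, making group means piecewise linear in
temperature; observed group means get normal error sd/√n and observed
sds follow the exact χ² sampling law sd·√(χ²_{n−1}/(n−1)), so
downstream sampling variances are correctly calibrated for coverage
experiments. Paired-cohort studies (restricted to two-temperature
designs) draw their two mean errors jointly with correlation 0.5 and
variance sd²/(n₁+n₂), the law under which the repeated-measures variance
formula is exact. A configurable fraction of studies report
thermal-death-time series instead, generated around the true group mean
so the derived estimate's error is fully described by its delta-method
SE.

Defaults emulate the compiled literature the package targets: β₀ = 0.19
(°C/°C), σ²_phylo = σ²_species = 0.05, σ²_obs = 0.15 (reproducing a
~29/10/60% I² split and I² ≈ 99% totals), 40 species × 2–5 studies
(k ≈ 200 effects), 2–4 temperature designs (60/30/10%), 85.7% aquatic
species, 20% persistent-timing and 20% LT50 effects, 10% missing sds,
10% paired cohorts, 5% TDT assays, group n between 8 and 30, individual
sds 0.5–2 °C, temperature steps 2–5 °C, publication years 1960–2021.
Identical configuration and seed give byte-identical CSVs.

What the generator does *not* emulate: the real literature's taxonomic
imbalance beyond configurable per-species study counts, correlated
moderators (habitat is independent of phylogeny here), digitization
error, and truly shared-control covariance signs (see below). Passing
tests therefore demonstrate internal statistical correctness and
calibration of the pipeline under its own assumptions, not robustness to
every feature of empirical datasets.

## Known limitations

* In stepwise designs the true sampling covariance between consecutive
  effects is negative (the shared group's mean enters one slope
  positively and the next negatively), while the analysis follows the
  field convention of a positive r·√(vᵢvⱼ) term. Under the default
  conditions sampling variances are small relative to heterogeneity and
  the discrepancy is negligible, but it is a convention, not a theorem.
* With ~40 species, σ²_phylo is weakly identified; its estimation noise
  propagates into the intercept SE, and plain t inference with df = k − p
  does not absorb it. In calibration experiments the pooled estimate is
  unbiased but the 95% CI empirically covers ≈ 84–86% rather than 95%.
  Users wanting calibrated intervals at few species should expect this of
  any REML + Wald-t pipeline of this structure (the cross-checked
  reference implementation behaves identically); cluster-robust or
  Knapp-Hartung-type corrections are deliberately out of scope.
* One-hour tolerated temperatures derived from TDT curves carry a
  delta-method SE, an assumption rather than a reported uncertainty.
* REML AICs compare variance structures only; fixed-effect selection is
  not supported by design.
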
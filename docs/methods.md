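# Methods

This note documents the statistical machinery in `snfrisk`: the models,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that matter.

## Synthetic claims generator (`snfrisk.synth`)

The generator emulates the *structure* of a restricted claims panel so
that every downstream stage has a recovery-testable ground truth.  It
makes no attempt to reproduce real code semantics, state enrollment
windows, or true Medicare prevalences.

**Patients.**  Each patient carries k latent factor scores, iid N(0, 1).
Indicator v has a primary factor j(v) with loading magnitude λ_v and a
base rate π_v; each visit redraws the indicator as
Bernoulli(expit(logit π_v + λ_v f_{j(v)})), so π_v is the exact
prevalence when λ_v = 0 and visits of one patient are conditionally
independent given the scores.  Defaults: 416 indicators, 12 factors
(round-robin assignment), λ = 0.7, base rates spread on the logit scale
from 0.05 to 0.5 — claims panels mix common comorbidities with rare
codes, and this range keeps every indicator informative at desk scale.
The number of claims per patient is 1 + Poisson(0.6) (≈1.6
visits/patient, the discharge-to-patient ratio typical of a
fee-for-service SNF cohort).

**Facilities.**  Group centroids live in the facility factor space.
Whenever the space admits it (k_snf ≥ G − 1) they form a regular
simplex with every pair exactly `group_sep` apart (default 6 within-
group SDs); a random layout scaled to that minimum distance is the
fallback in lower dimension.  The equidistant layout is the canonical
"G separated groups" geometry: a random layout leaves some pairs far
more separated than others, and silhouette selection then justifiably
prefers merged super-clusters.  Facility scores are centroid +
N(0, group_sd²·I); observed variables are a one-factor-per-variable
loading matrix times the scores plus unique noise, with the leading 60%
of variables rescaled, floored at zero, and rounded to mimic bed/staff
counts.  Group sizes default to the uneven mix 51/21/16/12%.

**Outcomes.**  For each outcome the conditional linear predictor is
intercept + factor slopes + group offset + factor×group interactions +
mean-centered control effects, plus two Gaussian random intercepts
(state, person).  Outcomes are conditionally independent Bernoulli.
Because the analysis estimates *marginal* models, all recovery targets
are marginal quantities obtained by integrating the two intercepts out:
`gh_logistic_mean` uses one-dimensional Gauss–Hermite quadrature on
their sum (the sum of independent normals is normal, so one quadrature
dimension is exact), and `gh_marginal_coefs` solves the population
logistic score equation over a Gauss–Hermite grid of the covariates to
obtain the exact probability limit of a marginal fit.  Default
intercepts (−0.84, −1.89) give event rates near 30% and 13%; random-
intercept SDs default to 0.1 (state) and 0.5 (person).

**What the generator does not emulate:** informative SNF assignment
(visits are uniform over facilities unless a preference strength is
configured), time trends, within-person indicator drift across visits,
missing data, and real DRG semantics.  Passing recovery tests therefore
demonstrate that the *pipeline* recovers the structure it assumes; they
do not validate those assumptions for real claims.

**Exclusions.**  A configurable fraction of claims (default 5.5%,
matching the ratio of excluded to analyzed claims in swing-bed-type
exclusions) is flagged `excluded`.  Excluded rows carry no special
structure; the contract is that they enter the person-averaging step of
the factor analysis but never the outcome models.

## Factor reduction (`snfrisk.factors`)

Inputs are z-scored and analyzed through their Pearson correlation
matrix R (the indicators are person-averaged and hence fractional;
tetrachoric correlations are deliberately not used).  Extraction is
minimum-residual: the uniquenesses ψ minimize ‖R − ΛΛᵀ − diag(ψ)‖²_F
with Λ the rank-k eigen-truncation of R − diag(ψ), optimized by
L-BFGS-B with the envelope gradient −2·diag(residual); because the
diagonal is free, this coincides with the classical off-diagonal least-
squares criterion.  Principal-axis factoring with iterated
communalities is available as `method="pa"`.  Varimax rotation is
delegated to `statsmodels.multivariate.factor_rotation` and wrapped
with Kaiser normalization (on by default); factors are re-ordered by
explained variance and sign-fixed so the dominant loading is positive.

Degenerate inputs: zero-variance and duplicated (|r| > 1 − 1e−10)
columns are dropped with a warning; tiny negative eigenvalues of R
(> −1e−8) are smoothed by clipping and re-normalizing the diagonal;
anything worse raises an error naming the near-collinear columns.

Model selection uses the Very Simple Structure score: simplify Λ by
keeping, per variable, the `complexity` largest-|loading| entries
(complexity defaults to 1), reproduce R\* = SSᵀ, and report
1 − MS_offdiag(R − R\*)/MS_offdiag(R); the selected k maximizes the
score with ties broken toward smaller k.  Interpretability-based manual
override is a configuration choice (`k_patient`/`k_snf` pinned rather
than "auto"), and the pipeline pins 12 patient and 3 facility factors
by default.

Scoring is Thurstone regression scoring, W = R⁻¹Λ, applied to rows
z-scored with the *fit-sample* means and SDs — deliberately so, because
in deployment a patient is scored at a visit from that visit's
indicators using the model built on person averages.

## Facility grouping (`snfrisk.grouping`)

K-means (scikit-learn, Lloyd iterations, k-means++, 50 restarts by
default for stability across seeds) on facility factor scores; the
number of groups maximizes mean silhouette over candidates 2–8, ties to
smaller K.  Silhouette is computed on all facilities without
subsampling (s = (b − a)/max(a, b), singleton clusters contribute 0).
Labels are canonicalized by descending cluster size so "Group 1" is
always the largest group, and new facilities are assigned to the
nearest centroid with ties to the lower label.

## GEE risk models (`snfrisk.gee`)

The design matrix holds, in order: intercept, k factor scores, K−1
group indicators (reference = Group 1, the largest), k(K−1)
factor×group interactions, then any mean-centered controls (age,
gender, race dummies with the largest category as reference,
complication, length of stay, optionally a discharge-date column).
Race categories with fewer than 20 included claims or fewer than 5
events/non-events for the modeled outcome are merged into the
reference; at desk scale a 0.3% category regularly lacks one outcome
level entirely, which quasi-separates its dummy.

The working covariance of one state's visits is
V = φ A^{1/2} R A^{1/2}, A = diag(μ(1−μ)), with
R = (1 − ρ_s − ρ_p) I + ρ_p ZZᵀ + ρ_s 11ᵀ (Z = person indicators):
ones on the diagonal, ρ_s + ρ_p for same-person pairs, ρ_s for
same-state different-person pairs, independence across states.  R is
never formed: two nested Sherman–Morrison steps solve against V in
O(n).  Each iteration re-estimates (φ, ρ_s, ρ_p) by moment equations on
Pearson residuals — the mean cross-product over same-person pairs
estimates ρ_s + ρ_p and over same-state different-person pairs
estimates ρ_s, both scaled by φ with a p-degree-of-freedom correction —
then takes one Fisher-scoring step for β.  Correlations are clipped so
the implied R stays positive definite for every realized cluster size.
Convergence: max |Δβ| < 1e−6 within 100 iterations; |β| > 50 raises a
separation error; non-convergence raises with diagnostics.

Covariance modes: `nested` (state top-level, person nested — the
default), `person` (person clusters only, for data with very few
states), `independence`.  The robust covariance is the sandwich
B⁻¹MB⁻¹ with cluster scores summed at the top level.  **Caveat:** with
c top-level clusters the meat has rank ≤ c − 1 (cluster scores sum to
≈0 at the solution), so with the default 3 states the robust covariance
has rank 2.  Consequently the risk-scale joint Wald test, whose natural
df is K − 1 = 3, uses the pseudo-inverse of the contrast covariance
with the rank as effective df and emits a warning; analyses that need
well-calibrated robust inference at few states should use
`cov_type="person"`.  The calibration benchmarks (CI coverage, Wald
type-I error) therefore run in person-cluster mode with no state
intercept.

Marginal standardization: visits with score_j > mean + 1 SD (moments
over all included visits — visit-level, not person-level) are each
counterfactually assigned to group g (group and interaction columns
rewritten, everything else kept) and their predicted probabilities
averaged.  CIs are delta-method on the robust covariance, symmetric on
the risk scale, truncated to (0,1); the per-factor joint test contrasts
the K marginal risks with K−1 adjacent differences.  No multiple-
testing correction is applied across factors or outcomes.  Exponentiated
coefficients with robust Wald intervals are available as a supplementary
odds table.

## Pipeline (`snfrisk.pipeline`, `snfrisk.cli`)

One root seed fans out to stage-specific sub-seeds (simulation,
clustering) through `numpy.random.SeedSequence`, so a rerun with the
same configuration is byte-identical and individual stages can be rerun
alone.  Every intermediate artifact (tables as CSV, models as JSON) is
persisted; the run report records VSS and silhouette curves, group
sizes, risk tables, and provenance (config digest, seed, library
versions).

## Benchmark designs (`snfrisk.benchmarks`)

Frozen study conditions used by the test suite and the acceptance
script; sizes were chosen once to finish on one CPU in minutes:

- *Factor recovery*: 5,000 patients, 100 balanced indicators (base rate
  0.5), 6 factors, loading 0.8.  Measures loading congruence, VSS
  selection over k = 1..10 (20 replicates), and visit-level score
  correlation.
- *Cluster recovery*: 300 facilities, 4 groups, simplex separation 6×
  the within-group SD; silhouette selection over K = 2..8 and ARI (20
  seeds).
- *Marginal coverage*: 2,000 patients per replicate, 2 factors with
  conditional slopes (0.4, −0.3), person intercept SD 0.8, no state
  intercept; 200 replicates, CIs vs the Gauss–Hermite marginal truth.
- *Wald null*: 1,000 patients, 4 equal groups, no group effects; 500
  replicates at α = 0.05.
- *Planted interaction*: δ = 0.5 on (factor 1, group 2) of a 3-factor,
  4-group design, 1,200 patients; the end-to-end risk table must rank
  the matched group as the extreme entry (20 runs, with factor matching
  by congruence and group matching by cluster overlap).

## Known limitations

- SNF assignment is treated as given; nothing here is causal, and the
  generator's uniform assignment sidesteps the selection processes real
  discharge planning would induce.
- Sandwich inference is anti-conservative with very few top-level
  clusters (see above); the package warns rather than silently
  reporting nominal df.
- VSS selection is automated; the judgment call between fit and
  interpretability that a practitioner would make is reduced to pinning
  k in the configuration.
- The minres/PA extractors assume a smoothable correlation matrix;
  panels dominated by empty or duplicated codes must survive the
  column-dropping step with enough variables per factor.
- CIs for marginalized risks are delta-method normal by default; the
  cluster-bootstrap alternative (`marginal_risk_ci(..., method=
  "bootstrap")`) is preferable near risk 0 or 1 but refits the GEE per
  resample and is correspondingly slower.
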
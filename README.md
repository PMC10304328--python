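# snfrisk

Rehospitalization and mortality risk by patient type and skilled nursing
facility (SNF) group, estimated from high-dimensional claims data.

Hospitals discharge large numbers of Medicare patients to SNFs for
post-acute care, and 60-day rehospitalization and mortality rates vary
both with the patient's clinical profile and with the facility.  Both
sides are high-dimensional — hundreds of binary comorbidity/diagnosis
indicators per discharge, ~150 capacity/staffing/service variables per
facility — so `snfrisk` implements a three-stage analysis that reduces
each side to a handful of interpretable descriptors before modelling
risk:

1. **Dimension reduction.**  Binary patient indicators are averaged over
   each person's claims, and an exploratory factor model is fit by
   minimum-residual (unweighted least-squares) extraction on the Pearson
   correlation matrix, with varimax rotation (Kaiser-normalized).  The
   number of factors is selected with the Very Simple Structure (VSS)
   criterion, and Thurstone (regression) scores `F = Z R⁻¹ Λ` are
   assigned to every *visit* and every facility.  Facility variables get
   their own factor model.
2. **Categorization.**  Facilities are grouped by k-means on their
   factor scores; the number of groups K maximizes the mean silhouette
   score (Euclidean distance).  Group 1 is canonically the largest
   group, and new facilities are assigned to the nearest centroid.
3. **Risk prediction.**  For each outcome y ∈ {rehospitalization within
   60 days of SNF discharge, death within 60 days of hospital discharge}
   a marginal logistic model

   logit P(y=1) = β₀ + Σⱼ βⱼ fⱼ + γ_g + Σⱼ δⱼ_g fⱼ + θᵀx

   is estimated by GEE with a working covariance that is the **sum of
   two compound-symmetry components**: a common correlation ρ_state
   between visits from the same state and an additional ρ_person between
   visits from the same person, inverted in O(n) by nested
   Sherman–Morrison identities.  Controls x (age, gender, race,
   complication flag, hospital length of stay) are mean-centered and
   enter only the *adjusted* models.  Risks are reported by **marginal
   standardization**: among visits scoring above +1 SD on factor j, each
   visit is counterfactually assigned to group g and the predicted
   probabilities are averaged; delta-method 95% CIs use the robust
   (sandwich) covariance, and a joint Wald test per factor asks whether
   that risk is equal across all groups.

Because real Medicare claims are restricted, the package ships a
synthetic claims generator (`snfrisk.synth`) whose latent structure — factor-driven indicators, clustered facility
scores, state/person random intercepts, planted factor×group effects —
is fully known, so every stage is tested for *parameter recovery*
against ground truth.

## Worked example

Run the whole pipeline on a synthetic dataset at the default scale
(4,000 patients, 416 patient indicators, 12 patient factors, 400 SNFs,
154 facility variables, 3 facility factors):

```python
from snfrisk import RunConfig, SynthConfig, run_pipeline

report = run_pipeline(RunConfig(simulate=SynthConfig(seed=1), seed=1), "out/")
print(report.cluster_model.K, dict(report.cluster_model.group_sizes()))
print(report.risk_tables[("rehosp60", True)].pivot())
```

prints (risks rescaled to percent):

```
groups: 4 | sizes: {1: 204, 2: 78, 3: 63, 4: 55} | mean silhouette: 0.567
rehosp60 adjusted: rho_state=-0.0002  rho_person=0.0635  n=5928
        group1  group2  group3  group4      p
factor
1         29.3    29.5    25.5    28.9  0.104
2         29.3    32.5    26.6    32.5  0.000
3         39.0    42.4    38.1    42.0  0.333
4         39.8    42.2    35.0    39.5  0.000
```

Reading the table: silhouette selection found the 4 generating facility
groups (labels ordered by size); ρ_person ≈ 0.06 is the working
correlation induced by the person-level random intercept; each row gives
the adjusted 60-day rehospitalization risk for patients scoring > +1 SD
on that factor were they assigned to each SNF group, and `p` is the
joint Wald test of equal risk across groups — small p-values flag
patient types whose outcome depends on where they are sent.

The same stages are available from the shell:

```bash
snfrisk simulate --config synth.yml --out data/ --seed 1
snfrisk reduce --claims data/claims.csv --facilities data/facilities.csv \
    --k-patient 12 --k-snf 3 --out reduced/
snfrisk cluster --scores reduced/snf_scores.csv --k auto --out clustered/
snfrisk fit --claims data/claims.csv --scores reduced/claim_scores.csv \
    --groups clustered/snf_groups.csv --outcome rehosp60 --adjusted --out fits/
snfrisk run --config run.yml --out out/
```

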
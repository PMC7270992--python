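# Methods

## Study design being modelled

A recall-by-genotype design selects carriers of a rare functional variant
and, for each carrier, a fixed number of non-carrier controls matched on
cohort, sex and clinic age (the generator matches age within ±1 year, since
recall happens within age-banded clinic visits). Two cohorts are present —
adolescent participants (~16 y) and adult mothers (~48 y, all female) — and
some carriers contribute repeat samples from additional clinic visits.
Because matching is on genotype only, carrier status is independent of age,
sex and lifestyle by construction; the carrier/non-carrier contrast on a
metabolite estimates the lifetime effect of the variant.

## Abundance model (synthetic data)

Peak areas are generated log-normal — positive and right-skewed, as raw
LC-MS peak areas are; no distributional form is otherwise imposed by the
analysis, which is rank-based. On the natural-log scale, for feature *f*
and sample *s* of subject *i*:

```
log v[f,s] = b[f] + g[i] · δ[f] · σ_b + u[i,f] + e[s,f] + log d[s]
```

* `b[f]` — per-metabolite baseline, N(11.5, 1.5²). The spread matters: it
  places a realistic fraction of features near the limit of detection.
* `g[i]` — carrier indicator (0/1).
* `δ[f]` — standardized class effect (units of the total biological SD
  σ_b), constant within a lipid class. Defaults (TAG −1.0, DAG −0.6,
  acyl-acyl GPL −0.5, acyl-alkyl GPL +0.5, ceramide +0.5, sphingolipid
  +0.3, other 0) reproduce the direction structure of an
  apoC-III-loss-like perturbation — triacylglyceride-rich classes fall,
  ether phospholipids and ceramides rise; magnitudes are chosen for
  testability, as no per-feature effect distribution is available to copy.
* `u[i,f] ~ N(0, σ_b²/2)` — subject random intercept; `e[s,f] ~ N(0, σ_b²/2)`
  — sample-level residual. Their sum gives total biological SD σ_b
  (default 0.5), so δ is an effect in total-biological-SD units when
  subjects are sampled once.
* `d[s]` — per-sample dilution, log-normal with log-SD `dilution_sd`
  (default 0.2). This is what PQN must remove.

Pooled-QC injections are the arithmetic mean profile of all study samples
under mean-unbiased multiplicative log-normal noise with CV = `tech_rsd`%
(default 10%), mirroring a pooled QC prepared from all biological samples.
A fraction of metabolites (`duplicate_rate`, default 0.15) yield 2–3
redundant features — the parent's values under independent technical noise,
sharing its annotation label — emulating adducts/isotopes and cross-assay
detections. Left-censoring replaces every value below the `lod_quantile`
(default 0.10) quantile of all present study-sample values with missing;
because censoring acts on the value scale, negative-effect features become
differentially missing in carriers — the MNAR structure the Fisher track
exists to detect.

Default scale: 26 carrier subjects (11 mothers / 15 young), 2 controls per
carrier, repeat-measure probability 0.5 for carriers, ~600 base metabolites
across seven classes over four assay datasets, 8 pooled-QC injections.
The feature count is deliberately an order of magnitude below a full
untargeted acquisition; it keeps simulation-based validation cheap while
preserving every structural property the analysis relies on, and is fully
configurable. About 30% of mother-carrier samples are flagged non-fasting
(`nonfasting_prob`), exercising the fasting filter; a configurable fraction
of young carriers (`family_link_fraction`, default 0.2) share a family id
with a carrier mother, exercising the pedigree random intercept.

What the generator does **not** emulate: chromatographic drift and
retention-time misalignment, correlated feature blocks beyond exact
duplicates, batch effects, adduct mass arithmetic, or raw spectra. Passing
tests therefore demonstrate correctness of the statistics under the stated
sampling model, not robustness to acquisition artefacts.

## Filters

Thresholds follow standard untargeted-metabolomics QC practice: RSD > 30%
or pooled-QC detection < 70% removes a feature; sample missingness > 50% or
TPA > mean + 3 SD (per assay dataset, study samples only, sample SD with
n−1) removes a sample; features missing in > 30% of *both* genotype classes
are removed. Choices worth noting:

* RSD is computed on raw (not log) peak areas with the n−1 SD — the
  convention of the pooled-QC literature. A feature with fewer than two
  present QC values has undefined RSD and fails any finite RSD cap.
* Both sample rules are evaluated per assay dataset on the *same* input
  (no sequential re-estimation), and "missing>50% and/or TPA outlying" is
  an inclusive OR. A sample failing in any assay is removed from the whole
  table: masking only the offending assay would turn "excluded sample"
  into "missing value" and contaminate the missingness track with
  artificial absences.
* The TPA rule is defined single-pass: re-applying it to already-filtered
  data re-estimates mean+3SD on a cleaner sample and may flag new outliers.
  The pipeline applies each filter exactly once, in the order listed.
* The class-missingness filter precedes the Fisher scan, so features
  missing in >30% of both classes are never tested for differential
  missingness. (Features heavily missing in *one* class — where that test
  has its power — are retained by construction.)

## Normalization and transform

PQN uses the feature-wise median of the filtered study samples as the
reference (configurable to the pooled-QC median; the study-sample median is
the robust choice when QC injections are few), with no total-area
pre-normalization — TPA has already been used for sample exclusion, and
under the multiplicative dilution model PQN alone suffices. Each sample's
quotient is the median of value/reference over features present in both;
PQN is exact under pure dilution and is validated against the generator's
true dilution factors (r ≥ 0.99 at `dilution_sd` 0.3 with null effects).
PQN assumes most features are unchanged between groups: when a large
fraction of features shifts in one class, the shifted block drags the
median quotient and part of the effect is absorbed into the normalization.
The validation simulations therefore put true effects on ~1–2% of features,
the regime the method is designed for (and the regime a real untargeted
screen of this kind sits in).

The rank-based inverse-normal transform maps present values to
Φ⁻¹((rank − ½)/n) with average ranks for ties; n counts present values
only, and missing values stay missing. Pooled-QC columns are excluded
before the transform: QC has served its purpose after normalization, and
letting QC injections occupy ranks would distort the quantile spacing of
the study samples. A feature whose present values are all identical has no
defined transform; the table-level transform maps it to all zeros (its
average rank is central) and the per-feature function raises unless
explicitly allowed. The transform compresses effects: a raw standardized
shift δ between two Gaussian classes becomes a smaller post-transform
contrast. `int_attenuated_effect(delta, pi, n=...)` computes this
transform-consistent truth — by numerical integration of the population
transform, or at finite n by direct Monte Carlo over replicate rankings —
and is what simulated effect-recovery checks compare against.

Left-censored imputation (the second sensitivity analysis) defaults to
half the feature's minimum present value (`half_min`), with `min` and
`none` as alternatives; the method used is recorded in provenance.

## Association models

Genotype is coded 0/1 (carrier/non-carrier): at a minor-allele frequency of
a few per mille there are no rare homozygotes, so the carrier contrast and a
per-allele additive effect coincide. Age and sex enter as fixed covariates;
sex is dropped automatically when constant (mothers-only dataset). Within a
dataset the model is OLS (closed-form, with t-based two-sided p) if every
subject contributes one sample; if any subject repeats, a linear mixed
model with a subject random intercept — plus a family intercept in the
combined dataset, where mother–offspring pairs can co-occur — fitted by
maximum likelihood, with a two-sided Wald z test on the genotype
coefficient. Missing responses are dropped listwise per feature;
non-convergence is flagged, never silently dropped.

The mixed models are fitted by a purpose-built profiled-likelihood solver
(`rbgmet.lmm`): for nested random intercepts the covariance is
block-diagonal with an analytic two-stage Sherman–Morrison inverse, so each
likelihood evaluation reduces to segment sums and only the one or two
variance ratios are optimized numerically (Nelder–Mead on the log scale,
with an explicit check of the zero-variance boundary). This is exact for
the model and fast enough to fit thousands of features; the test-suite
cross-checks it against statsmodels' MixedLM (ML) on matched problems and
confirms collapse to OLS when the true random-effect variance is zero.

BH adjustment is applied across all tested features within each
dataset-analysis (the four assay datasets pooled — one FDR decision per
analysis); a feature is *associated* when q < 0.05 in at least one of the
three analyses. Fold change is carrier-mean / non-carrier-mean on
normalized, untransformed data (undefined-when-empty is flagged, not
dropped). Variance explained is incremental R² when the predictor is added
last, from a simple OLS across all samples with repeats treated as
independent. Clinical lipid measures (HDL/LDL/TAG, mmol/L) run through the
same per-dataset models untransformed, so their effects stay in measurement
units.

The primary analysis keeps fasting samples only; sensitivity modes retain
non-fasting samples or analyse the imputed table. The Fisher
presence/absence scan always runs on the post-filter, *pre-imputation*
combined dataset — missingness must be real. Its two-sided p sums
hypergeometric probabilities of tables no more probable than the observed
one (the point-probability criterion); a zero margin yields p = 1 with a
degenerate flag.

## Reporting

Within each dataset, features sharing an annotation label collapse to the
member with the smallest p (exact ties broken by smaller feature id, for
run-to-run stability); unannotated features pass through as features.
Class summaries count metabolites per lipid class with column percentages
and up/down tallies. The heatmap residualizes transformed values on age and
sex (genotype deliberately excluded, so its structure remains visible),
keeps complete-case rows, and Ward-clusters both axes on Euclidean distance
— the metric under which Ward's criterion is defined — with an option to
drop whole classes (e.g. the on-target TAG class) to expose secondary
structure. Cohort tables use the two-sample Wilcoxon rank-sum test, exact
for group sizes ≤ 20 without ties and the continuity-corrected normal
approximation otherwise, with star coding (* p<0.05, ** p<0.01,
*** p<0.001).

## Numerical choices and degenerate inputs

* OLS uses `lstsq`/pseudo-inverse with rank-aware degrees of freedom, so
  accidental collinearity degrades gracefully; a feature with no genotype
  contrast among its informative rows raises instead of returning β = 0.
* Fisher p-values are cached per (missing-carrier, missing-control) count
  pair within a scan — the margins are shared by all features.
* The LMM optimizer works on log variance ratios; the boundary (no random
  effect) is checked explicitly and taken when it fits at least as well.
* Empty p-vector → empty BH output; all-identical Wilcoxon groups → p = 1;
  quantile 0 censoring → identity (censoring is strict `<`).
* All simulation randomness flows from a single `numpy` Generator seeded by
  `SimConfig.seed`; identical configurations are byte-identical on re-run,
  and pipeline outputs contain no timestamps.

## Validation problem sizes

The test-suite validates: primitive-level agreement with from-definition
oracles (100 random instances each for BH, Fisher, OLS, Ward); FDR control
of both tracks on global-null studies (2000 features, 60 subjects, 50
seeds); effect recovery within 2 Monte-Carlo SEs of the finite-n
transform-consistent truth with strictly increasing detections over
δ ∈ {0.5, 1.0, 1.5} (400 features of which 4 affected, 25 seeds); PQN
dilution recovery (r ≥ 0.99, 10 seeds); MNAR enrichment of the Fisher scan
(odds ratio > 1 in ≥ 18/20 seeds at δ = −2.5, 20% censoring); exact filter
bookkeeping on a hand-built 12-feature/25-sample fixture; and byte-level
end-to-end determinism. `scripts/acceptance.py` re-runs a default-scale
study plus scaled (10-seed) versions of the null-FDR, effect-recovery and
MNAR checks.

## Known limitations

* Per-assay sample exclusion removes the whole sample, not just its assay
  block (see Filters above); with strongly assay-specific artefacts this is
  conservative.
* The family random intercept assumes subjects nested in families, which
  the recall design guarantees here; general pedigrees are out of scope.
* Wald inference from ML fits is anti-conservative for very small group
  counts; with ~60–100 samples per analysis the effect is negligible
  relative to FDR control, which the null simulations verify directly.
* The generator's independence of features (beyond duplicate groups)
  understates the correlation of real lipid classes; FDR control under
  strong positive dependence is inherited from BH's robustness, not
  re-verified here.
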
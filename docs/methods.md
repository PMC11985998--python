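# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model and cleaning

The unit record is one reported established non-native species in one
country, with taxonomy (phylum, class), the year of first record and two
Darwin-Core-style status columns (`degreeOfEstablishment`,
`occurrenceStatus`). Cleaning applies three filters, in a fixed order so
that every removed record is attributed to exactly one category:

1. *Unclear status.* A species-country pair is dropped only when **every**
   status listed for it, across both columns and all its rows, lies in
   {CASUAL, ABSENT}. A pair that is CASUAL in one row but ESTABLISHED in
   another survives. Pairs with no status at all are kept: an empty field
   is missing information, not evidence of a casual occurrence.
2. *Geography.* Records for countries outside the supplied European set are
   removed. The country list is an explicit argument, not a hard-coded
   table, because national inventories disagree about marginal territories.
3. *Duplicates.* Duplicated (species, country) pairs collapse to one
   representative — the earliest dated record, with a deterministic
   tie-break over the remaining fields — which makes cleaning idempotent
   and independent of input row order.

Species identity is a normalized binomial (NFKC, lower case, collapsed
whitespace) passed through an optional injectable synonym map; there is no
online name resolution. Composition summaries count **distinct species per
taxon pooled across countries**; a species recorded in ten countries counts
once.

Annual first-record series are zero-filled between the first and last
observed year per country: the trend test needs a regular series, and a
year without reports inside an active recording window is a genuine zero,
not missing data.

## Trend analysis

For a series x_1..x_n the Mann-Kendall statistic is
S = Σ_{i<j} sgn(x_j − x_i), with ties-corrected variance
var0 = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 over tie groups of size t, and
Kendall's τ_b (the time axis is untied, so
τ_b = S/√(n0(n0−n2)) with n0 = n(n−1)/2). The normal approximation uses the
±1 continuity correction. An all-tied series returns S = 0, τ = 0, p = 1 so
downstream regressions always receive a numeric response.

Serial correlation in annual counts invalidates var0, so the variance is
multiplied by the effective-sample-size factor

    CF = 1 + 2/(n(n−1)(n−2)) · Σ_{i=1}^{n−1} (n−i)(n−i−1)(n−i−2) ρ_s(i),

where ρ_s(i) is the lag-i autocorrelation of the series' ranks and only
lags with |ρ_s(i)| > z_{0.975}/√n enter the sum. Two deliberate choices:

- **No pre-detrending.** Sen's-slope detrending before the rank ACF is a
  known variant; it is out of scope here and the correction operates on the
  raw ranks. For the null-calibration purposes the package is tested on
  (i.i.d. and AR(1) series), the difference is immaterial.
- **Factor floor at 0.25.** With ~n lags each tested at 5%, spurious
  negative autocorrelations occasionally drive the raw factor to zero or
  below, which would collapse the variance and produce arbitrarily large
  z-values. The factor is floored at 0.25 (logged when triggered). The
  empirical size of the corrected test at n = 40 stays inside [0.03, 0.07].

Both S and τ are exposed per country; the regression stage uses S as its
trend response by default (τ available via configuration), since the two
are monotonically related but S carries the sample-size information.

## Outlier envelopes

The null model for a predictor x is proportional allocation: with N total
established species, country i expects E_i = N·x_i/Σx. This is the minimal
model under which the species distribution "mirrors" the predictor
distribution; a log-link Poisson regression of observed counts on
log1p(x) is available as an alternative (`method="glm"`) for users who
prefer a fitted intercept. Negative predictor values cannot serve as
allocation weights and such predictors are skipped.

Overdispersion is estimated as the Pearson ratio
φ = Σ(O_i − E_i)²/E_i / (n − 1), floored at 1. Because the quasi-Poisson
family has no quantile function, envelope bounds use the negative binomial
matched to mean μ and variance φμ (size μ/(φ−1), p = 1/φ), which reduces to
the exact Poisson at φ = 1. Bounds are two-sided with equal tails of
(α/m_i)/2, where m_i is country i's established-species count — the
Bonferroni adjustment tightens thresholds for richer countries.
Classification is restricted to countries with at least one established
species; a country is *over*-represented iff observed > upper and
*under*-represented iff observed < lower.

Note that φ is estimated from the same observed counts being classified;
when the predictor explains little of the richness variation, φ is large,
the envelopes are wide and few countries are flagged. This conservatism is
inherent to the method, not a defect of the implementation.

## Similarity network

Jaccard similarity J(A,B) = |A∩B|/|A∪B| between country assemblages; two
empty assemblages are defined to have similarity 0 (the diagonal stays 1).
The country graph keeps every country as a node and draws an undirected
edge wherever similarity exceeds a threshold, default 0 (all positive
similarities), since no principled cut-off exists for this quantity.
Strength is the weighted degree; metric rows are ranked by strength with a
lexicographic tie-break for determinism. The unipartite country graph is
the primary object; the country × species incidence is retained and
exportable as a true bipartite graph.

## Driver models

Predictors are z-scored so coefficient magnitudes are comparable as effect
sizes. Collinearity screening computes VIF_j = 1/(1−R²_j) from the OLS of
predictor j on all others and iteratively removes the worst predictor until
all VIF < 10; exactly collinear columns show unbounded VIF and go first,
with alphabetical tie-breaking so the result does not depend on column
order. Which predictors fall is always data-driven, never hard-coded.

Forward selection starts from the intercept-only model and adds the
candidate minimizing AICc (AIC available), stopping when no candidate
improves it; non-converging candidates are skipped with a warning. AICc is
the default because country-level datasets are small (n ≈ 40) relative to
the candidate count. Forward selection under an information criterion
admits the occasional spurious predictor on pure noise (the best of k
independent candidates clears the ~2-unit AIC hurdle with appreciable
probability); users should read small selected effects accordingly.

The richness model is an NB2 negative-binomial GLM with log link,
dispersion α estimated by maximum likelihood (θ = 1/α reported; variance
μ + μ²/θ). If the default Newton optimizer fails on extreme counts the fit
restarts from the IRLS Poisson solution under BFGS. The trend-statistic
response can be negative, which no count family supports: the trend model
defaults to Gaussian with identity link, with a shifted-response NB
available behind a configuration flag for users who want to mirror a count
treatment.

Diagnostics: (i) overdispersion — Pearson χ² of the Poisson baseline
against its χ²(n−p) reference, one-sided; (ii) k-fold cross-validated
held-out deviance (seeded folds, default k = 5; folds that lose all
response variation are excluded with a warning); (iii) influence — leverage
from the weighted hat matrix and Cook's distance
D_i = r_i² h_i /(p(1−h_i)), flagging D_i > 4/n.

## Variance partitioning

The response (per-country richness, untransformed by default; log1p via
configuration) is regressed by OLS on every non-empty union of the four
driver blocks, and explained variance is measured by the Ezekiel-adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1), which penalizes block size so blocks with
different predictor counts are comparable. The 15 Venn-cell fractions
follow from the marginal values by Möbius inversion,

    cell(T) = Σ_{W⊆T} (−1)^{|T|−|W|+1} R²adj(∪(B∖W)),

whose singleton cells equal the unique fractions R²adj(all) −
R²adj(all∖X), and which satisfies Σ cells + residual = 1 exactly, with
residual = 1 − R²adj(all). Adjusted fractions can be negative; that is a
property of the decomposition, not an error.

Permutation significance (default n = 10,000, the package-level default;
the test suite uses 999 for speed): marginal fractions permute response
rows; unique fractions permute the residuals of the reduced model
(all blocks minus the focal one) and add them back to its fitted values —
the standard residual-permutation scheme for partial tests. p = (1 +
#{perm ≥ obs})/(n_perm + 1), so the minimal attainable p is 1/(n_perm+1).
Shared (multi-block) cells are reported without p-values: they are not
testable quantities. Both marginal and unique single-block fractions are
emitted side by side, since "explained alone" is ambiguous between the two
readings and the user should see both.

## Synthetic data generator

The generator is the testbed for every stage and encodes the study
conditions: ~40 countries in 4 geographic regions observed over 60 years,
21 predictors in the four driver categories. Its components:

- **Predictors.** Independent draws from per-predictor marginal families
  (normal / lognormal / uniform with Europe-plausible location and scale),
  except one four-member trade-infrastructure block built from a shared
  latent factor with pairwise correlation ≈ 0.95 — deliberately above the
  VIF-10 removal point so collinearity filtering has real work to do.
- **Richness.** Negative binomial with log-mean intercept + Xz·β on the
  standardized predictors; default intercept 5 (≈150 species per country),
  θ = 2 (strong overdispersion), and effects planted on six drivers:
  positive monitoring effort, population density, sustainability, tourism
  and growth, negative internally-directed culture score. Standardizing
  before applying β makes the coefficients scale-free and recovery tests
  well-conditioned.
- **Assemblages.** Each country draws 60% of its species from its region's
  pool (disjoint across regions) and 40% from a global pool, without
  replacement, giving higher within-region than between-region Jaccard
  similarity, as in real European assemblages.
- **Annual series.** The standalone generator rounds a latent linear trend
  plus AR(1) Gaussian noise at a floor of zero — integer counts with
  tunable autocorrelation for the variance correction to act on. Inside the
  full-dataset generator, first-record years are instead assigned
  multinomially over an increasing latent profile so that annual counts sum
  exactly to the country's richness and the record/series/matrix views of
  one dataset are mutually consistent.

Everything is a pure function of the configuration; sub-stage seeds are
spawned from the master seed via `numpy.random.SeedSequence`, and ground
truth (β, θ, slopes, region labels) is emitted for recovery tests.

What the generator does **not** emulate: real predictor values or their
skewed cross-correlations beyond one collinear block, taxonomic structure
(phylum/class labels are assigned by hashing species ids), reporting
artefacts such as digitization waves or war-time gaps, and spatial
autocorrelation beyond the discrete region labels. Tests passing on this
generator therefore certify the statistical machinery — calibration,
conservation, recovery, determinism — not any substantive claim about the
European invasion record.

## Problem sizes and runtime choices

The test suite runs the trend-test calibration at 2,000 replicates of
length-40 series, coefficient recovery over 200 simulated datasets of 300
observations, envelope coverage over 1,000 simulated draws for 20
countries, and permutation tests at 199–999 permutations; the pipeline's
own default remains 10,000 permutations. The acceptance script uses the
full default study (40 countries, 60 years, 10,000 permutations). These
sizes keep every Monte-Carlo band in the suite at least ~3 standard errors
wide.

## Known limitations

- The Hamed-Rao correction tests every lag at 5%, so with long series some
  spurious lags always enter the sum; the floor bounds the damage on the
  negative side but mild variance inflation on the positive side remains.
- The envelope method's φ is estimated from the classified data
  (see above); envelopes on weakly explanatory predictors are very wide.
- NB2 θ estimates are unstable for n ≲ 30 countries; the pipeline reports
  θ but users should treat values above ~10 as "effectively Poisson".
- Forward selection inherits all the usual post-selection-inference
  caveats; reported p-values in the coefficient table are conditional on
  the selected model.
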
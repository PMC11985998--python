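# aliendrivers

Country-level analysis of the drivers behind the *reporting* of established
non-native species. Invasion ecologists and biosecurity analysts who work
with national first-record inventories (SInAS/sTWIST-style occurrence
tables) can use this package to ask, for a set of countries:

- how fast is the reporting of newly established non-native species rising,
  and is the trend robust to serial correlation in the annual counts?
- which countries harbour significantly more or fewer established species
  than a given national predictor (GDP, tourism, agricultural land, …)
  would suggest?
- how similar are national species assemblages, and which countries act as
  hubs of shared composition?
- which socio-economic, cultural, environmental and land-use predictors
  jointly explain national richness and reporting trends, and how is the
  explained variance shared among those four driver classes?

Every stage is also exercised end to end by a synthetic-data generator with
known ground truth, so the statistical machinery is testable without any
data download.

## Methods at a glance

- **Reporting trends.** Per country, the Mann-Kendall statistic
  S = Σ_{i<j} sgn(x_j − x_i) on the zero-filled annual first-record series,
  with ties-corrected variance, Kendall's τ_b, and the Hamed–Rao
  variance-correction factor
  CF = 1 + 2/(n(n−1)(n−2)) · Σ_i (n−i)(n−i−1)(n−i−2) ρ_s(i)
  over the significant rank autocorrelations ρ_s(i).
- **Outlier envelopes.** Null expectation E_i = N·x_i/Σx (richness mirrors
  the predictor), Pearson dispersion φ, and two-sided count bounds covering
  (1 − α/m_i) of a Poisson (φ = 1) or mean/variance-matched negative
  binomial (φ > 1), with m_i the country's species count — a per-country
  Bonferroni adjustment.
- **Similarity network.** Jaccard similarity J = |A∩B|/|A∪B| between
  country assemblages; an undirected weighted graph over a similarity
  threshold, with degree/strength centralities.
- **Driver models.** Iterative VIF filtering (threshold 10), forward
  selection under AICc, negative-binomial GLM (log link, θ by ML) for
  richness and a Gaussian model for the trend statistic, plus a Pearson
  overdispersion test, k-fold cross-validated deviance and Cook-style
  influence diagnostics.
- **Variance partitioning.** Adjusted R² (Ezekiel) for all 15 unions of the
  four driver blocks; the 15 Venn-cell fractions by Möbius inversion (the
  singleton cells are the unique fractions R²(all) − R²(all∖X));
  permutation tests (default n = 10,000) for marginal and unique fractions.

## Worked example

```python
from aliendrivers.simulate import SynthConfig, generate_dataset
from aliendrivers.trends import modified_mk_test
from aliendrivers.models import standardize, filter_collinear, forward_select, fit_glm
from aliendrivers.records import PredictorTable

cfg = SynthConfig(seed=7, n_countries=40, n_years=60)
ds = generate_dataset(cfg)

r = modified_mk_test(ds.annual_series["C000"])
print(f"C000 trend: S={r.S}, tau={r.tau:.3f}, CF={r.correction_factor:.3f}, p={r.p_value:.3g}")

Xz = PredictorTable(standardize(ds.predictors.data), ds.predictors.categories)
filtered, rep = filter_collinear(Xz, 10.0)
print("VIF-removed:", [n for n, _ in rep.removed])
trace = forward_select(ds.richness, filtered)
fit = fit_glm(ds.richness, filtered.data[trace.final_predictors])
print(f"theta = {fit.theta:.2f}")
print(fit.coefficients.round(3).to_string())
```

prints

```
C000 trend: S=487, tau=0.324, CF=3.065, p=0.0619
VIF-removed: ['research_expenditure', 'n_intl_airports']
theta = 4.25
                    estimate  std_error  p_value
intercept              5.045      0.078    0.000
trompenaars_7         -0.461      0.085    0.000
country_growth         0.386      0.083    0.000
port_traffic           0.265      0.079    0.001
population_density     0.209      0.084    0.012
n_tourists             0.161      0.085    0.057
trompenaars_1         -0.163      0.082    0.045
```

C000's reporting series rises (S = 487, τ = 0.32) but its serial
correlation inflates the variance threefold (CF = 3.07), leaving the trend
only borderline significant. The VIF screen drops two members of the
collinear trade-infrastructure block, and the selected negative-binomial
model recovers the planted driver structure: the culture score
(`trompenaars_7`, planted negative) depresses reported richness while
growth, density and tourism raise it; θ ≈ 4 indicates moderate
overdispersion.

The same pipeline runs from the shell:

```sh
aliendrivers all --seed 7 --outdir out/       # synthetic end-to-end run
aliendrivers simulate --seed 7 --outdir data/ # just the dataset + ground truth
aliendrivers clean data/records.csv --outdir cleaned/
```

writing cleaned records, composition tables, per-country trend statistics,
the outlier envelope table, the similarity network (CSV + GraphML), both
GLM coefficient tables and the variance-partition fractions, plus a
manifest with per-file SHA-256 hashes — two runs with the same seed are
byte-identical.

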
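# pathrise

Do alien plant species introduced by different pathways differ in invasion
success?  `pathrise` re-implements, as a tested and reusable Python
pipeline, the statistical machinery used to answer that question for a
national alien flora: ~1,000 neophyte species (post-1500 arrivals), each
assigned to one or more of four introduction pathways —

* **release** — deliberately sown or planted in the wild,
* **escape** — escaped from cultivation (the species itself is the traded
  commodity for these two),
* **contaminant** — unintentionally introduced with a commodity,
* **stowaway** — unintentionally introduced without a commodity association

— together with its invasion status (casual < naturalized < invasive),
first-record year, biological traits, and range measures (occupied mapping
grid cells, occupied habitat types).  The package is aimed at invasion
ecologists and biostatisticians who want these analyses on their own flora
tables, or who want a calibrated synthetic benchmark for method work.

## What it computes

**Temporal dynamics** (`introduction_dynamics`).  Cumulative first-record
curves per pathway, fitted by sequential polynomial regression (powers
added until the partial-F test goes non-significant) and by local-linear
tricube LOESS whose span is chosen by ANOVA-style deletion tests against an
under-smoothed start fit, with complexity measured as the equivalent number
of parameters ENP = tr(L).  Rates of introduction are compared through
inclusion curves: the cumulative proportion of a pathway's species recorded
by year *t* is modelled as logit F(t) = a + bt, the time to 50% inclusion
is t50 = −a/b, and its 95% CI comes from Fieller's theorem for the ratio of
the two coefficients.  Two likelihoods are available: an interval-censored
logistic likelihood on the yearly increments (default; a survival-analysis
view with correct frequentist coverage) and the classical binomial
pseudo-likelihood on cumulative counts.

**Trait trees** (`pathway_trees`).  A from-scratch binary classification
tree engine in the CART tradition: balanced class priors (the null model
misclassifies 50%), six split-homogeneity measures (Gini, symmetric Gini,
entropy, class probability, twoing, ordered twoing), surrogate splits
ranked by association for routing cases with missing values, penalties for
high-level categorical and missing-prone splitters, minimal cost-complexity
pruning, and optimal-size selection by 50 repeated stratified 10-fold
cross-validations under the minimum-cost and one-SE rules (modal size
across repeats).

**Status contingency** (`status_contingency`).  The pathway × status table
(multi-label: a species counts once per pathway) is tested for independence
with G = 2·Σ O·ln(O/E), cross-checked against the Poisson log-linear
deviance drop; cell departures are flagged from adjusted standardized
residuals r = (O−E)/√(E(1−p_row)(1−p_col)); a 4×3×2 deletion test asks
whether the association shifted between species introduced before and after
a split year.

**Range models** (`range_models`).  Linear mixed models of log occupied
grid cells and log occupied (seminatural) habitats on √residence-time and
pathway contrasts, with random intercepts at nested taxonomic ranks.
Random structures are compared by REML likelihood-ratio tests with the
boundary-corrected ½χ²₀+½χ²₁ reference, fixed structures reduced top-down
by ML deletion tests, and final models reported by REML.  Single-grouping
structures use an exact profiled-REML fitter; nested structures use
`statsmodels` MixedLM (the two agree to numerical precision).

**Synthetic flora** (`synthetic_flora`).  A generator whose defaults encode
the study's published quantities (pathway totals 93/599/443/254, per-pathway
status proportions, t50 values 144.9/146.8/172.9/163.8 y, range-model slopes
and variance components, trait–pathway associations).  Because published
margins condition on pathway *membership* while the generator draws
conditionally on a primary pathway, the per-pathway tables are calibrated by
inverting the known membership mixture, and integer range counts use
log-scale stochastic rounding so that log-linear fits recover the
generating parameters without discretization bias.

## Worked example

The published pathway × status counts ship with the package:

```python
from pathrise.datasets import czech_pathway_status_counts
from pathrise.status_contingency import g_test, status_proportions

res = g_test(czech_pathway_status_counts())
print(res)
```

```
G = 39.972, df = 6, P = 4.61e-07
release        51 (  71.4)***    23 (  14.9)*      19 (   6.8)***
escape        444 ( 459.7)*     109 (  95.7)*      46 (  43.6)
contaminant   367 ( 340.0)***    53 (  70.8)**     23 (  32.2)*
stowaway      204 ( 194.9)       37 (  40.6)       13 (  18.5)
```

Pathway and status are far from independent (G = 39.97 on 6 df).  Released
species are strongly over-represented among invasives (O = 19 vs E = 6.8,
adjusted residual +5.06) and under-represented among casuals, while
contaminants naturalize less often than chance expects (53 vs 70.8,
residual −2.80): invasion success falls as human assistance becomes less
direct.  `status_proportions` gives the per-pathway shares — 45.1% of
released species naturalized or invasive, against 25.9% (escape), 17.2%
(contaminant) and 19.7% (stowaway).

Rates of introduction, on a synthetic flora drawn at the study conditions:

```python
from pathrise.synthetic_flora import SyntheticConfig, generate
from pathrise.introduction_dynamics import build_cumulative, fit_inclusion_glm

flora = generate(SyntheticConfig(n_species=1007, seed=1))
for p in ("release", "escape", "contaminant", "stowaway"):
    curve = build_cumulative(flora, p)
    est = fit_inclusion_glm(curve, origin_year=1800)
    print(f"{p:<12s} t50 = {est.t50:6.1f} y  (95% CI {est.ci_low:.1f}-{est.ci_high:.1f})")
```

```
release      t50 =  150.7 y  (95% CI 134.8-187.5)
escape       t50 =  146.2 y  (95% CI 142.8-149.8)
contaminant  t50 =  177.8 y  (95% CI 171.2-186.2)
stowaway     t50 =  163.6 y  (95% CI 158.0-170.2)
```

Deliberate pathways reach half of their eventual species pool some two to
three decades sooner than unintentional ones; the release and escape
intervals overlap (rates not distinguishable) while stowaways run
significantly ahead of contaminants.

The same analyses are available from the shell:

```bash
pathrise generate --n 1007 --seed 1 --out flora.csv
pathrise contingency --flora flora.csv --out contingency.json
pathrise dynamics --flora flora.csv --pathway escape
pathrise run --config pipeline.yaml        # all stages, one summary.json
```

## Layout

```
src/pathrise/core_data.py             species records, CSV/YAML I/O, validation
src/pathrise/synthetic_flora.py       calibrated generator (study conditions)
src/pathrise/introduction_dynamics.py curves, LOESS/polynomials, Fieller t50
src/pathrise/pathway_trees.py         CART-style tree engine + CV selection
src/pathrise/status_contingency.py    G-test, residuals, three-way deletion test
src/pathrise/range_models.py          mixed models, boundary LR, contrasts
src/pathrise/pipeline.py, cli.py      orchestration and the pathrise CLI
docs/methods.md                       modelling assumptions and choices
```
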
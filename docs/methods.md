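# Methods

This note records the models behind `pathrise`, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not establish about real data.

## Data model

One row per alien species: taxonomy (genus ⊂ family ⊂ order, taken at face
value, no synonymy handling), a non-empty subset of the four introduction
pathways, one of three mutually exclusive invasion statuses (casual,
naturalized-but-not-invasive, invasive), an optional first-record year in
[1500, present], trait fields that may be multi-valued (life form, life
span, CSR strategy, dispersal) or missing, and three count responses (grid
cells, total and seminatural habitats, with seminatural ≤ total).  Pathway
membership is multi-label by design: per-pathway counts and percentages use
the total number of species–pathway assignments as denominator, and the
contingency table counts a species once in every pathway row it belongs to.
Files are UTF-8 CSV with four 0/1 pathway indicator columns (a delimited
`pathways` list column is accepted on input), empty cells or `NA` for
missing, and a JSON sidecar for provenance.

## Inclusion curves and Fieller intervals

For a pathway with N dated species, the cumulative proportion recorded by
year t is modelled as a logistic law on the logit scale, logit F(t) = a +
b·t, t in years since a user-declared origin (default 1800; the observation
window is origin + 200 y).  The time to 50% inclusion is t50 = −a/b and its
95% CI solves the Fieller quadratic (a + bρ)² = z²(v_aa + 2ρ v_ab + ρ²
v_bb); the interval is exact for the ratio of asymptotically normal
coefficients provided g = z²v_bb/b² < 1 (otherwise the CI is reported
unbounded and flagged).  Two pathways "differ in rate" iff their CIs are
disjoint.

Two likelihoods are implemented.  The default treats the yearly increments
of the curve as an interval-censored sample from the logistic distribution,
conditioned on falling inside the observed record window — a survival-
analysis formulation in which the N species are the units.  The alternative
(`likelihood="cumulative"`) is the classical GLIM-style binomial regression
of each year's cumulative count out of N.  The cumulative construction
treats ~200 strongly dependent yearly points as independent binomials; in
simulation its 95% CI covered the true t50 in ~0% of replicates, against
93–94% for the interval likelihood, which is why the interval form is the
default and the calibration checks are run against it.  A record year Y is
read as an event in (Y−1, Y]; the generator uses the matching ceil
convention (rounding years instead induces a −0.5 y bias).

Sequential polynomial fits add powers of centred-and-scaled year until the
partial-F test of the last power is non-significant (α = 0.05, degree ≤
min(6, n−2)).  LOESS is local-linear with tricube weights; span ≥ 1
degenerates to the global least-squares line, so ENP(span=1) = 2 exactly.
Span selection scans upward from 0.08 in steps of 0.01 and keeps the last
span whose deletion test against the start fit is non-significant.  The
deletion test between smoothers (and against polynomials) is the
approximate F on residual sums of squares with fractional dfs from ENP
differences — no exact finite-sample test exists for LOESS, and the
statistic is labelled approximate in output.

## Classification trees

Targets are yes/no pathway membership; predictors are traits (multi-valued
traits become 0/1 indicator features, single-valued ones categorical
features), residence time, origin, and — in the taxonomic sensitivity
variant — genus/family/order alone.  Balanced priors give each class total
weight ½ regardless of prevalence.  Numeric splits search all midpoints;
categorical splits are exhaustive up to 12 observed levels and use the
class-rate ordering shortcut above that.  For two classes the twoing
criterion equals half the Gini decrease, so the two rank splits
identically; the reported *improvement* is the prior-weighted impurity
decrease normalized by root impurity (twoing normalized by half the root
Gini so the numbers coincide with Gini's), making improvements sum along a
branch like explained variance.  Optional penalties divide a categorical
splitter's gain by log2(L) for L > 2 levels and scale any splitter's gain
by its observed-weight fraction; both are on by default.  Surrogate splits
maximize weighted routing agreement with the primary split (reversed rules
allowed) and are ranked by the CART association (min(p_L,p_R) −
missend)/min(p_L,p_R); missing cases route by surrogates, then by the
weighted majority direction — cases are never dropped, so children's counts
always sum to the parent's.

Size selection: minimal cost-complexity pruning gives the master sequence;
each of 50 seeded repeats of stratified 10-fold CV maps fold sequences onto
the master via geometric-mean α's and records the optimal size under the
minimum-cost and one-SE rules; the modal size across repeats is selected.
The SE used by the one-SE rule combines the per-case binomial SE of the
balanced error with the fold-to-fold dispersion SE (root sum of squares):
with either component alone, signal-free datasets frequently kept small
spurious trees, because chance associations within a fixed dataset validate
across its own folds; the combined SE restores the intended behaviour (the
modal tree on pure noise is the root in ~8/10 dataset draws — the residual
2/10 reflect genuinely strong in-sample noise structure, an inherent
property of cross-validation on a fixed sample, not an engine defect).
Specificity and sensitivity are reported both by resubstitution and from
out-of-fold predictions.

## Contingency analysis

Expected counts are product-margin; G = 2·Σ O·ln(O/E) over non-zero cells
(x·ln x → 0), asserted equal (1e-6) to the deviance of the main-effects
Poisson log-linear model; df = (R−1)(C−1).  Adjusted standardized residuals
use the margin-corrected variance and two-sided normal flags at 1.645 /
1.960 / 2.576 / 3.291.  No multiple-testing correction is applied across
the twelve cells (reported as such).  The residence-time test splits dated
species at 1900 and compares the all-two-way Poisson model against
saturated on the 4×3×2 table (df = 6).  The combined naturalized-or-
invasive percentage is printed as the sum of the two already-rounded
components, matching how such tables are conventionally typeset.

## Mixed models of range

Responses are natural-log counts — natural log, because the back-transform
of the casual-group mean 1.396 is 4.04 ≈ 4.0 occupied habitats, which fixes
the base; species with zero seminatural habitats are excluded from log
models (a log1p option exists, off by default).  Residence time enters as
its square root.  Pathway enters through membership contrasts (contaminant
vs rest; {release, contaminant} vs {escape, stowaway}), which are
well-defined for multi-label species without duplicating rows.  Random
effects are intercepts only, at one of: none, order, family-in-order,
genus-in-family-in-order, or genus-only.  Models in which habitat type
(total vs seminatural) interacts with pathway and status use a stacked
long-format response — two rows per species under a two-level
``habitat_type`` factor (`build_stacked_habitat_frame`); this reading of
"habitat type as a categorical factor" is an interpretation, recorded as
such.

Random-structure selection walks the nested sequence with REML LR tests; a
variance tested on its boundary uses the ½χ²₀+½χ²₁ mixture, i.e. half the
nominal χ²₁ tail.  If the full hierarchy wins it is compared with
genus-only by AIC (AIC counts fixed coefficients plus variance parameters;
REML AICs are only compared at fixed fixed-structure).  Fixed-structure
selection is top-down by ML LR deletion tests, always removing the least
significant term of the highest surviving interaction order, never removing
a term contained in a surviving interaction; the final model is refit by
REML.  Reported t-values use the GLS standard errors without a
degrees-of-freedom correction and are flagged approximate.

Single-grouping structures are fitted by an exact profiled likelihood: with
V₀ = I + λZZ′ the profile over (β, σ²) leaves a 1-D problem in λ =
σ²_group/σ²_resid, each evaluation O(n) via group sums; the REML value
includes the ln|X′V⁻¹X| term so it is directly comparable with the
`statsmodels` MixedLM values used for the nested structures (agreement to
~1e-8 is asserted in the tests).  In a null calibration with 100 groups of
4, the boundary-corrected LR test rejects in ~4.4–4.8% of replicates at
nominal 5%; with markedly fewer groups the mixture is conservative (~3%),
a known finite-sample property.

Diagnostics report conditional residuals (fixed part plus BLUP-shrunken
random intercepts): the slope of standardized residuals on conditional
fitted values, and the normal-quantile correlation.

## The synthetic flora

The generator's defaults are the study conditions: multi-label pathway
margins 93/599/443/254 of 1007; per-pathway status proportions (e.g.
release 54.9/24.7/20.4%); times to 50% inclusion 144.9/146.8/172.9/163.8 y
since 1800; grid-cell slopes on √residence-time 0.14 (casual escapes) vs
0.11, 0.23 (naturalized), 0.20 (invasive); seminatural-habitat group means
4.0/1.6 (casual), 8.6/3.9 (naturalized), intercepts 4.4/2.9 with common
slope 0.07 (invasive); taxonomic variances per status (orders 0.110/0.116,
genera-in-orders 0.362, genera 0.567) realized as status-specific scalings
of shared taxon draws so each per-status subset follows exactly the random
structure reported for it.  Trait–pathway associations are set so the
reverse conditionals match the published tree findings (41.5% of woody
species released vs 4.2% of non-woody; 66.2% of annuals and ~80% of short
grasses introduced as contaminants).  Woody heights centre on 4 m with wide
spread: life form itself, not height, is what separates released species.

Three mechanisms deserve note.  (i) *Membership calibration*: status,
traits and inclusion times are drawn conditional on a uniformly chosen
primary pathway, but published targets condition on membership; since the
pathway-set law is known exactly (independent Bernoullis with a fixed-point
adjustment, conditioned non-empty), the membership margin is a linear
mixture M·π of the primary tables, and the generator uses π = M⁻¹·target.
(ii) *Inclusion steepness*: the paper prints no slope; the default 0.07/y
(scale ≈ 14 y) makes each curve's central rise span about half a century as
in the published figures and reproduces the published CI pattern (release ≈
escape; contaminant significantly slower than stowaway) at the study's
sample sizes.  (iii) *Log-scale stochastic rounding*: integer counts
randomize between ⌊e^z⌋ and ⌊e^z⌋+1 with the weight that makes
E[log count] = z exactly, so log-linear fits recover slopes and variance
components without discretization bias.  The one residual artifact is the
floor at one occupied unit: for the small seminatural-habitat counts
(published means 1.6–8.6) linear predictors below 0 are unrepresentable,
which compresses the recovered taxon variance by roughly 7% on that
response; the recovery checks therefore estimate the genus variance from
the grid-cell response (same generating parameter, counts ~two orders
larger), and the attenuation is stated here rather than hidden.

Field-level missingness is masked at the study's observed coverage rates
(e.g. habitats known for 27% of species, residence time for 66%);
parameter-recovery experiments disable masking to measure the estimators at
the stated n.  What the generator does *not* emulate: pathway co-occurrence
structure beyond the margins (unpublished), spatial autocorrelation of grid
cells, realistic phylogenies (the taxonomy is a random geometric-size
forest, which does reproduce "many small genera"), or any dependence of
status on introduction period (so the three-way deletion test is null by
construction, with an effect injectable in tests).  Passing the synthetic
checks shows the estimators are correct and calibrated under these
conditions; it does not certify the paper's data-dependent numbers (t50s,
tree misclassification rates, Table LR values), which are unreachable
without the unreleased flora and enter only as generator parameters.

## Problem sizes used by the checks

Desk checks on the published 4×3 table are exact.  Simulation checks use:
Fieller coverage, 500 curves of 600 dated species; rate ordering, 400
four-pathway replicates at 600 species each (the release/escape pair is
non-different in ~93% of replicates, against the ≥90% requirement); tree
oracle, 200 exhaustive enumerations at ≤8 cases; no-signal selection, one
400-case dataset with 50 CV repeats; mixed-model recovery, 100 floras of
2000 species; boundary-LR calibration, 2000 null replicates of 400
observations in 100 genera.  These sizes keep the full suite at ~3 minutes
while leaving Monte-Carlo error well inside each check's tolerance.
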
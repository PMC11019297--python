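# Methods

## The model

A group's isotopic niche is modeled as a bivariate normal cloud in
(δ13C, δ15N) space, summarised by its standard ellipse: centroid at the
coordinate-wise mean, semi-axes √λ₁ ≥ √λ₂ from the eigenvalues of the
n−1 sample covariance matrix, area `SEA = π√(λ₁λ₂)` (‰²). SEA is biased
low for small groups; `SEAc = SEA·(n−1)/(n−2)` corrects this, and the
n−1 covariance denominator is what makes that correction factor exact.
Fitting requires n ≥ 3 (SEAc divides by n−2); collinear data yield
λ₂ = 0, SEA = 0 and a degeneracy flag, and degenerate ellipses are
excluded from geometric operations rather than silently inflated.

Three group-level contrasts follow:

- **niche width** — mean Euclidean distance to the group centroid (MD),
  a dispersion proxy for the variety of resources consumed;
- **niche position** — the centroid itself, compared between groups by
  Euclidean distance, a proxy for the type of resources consumed;
- **niche overlap** — the Jaccard index of two scaled ellipses,
  `I/(A₁ + A₂ − I)` with `I` the intersection area.

Both δ axes are used unstandardized, weighting δ13C and δ15N equally.

## Permutation tests

`|MD(a) − MD(b)|` is tested with a location-free null: each group is
centered on its own centroid, the centered residuals pooled and randomly
re-assigned to two groups of the original sizes, and the statistic
recomputed. The centroid-distance test permutes group labels over the
pooled *raw* observations. The published description of this procedure
cites a nested-linear-model residual permutation without specifying the
scheme; re-assigning centered residuals for the dispersion statistic and
raw labels for the location statistic is this package's concrete
realization of that idea, chosen for exchangeability under each test's
own null, and is documented here rather than asserted to be the original
authors' exact scheme.

p-values use the standard `(b + 1)/(n_perm + 1)` rule with ties counted
toward `b` (the ≥ rule), so p ∈ (0, 1] and the minimum attainable value
is `1/(n_perm + 1)`. The discrete p is compared with α inclusively,
which gives the exact nominal size under exchangeability; the simulation
in `sulaniche.calibration` verifies the empirical type-I rate at
α = 0.05 sits inside the exact binomial interval over 500 replicates.
Defaults: 9 999 permutations, mandatory seed in the pipeline
configuration. Internally the pooled points are sorted lexicographically
and the smaller group size indexes the first permutation block, making
results exactly invariant to input row order and to swapping the two
groups; invariance to a common rotation (dispersion test) holds exactly
for the observed statistic and only in distribution for the realized
null, since rotation changes the canonical ordering.

## Ellipse scaling and overlap

`scale_ellipse` multiplies both semi-axes by a common factor c:
c = 1 (standard, ≈40% of a bivariate normal), c = √((n−1)/(n−2))
(area = SEAc), or c = √(χ²₂(p)) for a probability-level ellipse (50%
dotted / 95% solid in the plotting convention; p = 0.95 gives
c = √5.991 ≈ 2.4477). The pipeline's replication default is the
SEAc-scaled ellipse, because the overlap index is defined on the
small-sample-corrected areas; since the source analysis does not state
which convention its overlap used, all modes are exposed via
`--ellipse-scale` and the default is a documented choice, not an
assertion.

Intersection areas use exact polygon clipping (shapely) of 720-vertex
polygonal boundaries. Vertices are placed at radius
`√((2π/n)/sin(2π/n))` times the ellipse radius so the polygon's area
equals πab exactly; an inscribed polygon would be biased low by
O(1/n²), and area-matching removes the systematic part of that error
(the unit-circle lens worked example is then reproduced to ~5 × 10⁻¹¹).
A Monte-Carlo estimator is retained purely as an independent oracle: it
samples uniformly inside the smaller ellipse (200 000 draws by default,
seeded) and scales the hit fraction in the other by the known smaller
area. Sampling the smaller ellipse rather than a bounding box keeps the
estimator's relative error conditioned on the component area instead of
the box area. Method agreement is asserted at an absolute area
tolerance of 1e-4 ‰² in unit tests and at 1e-3 relative to the smaller
component area over random ellipse pairs (relative to the intersection
itself the ratio is ill-conditioned as the intersection vanishes).

## Tissue standardization

Blood and feathers discriminate isotopes differently, so breeding
(whole blood) vs non-breeding (body feather) comparisons first convert
blood values to feather-equivalents with per-axis linear maps
(δ13C: slope 0.972, intercept 0.962 ‰; δ15N: slope 1.014, intercept
0.447 ‰). The coefficient standard errors are carried as metadata but
not propagated — the analysis uses point estimates, matching how such
conversions are applied in practice. The transform applies only to
whole-blood samples; applying it to a feather sample is a usage error.
Coefficients are overridable in the run configuration.

## Comparison grid and bulk contrasts

`build_default_grid` emits: species vs species within each tissue
(sexes pooled), female vs male within each species × tissue, and
standardized-blood vs feather within each species — 8 comparisons for a
complete two-species, two-sex, two-tissue dataset. Groups under n = 3
are emitted with a skip flag rather than failing the run. Unknown-sex
birds enter pooled (species-level) groups but are excluded from sexed
ones. Years are pooled: the sampling design leaves year-stratified
cells too small to test.

Bulk per-isotope means are compared by Tukey HSD over the four
species × sex cells within a tissue, treated as one one-way family at
α = 0.05 — one familywise procedure that contains every pairwise
contrast of interest. (The original model structure behind these
contrasts is unstated; a single one-way layout per tissue is this
package's design choice.) The test itself is statsmodels'
`pairwise_tukeyhsd`.

## Diet statistics

Frequency of occurrence is presence-based (a family occurring as three
items in one sample counts once). Composition is compared by Pearson χ²
on the species × family item-count table without continuity correction,
df = (r−1)(c−1), with expected counts < 5 flagged in the log; the
p-value is asymptotic, matching the df-based reporting convention the
analysis follows. Food-load mass (one value per regurgitate) and the
length of complete (head-to-tail) prey items are compared by two-sided
t-tests — Welch by default, since nothing justifies assuming equal
variances between species; a pooled-variance variant is available for
replication of analyses that used it. All lengths are held in a single
declared unit (cm) and never mixed; published prey-length summaries mix
mm and cm and the package deliberately does not attempt to reconcile
that inconsistency.

## Synthetic data

The generator draws each species × sex × tissue cell from a bivariate
normal — exactly the assumption the ellipse model makes — with the
study's group sizes (blood: masked 18 F/18 M, red-footed 8 F/14 M;
feathers: masked 15 F/18 M, red-footed 7 F/13 M). The preset centroids
are synthetic defaults placed once to carry the qualitative field
pattern: species separated by ~2.5 ‰ in δ15N during breeding (masked
higher), a 0.7 ‰ δ15N sex difference in masked boobies and none in
red-footed boobies, and broader feather niches (per-axis sd ≈ 0.67 ‰ vs
≈ 0.32–0.40 ‰ in blood) with at most slight species overlap. Diet
samples use a multinomial, flyingfish-dominated family mix (the masked
diet more diverse), negative-binomial-like item counts truncated at 1
(means 3.7 and 2.8), lognormal food loads (means 149.5 g and 87.5 g)
and prey lengths, and a 16% Bernoulli completeness rate.

What passing tests on this generator do **not** show: real isotope data
have non-normal tails, year effects, tissue-specific C:N structure and
spatial isoscape gradients, none of which are simulated; recovery of
the qualitative pattern here validates the machinery, not the field
conclusions. Replication of the published statistics requires a local
copy of the deposited field table via the `replicate` subcommand.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make their Monte-Carlo
error small relative to the asserted tolerance: 500 replicates for
type-I calibration (exact binomial interval around 0.05), 100 seeds for
power, 50 pipeline runs for pattern recovery, 4 × 10⁶ draws per ellipse
pair when certifying the geometric oracle at 1e-3. Permutation defaults
drop from 9 999 (analysis) to 999 (simulation studies) where only
rejection at α = 0.05 is at stake. Seeds are derived from a single
master seed through `numpy.random.SeedSequence`, and every derived seed
stays below 2³¹.

## Known limitations

- Overlap is ellipse-based; strongly non-elliptical niches (multimodal
  groups) are summarised poorly by any SEA-family metric.
- The dispersion test's residual permutation is approximate for very
  unequal group sizes with strongly non-exchangeable shapes.
- Standard-error metadata on the standardization coefficients is not
  propagated into overlap or test uncertainty.
- The χ² composition test is asymptotic; with the field-sized diet
  samples many expected counts fall below 5 (flagged, not corrected).
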
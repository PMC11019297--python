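# sulaniche

Quantitative trophic ecology of two sympatric booby species (the masked
booby *Sula dactylatra* and the red-footed booby *Sula sula*) from
stable-isotope and diet data. The package implements, as a tested and
reusable pipeline, the standard analysis for asking whether closely
related seabirds sharing a colony partition their trophic niche —
between species, between the sexes, and between the breeding and
non-breeding periods.

## What it computes

Each group of birds (a species × sex × tissue cell) is a cloud of
points in bivariate (δ13C, δ15N) space, δ values in ‰. Whole blood
integrates the breeding-season diet; body feathers integrate the
non-breeding (molt) period.

- **Isotopic niche ellipses.** The standard ellipse of a group has
  semi-axes √λ₁, √λ₂ from the eigenvalues of the sample covariance
  matrix, area `SEA = π√(λ₁λ₂)` and small-sample corrected area
  `SEAc = SEA·(n−1)/(n−2)`. Ellipses can be rescaled to bivariate-normal
  probability levels (50%, 95%) via the χ²(2 df) quantile.
- **Niche overlap.** Jaccard index of two scaled ellipses,
  `overlap / (area₁ + area₂ − overlap)`, with the intersection computed
  by exact polygon clipping (a seeded Monte-Carlo estimator serves as an
  independent cross-check).
- **Niche width.** Mean Euclidean distance of individuals to their group
  centroid; groups compared by a residual permutation test on
  `|MD(a) − MD(b)|`.
- **Niche position.** Euclidean distance between group centroids, tested
  by permuting group labels over the pooled observations.
- **Tissue standardization.** Whole-blood values are converted to
  feather-equivalents with the linear maps
  `δ13C_f = 0.972·δ13C_b + 0.962` and `δ15N_f = 1.014·δ15N_b + 0.447`
  before any breeding vs non-breeding comparison.
- **Bulk isotope contrasts.** Tukey HSD over the species × sex cells
  within each tissue, per isotope, at family-wise α = 0.05.
- **Diet.** Frequency of occurrence per prey family, χ² homogeneity of
  family composition, and Welch t-tests on food-load mass and on the
  length of head-to-tail-complete prey items.

A synthetic-data generator reproduces the study design (8 isotope cells
with the field group sizes, flyingfish-dominated diets with ~16% of
items complete), so the whole pipeline is testable without any download.

## Worked example

```sh
sulaniche simulate --out demo/data --seed 1
sulaniche compare --isotopes demo/data/isotopes.csv \
    --diet demo/data/diet.csv --seed 1 --n-perm 9999 --out demo/report
sulaniche replicate --isotopes demo/data/isotopes.csv --seed 1 \
    --n-perm 9999 --out demo/rep
```

The `replicate` view prints one line per comparison of the default
grid; with the bundled synthetic preset (seed 1) it prints:

```
inter_specific_whole_blood: dispersion diff 0.097 (p=0.215), centroid dist 2.620 (p=0.0001), overlap 0.0%
inter_specific_body_feather: dispersion diff 0.046 (p=0.764), centroid dist 1.267 (p=0.0001), overlap 0.0%
masked_female_vs_male_whole_blood: dispersion diff 0.008 (p=0.933), centroid dist 0.748 (p=0.0001), overlap 0.5%
masked_female_vs_male_body_feather: dispersion diff 0.404 (p=0.0118), centroid dist 0.271 (p=0.545), overlap 36.2%
red_footed_female_vs_male_whole_blood: dispersion diff 0.095 (p=0.395), centroid dist 0.113 (p=0.737), overlap 40.3%
red_footed_female_vs_male_body_feather: dispersion diff 0.223 (p=0.378), centroid dist 0.682 (p=0.108), overlap 32.7%
masked_breeding_vs_non_breeding: dispersion diff 0.350 (p=0.0006), centroid dist 1.666 (p=0.0001), overlap 0.0%
red_footed_breeding_vs_non_breeding: dispersion diff 0.403 (p=0.0008), centroid dist 0.206 (p=0.454), overlap 22.0%
```

Reading the first and fifth lines: during breeding the two species'
niche positions differ strongly (centroid distance 2.62 ‰, permutation
p = 0.0001, the minimum at 9 999 permutations) with zero ellipse
overlap, while female and male red-footed boobies are indistinguishable
(centroid distance 0.11 ‰, p = 0.74, 40% overlap) — the qualitative
pattern the synthetic preset is built to carry. `demo/report/` holds the
same results as CSV tables plus a `summary.yaml`; re-running with the
same seed reproduces the files byte-for-byte.

The same `replicate` subcommand accepts a locally supplied copy of the
study's deposited isotope table (Dryad doi:10.5061/dryad.573n5tbg4, not
bundled) with an optional `--column-map` YAML to rename its headers.

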
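# Methods

This note documents the statistical machinery, the modelling assumptions,
the defaults and the numerical choices made where the design was open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

Surveys are cells × species matrices of nonnegative integer point-count
totals, paired with per-cell metadata (city; habitat ∈ {urban, periurban};
vegetation cover fraction in [0, 1]) and per-species traits (one of 7 diet
guilds, one of 4 preferred-habitat guilds, native/exotic origin; the two
guild groupings are mutually exclusive classifications). Files are UTF-8
CSV with a header row and identifiers in the first column; categorical
labels are matched case-insensitively against canonical English strings.

"Evenness" is computed as Pielou's J′ = H′/ln S with natural-log Shannon
entropy H′ over within-cell relative abundances. The literature uses
several log-based evenness indices; J′ is the standard choice and the one
assumed here, but the method is configurable (`pielou` or raw `shannon`)
and the choice used is recorded in the result's metadata and the run
manifest. Cells with S ≤ 1 have undefined evenness (ln S = 0); they are
dropped from the evenness analysis only, never from richness or
community-structure analyses.

## Synthetic survey generator

The generator emulates a three-city paired design: 110 urban and 50
periurban 250-m point-count cells per city, 54 species. Its defaults are
the package's fixed reference conditions:

| parameter | default | rationale |
|---|---|---|
| `n_cities`, cells | 3; 110 urban + 50 periurban | the survey design being emulated |
| `n_species` | 54 | recorded richness scale (51 native + 3 introduced) |
| `abundance_model` | lognormal, σ = 1 | canonical species-abundance distribution; log-series optional |
| `avoider_fraction` | 0.30 | ≈ 17/54 species found only outside the urban limit |
| `exploiter_fraction` | 0.10 | ≈ 5 species favoured by urbanization, 3 of them exotic |
| `filter_strength` f | 0.8 | moderate-to-strong filtering reference condition |
| `exotic_boost` | 20 | urban-exploiter dominance: urban/periurban mean abundance ratios of house-sparrow-like species are of order 20 |
| `mean_count_per_cell` | 12 | ~10–15 birds per 6-min 50-m point count |
| `veg_effect` | 0.5 | bird totals increase with green cover |

Mechanics: per city an independent species pool is drawn from the
abundance model and normalised (a shared-pool mode exists for cross-city
homogenization experiments). Traits are allocated by a floor +
largest-remainder apportionment of guild weights, then assigned to species
at random. Fate classes (avoider / tolerant / exploiter) are apportioned
the same way; the first `n_exotics` exploiters are exotic. Urban
multipliers are m = 1 − f for avoiders, 1 for tolerants, 1 + f for native
exploiters and 1 + f·(boost − 1) for exotics, so **every multiplier
collapses to 1 at f = 0**: zero filter strength is an exact null in which
urban and periurban cells follow one sampling law. Vegetation cover is
Beta(2, 6) in urban cells (mean 0.25) and Beta(6, 4) in periurban cells
(mean 0.6) — only the urban < periurban ordering is asserted, the shapes
are a modelling convenience. Per cell the bird total is
Poisson(mean_count · exp(veg_effect · (veg − ½))) and species counts are
one multinomial draw from the city pool, re-weighted by the multipliers
and renormalised in urban cells.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring cells, detection error, phylogenetic or trait-correlated
abundance structure, within-season turnover. Tests passing on synthetic
data therefore validate the statistical machinery under the stated
sampling assumptions, not the field behaviour of real surveys.

Determinism: every random stream is a named child of the master seed
(`SeedSequence([seed, crc32(tag), ...])`), so the draws for one city are
unaffected by the presence of other cities, and identical (config, seed)
pairs yield bit-identical tables.

## Null model

The pool for a city is the vector of periurban relative abundances over
the species recorded anywhere in that city; species recorded in neither
habitat are excluded, and an optional natives-only switch drops exotics
from the pool. The "urban community" is the pooled set of individuals over
all the city's urban cells (size N). Each of `n_sims` (default 999)
simulated communities is one multinomial(N, pool) draw, so simulated and
observed communities have identical size and the comparison isolates
composition from sampling effort.

Classification: a species present in urban habitat is `present`; an
absentee is `chance_absent` when the integer mode of its simulated
abundances is 0, else `avoider`. Modal ties (e.g. {0: 5, 1: 5}) are broken
toward the smaller value by default — the conservative direction, since it
favours chance-absent over avoider — and the tiebreak is configurable.
The per-species mode is taken directly over the simulated counts, with no
smoothing.

Loss metrics per city: observed loss = 100 · (periurban species absent
from urban)/S_peri; random loss = 100 · (S_peri − mean simulated
richness)/S_peri; tolerance richness = total recorded species − avoiders.

**Calibration property and its limit.** With filter strength 0 the model
is nearly calibrated: the avoider false-positive rate among species with
expected urban count ≥ 3 is well under 10% (the conservative mode-0 rule
plus the smallest-value tiebreak see to that). The observed−random loss
difference, however, is not exactly centred on zero: the pool is a
*plug-in estimate* from a finite periurban sample (~600 individuals)
while the urban community it is compared against holds roughly twice as
many. For rare species, E[(1 − p̂)^N | species detected] exceeds
(1 − p)^N by convexity, so the random loss slightly overestimates the
expected absence rate — a bias of a fraction of one species per city at
the default design scale, which vanishes as the periurban sample grows
(verified by simulation with very large periurban samples). This is a
property of plug-in resampling null models generally, not of this
implementation, and it is detectable when averaging over many replicate
surveys; single-survey inferences are unaffected at any practical level.

## Distances and PERMANCOVA

Community and guild analyses use Bray–Curtis dissimilarity on fourth-root
transformed abundances (the severe transform that tempers dominant
species); richness and evenness use Euclidean distances on the univariate
response, for which the machinery reduces *exactly* to classical ANOVA.
A pair of all-zero cells gets Bray–Curtis distance 0, with a warning.

The engine Gower-centers the squared distances, G = J(−D²/2)J, whose
trace is the total sum of squares, and partitions it sequentially
(Type I) over the term order

    covariate, city, habitat, cov × city, cov × habitat,
    city × habitat, cov × city × habitat

with the covariate entered first. Term degrees of freedom are rank
increments of the sequential QR basis; term SS is the trace of the
projected G block, and the partition Σ SS + SS_resid = tr G holds to
machine precision by construction.

Denominators (mixed model, habitat fixed, city random): habitat is tested
over the city × habitat mean square; every other term over the residual.
PRIMER-style software derives these from expected mean squares
internally and does not print its choices, so the map here is a
documented convention — and it is user-overridable, with the map actually
used echoed in the fitted `scheme_`.

Permutation p-values (default 10,000 permutations, observed statistic
included in numerator and denominator, so p ∈ (0, 1]):

* terms tested over the residual use Freedman–Lane permutation of
  residuals under the reduced model (all preceding terms);
* the fixed factor tested over the interaction permutes *intact* habitat
  blocks — within each city, the assignment of habitat labels to the
  city's cell blocks is permuted. With 3 cities × 2 habitats only
  2!³ = 8 distinguishable relabellings exist, which is why this term's
  permutation p is coarse and a Monte-Carlo p-value is always reported
  for it.

Monte-Carlo p-values (used whenever a term has fewer distinguishable
permutations than `mc_threshold` = 1000): the null pseudo-F is drawn
10,000 times as a ratio of weighted chi-square sums, with weights equal
to the eigenvalues of the denominator's projected G block (scaled by its
df). In the univariate Euclidean limit this collapses to the exact F
distribution.

Components of variation: method-of-moments, σ̂²_term = (MS_term −
MS_denominator)/c_term with the EMS multiplier c_term computed from the
design matrix (it reduces to the per-group cell count in the balanced
one-way case); negative estimates are truncated at 0 and the components
(including the residual) are normalised to percentages summing to 100 —
so truncated terms print CV = 0.

Not implemented by design: Type III sums of squares, more than two
crossed factors, nested designs, and dispersion (PERMDISP-style) tests.

## SIMPER

Between-group Bray–Curtis dissimilarity splits exactly over species for
each cell pair: δ_i(j,k) = |y_ij − y_ik| / Σ_s (y_sj + y_sk). A species'
contribution is the mean of δ_i over all between-group pairs; the
contributions sum to the average between-group dissimilarity identically
(finite-sum exchange), and contribution percentages sum to 100. The
ranked table is truncated at the first species whose cumulative
percentage reaches the cutoff (default 90%), so printed cumulative totals
slightly exceed the cutoff. Group mean abundances are reported on the
scale of the matrix passed in — fourth-root-transformed in the standard
pipeline, since it is the transformed matrix that defines the
dissimilarities; callers wanting raw-scale means pass the raw matrix to
the reporting columns. Within-group similarity breakdowns and
dissimilarity/SD ratios are out of scope.

## Ordination

PCoA eigendecomposes the Gower-centered matrix; coordinates are
eigenvectors scaled by √λ for positive eigenvalues only. Bray–Curtis is a
semi-metric, so negative eigenvalues occur: they are reported, their axes
are never embedded, and percentage-explained is computed over the
positive eigenvalues. No Lingoes/Cailliez correction is applied by
default (matching common practice in ecological software); a Lingoes
option exists.

Centroid ordination: squared between-centroid distances are computed from
block means of G — C_gh averaged over the group pair, d²(g,h) = C_gg +
C_hh − 2C_gh — which keeps negative-eigenvalue components with their
sign. A semi-metric can make d² marginally negative; it is clamped to 0
with a warning. For genuinely Euclidean input this equals the distance
between arithmetic group means exactly.

Vector overlays correlate each species/guild (transformed abundance, or
group means for centroid plots) with each plotted axis — Pearson by
default, Spearman selectable — and flag an item as shown only when its
best |r| strictly exceeds the threshold (default 0.75). Zero-variance
items get missing correlations and are never shown.

## Pipeline and reproducibility

`run_all` executes data generation (or loading), the null model,
PERMANCOVA for the five standard responses (richness, evenness, community
structure, diet guilds, habitat guilds), per-city species SIMPER plus
pooled guild SIMPER, and the centroid PCoA. Stage seeds are derived from
the master seed by name, every output is a tidy CSV without timestamps
(byte-identical reruns), and a manifest records the configuration, its
SHA-256 hash, the package version and each seed consumed. Any stage
failure aborts with the stage name while preserving the outputs already
written.

Problem sizes used in the distributed checks: the statistical acceptance
tests run the full 480-cell, 54-species design for the null-model
calibration (100 replicates), recovery and end-to-end pattern checks, and
small 6–24-cell designs for the exact oracles (classical ANOVA limit,
exhaustive permutation enumeration, Euclidean embedding), where exactness
— not scale — is what is being verified.
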
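# urbfilter

Urbanization filters bird communities: only a fraction of the species found
in the landscape around a city persists inside it, and the survivors are a
biased sample — habitat generalists, granivores, omnivores and a handful of
exotic "urban exploiter" species. `urbfilter` implements the statistical
pipeline used to demonstrate this with point-count survey data from paired
urban / periurban grids in several cities:

1. **Resampling null model for species loss.** For each city, the periurban
   community defines a species pool with relative abundances *p₁ … p_S*.
   999 random urban communities are built by drawing, with replacement,
   *N* individuals from that pool (multinomial sampling), where *N* is the
   size of the city's pooled urban community. A species absent from urban
   habitat is *chance-absent* when the mode of its simulated abundances is
   0, and an *urban avoider* (nonrandom absence) otherwise. Per city the
   model reports the observed loss (% of periurban species absent from
   urban habitat), the random loss (% expected under the null model) and
   the *tolerance* richness (total recorded species minus avoiders).
2. **PERMANCOVA.** Distance-based permutational analysis of covariance on
   Bray–Curtis (community, guild structure) or Euclidean (richness,
   evenness) matrices, with vegetation cover as covariate, habitat
   (urban/periurban) as a fixed factor and city as a random factor:
   sequential sums of squares from the Gower-centered matrix, pseudo-*F*
   with mixed-model denominators (habitat tested over city × habitat),
   10,000-permutation p-values, Monte-Carlo p-values when few
   distinguishable permutations exist, and components of variation.
3. **SIMPER.** Exact per-species decomposition of the average
   between-habitat Bray–Curtis dissimilarity, ranked and truncated at a 90%
   cumulative cutoff.
4. **PCoA.** Principal coordinates ordination of cell-level or
   city × habitat centroid dissimilarity matrices, with species/guild
   correlation vectors (shown when |r| > 0.75).

Field surveys of this kind are rarely deposited, so the package ships a
**synthetic survey generator** that emulates the study design (3 cities,
110 urban + 50 periurban point-count cells, 54 species, 7 diet and 4
preferred-habitat guilds) with a known, tunable filtering ground truth —
every downstream stage is testable against that truth.

## Worked example

```python
import urbfilter as uf

survey, cells, traits, truth = uf.generate_study(uf.GeneratorConfig(seed=7))

nm = uf.NullModel(n_sims=999, seed=7).fit(survey, cells, traits)
print(nm.loss_[["S_periurban", "observed_loss_pct", "random_loss_pct"]].round(2))
```

```
       S_periurban  observed_loss_pct  random_loss_pct
city
city1           52               1.92             1.84
city2           49               8.16             0.95
city3           53               5.66             2.63
```

Observed loss exceeds the loss expected from random dispersal alone —
the signature of nonrandom filtering (the generator's default filter
strength is 0.8). The community-structure PERMANCOVA on the same data:

```python
from urbfilter import Permancova, bray_curtis, fourth_root

D = bray_curtis(fourth_root(survey))
est = Permancova(fixed_factor="habitat", random_factor="city",
                 covariate="veg_cover", n_perms=10000, seed=7).fit(D, cells)
print(est.results_[["df", "pseudo_F", "p_perm", "p_MC", "CV_pct"]].round(3))
```

```
                             df  pseudo_F  p_perm   p_MC  CV_pct
term
veg_cover                     1    44.412   0.000    NaN  45.499
city                          2    70.394   0.000    NaN   9.078
habitat                       1     8.980   0.250  0.047   6.323
veg_cover x city              2     5.770   0.000    NaN  15.089
veg_cover x habitat           1     1.226   0.281    NaN   1.358
city x habitat                2     3.502   0.000    NaN   1.727
veg_cover x city x habitat    2     0.942   0.553    NaN   0.000
Residual                    468       NaN     NaN    NaN  20.927
```

Habitat is tested over the city × habitat interaction; with three cities
and two habitats only a handful of distinguishable relabellings exist, so
its permutation p-value is coarse (0.25 = 2/8) and the Monte-Carlo
p-value (0.047) is the one to read — exactly the situation the
Monte-Carlo fallback exists for. Vegetation cover, entered first, absorbs
the large share of variation that covaries with urbanization.

The whole pipeline (null model, five PERMANCOVA responses, SIMPER tables,
centroid PCoA, manifest, figures) runs from the shell:

```bash
urbfilter run --synthetic --seed 7 --out results/
```

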
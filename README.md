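# divrao

Spatial partitioning of taxonomic and functional diversity for communities
sampled along environmental gradients, in the Rao / Simpson equivalent-numbers
framework — with multi-site turnover/nestedness decomposition of β diversity,
constrained co-occurrence null models, and a synthetic metacommunity generator
for end-to-end testing.

## The scientific problem

Gradient surveys (the motivating case: dung beetles trapped along a tropical
mountainside, three transects per 100-m altitude belt) ask where regional
diversity resides: within transects (α1), among transects of a belt (β1), or
among belts (β2)?  And does *functional* diversity — weighting species by
their trait differences — partition the same way as *taxonomic* diversity?
When taxonomic β2 is large but functional β2 is negligible, different belts
host different species doing the same ecological jobs: environmental
filtering on the Grinnellian niche with ecological redundancy on the
Eltonian one.

## The model

For a community with relative abundances `p` and species dissimilarities
`d_ij ∈ [0, 1]`, Rao quadratic entropy is

    Q = Σ_ij d_ij p_i p_j ,

the expected dissimilarity between two random individuals.  With `d_ij = 1`
for every pair, Q is the Simpson index `1 − Σ p_i²`, so one machinery covers
both facets; `d_ij` comes from a Gower combination of guild (categorical)
and mean biomass (quantitative, range-normalised over the species pool).
Entropies are converted to equivalent numbers by Jost's correction
`D = 1/(1 − Q)` — "how many equally abundant, maximally distinct species
would give this entropy" — which makes the additive partition

    α1 (within transects) → α2 (within belts) → γ (region),
    β1 = α2 − α1,  β2 = γ − α2

independent of α, and each component is reported as a share of γ.
Complementarily, incidence-based multi-site Sørensen β is decomposed into
its turnover (Simpson-type replacement) and nestedness-resultant parts, and
observed components are tested against two constrained randomizations: a
fixed-fixed binary null (checkerboard swaps preserving row and column sums
of the presence/absence matrix) and an abundance null that additionally
conserves each transect's individual count.

## Worked example

```python
import divrao as dv

matrix, traits, hierarchy, truth = dv.generate(seed=1)   # synthetic survey
model = dv.DiversityModel(matrix, hierarchy, traits=traits)
res = model.fit(n_null=199, seed=1, null_stats=("alpha2", "beta2"),
                null_models=("binary",))
print(res.summary())
```

```
Diversity partition (Jost-corrected Rao/Simpson, equivalent numbers)
========================================================================
sites: 21   species: 56   individuals: 3709   groups: 7

[TD]  alpha1=3.513  beta1=0.228  alpha2=3.741  beta2=10.177  gamma=13.918
      proportions of gamma: alpha1 25.2%  beta1 1.6%  beta2 73.1%
[FD]  alpha1=1.029  beta1=0.001  alpha2=1.030  beta2=0.005  gamma=1.035
      proportions of gamma: alpha1 99.4%  beta1 0.1%  beta2 0.5%

beta2-TD (multi-site Sorensen): total=0.798  turnover=0.740 (92.7%)  nestedness=0.058 (7.3%)
beta2-FD (multi-site Sorensen): total=0.500  turnover=0.346 (69.2%)  nestedness=0.154 (30.8%)

null models (199 permutations, seed 1):
  binary:TD:alpha2         obs=9.151  null=15.961±0.581  Z=-11.73  p=0.0050
  binary:TD:beta2          obs=19.404  null=12.594±0.581  Z=+11.73  p=0.0050
  binary:FD:alpha2         obs=1.088  null=1.088±0.005  Z=+0.12  p=0.8950
  binary:FD:beta2          obs=0.005  null=0.006±0.005  Z=-0.12  p=0.8950
```

Reading it: the region holds ~13.9 equivalent species of taxonomic diversity,
73% of which lives *among* altitude belts (β2), and that among-belt share is
far above its fixed-fixed null expectation (Z ≈ +11.7) while within-belt
diversity is below it — environmental filtering.  Functional γ is barely
above its floor of 1 and is >99% α1: the belts are functionally redundant.
Taxonomic β2 is overwhelmingly turnover (92.7%), i.e. replacement rather
than nested impoverishment.

The same analysis runs from the shell on delimited-text inputs
(site-by-species counts, a species×{guild, biomass} table, a transect→belt
map):

```bash
divrao simulate --seed 1 --out data/
divrao partition --matrix data/matrix.csv --hierarchy data/hierarchy.csv \
                 --traits data/traits.csv
divrao run --config config.yaml     # full pipeline incl. null models
```

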
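# traitgroups

Consensus clustering of species trait data under measurement uncertainty,
and functional-group diversity metrics built on the result.

## The problem

Classifying species into *functional groups* — sets of species with similar
trait values — turns hard-to-interpret continuous functional-diversity
metrics into simple, species-like categories that standard biodiversity
metrics apply to directly. Two things make the classification fragile:
trait tables assembled at scale are dominated by *imputed* values whose
prediction error is rarely propagated, and traits are strongly correlated,
so clustering results shift with trait selection. `traitgroups` addresses
both with a resampling consensus framework aimed at ecologists building
trait-based classifications (the motivating application is a global tree
flora of ~48,000 species with 18 log-scale traits), but the machinery is
generic for any complete species × trait matrix with an empirical error
model.

## The method

Given a trait matrix **X** (N species × M traits, natural-log scale) and
per-trait pools of empirical prediction errors ε nested within coarse taxa:

1. **Resample.** Draw S perturbed realizations W⁽ˢ⁾ = X + ε, each cell's
   error sampled uniformly with replacement from its (taxon, trait) pool;
   traits with no observed errors use the taxon's pooled union. Errors are
   independent across cells.
2. **Mixture fit.** Fit full-covariance Gaussian mixtures to each resample
   by EM (full covariances absorb trait correlation) and select the
   component count G⁽ˢ⁾ that minimizes
   BIC = −2·ℓ + p·ln N, with p = (G−1) + GM + GM(M+1)/2.
   Species are assigned by the posterior responsibilities τ (argmax, or A
   categorical draws).
3. **Consensus.** Accumulate the co-assignment matrix C, where C(i,i′) is
   the fraction of ensemble label vectors placing i and i′ in the same
   group (C(i,i) = 1). Each entry is a mean of S (or S·A) Bernoulli
   indicators, so its standard error is at most √(0.25/S) — ≈ 0.07 at the
   default S = 50.
4. **Hierarchy.** Apply Ward linkage to D = 1 − C and cut the dendrogram at
   the K\* maximizing the total silhouette score
   s(i) = (b − a)/max(a, b) computed from D.

Downstream: per-species stability (share of consensus mass inside the final
group), group-level consensus summaries, a single-run-vs-consensus ARI
comparison, and community metrics — functional group richness (number of
groups present) and functional redundancy (Simpson's Σp² over group
proportions).

## Worked example

```python
from traitgroups import ConsensusClustering, adjusted_rand_index
from traitgroups.synthetic import SyntheticSpec, generate_mixture

spec = SyntheticSpec(n_species=400, n_traits=6, n_groups=4, separation=8.0,
                     covariance="correlated", rho=0.4, error_mae=0.15, seed=1)
table, truth, error_model = generate_mixture(spec)

model = ConsensusClustering(table, error_model, n_resamples=20,
                            g_range=(1, 8), k_range=(2, 10))
results = model.fit(seed=1)
print(results.summary())
print("ARI vs ground truth:", round(adjusted_rand_index(results.labels, truth), 3))
```

```
Consensus Clustering Results
============================================================
Species (N)                 400
Traits (M)                  6
Resamples (S)               20
Assignment mode             argmax
Label vectors accumulated   20
Consensus SE bound          0.1118
Scaling                     robust
Linkage                     ward
------------------------------------------------------------
Selected G* per resample    min 4  median 4  max 4
Selected K*                 4
Mean silhouette at K*       1.000
Within-group consensus      1.000 (sd 0.000)
Mean species stability      1.000
Group sizes                 min 95  mean 100.0  max 107
Wall time (s)               3.6
============================================================
ARI vs ground truth: 1.0
```

Every resample's BIC scan picked G\* = 4, the silhouette-optimal cut found
K\* = 4, and the final labels match the planted groups exactly (ARI = 1).
With well-separated groups and modest error pools the consensus matrix is
essentially block-structured — within-group consensus 1.0 means every
resample agreed on every pair; real datasets sit far below that, and the
mean silhouette and within-group consensus quantify how much trait error
erodes group cohesion. The SE bound 0.1118 = √(0.25/20) is the worst-case
Monte-Carlo uncertainty of a consensus entry at S = 20.

`ConsensusClusteringResults` also exposes `species_stability()`,
`group_summary()`, `bic_curves()`, `silhouette_curve()`, `save_consensus()`
(HDF5, upper triangle), `save_labels()` and `to_newick()`.

The same pipeline runs from the shell:

```bash
traitgroups simulate --n-species 400 --n-groups 4 --seed 1 --out sim
traitgroups cluster --traits sim_traits.csv --errors sim_errors.csv \
    --n-resamples 20 --g-min 1 --g-max 8 --k-min 2 --k-max 10 \
    --seed 1 --out run/
traitgroups diversity --community sites.csv --groups run/labels.csv \
    --min-groups 4 --out metrics.csv
```

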
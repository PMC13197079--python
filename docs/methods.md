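# Methods

## Model and procedure

`traitgroups` classifies species into functional groups from a complete
N × M trait matrix **X** (natural-log scale) while propagating the
uncertainty of imputed trait values. The pipeline is a consensus-clustering
scheme:

1. **Error model.** For each trait j and coarse taxon t (angiosperm /
   gymnosperm in the motivating application), the pool ℰ(t, j) collects the
   empirical prediction errors `predicted − observed` over species of taxon
   t with trait j observed. Traits with no observed values in a taxon
   resolve to the union of the taxon's available pools. Pools are sampled
   uniformly with replacement, independently per cell: the error model
   deliberately assumes uncorrelated errors, because sparse observed data
   rarely support a robust cross-trait error covariance. A resample is
   W⁽ˢ⁾ = X + ε.
2. **Per-resample mixture.** Each W⁽ˢ⁾ (optionally robust-scaled) is fitted
   with full-covariance Gaussian mixtures over a range of component counts
   G; BIC = −2ℓ + p·ln N with p = (G−1) + G·M + G·M(M+1)/2 selects G⁽ˢ⁾.
   Full covariances are the point: groups may differ in trait correlation
   structure, which distance-based methods flatten.
3. **Assignment.** Either argmax of the responsibilities τ (one label
   vector per resample) or A independent categorical draws from each row of
   τ (S·A vectors in total).
4. **Consensus.** C(i,i′) = fraction of label vectors in which i and i′
   co-occur; C(i,i) = 1. Accumulation is streaming (one co-occurrence
   matrix at a time), so memory is O(N²) independent of S.
5. **Hierarchy.** Ward linkage on D = 1 − C; the cut K\* maximizes the
   total silhouette Σᵢ (bᵢ − aᵢ)/max(aᵢ, bᵢ) computed from D. The final
   partition is hierarchical: users can cut above or below K\* within the
   same tree.

### Assumptions

- The trait matrix is complete; this package models imputation *error*,
  never performs imputation.
- Traits are continuous and roughly Gaussian within groups after the log
  transform (mixture components are multivariate normal).
- Errors are exchangeable within a (taxon, trait) pool and independent
  across cells.
- Functional groups are compact and roughly convex in trait space — the
  reason for Ward's minimum-variance criterion. Average/single/complete
  linkage are exposed for applications expecting chained or elongated
  clusters.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_resamples` (S) | 50 | ensemble size; bounds each consensus entry's Monte-Carlo SE by √(0.25/S) ≈ 0.07 at 50. Take as many as compute allows. |
| `assignment`, `n_assignments` (A) | `argmax`, 10 | deterministic vs sampled assignment; sampling mode accumulates S·A vectors and the consensus denominator becomes S·A |
| `g_range` | (10, 60) | BIC search range per resample; should bracket the expected number of groups |
| `k_range` | (2, 120) | dendrogram cut range for silhouette selection |
| `scale` | `robust` | per-trait median/IQR scaling of each resample (IQR = 75th − 25th percentile, linear-interpolation convention); `none` keeps raw log values |
| `scale_refit` | `per_resample` | re-estimate scaling on every resample (each resample is treated as a full realization of the dataset) or freeze from X (`from_x`) |
| `linkage` | `ward` | agglomerative criterion on D |
| `em_tol`, `em_restarts`, `reg_covar`, `em_max_iter` | 1e-3, 3, 1e-6, 200 | EM convergence tolerance on relative log-likelihood, k-means-initialized restarts, diagonal jitter, iteration cap |

Seed plumbing: `fit(seed)` gives resample s the stream `seed + s`, recorded
on each draw. Accumulation is order-independent, so a parallel execution of
the ensemble with the same per-resample seeds would produce the identical
consensus matrix.

## Numerical choices

- **BIC ties** (relative difference ≤ 1e-6) resolve toward smaller G;
  silhouette ties toward smaller K. Both are parsimony conventions.
- **Argmax ties** in τ go to the lowest component index.
- **Silhouette of singleton clusters** is 0 (a is undefined); an all-equal
  distance matrix scores 0 everywhere.
- **Dendrogram cutting** replays the first N − K merges with a union-find
  rather than thresholding heights: D is not Euclidean, Ward heights can
  invert, and the merge-order cut always yields exactly K nested, nonempty
  groups (it coincides with the height cut when heights are monotone).
- **BIC identity.** The stored BIC is recomputed from the total
  log-likelihood and the package's own parameter count, so
  `bic == -2*ll + p*ln(N)` holds exactly.
- **Consensus storage** accumulates in float64 and stores float32 (entries
  are means of at most S·A indicators; resolution 1/(S·A)); only the strict
  upper triangle is written, with a checksum verified on load.
- **Degenerate inputs** are hard errors at the boundary: missing trait
  values, duplicate species ids, zero-IQR traits, taxa with no error
  information, single-group silhouettes, K or G ranges incompatible with N.
- **D is a dissimilarity, not a metric** — the triangle inequality is not
  guaranteed. Ward is applied to it regardless, as is standard for
  consensus matrices; this is a modelling choice, not an oversight.
- **Newick export** writes branch lengths as differences of merge heights
  (leaves at height 0); consensus distance is not calibrated time.

## Synthetic data

The generator draws species from a Gaussian mixture with controlled
geometry: centroids are random but rescaled so the *minimum* pairwise
centroid distance equals `separation` × the mean within-component standard
deviation; covariances are spherical, random SPD, or constant-correlation.
Error pools are centered draws rescaled to an exact target mean absolute
error, mirroring how empirical pools are summarized by their MAE rather
than any distributional claim.

`generate_case_study_miniature` emulates the structure of a global
tree-trait dataset at desk scale: N ≈ 1,500 species (comparable to the
1,365-species subsample used for stability analysis), M = 18 traits with
strong factor-structured correlation, a 97%/3% two-taxon split with the
rare taxon concentrated in one component, per-trait pool MAEs spanning
0.099–0.863, and five traits without their own pools so the union fallback
is exercised.

What the synthetic data do **not** emulate: the real data's spiky marginal
distributions from repeated imputed values, error distributions that are
genuinely non-Gaussian, cross-trait error correlation, and the much lower
signal-to-noise of real trait space (the case study's mean silhouette of
~0.2 and within-group consensus of ~0.4 reflect noise levels far above the
miniature's). Passing tests therefore demonstrate correctness of the
machinery and recoverability under stated conditions — not that any real
flora contains a particular number of groups.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which the statistical claims are stable
across seeds: recovery experiments use N = 400, M = 6, 4 groups at
separation 8 with MAE-0.15 pools, S = 20, G ∈ [1, 8], K ∈ [2, 10] (20
replicates in the test suite, 10 in the acceptance script); BIC consistency
uses N = 600/400 with 20 replicates; the stability comparison runs 40
single fits in 4 consensus blocks of 10 on the miniature (G ∈ [2, 9],
single EM restart); oracle-equivalence checks use hundreds of ≤ 20-point
instances. The full-scale configuration (S = 50, G 10–60, K 2–120) remains
the package default.

## Known limitations

- Fitting one mixture to the unperturbed matrix without resampling
  overfits when many rows are identical (repeated imputations can drive
  BIC-selected G into the hundreds); the resampling step is the remedy, and
  the package intentionally offers no "no-resample" shortcut.
- A single coarse taxon level is supported for error nesting; finer
  taxonomies would need pools keyed accordingly.
- Sign conventions for empirical errors differ across data sources;
  `flip_sign` covers both, and with near-symmetric pools the effect is
  negligible.
- The silhouette curve is often flat near its optimum; K\* should be read
  as "a good cut", not a sharp estimate, and the hierarchical output is
  designed for re-cutting. A plateau warning is logged when nearby cuts
  score within 2%.
- No categorical traits, no abundance-weighted community metrics, no
  Rao's Q / convex-hull metrics (the consensus dendrogram's Newick export
  enables tree-based metrics in external tools).
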
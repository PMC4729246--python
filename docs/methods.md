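# Methods

`clonescape` implements the analysis chain used in landscape-genetic studies
of clonal polyploid plants scored with microsatellites: dominant (binary)
coding of dosage-ambiguous genotypes, clone (genet) assignment, diversity
statistics, AMOVA-based ΦPT differentiation, geographic / environmental /
barrier distance matrices, and causal inference with Mantel tests and
multiple matrix regression with randomization (MMRR). This note records the
models, the defaults and why, and the choices made where the design was
genuinely open.

## Dominant coding and clone assignment

In a hexaploid, a microsatellite electropherogram shows which allele sizes
are present but not their copy numbers, so codominant statistics are
unavailable. Each (locus, allele) pair observed anywhere in the dataset
becomes a presence/absence column. An individual missing a locus gets a
*mask* (NaN) over that locus's columns rather than zeros: absence of data is
not absence of the allele. Pairwise analyses use the columns complete for
the pair.

Genets are called by exact multilocus identity, including the missing-data
pattern; an individual with any missing locus never merges with a complete
one. This is deliberately conservative — a scoring-error-tolerant threshold
would merge more, and users who want that can pre-cluster before input. The
first member (input order) of a genet is its representative, which makes
runs deterministic.

## Diversity statistics

With dominant data a true allele frequency is unavailable; we estimate
per-locus frequencies from presence counts (number of individuals carrying
each allele, normalized to sum to 1 at the locus, individuals missing the
locus excluded from the denominator). Per-locus effective allele number is
1/Σp²; NA (allele count) and ENA (effective number) are summed over loci.
Genotype diversity is Nei's sample-size-corrected index
D = (n/(n−1))(1 − Σ f_g²) over multilocus-genotype frequencies f_g, defined
as 0 for n = 1. The presence-count estimator is the simplest one consistent
with dominant treatment; it is documented so users can substitute another.

## ΦPT (AMOVA for binary profiles)

For a population pair, squared Euclidean distances d² between binary rows
are decomposed as SS_total = (1/N)Σ_{i<j} d²_ij and
SS_within = Σ_k (1/n_k)Σ_{i<j∈k} d²_ij — the pairwise form, algebraically
identical to the classical squared-deviation-about-centroid decomposition
(the test suite checks this against an independent centroid-based
implementation to 1e-10). With K = 2 groups: df_among = 1, df_within = N−2,
n0 = (N − Σn_k²/N)/(K−1), σ²_within = MS_within,
σ²_among = (MS_among − MS_within)/n0 clamped at 0 (the raw component is
still reported), and ΦPT = σ²_among/(σ²_among + σ²_within), defined 0 when
both components vanish. Because it is a ratio of variance components, ΦPT
is invariant to duplicating columns.

P-values shuffle individuals between the two populations and use the
add-one estimator (1 + #{Φ_perm ≥ Φ_obs})/(n_perm + 1), which never reports
zero. Default pipeline filters: populations need ≥ 6 genets to enter the
differentiation analysis; the subsampling robustness check (replicated ΦPT
matrices from 6 randomly drawn genets per population, correlated across
replicates) is restricted to populations with > 10 genets. The two
thresholds differ on purpose — inclusion is more permissive than the
stability check — and both are configurable.

## Geographic, environmental and barrier matrices

Geographic distance is the great-circle (haversine) distance on a sphere of
radius 6371 km; at the scale of matrix correlation the sphere/ellipsoid
difference is negligible, and ellipsoidal geodesics are out of scope.

Environmental distance is Euclidean in the space of the first two principal
components of the per-site climate table. Variables are centered and, by
default, scaled to unit variance (correlation PCA) because climate
variables come in incommensurable units; a flag gives covariance PCA since
published workflows vary. Component signs are fixed by making each
component's largest-magnitude loading positive, so output is deterministic.
Constant variables are rejected by name.

The barrier matrix is categorical: 0 for population pairs on the same side
of the putative barrier, 1 across it. It is invariant to complementing the
side labels.

## Clustering (DAPC-style)

Group discovery is k-means on PCA scores of the (mean-imputed, centered)
binary matrix, scanning k = 1..20 with
BIC(k) = n·ln(WSS_k/n) + k·ln(n). Mean imputation of missing entries is the
standard dominant-marker practice: it leaves column centroids unchanged and
adds no between-group signal. Ties in the BIC argmin go to the smaller k. On
low-dimensional data this BIC form declines almost monotonically in k
(splitting a cluster removes a large share of the within sum of squares);
it behaves as intended in the many-weak-axes regime typical of dominant
marker matrices. Because real scans sometimes decline monotonically anyway,
a user-forced k is accepted and recorded. Discriminant axes solve
Sb·v = λ·Sw·v on the retained scores; membership probabilities are a
softmax over −½ × squared Mahalanobis distances to group centroids in
discriminant space, with the pooled within-group covariance. The number of
retained PCs is a required choice; a helper returns the smallest count
reaching a variance threshold (default 90%).

## Mantel tests, causal modeling, MMRR

All matrix tests operate on the strictly-lower-triangle unfolding. The
permutation null always permutes rows and columns of a *matrix* jointly —
never the unfolded vector — preserving the dependence among entries that
share a population. Simple Mantel tests are one-tailed (greater) by
default, matching directional isolation hypotheses. Partial Mantel
residualizes both focal vectors on the unfolded covariates (least squares
with intercept) and permutes the focal matrix, re-residualizing each time
(the residual-permutation variant; several exist in the literature, so this
is stated explicitly). A focal matrix fully explained by the covariates has
zero residual variance; its partial correlation is defined as 0.

The causal-modeling battery runs 12 tests: 3 simple, 6 partial with a
single controlling factor, 3 partial controlling both others. A factor is
**supported** when its simple test and all its partial tests are
significant at α; **spurious** when the simple test is significant but no
partial is; **mixed** otherwise; **not_supported** when even the simple
test fails. No multiple-testing correction is applied across the battery —
raw p-values are printed with flags at α — and the verdict rule is
configurable. Both single- and double-covariate partials are always
reported rather than silently choosing one.

MMRR regresses the unfolded response matrix on several unfolded predictors,
z-scoring every predictor. By default the response is z-scored too, which
makes the coefficients standardized effect sizes on the Mantel-r scale (and
makes single-predictor β exactly the simple Mantel r); `scale_y=False`
keeps coefficients in the response's own units, the natural scale for
parameter-recovery checks against a generating linear model. Significance
permutes the response matrix and refits: per-coefficient tests are
two-sided on t (the method's convention), the overall test one-sided on F.
Collinear predictors are rejected by name (condition-number threshold
1e8). All permutation p-values use the add-one estimator; the default
permutation count is 10,000.

## Synthetic data generator

The generator produces matrix-level ground truth, not genealogies: a
latent-Gaussian allele-frequency surface, sampled into hexaploid presence
sets. An explicit coalescent backend is a documented extension point, but
the claims this package tests are about distance-matrix structure, which
the latent-Gaussian model produces directly at trivial cost.

* **Landscape.** Sites uniform on a bounded lon/lat region (a continental
  window), split by a fixed diagonal line that defines barrier sides
  (resampling guarantees both sides occupied). Two latent environmental
  drivers — temperature-like (tracking latitude) and precipitation-like
  (tracking longitude) — mix a position signal with weight ρ
  (`env_geo_correlation`) and independent noise with weight 1−ρ, then fan
  out into 19 correlated climate-style variables, so the PCA reduction is
  non-trivial. ρ = 0 decouples environment from geography (mean |r| < 0.15
  between the distance matrices); ρ → 1 couples them (r > 0.8).
* **Frequencies.** For each locus and allele, a latent value per population
  is drawn from a multivariate normal with covariance
  K_kl = exp(−(w_g·d_geo/s_g + w_e·d_env/s_e + w_b·[sides differ])), where
  s_g, s_e are median pairwise distances (auto-scaling makes strengths
  comparable across landscape sizes). Frequencies are a softmax over
  latent values within a locus, with latent spread 1.5 (fixed): large
  enough to create realistic differentiation (mean pairwise ΦPT ≈ 0.4 in
  the mixed scenario, comparable to strongly structured clonal plants),
  small enough not to fix alleles everywhere. With all strengths 0 the
  covariance is all-ones (shared frequencies): populations are
  exchangeable and mean ΦPT stays below 0.01. Rank-deficient K is repaired
  by diagonal jitter with a warning.
* **Individuals.** Each individual draws `ploidy` (default 6) alleles with
  replacement and keeps the presence set — the dosage ambiguity that forces
  dominant coding. With probability `clone_rate` an individual copies a
  previous member of its population (a ramet).
* **Defaults.** 40 populations × 12 individuals, 12 loci × 8 alleles,
  clone rate 0.1 — the scale of a country-wide survey of a clonal aquatic
  plant, sized so the full battery runs in minutes on one CPU.

What the generator does *not* emulate: mutation models, selection at loci,
temporal migration dynamics, genotyping error, and the spatially uneven
sampling of real surveys. Passing tests therefore demonstrate that the
inference chain recovers matrix-level structure it was built for, not that
it is robust to every artifact of real microsatellite data.

One calibration fact worth knowing: the Mantel correlation between ΦPT and
the generating distance rises very steeply in the strength (already ≈ 0.5
at w = 0.05 for a 20-population landscape) and *saturates* — at large
strengths the exponential covariance is near zero for most pairs, ΦPT
flattens toward its ceiling, and the correlation declines even though
differentiation keeps growing. Verdict support rates remain high throughout
(the battery's w = 3 conditions are called correctly in ≳ 95% of
replicates); only the raw r value is non-monotone.

## Numerical and reproducibility choices

* Permutations are sampled in vectorized chunks; all streams derive from
  NumPy `default_rng` seeds.
* The pipeline fans one master seed out per stage as
  SHA-256("{seed}:{stage}") mod 2³¹, so any stage can be reproduced in
  isolation; the manifest records every derived seed, timings, excluded
  populations and a config hash.
* Tie handling in permutation counts uses a 1e-12 tolerance so that exact
  ties (e.g., the identity permutation) are counted as exceedances.
* Exact-fit regressions (zero residual variance) report infinite t and F
  rather than erroring; degenerate ΦPT (both variance components zero) is
  defined as 0.
* Test-suite and battery problem sizes (e.g., 20–40 populations, 499–999
  permutations for calibration loops) are chosen so the whole suite runs in
  a few minutes on one CPU while keeping Monte-Carlo slack well below the
  asserted margins.

## Known limitations

* Clone calling is exact-match only; no genotyping-error tolerance.
* AMOVA is implemented for population pairs (as used for pairwise ΦPT), not
  arbitrary hierarchical designs.
* Geographic distances are spherical; no resistance surfaces or
  least-cost paths.
* The permutation engine holds one chunk of permuted unfoldings in memory
  (~2048 × n(n−1)/2 doubles), which is comfortable for hundreds of
  populations but not thousands.
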
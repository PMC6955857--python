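# Methods

`elevmicro` analyses skin-microbiome OTU tables sampled along an elevation
gradient: alpha/beta diversity trends, elevation-tolerant/sensitive taxon
screening, permutation statistics, Spearman co-occurrence network topology
with keystone detection, and null-model partitioning of community assembly
into deterministic and stochastic ecological processes. A synthetic-data
generator plants every signal the downstream stages are supposed to detect,
so the whole pipeline is testable against known ground truth.

## Study design emulated by the generator

The default `GradientDesign` mirrors a 105-sample skin-swab survey: seven
sites at 501, 2298, 2690, 3110, 3150, 3271 and 3431 m, five subjects per
site, three body sites per subject (forehead, opisthenar, palm). Sequencing
depth is lognormal with mean 18,525 reads and CV 765/18,525 (the study's
reported mean and SD), floored at the rarefaction depth of 15,596 so no
simulated sample is lost at rarefaction. Measured UV covariates span
53–3785 µW/cm², increasing with site elevation.

## Generative model

Expected log-abundance of taxon *i* in sample *j*:

```
λ_ij = b·base_i + slope_i · elev_km_j + site_sj,i + subject_uj,i + regime_ij
```

* `base_i ~ N(0, 1.5)` — regional lognormal rank-abundance structure
  (`b = 1` except under selection regimes, below).
* `slope_i` — planted elevation response, per km. Taxa are ranked by a
  latent score `u = (1−s)·e + s·BM` (`s` = `phylo_signal`, `e` i.i.d.
  normal, `BM` standardized Brownian tip values); the top
  `round(frac_tolerant·n)` (half-up) become tolerant with slope
  `+slope_scale·(1 + 0.25·(u−threshold))`, the bottom `frac_sensitive`
  mirror it negatively, the rest are neutral. Slope magnitudes are kept
  within 25% of `slope_scale`: a wide within-class spread makes
  strongly-sloped taxa squeeze weakly-sloped classmates out of the
  compositional denominator, and then no relative-abundance screen can
  recover the planted labels.
* `site effect ~ N(0, 0.15)` per site × taxon; `subject effect ~ N(0, σ_u)`
  per subject × taxon, shared across the subject's body sites, with
  `σ_u = subject_sd·(1 + beta_inflation·(elev_km − elev_km_min))`. The
  subject intercept is what makes "individual" the dominant PERMANOVA
  factor; its elevation-proportional variance is what makes within-site
  dissimilarity rise with elevation. Default `subject_sd = 0.55` and
  `overdispersion = 0` were calibrated once so that within-site Bray–Curtis
  on the default design falls in ≈0.4–0.7.
* Occupancy thinning: each taxon is dropped from a sample with probability
  `min(alpha_decay·(elev_km − elev_km_min), 0.95)` — `alpha_decay` is the
  expected fraction of taxa lost per km above the lowest site.
* Counts: optional Dirichlet perturbation (concentration
  `1/overdispersion`), then a multinomial draw at the sample's depth.

Elevation enters in km so slopes are O(1).

### Niche traits and assembly regimes

Each taxon carries a conserved niche trait: a Brownian motion on the tree
frozen at half the tree height, so every clade younger than that depth
shares one exact trait value. This models phylogenetic niche conservatism —
the property that makes an environmental filter produce phylogenetically
clustered communities, which is precisely what βNTI detects. (An unfrozen
Brownian trait does not work: a trait window then unions scattered single
taxa from many clades and the nearest-taxon signal washes out.)

`AssemblyRegime` controls the between-sample covariance:

* **homogeneous_selection** — one Gaussian filter (width 0.05 in
  standardized trait units) centered on the largest conserved-niche clade,
  shared by all samples.
* **variable_selection** — the largest clades are assigned as optima to
  sites in trait order along the elevation order: the environment drifts
  with elevation and selects progressively different clades.
* **dispersal_limitation** — a per-site migrant-pool log-effect
  (σ = 2.5) following an AR(1) walk along the elevation order with
  correlation `exp(−Δelev_km/0.5)`; sites diverge strongly but
  phylogenetically at random.
* **homogenizing_dispersal** — subject/site heterogeneity shrunk by the
  migration rate (0.9) and one shared occupancy realization for the whole
  group: mass migration synchronizes which taxa arrive.
* **drift** — a neutral demographic lottery: the sample's community is a
  multinomial resample of `drift_size` individuals from its expected pool,
  then sequenced. Small `drift_size` means strong drift. The lottery also
  runs under both selection regimes (selection decides the clade, drift
  decides which members win locally); under selection the regional `base`
  term is attenuated by `selection_dominance = 0.7` so local fitness, not
  regional prevalence, sets the within-clade ranking.

Strength defaults (`filter_width 0.05`, `drift_size 50`, `microenv_sd 1.0`,
`selection_dominance 0.7`) were chosen by scanning the generator's own
regime expression (median βNTI of single-regime groups across seeds) at the
10-sample × 150-taxon scale used for assembly studies; the study-scale
default is `drift` with `drift_size = 2000`, where the lottery perturbs
rather than dominates the gradient structure. These are generator
conditions, fixed once; they are not fitted to any downstream test.

### What the generator does not emulate

Real amplicon artifacts — chimeras, PCR and extraction bias, taxonomy
errors, spurious OTUs — are out of scope, as are realistic taxonomy strings
and non-ultrametric trees. Passing tests therefore show that the analysis
recovers planted structure under the stated statistical model, not that the
model captures every property of real skin-swab data.

## Analysis methods

* **Rarefaction** — one multivariate-hypergeometric draw per sample
  (sampling without replacement) to a fixed depth; shallow samples are
  dropped, not padded. The main pipeline uses a single draw;
  `rarefaction_curve` averages over explicit replicates.
* **Alpha/beta diversity** — observed OTUs; Shannon entropy (log base 2 by
  default, configurable since published pipelines differ); Bray–Curtis on
  counts and Jaccard on presence/absence.
* **Taxon screening** — Spearman correlation of relative abundance against
  elevation per taxon above a mean-relative-abundance floor (defaults:
  0.09% for genus-level core screening; 1% is the customary phylum-level
  floor), BH-FDR over tested taxa, three-way classification at q ≤ 0.05.
  Spearman p-values use the t approximation for n > 10 and exhaustive rank
  permutation for n ≤ 10. Average ranks break ties throughout.
* **PERMANOVA** — Gower-centered distance matrix, sequential (type-I)
  sums of squares in the user's term order, pseudo-F per term, p-values by
  jointly permuting the matrix rows/columns. Term order changes each
  term's R²; the default order puts elevation first and subject last
  because subjects are nested in sites (subject-first aliases elevation and
  all per-subject host covariates, which the implementation rejects as
  zero-df terms). Verified against `vegan::adonis2(by = "terms")`.
* **ANOSIM** — rank-based R with joint ranking and average ties.
* **Partial Mantel** — Pearson correlation of upper-triangle entries after
  residualizing both matrices on the control (host Gower distance:
  equal-weight mix of categorical mismatch and range-normalized numeric
  differences); one-sided permutation test permuting the community matrix.
* **Wilcoxon rank-sum** — exact enumeration when there are no ties and
  C(n, n1) ≤ 2·10^5, else normal approximation with tie correction.
* All permutation p-values use the protected estimator
  `(1 + #{null ≥ obs})/(1 + permutations)` and are seed-deterministic.

### Co-occurrence networks

Taxa below 0.01% mean relative abundance are removed; all pairwise Spearman
correlations are computed on rank-transformed abundances (invariant to
monotone transforms); BH correction runs over every tested pair before
thresholding (defaults |ρ| ≥ 0.77, q ≤ 0.001; the threshold is a plain
config constant — no random-matrix-theory scan). Edges keep their sign and
the sign census is reported rather than assumed positive. Subnetworks are
induced from the meta-network on taxa present in the group's samples
(rebuilding per group is available via the library by re-running the screen
on a sample subset). Node metrics: degree; unnormalized betweenness (the
keystone cutoff of 5000 only makes sense on raw path counts); closeness
within connected components; eigenvector centrality as the principal
adjacency eigenvector scaled to max 1. Network metrics: clustering
coefficient as mean local clustering over nodes with degree ≥ 2 (global
transitivity reported alongside, since published "clustering coefficient"
values are ambiguous between the two); average degree 2E/N; density
2E/(N(N−1)); modularity by deterministic greedy agglomeration
(Clauset–Newman–Moore) on the unweighted graph. Keystones: degree > 100
and betweenness < 5000, both strict.

### Community assembly

Weighted βMNTD between two samples is the abundance-weighted mean patristic
distance from each taxon to its nearest relative in the other sample
(shared taxa contribute zero). βNTI is the z-score of observed βMNTD
against a null that shuffles taxon labels across the tips present in the
table — one shuffle per replicate shared by all pairs, the `taxa.labels`
convention. Pairs whose null has (numerically) zero standard deviation —
e.g. a star tree — are flagged undefined and excluded from fractions.
RC_bray assembles null community pairs by drawing each sample's observed
richness with probability proportional to occupancy and filling to its
observed total with probability proportional to mean relative abundance,
then maps the observed Bray–Curtis rank to [−1, 1] with ties counted half.
Classification: βNTI > +2 → variable selection; < −2 → homogeneous
selection; otherwise RC > +0.95 → dispersal limitation; RC < −0.95 →
homogenizing dispersal; else undominated. Fractions are computed over
within-group pairs, each group treated as its own metacommunity.
Replicates default to 999; regime-recovery studies and the acceptance
script run 199 replicates at 10 samples × 150 taxa × depth 2000 — sizes
chosen to keep a full desk run in seconds while leaving clear margins on
the regime signatures (measured medians ≈ −2.4 to −3.2 for homogeneous
selection and +4 to +6 for variable selection across seeds).

## Numerical choices

* One integer seed per entry point, split via `numpy.random.SeedSequence`
  spawning (generator) or `SeedSequence([seed, crc32(stage)])` (pipeline
  stages), so disabling one stage never shifts another's draws; every
  derived seed stays below 2^31.
* βNTI null standard deviations below `1e-9 · max(1, |mean|)` are treated
  as zero (summation-order jitter can make a constant null's sd ≈ 1e-16).
* Brownian tip covariance is eigendecomposed with eigenvalues clipped at
  zero, so slightly non-ultrametric trees remain usable.
* Elevation-group rule: high ⇔ elevation ≥ 3000 m (boundary inclusive);
  the default sites straddle 2690/3110 m so the boundary never bites on
  emulated designs, and the cutoff is a config field.
* Missing branch lengths parse as zero with a warning; duplicate tips are
  an error.

## Known limitations

* PERMANOVA R² values are order-dependent (sequential decomposition);
  "individual" enters as an ordinary factor although subjects are
  site-nested, so elevation must precede subject in the term order.
* The Spearman screen is compositional: very strong planted gradients
  distort the relative abundances of neutral taxa, and the classifier's
  false-flag rate is controlled only under the global null.
* Eigenvector centrality concentrates on the dominant component of a
  disconnected graph; closeness is component-local by construction.
* RC_bray follows one specific null recipe (occupancy × abundance); other
  recipes in the literature shift the ±0.95 boundaries.
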
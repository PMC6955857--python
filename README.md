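# elevmicro

Analysis of skin-microbiome communities along an elevation gradient:
diversity trends, elevation-tolerant/sensitive taxon screening, permutation
statistics, Spearman co-occurrence networks with keystone detection, and
null-model partitioning of community assembly into deterministic and
stochastic ecological processes. A synthetic-data generator plants every
signal the pipeline is supposed to detect, so each stage is tested against
known ground truth.

## Who this is for

Microbial ecologists working with OTU count tables (samples × taxa), a
rooted 16S phylogeny (Newick), and per-sample metadata (subject, elevation,
body site, host covariates) who want the downstream statistics of an
elevation-gradient skin study as a reproducible, seed-deterministic
library and CLI rather than a collection of one-off scripts.

## The statistics at the core

* **Diversity.** Rarefaction without replacement to a fixed depth; observed
  OTUs and Shannon entropy H = −Σ pᵢ log₂ pᵢ; Bray–Curtis
  d(x,y) = 1 − 2·Σ min(xᵢ,yᵢ)/(Σx + Σy) and Jaccard d = 1 − |A∩B|/|A∪B|.
* **Gradient inference.** OLS trends of per-sample statistics on elevation;
  Spearman screening of taxa against elevation with Benjamini–Hochberg FDR
  (ρ > 0, q ≤ α → *elevation-tolerant*; ρ < 0, q ≤ α →
  *elevation-sensitive*); PERMANOVA (adonis-style sequential
  decomposition of a Gower-centered distance matrix, pseudo-F, permutation
  p); ANOSIM R = (r̄_between − r̄_within)/(n(n−1)/4); partial Mantel
  correlation controlling host factors; Wilcoxon rank-sum.
* **Networks.** Spearman edge screen (|ρ| ≥ 0.77, BH q ≤ 0.001 by default)
  over taxa above a 0.01% mean-abundance floor; per-group subnetworks;
  degree, unnormalized betweenness, closeness, eigenvector centrality;
  clustering coefficient, average degree 2E/N, density 2E/(N(N−1)),
  greedy modularity; keystone taxa = degree > 100 and betweenness < 5000.
* **Assembly.** Weighted βMNTD between sample pairs; βNTI as its z-score
  against a tip-shuffling null; Bray–Curtis Raup–Crick (RC) against an
  occupancy × abundance null, scaled to [−1, 1]. βNTI > +2 → variable
  selection, βNTI < −2 → homogeneous selection, else RC > +0.95 → dispersal
  limitation, RC < −0.95 → homogenizing dispersal, else undominated.
  Selection is deterministic; the rest are stochastic.

See `docs/methods.md` for the generative model, null-model conventions,
calibrated defaults, and known limitations.

## Worked example

```python
from elevmicro import diversity, gradient_stats, synthetic_data

phylo, truth, table, meta = synthetic_data.simulate_dataset(n_taxa=300, seed=42)
rare = diversity.rarefy(table, depth=15_596, seed=1)
meta = meta.loc[rare.sample_ids]

alpha = diversity.alpha_diversity(rare)
fit = gradient_stats.fit_trend(alpha["observed_otus"], meta["elevation_m"] / 1000)
print(f"richness slope: {fit.slope:+.1f} OTUs/km (r^2={fit.r_squared:.2f}, p={fit.p_value:.1e})")

bray = diversity.bray_curtis_matrix(rare)
wfit = gradient_stats.within_group_dissimilarity_trend(bray, meta)
print(f"within-site Bray-Curtis slope: {wfit.slope * 1000:+.3f}/km (p={wfit.p_value:.1e})")

classes = gradient_stats.classify_elevation_response(rare, meta, mean_abund_floor=0.0009)
n_tol = sum(c.taxon_class == "tolerant" for c in classes)
n_sen = sum(c.taxon_class == "sensitive" for c in classes)
print(f"elevation-tolerant: {n_tol}, elevation-sensitive: {n_sen} of {len(classes)} tested")

res = gradient_stats.permanova(bray, meta,
    ["elevation_m", "gender", "body_site", "subject_id"], permutations=199, seed=2)
for r in res:
    print(f"  {r.term:12s} R2={r.r_squared:.3f} p={r.p_value}")
```

prints

```
richness slope: -44.7 OTUs/km (r^2=0.91, p=5.5e-55)
within-site Bray-Curtis slope: +0.090/km (p=2.3e-37)
elevation-tolerant: 8, elevation-sensitive: 81 of 107 tested
  elevation_m  R2=0.165 p=0.005
  gender       R2=0.020 p=0.005
  body_site    R2=0.008 p=0.36
  subject_id   R2=0.560 p=0.005
  Residual     R2=0.248 p=nan
```

The default generator plants richness loss and rising within-site
dissimilarity with elevation — both trends are recovered with the expected
signs. The individual (subject) is the dominant PERMANOVA factor and
elevation the second, with body site negligible; R² values are sequential,
so term order matters (the subject term, fitted last, absorbs the
host-covariate structure). Under the default thinning most screened taxa
genuinely decline with elevation, hence the sensitive-heavy split.

## Command line

```bash
elevmicro simulate --outdir sim --seed 1          # table.tsv tree.nwk metadata.tsv truth.tsv
elevmicro all --config config.yaml --outdir run   # full pipeline + manifest.json
```

Subcommands `diversity`, `gradient`, `network`, `assembly` run single
stages. Every threshold (rarefaction depth 15,596; abundance floor 0.01%;
ρ ≥ 0.77; q ≤ 0.001; βNTI ±2; RC ±0.95; 3000 m elevation cutoff; keystone
degree/betweenness cutoffs) is a config field with these defaults.

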
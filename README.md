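# intertidal

Statistical analysis of intertidal microeukaryote community surveys:
alpha and beta diversity, ordination and permutation tests, and a two-step
phylogenetic null model that partitions pairwise community turnover into
deterministic and stochastic ecological processes.

## The problem

Amplicon surveys of coastal microeukaryotes (planktonic and benthic, sampled
along tens of kilometres of shoreline) routinely ask two questions: *how do
communities differ* between habitats, size fractions and seasons, and *which
ecological processes assemble them* — environmental selection, dispersal, or
drift? This package implements the full downstream statistical layer of such
a survey, starting from a site-by-OTU count table, a rooted phylogeny over
the OTUs, and per-sample metadata. It is aimed at microbial ecologists who
have finished OTU clustering and want reproducible, seeded, testable
statistics rather than a pile of one-off R snippets.

## The core model

For every pair of communities *(x, y)* the assembly analysis computes:

**β-mean nearest taxon distance** (abundance-weighted):

    βMNTD(x,y) = ½ [ Σᵢ f_i(x) · min_{j∈y} d(i,j)  +  Σⱼ f_j(y) · min_{i∈x} d(j,i) ]

where *d* is the patristic distance and *f* the relative abundance.
Standardizing the observed βMNTD against a null distribution obtained by
shuffling OTU labels across the tips of the phylogeny gives

    βNTI = (βMNTD_obs − mean_null) / sd_null.

**Bray–Curtis Raup–Crick** (RC_bray): each null iteration rebuilds every
sample by drawing its observed richness with probability ∝ regional
occupancy, then filling to its observed read total with probability ∝
regional relative abundance; the observed Bray–Curtis dissimilarity is
located in the null ECDF and rescaled to [−1, 1].

Pairs are classified: βNTI > +2 → heterogeneous selection; βNTI < −2 →
homogeneous selection; otherwise RC_bray > +0.95 → dispersal limitation,
RC_bray < −0.95 → homogenizing dispersal, else ecological drift. Per-group
process fractions summarize the classification.

Around this core the package provides rarefaction, Shannon and Faith's PD,
one-way ANOVA group tests, Spearman alpha–environment screens with Holm
correction, Bray–Curtis on log(x+1) counts, NMDS (Kruskal stress-1), ANOSIM,
Mantel and partial Mantel tests, geographic distance matrices and
distance-decay regressions — all seeded and all with the +1 permutation
p-value correction.

A synthetic-data generator produces OTU tables, phylogenies, coordinates and
environmental metadata under six named assembly regimes with known ground
truth, so every statistic can be validated by parameter recovery.

## Worked example

```python
from intertidal import ScenarioConfig, generate_bundle, CommunityAssemblyModel
from intertidal import community

bundle = generate_bundle(ScenarioConfig(regime="dispersal_limitation", seed=7,
                                        n_sites=12, n_taxa=400, depth=800,
                                        groups="per_site"))
model = CommunityAssemblyModel(bundle.table, bundle.tree,
                               metadata=bundle.metadata)
results = model.fit(n_null=999, seed=0)
print(results.summary())

bc = community.bray_curtis(community.transform_community(bundle.table))
geo = community.geo_distance_matrix(bundle.metadata)
dd = community.distance_decay(bc, geo, n_perm=9999, seed=0)
print(f"distance-decay: Spearman r = {dd.statistic:.3f}, p = {dd.p_value:.4f}")
```

prints

```
Community assembly null-model results
=============================================
samples:            12
OTUs:               261
pairs:              66
null iterations:    999
betaMNTD weighting: abundance
thresholds:         |betaNTI| > 2, |RC_bray| > 0.95
betaNTI:            mean -0.039, sd 0.827
---------------------------------------------
process fractions (all pairs):
  heterogeneous_selection    4.5%
  homogeneous_selection      0.0%
  dispersal_limitation      57.6%
  homogenizing_dispersal     1.5%
  drift                     36.4%
  valid pairs: 66, NA: 0

distance-decay: Spearman r = -0.530, p = 0.0003
```

Communities were simulated under dispersal limitation (site-specific source
pools, short dispersal scale), and the classifier recovers it: βNTI is
centred (no selection signal), 58% of pairs exceed the RC_bray cutoff, and
community similarity decays significantly with shore distance.

The same analysis runs from the shell:

```sh
intertidal generate --regime dispersal_limitation --n-sites 12 --n-taxa 400 \
    --depth 800 --groups per_site --seed 7 --out-dir data/
intertidal run --otu-table data/otu_table.tsv --tree data/tree.nwk \
    --metadata data/metadata.tsv --depth 800 --out-dir results/
```

`intertidal run` writes alpha.tsv, bray_curtis.tsv, nmds.tsv, anosim.tsv,
mantel.tsv, distance_decay.tsv, bnti.tsv, rcbray.tsv, processes.tsv,
process_summary.tsv and a run_summary.json recording versions, config hash
and every seed; re-running the same config reproduces every table
byte-for-byte.

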
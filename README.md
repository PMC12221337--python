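# sedibiome

Statistical inference chain for sediment microbiome biogeography along
estuarine salinity gradients. The package targets the standard analysis
sequence of a 16S + metagenome transect study — from an OTU count table,
a rooted phylogeny, sample geochemistry and GPS coordinates to a complete,
reproducible set of community-ecology statistics — and ships a synthetic
data generator so every step can be exercised and validated end-to-end
without sequencing data.

## What it computes

* **Diversity** — rarefaction to a fixed depth (without replacement),
  observed richness, Shannon (nats), Simpson dominance Σp², Chao1, ACE,
  Good's coverage, and Bray–Curtis dissimilarity
  d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ).
* **Community assembly** — the two-step phylogenetic/taxonomic null-model
  partition. Per sample pair, βMNTD (abundance-weighted mean nearest-taxon
  patristic distance) is compared with a tip-shuffle null
  (999 randomizations); the z-score βNTI classifies pairs with |βNTI| > 2 as
  deterministic selection (heterogeneous if > +2, homogeneous if < −2).
  Pairs inside the envelope are split by the Raup–Crick metric on
  Bray–Curtis, RC = 2·[#(null < obs) + ½·#(null = obs)]/reps − 1, into
  dispersal limitation (RC > 0.95), homogenizing dispersal (RC < −0.95) and
  drift.
* **Co-occurrence networks** — Spearman ρ on relative abundances of the
  top-100 OTUs; edges require ρ > 0.6 **and** p < 0.01; average degree
  2E/V, average path length, diameter, clustering coefficient, and the
  Newman modularity Q of a seeded Louvain partition.
* **Ordination & space** — PCoA, non-metric MDS (Kruskal stress-1),
  UPGMA dendrograms, ANOSIM, Mantel tests, haversine geographic distances,
  PCNM spatial eigenfunctions (MST-edge truncation), CCA and
  Hellinger-RDA with marginal permutation tests, and variation partitioning
  with Ezekiel-adjusted R² into pure-environment, pure-space, shared and
  unexplained fractions.
* **Nitrogen cycling** — RPKM normalisation of KO read counts, aggregation
  into nitrogen-cycle gene families (narG/H, napA/B, nirS/K, norB/C, nosZ,
  nirB/D, nrfA, nifD/H/K, hao, amoA/B/C–pmoA/B/C, hdh, …) and pathway
  modules, and Kruskal–Wallis comparisons between salinity groups.
* **Synthetic studies** — Yule phylogenies, Brownian niche traits, a
  15-site salinity transect (0.12–35.8 ppt, low/mid/high terciles of five
  sites each) and multinomial communities under four assembly regimes
  (selection, dispersal limitation, drift, homogenizing dispersal), plus
  group-structured negative-binomial KO tables.

## Worked example

Run the full chain on a simulated selection-structured transect:

```bash
sedibiome pipeline --config config.yaml --seed 7
```

with `config.yaml`:

```yaml
output_dir: run_out
rarefaction_depth: 3581
simulate: {n_taxa: 200, n_samples: 15, depth: 10000, regime: selection}
null_model: {n_reps: 999}
n_perm: 999
```

The report (also written to `run_out/report.json`) includes, for seed 7:

```
"anosim":  {"r": 0.9289, "p": 0.001}
"vpa_percent": {"pure_env": 8.42, "pure_space": 35.78, "shared": 51.48,
                "total_explained": 95.68}
"assembly_total_percent": {"deterministic": 79.0, ...}
"network": {"n_nodes": 100, "avg_degree": 37.0, "apl": 2.15,
            "diameter": 6, "modularity": 0.39, ...}
```

Read: the salinity groups separate almost perfectly (ANOSIM R near 1 —
expected, the regime is pure selection along the gradient); environment and
space jointly explain ~96 % of community variation with a large shared
fraction (salinity and position are confounded on a transect); four fifths
of sample pairs are classified as deterministic selection; the dominant-OTU
network is dense and weakly modular. Each stage also writes its own TSV
(alpha diversity, Bray–Curtis matrix, ordination scores, PCNM vectors,
per-pair βNTI/RC table, GraphML network, nitrogen family/module RPKM).

The same stages are available piecemeal (`sedibiome simulate`, `diversity`,
`ordinate`, `spatial`, `stats`, `assembly`, `network`, `nitrogen`) and as
library functions (`sedibiome.beta_nti`, `sedibiome.raup_crick_bray`,
`sedibiome.variation_partitioning`, …).

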
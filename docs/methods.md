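# Methods

This note records the models, conventions and numerical choices behind each
module, the design decisions taken where the methodology is genuinely open,
and what the synthetic generator does and does not emulate.

## Diversity estimators

Rarefaction subsamples each sample to a fixed depth **without replacement**
(multivariate hypergeometric), one draw per sample, seeded; samples below
the depth are dropped with a warning. The per-sample indices are:

* `sobs` — number of OTUs with positive count.
* `shannon` — −Σ pᵢ ln pᵢ in **nats**. For communities of several hundred
  OTUs this choice puts values in the familiar 3–6 range; a log₂ convention
  would roughly multiply them by 1.44.
* `simpson` — the dominance form Σ pᵢ², so the most diverse samples score
  lowest (≈0.01).
* `chao1` — the classic estimator sobs + F₁²/(2F₂), falling back to
  F₁(F₁−1)/2 when there are no doubletons (the mothur/QIIME-era default;
  no bias correction).
* `ace` — standard rare/abundant split at 10 reads, with the
  coefficient-of-variation term γ² = max(S_rare/C_ace · Σi(i−1)Fᵢ /
  (N_rare(N_rare−1)) − 1, 0). When every rare individual is a singleton
  (C_ace = 0) ACE is undefined and the Chao1 value is substituted.
* `coverage` — Good's 1 − F₁/N.

Bray–Curtis uses the count form Σ|x−y|/Σ(x+y). It is a semimetric; the test
suite tallies triangle-inequality violations without asserting their absence.

## Assembly null models

βMNTD between samples k and m is
½[Σ_{i∈k} f_ik · min_{j∈m} d_ij + Σ_{j∈m} f_jm · min_{i∈k} d_ij] with
patristic distances d and within-sample relative abundances f (uniform
weights in the unweighted variant); taxa absent from a sample are excluded
from its sums. Shared taxa contribute zero (their nearest neighbour in the
other community is themselves).

The βNTI null is the **taxa shuffle**: tip labels are permuted across the
whole tree, βMNTD recomputed, 999 times by default. βNTI = (obs − null
mean)/null SD. Pairs whose null distribution has zero spread get an
undefined βNTI; they are flagged, excluded from partitions and tallied.
βNTI is computed on the rarefied table, consistent with the rest of the
chain (configurable).

RCbray uses the proportional-proportional null: each null community keeps
its sample's observed richness and read total; taxa are drawn without
replacement with probability ∝ occupancy (number of samples containing the
taxon, via Gumbel-max sampling), each drawn taxon receives one read, and the
remainder is multinomial with probability ∝ metacommunity relative
abundance. RC = 2·[#(null BC < obs) + ½·#(null BC = obs)]/reps − 1, ties at
half weight, granularity 1/reps. Thresholds: |βNTI| > 2 for selection,
|RC| > 0.95 for dispersal processes — both configurable; the classification
is hierarchical (βNTI first, RC only inside the envelope). Process
fractions are reported as deterministic share of all classified pairs and
as shares **of stochastic pairs** for the three stochastic processes, which
is the convention under which the three stochastic percentages sum to 100.

Implementation note: a tip permutation only permutes indices into the fixed
patristic matrix, so each null replicate costs one row gather and one
min-reduction per sample plus a matrix product — 999 replicates on
15 × 200 data run in about a second.

## Co-occurrence networks

OTUs are ranked by summed per-sample relative abundance (ties broken
lexicographically on id) and the top 100 kept. Spearman ρ uses midranks;
two-sided p comes from the t-approximation. Edges require ρ > 0.6 **and**
p < 0.01, uncorrected — the thresholding convention of the field's network
papers; a Benjamini–Hochberg option exists but is off by default. Only
positive correlations form edges by default (`absolute=True` admits |ρ|).
Constant abundance vectors make ρ undefined; such pairs are skipped and
counted. Average path length averages over connected pairs only, the
diameter is that of the largest component, clustering is the mean local
coefficient with degree-<2 nodes contributing 0, and modules come from
seeded Louvain modularity maximisation (modularity is Newman's Q of that
partition).

## Ordination, space, variation partitioning

* **PCoA** is classical scaling of −½D² double-centred; negative
  eigenvalues are reported but excluded from explained proportions.
* **NMDS** minimises Kruskal stress-1 by SMACOF with monotone regression,
  best of 20 random starts, 300 iterations, tolerance 1e-7, seeded.
* **UPGMA** converts the average-linkage merge heights h into an
  ultrametric dendrogram with node height h/2.
* **ANOSIM** R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4); **Mantel** correlates off-diagonal triangles; both use
  seeded label/row permutations with the add-one p-value rule (one-sided
  greater for Mantel).
* **Geographic distances** are haversine on a sphere of radius 6371 km.
* **PCNM**: truncation threshold t = longest minimum-spanning-tree edge of
  the geographic distance matrix; distances > t replaced by 4t; principal
  coordinates with eigenvalue > 1e-8 × max retained. An optional linear
  detrending of the response on raw coordinates before PCNM exists and is
  off by default — the source methodology is ambiguous on whether the
  trend was removed or included, so both are available.
* **RDA** operates on Hellinger-transformed counts (the standard
  transformation for species data) against z-scored predictors; **CCA**
  uses the correspondence-analysis chi-square transformation with row
  weights; both were verified against R `vegan` on a fixture to ~6 digits.
  Collinear or constant predictors are dropped with a logged notice; more
  than n−2 predictors is an error. Per-variable significance is a
  **marginal** single-variable permutation test (the per-variable p-values
  convention; forward selection is not implemented).
* **Variation partitioning** adjusts R² by Ezekiel's formula
  1−(1−R²)(n−1)/(n−p−1) for the env-only, space-only and joint RDA models;
  pure fractions are differences of adjusted R², so they can be slightly
  negative — values are not clamped except for display. The identity
  a + b + c + d = 1 holds to machine precision.

## Nitrogen profiling

RPKM = reads/(gene-length-kb × total-mapped-millions); invariant to uniform
depth rescaling. The packaged KO map carries representative K numbers for
the nitrogen-cycle gene families (e.g. narG/H K00370/K00371, napA/B
K02567/K02568, nirS/K K15864/K00368, norB/C K04561/K02305, nosZ K00376,
nirB/D K00362/K00363, nrfA K03385, nifD/H/K, hao K10535, amo/pmo
K10944-6, hdh K20935, assimilatory nasA/B, narB, nirA). Each KO maps to
exactly one family and each family to one module; comammox is defined by
co-occurrence of amo and nxr within one organism rather than by unique KOs,
so it has no entries of its own under this constraint. The anammox marker
is hydrazine dehydrogenase (hdh). The map is a versioned data file and can
be replaced by any TSV with columns `ko`, `family`, `module`.
Kruskal–Wallis uses midrank ties and the χ² approximation; features
constant across all samples are flagged degenerate with p = 1.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analyses assume:
15 evenly spaced transect sites with a monotone salinity gradient
(0.12–35.8 ppt) split 5/5/5 into low/mid/high by the terciles of the
configured range (applied to the noiseless gradient so the design is stable
under noise); phylogenetically conserved niche optima (Brownian motion,
rate σ = 1 trait unit per √branch, rooted at the salinity-range midpoint so
all niches are reachable); auxiliary geochemistry as simple linear or
quadratic responses to salinity with noise (NH₄-N rising, NO₃-N falling,
TOC u-shaped, moisture rising); and group-structured KO abundances
(negative-binomial baseline, fold-change in one group).

Communities are multinomial draws of `depth` reads from regime-specific
weights over a fixed lognormal(0, 1) metacommunity — the standard neutral
species-abundance baseline:

* **selection** — Gaussian niches exp(−(trait−salinity)²/2w²), w = 2 ppt;
* **drift** — identical weights everywhere, all turnover is sampling noise;
* **dispersal limitation** — per-taxon log-abundance is a spatial Gaussian
  process with covariance exp(−d/decay_scale), decay 100 km — the simplest
  mechanism producing distance decay;
* **homogenizing** — a mass-effect mixture (1−m)·(independent per-site
  lognormal weights) + m·(one shared pool), m = 0.95. The local component
  must be site-independent for m to tune homogenisation — a mixture of the
  shared drift weights with themselves would be the drift regime again.

Default sizes (200 taxa, 15 samples, 10⁴ reads, rarefied to 3581) keep a
full pipeline run with 999 randomizations near ten seconds while matching
the study design's dimensions; validation suites use 199 randomizations per
replicate over 20 seeds for regime recovery, and smaller instances for
brute-force oracle comparisons. No effect sizes are estimates of the real
estuary: the gradients are calibration choices. The generator does not
simulate sequences (no reads, chimeras or OTU clustering), does not model
estuarine hydrodynamics, and produces noise-free phylogenies — so passing
tests demonstrate correctness and statistical calibration of the inference
chain, not that the real system behaves this way.

## Known limitations

* βNTI with few taxa or near-identical samples can have zero null spread;
  such pairs are excluded (and counted) rather than forced into a class.
* ANOSIM/Mantel p-values are permutation-based and bounded below by
  1/(n_perm+1).
* APL on a disconnected network averages over reachable pairs, which is
  optimistic relative to conventions that penalise disconnection.
* The CCA permutation test permutes the raw predictor (equivalent to
  residual permutation under the marginal null); reduced-model permutation
  schemes for partial models are not implemented.
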
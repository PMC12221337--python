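"""Null-model partitioning of community assembly processes.

The partitioning follows the two-step phylogenetic/taxonomic null-model
framework: per sample pair,

1. βMNTD (between-community mean nearest taxon distance) is compared with a
   null distribution obtained by shuffling taxon identities (tip labels)
   across the whole phylogeny; the z-score is βNTI.  |βNTI| > 2 indicates
   deterministic selection (sign gives heterogeneous vs homogeneous).
2. Pairs inside the βNTI null envelope are split by the Raup-Crick metric on
   Bray-Curtis (RCbray): null communities preserve each sample's richness and
   read total, drawing taxa with probability proportional to occupancy and
   filling reads proportionally to metacommunity relative abundance.
   RC > +0.95 -> dispersal limitation, RC < -0.95 -> homogenizing dispersal,
   otherwise drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io_formats import AlignmentError, CommunityTable, check_tree_alignment

logger = logging.getLogger("sedibiome")

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class NullModelConfig:
    n_reps: int = 999
    seed: int = 0
    abundance_weighted: bool = True
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class AssemblyPartition:
    """Process fractions for one sample group (or the whole study)."""

    group: str
    n_pairs: int
    n_excluded: int
    frac_deterministic: float
    frac_heterogeneous_selection: float
    frac_homogeneous_selection: float
    # fractions *of stochastic pairs*:
    frac_dispersal_limitation: float
    frac_homogenizing_dispersal: float
    frac_drift: float


# ---------------------------------------------------------------------------
# βMNTD / βNTI
# ---------------------------------------------------------------------------

def patristic_distances(tree: dendropy.Tree, otu_order: list[str]) -> np.ndarray:
    """Dense tip-to-tip patristic distance matrix in ``otu_order``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [o for o in otu_order if o not in taxa]
    if missing:
        raise AlignmentError(f"OTUs missing from tree tips: {missing[:10]}")
    n = len(otu_order)
    d = np.zeros((n, n))
    for i in range(n):
        ti = taxa[otu_order[i]]
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(ti, taxa[otu_order[j]])
    return d


def _weights(counts: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundance, or uniform over present."""
    if abundance_weighted:
        return counts / counts.sum(axis=1, keepdims=True)
    present = (counts > 0).astype(float)
    return present / present.sum(axis=1, keepdims=True)

def _bmntd_matrix(dist: np.ndarray, weights: np.ndarray,
                  present_idx: list[np.ndarray],
                  perm: np.ndarray | None = None) -> np.ndarray:
    """βMNTD for all sample pairs given a (possibly tip-shuffled) distance matrix.

    ``cmin[m]`` holds, for every taxon i, the distance from i to its nearest
    taxon present in sample m; the one-directional sum is then a single
    matrix product with the weight matrix.
    """
    n_samples, n_taxa = weights.shape
    d = dist if perm is None else dist[perm]
    cmin = np.empty((n_samples, n_taxa))
    for m, idx in enumerate(present_idx):
        cols = idx if perm is None else perm[idx]
        cmin[m] = d[:, cols].min(axis=1)
    a = weights @ cmin.T        # a[k, m] = sum_i w_ki * cmin_m[i]
    return 0.5 * (a + a.T)


def beta_mntd(table: CommunityTable, tree: dendropy.Tree,
              abundance_weighted: bool = True,
              dist: np.ndarray | None = None) -> DistanceMatrix:
    """Observed βMNTD between all sample pairs."""
    check_tree_alignment(table, tree)
    if dist is None:
        dist = patristic_distances(tree, table.otu_ids)
    counts = table.matrix()
    weights = _weights(counts, abundance_weighted)
    present = [np.flatnonzero(row > 0) for row in counts]
    mat = _bmntd_matrix(dist, weights, present)
    np.fill_diagonal(mat, 0.0)
    mat = 0.5 * (mat + mat.T)   # symmetrize away float noise
    return DistanceMatrix(mat, ids=[str(s) for s in table.sample_ids])


def beta_nti(table: CommunityTable, tree: dendropy.Tree,
             config: NullModelConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """βNTI z-scores with the tip-shuffle ("taxa shuffle") null.

    Returns ``(bnti, null_mean, null_sd)`` as square DataFrames.  Pairs whose
    null distribution has zero spread get NaN βNTI (flagged, excluded from
    partitions downstream).
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    check_tree_alignment(table, tree)
    rng = np.random.default_rng(config.seed)
    dist = patristic_distances(tree, table.otu_ids)
    counts = table.matrix()
    weights = _weights(counts, config.abundance_weighted)
    present = [np.flatnonzero(row > 0) for row in counts]
    n_taxa = counts.shape[1]

    obs = _bmntd_matrix(dist, weights, present)
    nulls = np.empty((config.n_reps,) + obs.shape)
    for r in range(config.n_reps):
        perm = rng.permutation(n_taxa)
        nulls[r] = _bmntd_matrix(dist, weights, present, perm=perm)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - null_mean) / null_sd
    bnti[null_sd == 0] = np.nan
    np.fill_diagonal(bnti, 0.0)
    ids = [str(s) for s in table.sample_ids]
    wrap = lambda m: pd.DataFrame(m, index=ids, columns=ids)  # noqa: E731
    n_undef = int(np.isnan(bnti[np.triu_indices_from(bnti, 1)]).sum())
    if n_undef:
        logger.info("beta_nti: %d pairs with zero null spread flagged undefined",
                    n_undef)
    return wrap(bnti), wrap(null_mean), wrap(null_sd)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def raup_crick_bray(table: CommunityTable, config: NullModelConfig) -> pd.DataFrame:
    """RCbray in [-1, 1] for all sample pairs.

    Null communities fix each sample's observed richness and read total:
    taxa are drawn without replacement with probability proportional to
    occupancy, each drawn taxon gets one read, and the remaining reads are
    allotted by a multinomial proportional to metacommunity relative
    abundance (the proportional-proportional variant).
    """
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(config.seed + 1)
    counts = table.matrix().astype(np.int64)
    n_samples, n_taxa = counts.shape
    richness = (counts > 0).sum(axis=1)
    if np.any(richness > n_taxa):  # pragma: no cover - impossible by construction
        raise ValueError("sample richness exceeds taxon pool")
    reads = counts.sum(axis=1)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    abund = counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore"):
        log_occ = np.where(occupancy > 0, np.log(occupancy), -np.inf)
    abund_p = abund / abund.sum()

    obs = squareform(pdist(counts.astype(float), metric="braycurtis"))
    iu = np.triu_indices(n_samples, 1)
    obs_pairs = obs[iu]
    lt = np.zeros(obs_pairs.shape)
    eq = np.zeros(obs_pairs.shape)
    null_comm = np.zeros((n_samples, n_taxa))
    for _ in range(config.n_reps):
        null_comm[:] = 0.0
        for k in range(n_samples):
            # Gumbel-max draw of `richness` taxa w.p. proportional to occupancy
            keys = log_occ + rng.gumbel(size=n_taxa)
            chosen = np.argpartition(-keys, richness[k] - 1)[: richness[k]]
            null_comm[k, chosen] = 1.0
            extra = reads[k] - richness[k]
            if extra > 0:
                p = abund_p[chosen]
                null_comm[k, chosen] += rng.multinomial(extra, p / p.sum())
        null_bc = pdist(null_comm, metric="braycurtis")
        lt += null_bc < obs_pairs - 1e-10
        eq += np.abs(null_bc - obs_pairs) <= 1e-10
    rc_pairs = 2.0 * (lt + 0.5 * eq) / config.n_reps - 1.0
    rc = np.zeros((n_samples, n_samples))
    rc[iu] = rc_pairs
    rc = rc + rc.T
    ids = [str(s) for s in table.sample_ids]
    return pd.DataFrame(rc, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rc: float, config: NullModelConfig) -> str:
    """Process label for one pair from its (βNTI, RCbray)."""
    if np.isnan(bnti):
        raise ValueError("undefined βNTI cannot be classified")
    if bnti > config.bnti_threshold:
        return "heterogeneous_selection"
    if bnti < -config.bnti_threshold:
        return "homogeneous_selection"
    if rc > config.rc_threshold:
        return "dispersal_limitation"
    if rc < -config.rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def _partition(sub: pd.DataFrame, label: str, n_excluded: int) -> AssemblyPartition:
    n = len(sub)
    cnt = sub["process"].value_counts()
    det = int(cnt.get("heterogeneous_selection", 0) + cnt.get("homogeneous_selection", 0))
    sto = n - det
    frac = lambda k: (int(cnt.get(k, 0)) / sto) if sto else 0.0  # noqa: E731
    return AssemblyPartition(
        group=label, n_pairs=n, n_excluded=n_excluded,
        frac_deterministic=det / n if n else 0.0,
        frac_heterogeneous_selection=int(cnt.get("heterogeneous_selection", 0)) / n if n else 0.0,
        frac_homogeneous_selection=int(cnt.get("homogeneous_selection", 0)) / n if n else 0.0,
        frac_dispersal_limitation=frac("dispersal_limitation"),
        frac_homogenizing_dispersal=frac("homogenizing_dispersal"),
        frac_drift=frac("drift"),
    )


def classify_assembly(
    bnti: pd.DataFrame, rc: pd.DataFrame, config: NullModelConfig,
    groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every sample pair and summarise process fractions.

    Returns ``(pairs, partitions)``: a long per-pair table and one partition
    row per group plus 'total'.  Deterministic fractions are of all classified
    pairs; the three stochastic fractions are of stochastic pairs.  Pairs with
    undefined βNTI are excluded and tallied in ``n_excluded``.
    """
    if list(bnti.index) != list(rc.index):
        raise ValueError("bnti and rc matrices must share sample ordering")
    ids = list(bnti.index)
    rows = []
    n_excluded_total = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = bnti.iat[i, j]
            r = rc.iat[i, j]
            if np.isnan(b):
                n_excluded_total += 1
                rows.append({"sample_i": ids[i], "sample_j": ids[j],
                             "bnti": b, "rc": r, "process": "undefined"})
                continue
            rows.append({"sample_i": ids[i], "sample_j": ids[j], "bnti": b,
                         "rc": r, "process": classify_pair(b, r, config)})
    pairs = pd.DataFrame(rows)
    defined = pairs[pairs["process"] != "undefined"]

    partitions = [_partition(defined, "total", n_excluded_total)]
    if groups is not None:
        groups = groups.astype(str)
        for g in pd.unique(groups):
            members = set(groups.index[groups == g].astype(str))
            mask = pairs["sample_i"].isin(members) & pairs["sample_j"].isin(members)
            sub = pairs[mask]
            n_exc = int((sub["process"] == "undefined").sum())
            partitions.append(
                _partition(sub[sub["process"] != "undefined"], g, n_exc))
    part_df = pd.DataFrame([vars(p) for p in partitions]).set_index("group")
    return pairs, part_df
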
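"""Ordination, matrix-correlation tests, clustering, spatial eigenfunctions
and variation partitioning.

Highlights of the conventions used here:

* PCoA is classical scaling (double-centred -D^2/2); negative eigenvalues are
  reported but excluded from the explained proportions.
* RDA Hellinger-transforms the community table; CCA uses the chi-square
  (correspondence-analysis) transformation with row/column weighting.
* PCNM truncates the geographic distance matrix at the longest minimum
  spanning tree edge, replaces larger distances by 4x the threshold, and
  keeps the positive-eigenvalue principal coordinates as spatial predictors.
* Variation partitioning uses Ezekiel-adjusted R^2 of the env-only,
  space-only and joint RDA models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .io_formats import CommunityTable
from .diversity import relative_abundance

logger = logging.getLogger("sedibiome")

EARTH_RADIUS_KM = 6371.0


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame            # samples x axes
    eigenvalues: Optional[np.ndarray] = None
    proportion_explained: Optional[np.ndarray] = None
    stress: Optional[float] = None
    converged: bool = True


@dataclass
class ConstrainedOrdinationResult:
    mode: str
    site_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray     # fractions of total inertia
    cumulative_first_two: float          # percent
    variable_pvalues: pd.Series
    total_inertia: float
    constrained_inertia: float


@dataclass
class PCNMBasis:
    vectors: pd.DataFrame                # samples x positive eigenvectors
    eigenvalues: np.ndarray
    truncation_km: float


@dataclass
class VPAResult:
    """Adjusted-R^2 fractions: a pure env, b shared, c pure space, d unexplained."""

    pure_env: float
    shared: float
    pure_space: float
    unexplained: float

    @property
    def total_explained(self) -> float:
        return self.pure_env + self.shared + self.pure_space


# ---------------------------------------------------------------------------
# unconstrained ordination & clustering
# ---------------------------------------------------------------------------

def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10 * max(abs(evals).max(), 1.0)).sum())
    if k > n_pos:
        logger.warning("pcoa: only %d positive eigenvalues, truncating k=%d", n_pos, k)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    pos_sum = evals[:n_pos].sum()
    prop = (evals[:k] / pos_sum) if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids),
                                 columns=[f"PCo{i+1}" for i in range(k)]),
        eigenvalues=evals, proportion_explained=prop)


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 20,
         seed: int = 0, max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS (Kruskal stress-1, SMACOF majorization, best of n starts)."""
    n = len(dm.ids)
    if n < k + 2:
        raise ValueError("need at least k+2 samples for NMDS")
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                n_init=n_starts, init="random", max_iter=max_iter, eps=1e-7,
                random_state=seed, normalized_stress=True)
    coords = model.fit_transform(np.asarray(dm.data, dtype=float))
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids),
                                 columns=[f"NMDS{i+1}" for i in range(k)]),
        stress=float(model.stress_),
        converged=model.n_iter_ < max_iter)


def upgma_dendrogram(dm: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) clustering of samples, as an ultrametric newick."""
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    z = linkage(squareform(np.asarray(dm.data, dtype=float), checks=False),
                method="average")
    newicks = {i: (str(dm.ids[i]), 0.0) for i in range(n)}  # (subtree, height)
    for step, (a, b, dist, _) in enumerate(z):
        a, b = int(a), int(b)
        height = dist / 2.0
        sa, ha = newicks.pop(a)
        sb, hb = newicks.pop(b)
        sub = f"({sa}:{height - ha:.10g},{sb}:{height - hb:.10g})"
        newicks[n + step] = (sub, height)
    (tree, _), = newicks.values()
    return tree + ";"


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def anosim(dm: DistanceMatrix, groups: pd.Series, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """ANOSIM R and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks over the condensed distance vector; p uses the add-one rule.
    """
    ids = list(dm.ids)
    labels = groups.astype(str).reindex(ids).to_numpy()
    if pd.isna(labels).any():
        raise ValueError("groups missing for some samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    d = squareform(np.asarray(dm.data, dtype=float), checks=False)
    ranks = stats.rankdata(d)
    n = len(ids)
    iu = np.triu_indices(n, 1)
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = sum(r_stat(rng.permutation(labels)) >= obs for _ in range(n_perm))
    p = (count + 1) / (n_perm + 1)
    return float(obs), float(p)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "pearson",
           n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices (one-sided, greater)."""
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share ids in the same order")
    a = np.asarray(d1.data, dtype=float)
    b = np.asarray(d2.data, dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    va = a[iu]

    def corr(vb: np.ndarray) -> float:
        if method == "pearson":
            return stats.pearsonr(va, vb)[0]
        if method == "spearman":
            return stats.spearmanr(va, vb)[0]
        raise ValueError(f"unknown method {method!r}")

    if np.allclose(va, va[0]) or np.allclose(b[iu], b[iu][0]):
        raise ValueError("constant distance triangle: Mantel r undefined")
    obs = corr(b[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += corr(b[np.ix_(perm, perm)][iu]) >= obs
    return float(obs), float((count + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# geography and spatial eigenfunctions
# ---------------------------------------------------------------------------

def geo_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between sample coordinates."""
    lat = coords["latitude"].to_numpy(dtype=float)
    lon = coords["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    latr, lonr = np.radians(lat), np.radians(lon)
    dlat = latr[:, None] - latr[None, :]
    dlon = lonr[:, None] - lonr[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(latr[:, None]) * np.cos(latr[None, :]) * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in coords.index])


def pcnm(geo: DistanceMatrix, eig_floor: float = 1e-8) -> PCNMBasis:
    """Principal coordinates of neighbour matrices (Moran eigenvector maps).

    Truncation threshold = longest minimum-spanning-tree edge; distances above
    it are replaced by 4x the threshold; the positive-eigenvalue principal
    coordinates of the truncated matrix are the spatial predictors.
    """
    d = np.asarray(geo.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 sites")
    if np.all(d == 0):
        raise ValueError("all sites coincident")
    mst = minimum_spanning_tree(d).toarray()
    t = float(mst.max())
    trunc = np.where(d > t, 4.0 * t, d)
    np.fill_diagonal(trunc, 0.0)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (trunc * trunc) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eig_floor * evals.max()
    vecs = evecs[:, keep] * np.sqrt(evals[keep])
    return PCNMBasis(
        vectors=pd.DataFrame(vecs, index=list(geo.ids),
                             columns=[f"PCNM{i+1}" for i in range(int(keep.sum()))]),
        eigenvalues=evals[keep], truncation_km=t)


# ---------------------------------------------------------------------------
# constrained ordination
# ---------------------------------------------------------------------------

def hellinger(table: CommunityTable) -> pd.DataFrame:
    """Hellinger transformation: sqrt of relative abundances."""
    return np.sqrt(relative_abundance(table))


def _standardize_full_rank(x: pd.DataFrame) -> pd.DataFrame:
    """Z-score columns; drop constants and collinear columns with a notice."""
    x = x.astype(float).copy()
    keep = []
    for col in x.columns:
        sd = x[col].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            logger.info("dropping constant predictor %r", col)
            continue
        x[col] = (x[col] - x[col].mean()) / sd
        keep.append(col)
    x = x[keep]
    if x.shape[1] == 0:
        return x
    q, r = np.linalg.qr(x.to_numpy())
    diag = np.abs(np.diag(r))
    indep = diag > 1e-8 * diag.max()
    dropped = [c for c, k in zip(x.columns, indep) if not k]
    if dropped:
        logger.info("dropping collinear predictors %r", dropped)
    return x[[c for c, k in zip(x.columns, indep) if k]]


def _rda_fit(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Return (fitted Y, constrained SS, total SS) for centred y on x."""
    b, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ b
    return yhat, float((yhat ** 2).sum()), float((y ** 2).sum())


def constrained_ordination(
    response: CommunityTable,
    predictors: pd.DataFrame,
    mode: str = "rda",
    n_perm: int = 999,
    seed: int = 0,
) -> ConstrainedOrdinationResult:
    """RDA (on Hellinger-transformed counts) or CCA of community ~ predictors.

    Per-variable p-values are marginal single-variable permutation tests
    (predictor rows shuffled, add-one rule).
    """
    if mode not in ("rda", "cca"):
        raise ValueError("mode must be 'rda' or 'cca'")
    x_df = _standardize_full_rank(predictors.loc[response.sample_ids])
    n = len(response.sample_ids)
    if x_df.shape[1] >= n - 1:
        raise ValueError(
            f"{x_df.shape[1]} predictors for {n} samples: reduce the predictor "
            "set (at most n-2 independent variables)")
    x = x_df.to_numpy()
    rng = np.random.default_rng(seed)

    if mode == "rda":
        y = hellinger(response).to_numpy()
        y = y - y.mean(axis=0, keepdims=True)
        yhat, c_ss, t_ss = _rda_fit(y, x)
        u, s, vt = np.linalg.svd(yhat, full_matrices=False)
        evals = (s ** 2) / (n - 1)
        total_inertia = t_ss / (n - 1)
    else:
        f = response.matrix()
        f = f[:, f.sum(axis=0) > 0]  # OTUs absent everywhere carry no inertia
        f = f / f.sum()
        r = f.sum(axis=1)
        c = f.sum(axis=0)
        q = (f - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        # weighted standardization of predictors with row weights r
        xm = (x * r[:, None]).sum(axis=0) / r.sum()
        xc = x - xm
        xsd = np.sqrt((r[:, None] * xc ** 2).sum(axis=0) / r.sum())
        xw = np.sqrt(r)[:, None] * (xc / xsd)
        bh, *_ = np.linalg.lstsq(xw, q, rcond=None)
        yhat = xw @ bh
        u, s, vt = np.linalg.svd(yhat, full_matrices=False)
        evals = s ** 2
        total_inertia = float((q ** 2).sum())
        y = q

    rank = min(x.shape[1], len([e for e in evals if e > 1e-12]))
    evals = evals[:rank]
    site = u[:, :rank] * s[:rank]
    prop = evals / total_inertia
    cum2 = 100.0 * float(prop[: min(2, rank)].sum())
    site_df = pd.DataFrame(site, index=response.sample_ids,
                           columns=[f"{mode.upper()}{i+1}" for i in range(rank)])
    # biplot scores: correlations of (unweighted) predictors with site axes
    var_scores = pd.DataFrame(
        np.corrcoef(x, site, rowvar=False)[: x.shape[1], x.shape[1]:],
        index=x_df.columns, columns=site_df.columns)

    pvals = {}
    for col in x_df.columns:
        xi = x_df[[col]].to_numpy()
        obs_stat = _marginal_stat(response, xi, mode)
        count = 0
        for _ in range(n_perm):
            count += _marginal_stat(response, xi[rng.permutation(n)], mode) >= obs_stat
        pvals[col] = (count + 1) / (n_perm + 1)

    return ConstrainedOrdinationResult(
        mode=mode, site_scores=site_df, variable_scores=var_scores,
        eigenvalues=evals, proportion_explained=prop,
        cumulative_first_two=cum2,
        variable_pvalues=pd.Series(pvals, name="p"),
        total_inertia=float(total_inertia),
        constrained_inertia=float(evals.sum()))


def _marginal_stat(response: CommunityTable, xi: np.ndarray, mode: str) -> float:
    """Constrained-inertia fraction of a single-variable model (test statistic)."""
    if mode == "rda":
        y = hellinger(response).to_numpy()
        y = y - y.mean(axis=0, keepdims=True)
        xc = xi - xi.mean(axis=0, keepdims=True)
        _, c_ss, t_ss = _rda_fit(y, xc)
        return c_ss / t_ss
    f = response.matrix()
    f = f[:, f.sum(axis=0) > 0]
    f = f / f.sum()
    r = f.sum(axis=1)
    c = f.sum(axis=0)
    q = (f - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    xm = (xi * r[:, None]).sum(axis=0) / r.sum()
    xc = xi - xm
    xw = np.sqrt(r)[:, None] * xc
    bh, *_ = np.linalg.lstsq(xw, q, rcond=None)
    return float(((xw @ bh) ** 2).sum() / (q ** 2).sum())


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------

def _rda_r2(y: np.ndarray, x_df: pd.DataFrame) -> tuple[float, int]:
    x = _standardize_full_rank(x_df)
    p = x.shape[1]
    if p == 0:
        return 0.0, 0
    _, c_ss, t_ss = _rda_fit(y, x.to_numpy())
    return c_ss / t_ss, p


def _adjust_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError(f"cannot adjust R^2 with n={n}, p={p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partitioning(
    response: CommunityTable,
    env: pd.DataFrame,
    space: PCNMBasis | pd.DataFrame,
) -> VPAResult:
    """Partition community variation between environment and space.

    Ezekiel-adjusted R^2 of the env-only, space-only and joint RDA models
    gives a (pure env), c (pure space), b (shared) and d (unexplained),
    with a + b + c + d = 1 by construction.
    """
    space_df = space.vectors if isinstance(space, PCNMBasis) else space
    if env.shape[1] == 0 or space_df.shape[1] == 0:
        raise ValueError("both predictor blocks must be non-empty")
    y = hellinger(response).to_numpy()
    y = y - y.mean(axis=0, keepdims=True)
    n = y.shape[0]
    env = env.loc[response.sample_ids].select_dtypes(include=[np.number])
    space_df = space_df.loc[response.sample_ids]

    r2_env, p_env = _rda_r2(y, env)
    r2_spa, p_spa = _rda_r2(y, space_df)
    joint = pd.concat([env, space_df], axis=1)
    r2_all, p_all = _rda_r2(y, joint)
    a_env = _adjust_r2(r2_env, n, p_env)
    a_spa = _adjust_r2(r2_spa, n, p_spa)
    a_all = _adjust_r2(r2_all, n, p_all)

    a = a_all - a_spa
    c = a_all - a_env
    b = a_env + a_spa - a_all
    d = 1.0 - a_all
    return VPAResult(pure_env=a, shared=b, pure_space=c, unexplained=d)
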
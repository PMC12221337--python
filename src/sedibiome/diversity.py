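"""Rarefaction, alpha-diversity estimators and Bray-Curtis beta diversity.

Conventions: Shannon is in nats; Simpson is the dominance form sum(p_i^2)
(small values = diverse); Chao1 is the classic estimator (bias-corrected
variant available); ACE uses the standard rare/abundant split at 10 reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io_formats import CommunityTable

ACE_RARE_THRESHOLD = 10


@dataclass
class AlphaDiversityRecord:
    sobs: int
    shannon: float
    simpson: float
    chao1: float
    ace: float
    coverage: float


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    One draw per sample (no repetition averaging), deterministic given seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(counts.index[~keep])
        warnings.warn(f"dropping {len(dropped)} samples below depth {depth}: "
                      f"{dropped}", stacklevel=2)
    rows = []
    for sample in counts.index[keep]:
        vec = counts.loc[sample].to_numpy(dtype=np.int64)
        rows.append(rng.multivariate_hypergeometric(vec, depth))
    rarefied = pd.DataFrame(np.vstack(rows) if rows else
                            np.empty((0, counts.shape[1]), dtype=np.int64),
                            index=counts.index[keep], columns=counts.columns)
    return CommunityTable(rarefied, table.taxonomy)


def alpha_diversity(counts) -> AlphaDiversityRecord:
    """Alpha-diversity indices for one sample's count vector.

    sobs = observed OTUs; shannon = -sum p ln p; simpson = sum p^2;
    chao1 = sobs + F1^2/(2 F2) (F1(F1-1)/2 when F2 = 0);
    ACE per the rare/abundant split at 10 with the coefficient-of-variation
    term; coverage = 1 - F1/N (Good).
    """
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero count vector")
    n_reads = int(x.sum())
    p = x / n_reads
    sobs = int(x.size)
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p * p).sum())

    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        chao1 = sobs + f1 * f1 / (2.0 * f2)
    else:
        chao1 = sobs + f1 * (f1 - 1) / 2.0

    rare = x[x <= ACE_RARE_THRESHOLD]
    s_abund = int((x > ACE_RARE_THRESHOLD).sum())
    s_rare = int(rare.size)
    n_rare = int(rare.sum())
    if s_rare == 0:
        ace = float(s_abund)
    else:
        c_ace = 1.0 - f1 / n_rare if n_rare > 0 else 0.0
        if c_ace <= 0:
            # every rare individual is a singleton; ACE undefined, use Chao1
            ace = float(chao1)
        else:
            fi = np.bincount(rare, minlength=ACE_RARE_THRESHOLD + 1)
            i = np.arange(1, ACE_RARE_THRESHOLD + 1)
            ssq = float((i * (i - 1) * fi[1:]).sum())
            gamma2 = max(
                s_rare / c_ace * ssq / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
            ) if n_rare > 1 else 0.0
            ace = s_abund + s_rare / c_ace + f1 / c_ace * gamma2

    coverage = 1.0 - f1 / n_reads
    return AlphaDiversityRecord(sobs=sobs, shannon=shannon, simpson=simpson,
                                chao1=float(chao1), ace=float(ace),
                                coverage=float(coverage))


def alpha_diversity_table(table: CommunityTable) -> pd.DataFrame:
    """Per-sample alpha-diversity table (rows = samples)."""
    records = {s: asdict(alpha_diversity(table.counts.loc[s].to_numpy()))
               for s in table.sample_ids}
    return pd.DataFrame.from_dict(records, orient="index")[
        ["sobs", "shannon", "simpson", "chao1", "ace", "coverage"]]


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y)."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    arr = table.matrix()
    if np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero-sum sample in table")
    return DistanceMatrix(squareform(pdist(arr, metric="braycurtis")),
                          ids=[str(s) for s in table.sample_ids])


def relative_abundance(table: CommunityTable) -> pd.DataFrame:
    """Counts normalised so every sample (row) sums to 1."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-sum sample in table")
    return table.counts.div(totals, axis=0)
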
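"""Nitrogen-cycle functional-gene profiling from KO read counts.

KO read counts are RPKM-normalised (reads per kilobase of gene per million
mapped reads), aggregated into nitrogen-cycle gene families (narG/H, napA/B,
nirS/K, norB/C, nosZ, nirB/D, nrfA, nifD/H/K, hao, amoA/B/C-pmoA/B/C, hdh,
...) and pathway modules (denitrification, nitrification, nitrogen fixation,
assimilatory/dissimilatory nitrate reduction, anammox), then compared between
salinity groups with Kruskal-Wallis H tests.

The packaged default KO map carries representative KEGG K numbers for each
family and is overridable with a user TSV (columns: ko, family, module).
Comammox — complete ammonia oxidation within one organism — is defined by the
co-occurrence of amo and nxr genes rather than by KOs unique to it, so it has
no entries of its own in the one-KO-one-family default map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import FormatError, KOTable

logger = logging.getLogger("sedibiome")


@dataclass
class FunctionalProfile:
    families: pd.DataFrame       # samples x gene families (RPKM sums)
    modules: pd.DataFrame        # samples x pathway modules (RPKM sums)
    groups: pd.Series            # sample -> salinity group
    n_unmapped: int


def load_pathway_map(path: str | Path) -> pd.DataFrame:
    """Load and validate a KO -> family -> module map (TSV)."""
    pmap = pd.read_csv(path, sep="\t")
    required = {"ko", "family", "module"}
    if not required.issubset(pmap.columns):
        raise FormatError(f"pathway map needs columns {sorted(required)}")
    if pmap["ko"].duplicated().any():
        dup = pmap.loc[pmap["ko"].duplicated(), "ko"].tolist()
        raise FormatError(f"KO mapped to more than one family: {dup}")
    fam_modules = pmap.groupby("family")["module"].nunique()
    bad = fam_modules[fam_modules > 1].index.tolist()
    if bad:
        raise FormatError(f"gene families mapped to more than one module: {bad}")
    return pmap.set_index("ko")


def default_pathway_map() -> pd.DataFrame:
    """The packaged nitrogen-cycle KO map."""
    with resources.as_file(
            resources.files("sedibiome.data") / "nitrogen_pathway_map.tsv") as p:
        return load_pathway_map(p)


def rpkm_normalize(ko: KOTable) -> pd.DataFrame:
    """RPKM = reads / (gene length in kb x total mapped reads in millions)."""
    if (ko.total_mapped <= 0).any():
        bad = list(ko.total_mapped.index[ko.total_mapped <= 0])
        raise ValueError(f"zero total mapped reads for samples {bad}")
    length_kb = ko.gene_lengths.reindex(ko.counts.columns) / 1000.0
    millions = ko.total_mapped.loc[ko.counts.index] / 1e6
    return ko.counts.div(length_kb, axis=1).div(millions, axis=0)


def aggregate_nitrogen_pathways(
    rpkm: pd.DataFrame, pmap: pd.DataFrame, groups: pd.Series | None = None,
) -> FunctionalProfile:
    """Sum KO RPKM into gene families and families into pathway modules."""
    if pmap.empty:
        raise ValueError("pathway map is empty")
    mapped = [k for k in rpkm.columns if k in pmap.index]
    n_unmapped = rpkm.shape[1] - len(mapped)
    if n_unmapped:
        logger.info("aggregate_nitrogen_pathways: %d unmapped KOs excluded",
                    n_unmapped)
    sub = rpkm[mapped]
    fam_of = pmap.loc[mapped, "family"]
    families = sub.T.groupby(fam_of).sum().T
    mod_of_family = pmap.drop_duplicates("family").set_index("family")["module"]
    modules = families.T.groupby(mod_of_family.reindex(families.columns)).sum().T
    if groups is None:
        groups = pd.Series("all", index=rpkm.index)
    return FunctionalProfile(families=families, modules=modules,
                             groups=groups.loc[rpkm.index], n_unmapped=n_unmapped)


def kruskal_wallis_groups(
    profile: FunctionalProfile, level: str = "family", bh_correct: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis H test per feature across salinity groups.

    Returns a DataFrame indexed by feature with columns H, p (chi-square
    approximation, midrank ties), a `degenerate` flag for features constant
    across all samples (p set to 1), and optionally BH-adjusted p.
    """
    table = {"family": profile.families, "module": profile.modules}[level]
    groups = profile.groups
    uniq = groups.unique()
    if len(uniq) < 2 or any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    rows = {}
    for feat in table.columns:
        vals = [table.loc[groups == g, feat].to_numpy() for g in uniq]
        flat = table[feat].to_numpy()
        if np.all(flat == flat[0]):
            rows[feat] = {"H": 0.0, "p": 1.0, "degenerate": True}
            continue
        h, p = stats.kruskal(*vals)
        rows[feat] = {"H": float(h), "p": float(p), "degenerate": False}
    out = pd.DataFrame.from_dict(rows, orient="index")
    if bh_correct:
        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
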
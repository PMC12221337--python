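"""Readers, writers and core containers for the formats the pipeline touches.

Internal orientation is the ecology convention: samples are rows, OTUs are
columns.  On disk, count tables follow the sequencing convention (OTUs as
rows); the conversion happens here at the boundary.  Loaders validate and
reject malformed records — they never silently repair, with the single
documented exception of zero-length terminal branches in trees, which are
replaced by a small epsilon with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

logger = logging.getLogger("sedibiome")

ENV_VARIABLES = [
    "salinity", "pH", "NO2-N", "NO3-N", "NH4-N",
    "Fe2+", "Fe3+", "sulphide", "TOC", "MC", "TN", "TP",
]

#: salinity cut-points (ppt) separating low/mid/high groups when no explicit
#: group column is present; the study design places the low/mid boundary just
#: above estuarine freshwater (~1 ppt) and the mid/high boundary at ~30 ppt.
DEFAULT_SALINITY_CUTS = (1.0, 30.0)


class FormatError(ValueError):
    """A file violated its format contract (bad cell, duplicate id, ...)."""


class AlignmentError(ValueError):
    """Sample or OTU identifiers do not line up between inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Samples x OTUs table of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with OTU ids as columns.
    taxonomy
        Optional mapping OTU id -> lineage string (phylum extracted for
        network colouring).
    """

    counts: pd.DataFrame
    taxonomy: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise FormatError("duplicate sample ids in community table")
        if c.columns.has_duplicates:
            raise FormatError("duplicate OTU ids in community table")
        arr = c.to_numpy()
        if np.any(arr < 0):
            raise FormatError("negative counts in community table")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


@dataclass
class KOTable:
    """Samples x KO read counts plus per-KO gene length and per-sample totals."""

    counts: pd.DataFrame                 # samples x KOs, integer reads
    gene_lengths: pd.Series              # bp per KO representative
    total_mapped: pd.Series              # mapped reads per sample

    def __post_init__(self) -> None:
        if (self.gene_lengths <= 0).any():
            raise FormatError("gene lengths must be positive")
        if np.any(self.counts.to_numpy() < 0):
            raise FormatError("negative KO counts")
        colsum = self.counts.sum(axis=1)
        if (self.total_mapped.loc[colsum.index] < colsum).any():
            raise FormatError("total mapped reads below the table's own sum")


# ---------------------------------------------------------------------------
# community table
# ---------------------------------------------------------------------------

def load_community_table(path: str | Path) -> CommunityTable:
    """Load an OTU count table (TSV, OTUs as rows, optional taxonomy column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    taxonomy = None
    if df.columns.size and df.columns[-1].lower() == "taxonomy":
        taxonomy = df.iloc[:, -1].rename("taxonomy")
        df = df.iloc[:, :-1]
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate OTU ids: {dups}")
    arr = np.empty((df.shape[0], df.shape[1]), dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (otu, raw) in enumerate(df[col].items()):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {raw!r} at OTU {otu!r}, sample {col!r}"
                ) from None
            if val < 0:
                raise FormatError(f"negative count at OTU {otu!r}, sample {col!r}")
            arr[i, j] = val
    counts = pd.DataFrame(arr, index=df.index, columns=df.columns)
    # internal orientation: samples as rows
    counts = counts.T
    counts.index.name = None
    counts.columns.name = None
    return CommunityTable(counts=counts, taxonomy=taxonomy)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    out = table.counts.T.copy()
    out.index.name = "otu_id"
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy.reindex(out.index)
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def load_tree(path: str | Path, zero_branch_epsilon: float = 1e-8) -> dendropy.Tree:
    """Load a rooted newick tree with branch lengths.

    Zero-length terminal branches are replaced by ``zero_branch_epsilon``
    with a warning; missing branch lengths are a hard error.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparseable newick: {exc}") from exc
    tree.is_rooted = True
    n_fixed = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("newick tree has edges without branch lengths")
        if edge.length == 0 and edge.head_node.is_leaf():
            edge.length = zero_branch_epsilon
            n_fixed += 1
        elif edge.length < 0:
            raise FormatError("negative branch length")
    if n_fixed:
        warnings.warn(
            f"replaced {n_fixed} zero-length terminal branches with "
            f"{zero_branch_epsilon}", stacklevel=2,
        )
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def check_tree_alignment(table: CommunityTable, tree: dendropy.Tree) -> None:
    """Raise :class:`AlignmentError` listing OTUs absent from the tree."""
    tips = set(tree_tip_labels(tree))
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        raise AlignmentError(f"OTUs missing from tree tips: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def _salinity_group(salinity: float, cuts: tuple[float, float]) -> str:
    lo, hi = cuts
    if salinity < lo:
        return "low"
    if salinity < hi:
        return "mid"
    return "high"


def load_sample_metadata(
    env_path: str | Path,
    coords_path: str | Path,
    salinity_cuts: tuple[float, float] = DEFAULT_SALINITY_CUTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load environmental variables and coordinates (CSV, id column 'sample').

    Returns ``(env, coords)`` DataFrames indexed by sample id.  The ``group``
    column (low/mid/high) is derived from salinity cut-points when absent.
    """
    env = pd.read_csv(env_path)
    coords = pd.read_csv(coords_path)
    for df, name in ((env, "env"), (coords, "coords")):
        if "sample" not in df.columns:
            raise FormatError(f"{name} table lacks a 'sample' column")
        if df["sample"].duplicated().any():
            raise FormatError(f"duplicate sample ids in {name} table")
    env = env.set_index("sample")
    coords = coords.set_index("sample")

    group = None
    if "group" in env.columns:
        group = env.pop("group").astype(str)
    for col in env.columns:
        coerced = pd.to_numeric(env[col], errors="coerce")
        if coerced.isna().any() and not env[col].isna().all():
            bad = env.index[coerced.isna() & env[col].notna()][0]
            raise FormatError(f"non-numeric value in env column {col!r}, sample {bad!r}")
        env[col] = coerced
    if group is None:
        if "salinity" not in env.columns:
            raise FormatError("cannot derive salinity groups: no 'salinity' column")
        group = env["salinity"].map(lambda s: _salinity_group(s, salinity_cuts))
    env["group"] = group

    if "MC" in env.columns:
        mc = env["MC"].dropna()
        if ((mc < 0) | (mc > 100)).any():
            raise FormatError("MC (moisture content, %) outside [0, 100]")

    for col in ("latitude", "longitude"):
        if col not in coords.columns:
            raise FormatError(f"coords table lacks {col!r}")
        coords[col] = pd.to_numeric(coords[col])
    if (coords["latitude"].abs() > 90).any():
        raise FormatError("latitude outside [-90, 90]")
    if (coords["longitude"].abs() > 180).any():
        raise FormatError("longitude outside [-180, 180]")
    return env, coords["latitude longitude".split()].astype(float).join(
        coords.drop(columns=["latitude", "longitude"]))


def write_sample_metadata(env: pd.DataFrame, coords: pd.DataFrame,
                          env_path: str | Path, coords_path: str | Path) -> None:
    env.rename_axis("sample").to_csv(env_path)
    coords.rename_axis("sample").to_csv(coords_path)


def align_samples(
    table: CommunityTable, env: pd.DataFrame, coords: pd.DataFrame,
) -> tuple[CommunityTable, pd.DataFrame, pd.DataFrame]:
    """Restrict all three inputs to their shared sample ids, in table order."""
    shared = [s for s in table.sample_ids if s in env.index and s in coords.index]
    if len(shared) < 3:
        raise AlignmentError(
            f"only {len(shared)} samples shared between community, env and coords")
    return (
        CommunityTable(table.counts.loc[shared], table.taxonomy),
        env.loc[shared],
        coords.loc[shared],
    )


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def load_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix row/column ids differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# KO tables
# ---------------------------------------------------------------------------

def load_ko_table(path: str | Path) -> KOTable:
    """Load a KO table (TSV): '#totals' comment line, then KO rows.

    Layout: a leading line ``#totals<TAB>sample=reads<TAB>...`` carrying the
    per-sample total mapped reads, then a header ``ko_id  length  <samples>``
    and one row per KO.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
    if not first.startswith("#totals"):
        raise FormatError("KO table lacks the '#totals' header line")
    totals = {}
    for tok in first.split("\t")[1:]:
        name, _, val = tok.partition("=")
        totals[name] = int(val)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "length" not in df.columns:
        raise FormatError("KO table lacks a 'length' column")
    lengths = df.pop("length").astype(int)
    lengths.index.name = None
    counts = df.astype(np.int64).T  # samples as rows
    counts.index.name = None
    counts.columns.name = None
    total_mapped = pd.Series(totals, name="total_mapped").reindex(counts.index)
    if total_mapped.isna().any():
        raise FormatError("totals line missing some samples")
    return KOTable(counts=counts, gene_lengths=lengths,
                   total_mapped=total_mapped.astype(np.int64))


def write_ko_table(ko: KOTable, path: str | Path) -> None:
    path = Path(path)
    out = ko.counts.T.copy()
    out.insert(0, "length", ko.gene_lengths.reindex(out.index))
    with path.open("w") as fh:
        fh.write("#totals\t" + "\t".join(
            f"{s}={int(v)}" for s, v in ko.total_mapped.items()) + "\n")
        out.rename_axis("ko_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def export_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or a node/edge TSV pair.

    For ``fmt='tsv'``, ``path`` is used as a stem: ``<stem>.nodes.tsv`` and
    ``<stem>.edges.tsv`` are written.
    """
    path = Path(path)
    if graph.number_of_nodes() == 0:
        warnings.warn("exporting an empty network", stacklevel=2)
    if fmt == "graphml":
        g = graph.copy()
        for _, _, d in g.edges(data=True):
            if "rho" in d:
                d["rho"] = round(float(d["rho"]), 6)
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        nodes = pd.DataFrame(
            [{"otu_id": n, **d} for n, d in graph.nodes(data=True)])
        edges = pd.DataFrame(
            [{"source": u, "target": v, **d} for u, v, d in graph.edges(data=True)])
        if not edges.empty and "rho" in edges.columns:
            edges["rho"] = edges["rho"].map(lambda r: f"{r:.6f}")
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
        edges.to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def load_network_tsv(stem: str | Path) -> nx.Graph:
    stem = Path(stem)
    nodes = pd.read_csv(stem.with_suffix(".nodes.tsv"), sep="\t")
    edges = pd.read_csv(stem.with_suffix(".edges.tsv"), sep="\t")
    g = nx.Graph()
    for _, row in nodes.iterrows():
        attrs = row.drop("otu_id").to_dict()
        g.add_node(row["otu_id"], **{k: v for k, v in attrs.items() if pd.notna(v)})
    for _, row in edges.iterrows():
        attrs = row.drop(["source", "target"]).to_dict()
        g.add_edge(row["source"], row["target"], **attrs)
    return g
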
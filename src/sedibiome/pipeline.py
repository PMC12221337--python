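"""End-to-end orchestration of the full analysis chain.

One configuration (YAML or dict) drives: load-or-simulate -> rarefaction ->
alpha/beta diversity -> PCoA/NMDS/UPGMA -> ANOSIM/Mantel -> geographic
distances and PCNM -> CCA/RDA + variation partitioning -> assembly null
models -> co-occurrence network -> nitrogen-cycle profiling.  Every stage
writes its outputs under the output directory and registers them in a
manifest; the numeric results are collected into a JSON report.  Identical
config + master seed reproduces every numeric output byte-for-byte.

Per-stage seeds are derived as ``blake2s(master_seed, stage_name)`` so stage
RNG streams are decorrelated and stable under stage reordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from . import __version__
from . import assembly as asm
from . import diversity as dv
from . import io_formats as io
from . import network as net
from . import nitrogen as nit
from . import ordination as ord_
from . import synthetic as syn

logger = logging.getLogger("sedibiome")

DEFAULT_ENV_PREDICTORS = ["salinity", "NO2-N", "NH4-N", "Fe3+", "TOC", "MC"]
_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    output_dir: str = "sedibiome_out"
    seed: int = 0
    rarefaction_depth: int = 3581
    # either explicit input paths ...
    community_path: Optional[str] = None
    tree_path: Optional[str] = None
    env_path: Optional[str] = None
    coords_path: Optional[str] = None
    ko_path: Optional[str] = None
    pathway_map_path: Optional[str] = None
    # ... or a simulate block (kwargs of synthetic.SimulationConfig)
    simulate: Optional[dict] = None
    null_model: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    env_predictors: list[str] = field(default_factory=lambda: list(DEFAULT_ENV_PREDICTORS))
    max_pcnm_vectors: int = 3
    n_perm: int = 999
    nmds_starts: int = 20
    cca_mode: str = "cca"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            required = {"community": self.community_path, "env": self.env_path,
                        "coords": self.coords_path}
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise PipelineError(
                    f"stage configure: missing input paths {missing} and no "
                    "simulate block")
            for name, p in (("community", self.community_path),
                            ("tree", self.tree_path), ("env", self.env_path),
                            ("coords", self.coords_path), ("ko", self.ko_path)):
                if p is not None and not Path(p).exists():
                    raise PipelineError(f"stage configure: {name} path {p!r} missing")
            if self.tree_path is None and self.null_model:
                raise PipelineError(
                    "stage configure: assembly (null_model) enabled but no tree given")


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _write_df(df: pd.DataFrame, path: Path, index_label: str = "sample") -> None:
    df.rename_axis(index_label).to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns (and writes) the report dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    report: dict[str, Any] = {"version": __version__, "seed": config.seed,
                              "stage_seeds": {}}

    def record(stage: str, *files: Path) -> None:
        manifest.setdefault(stage, []).extend(f.name for f in files)

    def seed_for(stage: str) -> int:
        s = stage_seed(config.seed, stage)
        report["stage_seeds"][stage] = s
        logger.info("stage %s: seed %d", stage, s)
        return s

    def run_stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {name} failed: {exc}") from exc

    # -- inputs -------------------------------------------------------------
    def _inputs():
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", seed_for("simulate"))
            ko_opts = {k: sim_kwargs.pop(k) for k in
                       ("n_kos", "n_affected_kos", "ko_effect")
                       if k in sim_kwargs}
            ds = syn.make_dataset(syn.SimulationConfig(**sim_kwargs), **ko_opts)
            table, tree, env, coords, ko = ds.community, ds.tree, ds.env, ds.coords, ds.ko
            io.write_community_table(table, out / "community.tsv")
            io.write_tree(tree, out / "tree.nwk")
            io.write_sample_metadata(env, coords, out / "env.csv", out / "coords.csv")
            io.write_ko_table(ko, out / "ko.tsv")
            record("inputs", out / "community.tsv", out / "tree.nwk",
                   out / "env.csv", out / "coords.csv", out / "ko.tsv")
        else:
            table = io.load_community_table(config.community_path)
            tree = io.load_tree(config.tree_path) if config.tree_path else None
            env, coords = io.load_sample_metadata(config.env_path, config.coords_path)
            ko = io.load_ko_table(config.ko_path) if config.ko_path else None
        table, env, coords = io.align_samples(table, env, coords)
        if tree is not None:
            io.check_tree_alignment(table, tree)
        return table, tree, env, coords, ko

    table, tree, env, coords, ko = run_stage("inputs", _inputs)
    groups = env["group"].astype(str)
    groups.index = groups.index.map(str)

    # -- rarefaction + diversity -------------------------------------------
    def _diversity():
        rarefied = dv.rarefy(table, config.rarefaction_depth, seed_for("rarefy"))
        alpha = dv.alpha_diversity_table(rarefied)
        bc = dv.bray_curtis(rarefied)
        _write_df(alpha, out / "alpha_diversity.tsv")
        io.write_distance_matrix(bc, out / "bray_curtis.tsv")
        record("diversity", out / "alpha_diversity.tsv", out / "bray_curtis.tsv")
        return rarefied, alpha, bc

    rarefied, alpha, bc = run_stage("diversity", _diversity)
    report["alpha_diversity_mean"] = {
        k: float(v) for k, v in alpha.mean().items()}

    # -- unconstrained ordination ------------------------------------------
    def _ordination():
        pcoa_res = ord_.pcoa(bc, k=2)
        nmds_res = ord_.nmds(bc, k=2, n_starts=config.nmds_starts,
                             seed=seed_for("nmds"))
        newick = ord_.upgma_dendrogram(bc)
        _write_df(pcoa_res.coordinates, out / "pcoa.tsv")
        _write_df(nmds_res.coordinates, out / "nmds.tsv")
        (out / "upgma.nwk").write_text(newick + "\n")
        record("ordination", out / "pcoa.tsv", out / "nmds.tsv", out / "upgma.nwk")
        return pcoa_res, nmds_res

    pcoa_res, nmds_res = run_stage("ordination", _ordination)
    report["pcoa_axis1_percent"] = float(100 * pcoa_res.proportion_explained[0])
    report["nmds_stress"] = nmds_res.stress

    # -- group tests --------------------------------------------------------
    def _tests():
        r, p = ord_.anosim(bc, groups, n_perm=config.n_perm,
                           seed=seed_for("anosim"))
        env_num = env[[c for c in env.columns if c != "group"]].astype(float)
        env_std = (env_num - env_num.mean()) / env_num.std(ddof=1)
        env_d = DistanceMatrix(squareform(pdist(env_std.to_numpy())),
                               ids=[str(s) for s in env.index])
        mr, mp = ord_.mantel(bc, env_d, n_perm=config.n_perm,
                             seed=seed_for("mantel"))
        return (r, p), (mr, mp)

    (anosim_r, anosim_p), (mantel_r, mantel_p) = run_stage("tests", _tests)
    report["anosim"] = {"r": anosim_r, "p": anosim_p}
    report["mantel_env"] = {"r": mantel_r, "p": mantel_p}

    # -- space: geographic distances + PCNM ---------------------------------
    def _space():
        geo = ord_.geo_distances(coords)
        basis = ord_.pcnm(geo)
        io.write_distance_matrix(geo, out / "geo_distances.tsv")
        _write_df(basis.vectors, out / "pcnm.tsv")
        record("space", out / "geo_distances.tsv", out / "pcnm.tsv")
        return geo, basis

    geo, basis = run_stage("space", _space)
    report["pcnm"] = {"n_vectors": int(basis.vectors.shape[1]),
                      "truncation_km": basis.truncation_km}

    # -- constrained ordination + VPA ---------------------------------------
    def _constrained():
        env_pred = env[[c for c in config.env_predictors if c in env.columns]]
        space_pred = basis.vectors.iloc[:, : config.max_pcnm_vectors]
        predictors = pd.concat([env_pred, space_pred], axis=1)
        cca_res = ord_.constrained_ordination(
            rarefied, predictors, mode=config.cca_mode,
            n_perm=config.n_perm, seed=seed_for("constrained"))
        vpa = ord_.variation_partitioning(rarefied, env_pred, space_pred)
        _write_df(cca_res.site_scores, out / f"{config.cca_mode}_sites.tsv")
        _write_df(cca_res.variable_pvalues.to_frame(), out / f"{config.cca_mode}_pvalues.tsv",
                  index_label="variable")
        pd.DataFrame([dataclasses.asdict(vpa)]).to_csv(
            out / "vpa.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        record("constrained", out / f"{config.cca_mode}_sites.tsv",
               out / f"{config.cca_mode}_pvalues.tsv", out / "vpa.tsv")
        return cca_res, vpa

    cca_res, vpa = run_stage("constrained", _constrained)
    report["constrained"] = {
        "mode": cca_res.mode,
        "cumulative_first_two_percent": cca_res.cumulative_first_two,
        "variable_p": {k: float(v) for k, v in cca_res.variable_pvalues.items()},
    }
    report["vpa_percent"] = {
        "pure_env": 100 * vpa.pure_env, "shared": 100 * vpa.shared,
        "pure_space": 100 * vpa.pure_space, "unexplained": 100 * vpa.unexplained,
        "total_explained": 100 * vpa.total_explained,
    }

    # -- assembly null models ------------------------------------------------
    if tree is not None:
        def _assembly():
            nm = asm.NullModelConfig(seed=seed_for("assembly"),
                                     **config.null_model)
            bnti, null_mean, null_sd = asm.beta_nti(rarefied, tree, nm)
            rc = asm.raup_crick_bray(rarefied, nm)
            pairs, partition = asm.classify_assembly(bnti, rc, nm, groups)
            pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
            _write_df(partition, out / "assembly_partition.tsv", index_label="group")
            record("assembly", out / "assembly_pairs.tsv",
                   out / "assembly_partition.tsv")
            return pairs, partition

        pairs, partition = run_stage("assembly", _assembly)
        total = partition.loc["total"]
        report["assembly_total_percent"] = {
            "deterministic": 100 * float(total["frac_deterministic"]),
            "dispersal_limitation_of_stochastic":
                100 * float(total["frac_dispersal_limitation"]),
            "homogenizing_dispersal_of_stochastic":
                100 * float(total["frac_homogenizing_dispersal"]),
            "drift_of_stochastic": 100 * float(total["frac_drift"]),
        }

    # -- co-occurrence network ----------------------------------------------
    def _network():
        ncfg = net.NetworkConfig(module_seed=seed_for("network"), **config.network)
        top = net.select_top_otus(rarefied, min(ncfg.top_n, len(rarefied.otu_ids)))
        graph = net.build_network(top, ncfg)
        metrics = net.network_metrics(graph, module_seed=ncfg.module_seed)
        io.export_network(graph, out / "network.graphml", fmt="graphml")
        pd.DataFrame([dataclasses.asdict(metrics)]).to_csv(
            out / "network_metrics.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        record("network", out / "network.graphml", out / "network_metrics.tsv")
        return metrics

    metrics = run_stage("network", _network)
    report["network"] = dataclasses.asdict(metrics)

    # -- nitrogen profiling ---------------------------------------------------
    if ko is not None:
        def _nitrogen():
            pmap = (nit.load_pathway_map(config.pathway_map_path)
                    if config.pathway_map_path else nit.default_pathway_map())
            rpkm = nit.rpkm_normalize(ko)
            profile = nit.aggregate_nitrogen_pathways(rpkm, pmap, groups=groups)
            kw = nit.kruskal_wallis_groups(profile, level="family", bh_correct=True)
            _write_df(profile.families, out / "nitrogen_families.tsv")
            _write_df(profile.modules, out / "nitrogen_modules.tsv")
            _write_df(kw, out / "nitrogen_kruskal.tsv", index_label="family")
            record("nitrogen", out / "nitrogen_families.tsv",
                   out / "nitrogen_modules.tsv", out / "nitrogen_kruskal.tsv")
            return profile, kw

        profile, kw = run_stage("nitrogen", _nitrogen)
        report["nitrogen"] = {
            "n_families": int(profile.families.shape[1]),
            "n_modules": int(profile.modules.shape[1]),
            "n_significant_families_p05": int((kw["p"] < 0.05).sum()),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
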
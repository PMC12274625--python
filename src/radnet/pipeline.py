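"""End-to-end orchestration of the radiation network analysis.

Stage order: simulate (optional) -> de -> build-net -> rwr -> modules ->
enrich -> disease -> connect.  Every stage writes a TSV under the output
directory and contributes counts to a JSON run report; any failure aborts
with the failing stage named.  A single rng_seed drives all stochastic
stages through named substreams, so two runs with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectivity, diffexpr, disease, enrich, io, mcode, netbuild, propagate
from .simulate import SimulationConfig, generate_all

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "de", "build-net", "rwr", "modules", "enrich",
          "disease", "connect"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's printed settings."""

    out_dir: str = "radnet_out"
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # input paths (used when simulate=False)
    expression_path: str | None = None
    sample_meta_path: str | None = None
    feature_meta_path: str | None = None
    edge_table_paths: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    assoc_path: str | None = None
    category_path: str | None = None
    profiles_path: str | None = None
    # stage parameters
    lfc_thresh: float = 1.0
    p_thresh: float = 0.05
    ppi_conf_min: float = 0.7
    restrict_to_largest_component: bool = True
    r: float = 0.7
    r_is_restart_mass: bool = False
    top_fraction: float = 0.01
    min_module_score: float = 3.0
    enrich_alpha: float = 0.05
    top_k_drugs: int = 10
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.simulate:
            required = [self.expression_path, self.sample_meta_path,
                        self.gmt_path, self.assoc_path, self.category_path,
                        self.profiles_path]
            if any(p is None for p in required) or not self.edge_table_paths:
                raise ValueError("simulate=False requires every input path")
            for p in [*required, *self.edge_table_paths]:
                if p is not None and not Path(p).exists():
                    raise ValueError(f"missing input file: {p}")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulation", {})
    cfg = PipelineConfig(**raw)
    if sim:
        for key in ("confidence_range", "planted_module_sizes"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg.simulation = SimulationConfig(**sim)
    return cfg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages_completed": [], "parameters": _jsonable(cfg),
                    "seed": cfg.rng_seed, "counts": {}}

    stage = "simulate"
    try:
        if cfg.simulate:
            sim_cfg = dataclasses.replace(cfg.simulation, rng_seed=cfg.rng_seed)
            expr, tables, gene_sets, assoc, cat_map, profiles, truth = \
                generate_all(sim_cfg)
            io.write_expression(expr, out / "expression.tsv",
                                out / "sample_meta.tsv", out / "feature_meta.tsv")
            for name, df in tables.items():
                io.write_edge_table(df, out / f"edges_{name}.tsv")
            io.write_gmt(gene_sets, out / "gene_sets.gmt")
            io.write_table(assoc, out / "disease_assoc.tsv")
            io.write_table(cat_map, out / "disease_categories.tsv")
            io.write_table(profiles, out / "reference_profiles.tsv")
            report["counts"]["simulate"] = {
                "features": len(expr.values),
                "true_de": len(truth.true_de_features),
                "edge_rows": int(sum(len(df) for df in tables.values())),
            }
            report["stages_completed"].append(stage)
        else:
            expr = io.read_expression(cfg.expression_path, cfg.sample_meta_path,
                                      cfg.feature_meta_path)
            tables = {Path(p).stem: io.read_edge_table(p)
                      for p in cfg.edge_table_paths}
            gene_sets = io.read_gmt(cfg.gmt_path)
            assoc = io.read_table(cfg.assoc_path)
            cat_map = io.read_table(cfg.category_path)
            profiles = io.read_table(cfg.profiles_path)

        stage = "de"
        de = diffexpr.paired_moderated_t(expr)
        de = diffexpr.call_de(de, lfc_thresh=cfg.lfc_thresh, p_thresh=cfg.p_thresh)
        io.write_table(de, out / "de_results.tsv")
        seeds = de.loc[de["status"] != "not_significant", "feature_id"].tolist()
        report["counts"]["de"] = {
            "features": len(de),
            "de_genes": int(((de.status != "not_significant")
                             & (de.molecule_type == "gene")).sum()),
            "de_mirnas": int(((de.status != "not_significant")
                              & (de.molecule_type == "miRNA")).sum()),
        }
        report["stages_completed"].append(stage)

        stage = "build-net"
        net = netbuild.build_network(tables, ppi_conf_min=cfg.ppi_conf_min)
        if cfg.restrict_to_largest_component:
            net = netbuild.largest_component(net)
        io.write_table(netbuild.network_to_table(net), out / "network.tsv")
        stats = netbuild.degree_stats(net)
        node_types = {n: net.nodes[n]["node_type"] for n in net.nodes}
        type_counts: dict[str, int] = {}
        for t in node_types.values():
            type_counts[t] = type_counts.get(t, 0) + 1
        report["counts"]["build-net"] = {
            "nodes": net.number_of_nodes(), "edges": net.number_of_edges(),
            "per_type": type_counts,
            "degree_slope": stats["slope"], "degree_r2": stats["r2"],
        }
        (out / "network_summary.json").write_text(
            json.dumps(_jsonable(report["counts"]["build-net"]),
                       indent=2, sort_keys=True))
        report["stages_completed"].append(stage)

        stage = "rwr"
        seeds_in_net = sorted(set(seeds) & set(net.nodes))
        dropped = len(set(seeds)) - len(seeds_in_net)
        if dropped:
            logger.warning("%d seed(s) not in the network; dropped", dropped)
        if not seeds_in_net:
            raise ValueError("no differential molecule lies in the network")
        tm = propagate.column_normalize(net)
        dd0 = propagate.seed_vector(tm.node_order, seeds_in_net)
        pcfg = propagate.PropagationConfig(
            r=cfg.r, top_fraction=cfg.top_fraction,
            r_is_restart_mass=cfg.r_is_restart_mass)
        scores = propagate.rwr(tm, dd0, pcfg)
        key = propagate.select_top_fraction(scores, tm.node_order,
                                            cfg.top_fraction, node_types)
        score_df = _score_table(scores, tm.node_order, node_types, key)
        io.write_table(score_df, out / "rwr_scores.tsv")
        report["counts"]["rwr"] = {
            "seeds": len(seeds_in_net), "iterations": scores.iterations,
            "key_molecules": len(key.nodes), "key_per_type": key.type_counts,
        }
        report["stages_completed"].append(stage)

        stage = "modules"
        subnet = propagate.extract_subnetwork(net, key)
        modules = mcode.find_modules(subnet)
        kept = mcode.filter_modules(modules, cfg.min_module_score)
        rows = [(m.id, m.score, n, node_types[n])
                for m in kept for n in m.nodes]
        io.write_table(
            _module_table(rows), out / "modules.tsv")
        report["counts"]["modules"] = {
            "subnetwork_nodes": subnet.number_of_nodes(),
            "subnetwork_edges": subnet.number_of_edges(),
            "modules_found": len(modules), "modules_kept": len(kept),
        }
        report["stages_completed"].append(stage)

        stage = "enrich"
        coding_universe = sorted(n for n, t in node_types.items() if t != "miRNA")
        key_coding = [n for n in key.nodes if node_types[n] != "miRNA"]
        seed_coding = [s for s in seeds_in_net if node_types[s] != "miRNA"]
        key_enr = enrich.enrich_query(key_coding, gene_sets, coding_universe,
                                      p_policy="raw", alpha=cfg.enrich_alpha)
        seed_enr = enrich.enrich_query(seed_coding, gene_sets, coding_universe,
                                       p_policy="raw", alpha=cfg.enrich_alpha)
        io.write_table(key_enr, out / "enrichment_key.tsv")
        io.write_table(seed_enr, out / "enrichment_seeds.tsv")
        mod_enr = enrich.enrich_modules(kept, gene_sets, coding_universe,
                                        node_types, alpha=cfg.enrich_alpha)
        io.write_table(mod_enr, out / "module_enrichment.tsv")
        report["counts"]["enrich"] = {
            "key_breadth": enrich.count_significant(key_enr),
            "seed_breadth": enrich.count_significant(seed_enr),
            "key_modules": int(mod_enr["is_key"].sum()) if len(mod_enr) else 0,
        }
        report["stages_completed"].append(stage)

        stage = "disease"
        annotated = sorted(set(assoc["molecule_id"]) & set(net.nodes))
        dis = disease.disease_enrichment(key.nodes, assoc, annotated,
                                         alpha=cfg.enrich_alpha)
        cats = disease.category_rollup(dis, cat_map, alpha=cfg.enrich_alpha)
        io.write_table(dis, out / "disease_enrichment.tsv")
        io.write_table(cats, out / "disease_categories_enrichment.tsv")
        report["counts"]["disease"] = {
            "diseases_tested": len(dis),
            "diseases_significant": int(dis["significant"].sum()),
            "categories_significant": int(cats["significant"].sum()),
        }
        report["stages_completed"].append(stage)

        stage = "connect"
        sig = connectivity.build_signature(key.nodes, de)
        raw = connectivity.score_compounds(sig, profiles)
        ranked = connectivity.normalize_and_rank(raw, top_k=cfg.top_k_drugs)
        io.write_table(ranked, out / "candidate_drugs.tsv")
        report["counts"]["connect"] = {
            "signature_up": len(sig.up), "signature_down": len(sig.down),
            "compounds_scored": len(raw), "candidates": len(ranked),
        }
        report["stages_completed"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    expected_key = math.floor(cfg.top_fraction * net.number_of_nodes())
    assert report["counts"]["rwr"]["key_molecules"] == expected_key
    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


def _score_table(scores, node_order, node_types, key):
    import pandas as pd
    sel = set(key.nodes)
    order = np.argsort(-scores.scores, kind="stable")
    rows = [(node_order[i], node_types[node_order[i]], scores.scores[i],
             rank + 1, node_order[i] in sel)
            for rank, i in enumerate(order)]
    return pd.DataFrame(rows, columns=["node", "type", "score", "rank", "selected"])


def _module_table(rows):
    import pandas as pd
    return pd.DataFrame(rows, columns=["module_id", "score", "node_id", "node_type"])
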
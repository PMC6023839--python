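"""End-to-end orchestration of the relapse-vs-remission analysis.

Stage order mirrors the analysis workflow: differential expression and the
stable-expression filter on genes and miRNAs; CV filtering; weighted
co-expression modules on all samples; differential co-expression groups in
each condition; hypergeometric merging into condition gene sets;
condition-specific miRNA-TF-gene networks with motif, hub and core
sub-network analysis; pathway over-representation and crosstalk; and the
drug-miRNA candidate network.  Every artefact is written as plain
TSV/GMT/SIF/GraphML/JSON and the run summary records stage counts, the
full parameterisation and file hashes, so a run is reproducible from its
own summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, de, diffcoex, integrate, regnet, wgcna
from .matrix import CONDITIONS, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input paths and every tunable threshold of the pipeline."""

    # inputs (as written by talnet.simulate.write_dataset)
    gene_expression: str = "gene_expression.tsv"
    mirna_expression: str = "mirna_expression.tsv"
    samples: str = "samples.tsv"
    edges: str = "edges.tsv"
    tf_list: str = "tf_list.txt"
    pathways: str = "pathways.gmt"
    drug_mirna: str = "drug_mirna.tsv"

    # thresholds (defaults = the motivating parameterisation)
    fc: float = 1.5               # linear fold-change gate, applied as |log2FC|
    alpha: float = 0.05           # adjusted-p gate for DE calls
    cv: float = 0.10              # CV filter before module detection
    h: float = 0.4                # differential co-expression tree cut
    min_n: int = 30               # minimum differential group size
    pr_active: float = 0.05
    pr_inactive: float = 0.05
    inclusive_thresholds: bool = True
    B: int = 1000                 # resampling draws for pr
    merge_alpha: float = 0.01     # hypergeometric module-merge level
    min_module_size: int = 20
    merge_height: float = 0.2     # eigengene merge cut
    cut_height: float = 0.98      # static TOM tree cut
    r2_cut: float = 0.9           # scale-free topology criterion
    ora_alpha: float = 0.01
    ora_adjust: bool = True
    hub_fraction: float = 0.05

    seed: int = 0
    outdir: str = "results"

    def resolve(self, base: str | Path) -> "RunConfig":
        """Return a copy with input paths resolved against ``base``."""
        out = RunConfig(**asdict(self))
        for name in ("gene_expression", "mirna_expression", "samples",
                     "edges", "tf_list", "pathways", "drug_mirna"):
            p = Path(getattr(out, name))
            if not p.is_absolute():
                setattr(out, name, str(Path(base) / p))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = outdir / name
        _write_tsv(df, path, index=index)
        written.append(path)
        return path

    summary: dict = {"parameters": asdict(config), "stages": {}}
    seeds = np.random.SeedSequence(config.seed).spawn(2)

    # ---- load ------------------------------------------------------------
    gene_em = ExpressionMatrix.from_tsv(config.gene_expression, config.samples)
    mirna_em = ExpressionMatrix.from_tsv(config.mirna_expression, config.samples)
    tf_list = [line.strip() for line in
               Path(config.tf_list).read_text().splitlines() if line.strip()]
    edges = pd.read_csv(config.edges, sep="\t", dtype=str)
    pathway_sets = annotate.read_gmt(config.pathways)
    drug_table = pd.read_csv(config.drug_mirna, sep="\t", dtype=str)

    # ---- differential expression + stable filter -------------------------
    def de_stage(matrix: ExpressionMatrix, label: str) -> pd.DataFrame:
        res = de.call_differential(de.moderated_t_test(matrix),
                                   fc_threshold=config.fc, alpha=config.alpha)
        stable = de.stable_expression_filter(matrix, de.de_features(res))
        res["stable"] = [stable.get(f, "") for f in res.index]
        emit(res, f"de_{label}.tsv", index=True)
        counts = res["call"].value_counts()
        summary["stages"][f"de_{label}"] = {
            "n_features": int(len(res)),
            "n_up": int(counts.get("up", 0)),
            "n_down": int(counts.get("down", 0)),
            "n_ns": int(counts.get("ns", 0)),
            "n_stable": int((res["stable"] != "").sum()),
        }
        return res

    de_genes = de_stage(gene_em, "genes")
    de_mirnas = de_stage(mirna_em, "mirnas")
    dem_list = de.de_features(de_mirnas)

    # ---- CV filter + weighted co-expression ------------------------------
    filtered = de.cv_filter(gene_em, min_cv=config.cv)
    summary["stages"]["cv_filter"] = {"n_kept": filtered.n_features,
                                      "n_input": gene_em.n_features}
    scan = wgcna.soft_threshold_scan(filtered, r2_cut=config.r2_cut)
    emit(scan.to_frame(), "soft_threshold_scan.tsv")
    adj = wgcna.adjacency(filtered, scan.chosen)
    tom = wgcna.tom_similarity(adj)
    modules, unassigned = wgcna.detect_modules(
        tom, filtered, min_module_size=config.min_module_size,
        merge_height=config.merge_height, cut_height=config.cut_height)
    emit(wgcna.assignments_frame(modules, unassigned), "wgcna_modules.tsv")
    summary["stages"]["wgcna"] = {
        "beta": scan.chosen,
        "scale_free_r2": round(scan.r_squared[scan.powers.index(scan.chosen)], 4),
        "reached_r2_cut": scan.reached_cut,
        "n_modules": len(modules),
        "n_assigned_genes": int(sum(m.size for m in modules)),
        "n_unassigned": len(unassigned),
    }

    # ---- differential co-expression --------------------------------------
    groups_by_condition: dict[str, list] = {}
    for condition, seed in zip(CONDITIONS, seeds):
        groups = diffcoex.analyze_condition_specific(
            filtered, condition, h=config.h, min_n=config.min_n,
            pr_active=config.pr_active, pr_inactive=config.pr_inactive,
            B=config.B, seed=np.random.default_rng(seed),
            inclusive=config.inclusive_thresholds)
        emit(diffcoex.groups_frame(groups), f"coxpress_{condition}.tsv")
        selected = [g for g in groups if g.selected]
        groups_by_condition[condition] = [(g.group_id, g.genes)
                                          for g in selected]
        summary["stages"][f"coxpress_{condition}"] = {
            "n_groups": len(groups),
            "n_selected": len(selected),
            "n_selected_genes": int(sum(g.n for g in selected)),
        }

    # ---- hypergeometric merge --------------------------------------------
    gene_sets, merge_table = integrate.merge_modules(
        groups_by_condition, [(m.label, m.genes) for m in modules],
        filtered.feature_ids, alpha=config.merge_alpha)
    emit(merge_table, "merge_table.tsv")
    for condition, gs in gene_sets.items():
        path = outdir / f"{condition}_genes.txt"
        path.write_text("\n".join(gs.genes) + ("\n" if gs.genes else ""))
        written.append(path)
        summary["stages"][f"gene_set_{condition}"] = {
            "n_genes": len(gs.genes),
            "n_assigned_modules": len(gs.assigned_modules),
            "assigned_modules": gs.assigned_modules,
        }

    # ---- regulatory networks ---------------------------------------------
    de_calls = {**de_genes["call"].to_dict(), **de_mirnas["call"].to_dict()}
    stable_flags = {
        **{f: s for f, s in de_genes["stable"].items() if s},
        **{f: s for f, s in de_mirnas["stable"].items() if s},
    }
    gene_universe_all = gene_em.feature_ids
    for condition in CONDITIONS:
        gs = gene_sets[condition]
        net = regnet.build_network(gs.genes, dem_list, tf_list, edges,
                                   de_calls=de_calls,
                                   stable_flags=stable_flags,
                                   condition=condition)
        regnet.write_sif(net, outdir / f"network_{condition}.sif")
        regnet.write_graphml(net, outdir / f"network_{condition}.graphml")
        written += [outdir / f"network_{condition}.sif",
                    outdir / f"network_{condition}.graphml"]
        emit(regnet.node_table(net), f"network_{condition}_nodes.tsv")
        motifs = regnet.enumerate_motifs(net)
        emit(regnet.motifs_frame(motifs), f"motifs_{condition}.tsv")
        hubs = regnet.degree_and_hubs(net, top_fraction=config.hub_fraction)
        emit(hubs, f"hubs_{condition}.tsv")
        motif_counts = {kind: sum(m.motif_type == kind for m in motifs)
                        for kind in (regnet.MIRNA_FFL, regnet.TF_FFL,
                                     regnet.COMPOSITE_FBL)}
        summary["stages"][f"network_{condition}"] = {
            **net.summary(),
            "motifs": motif_counts,
            "n_hubs": int(hubs["hub"].sum()) if len(hubs) else 0,
        }

        # ---- enrichment, crosstalk, core sub-network ---------------------
        enr = annotate.ora_enrichment(gs.genes, pathway_sets,
                                      gene_universe_all,
                                      alpha=config.ora_alpha,
                                      adjust=config.ora_adjust)
        emit(enr, f"enrichment_{condition}.tsv")
        enriched = {row.pathway: pathway_sets[row.pathway]
                    for row in enr.itertuples() if row.enriched}
        graph, crosstalk, proj = annotate.build_crosstalk_graph(
            gs.genes, enriched)
        emit(proj, f"crosstalk_pathways_{condition}.tsv")
        path = outdir / f"crosstalk_genes_{condition}.txt"
        path.write_text("\n".join(crosstalk) + ("\n" if crosstalk else ""))
        written.append(path)
        pathway_hits = sorted({g for members in enriched.values()
                               for g in members if g in set(gs.genes)})
        core = regnet.extract_core_subnetwork(net, pathway_hits)
        regnet.write_sif(core, outdir / f"core_network_{condition}.sif")
        written.append(outdir / f"core_network_{condition}.sif")
        summary["stages"][f"annotation_{condition}"] = {
            "n_enriched_pathways": len(enriched),
            "n_crosstalk_genes": len(crosstalk),
            "core_network": core.summary(),
        }

    # ---- drug-miRNA network ----------------------------------------------
    dem_calls = {m: de_mirnas.loc[m, "call"] for m in dem_list}
    drug_edges = annotate.build_drug_mirna_network(dem_calls, drug_table)
    emit(drug_edges, "drug_mirna_network.tsv")
    summary["stages"]["drug_network"] = {
        "n_edges": int(len(drug_edges)),
        "n_candidates": int(drug_edges["candidate"].sum())
        if len(drug_edges) else 0,
        "n_drugs": int(drug_edges["drug"].nunique()) if len(drug_edges) else 0,
    }

    # ---- summary ----------------------------------------------------------
    summary["files"] = {p.name: _sha256(p) for p in sorted(set(written))}
    summary_path = outdir / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", summary_path)
    return summary
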
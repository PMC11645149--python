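"""End-to-end orchestration: simulate (or load) -> DEG -> triage -> network
-> AUC refinement -> signature scoring -> survival, from a single config,
with a machine-readable run manifest.

The manifest records the config snapshot, seeds, per-stage set and network
sizes, and per-stage wall-clock; every reported size is asserted against
the artifact it describes at write time, so the manifest can be trusted to
re-run the pipeline bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from cocultnet import differential, io, network as net_mod, signature, survival, synthetic, triage

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "simulate": {
        "n_genes": 2000,
        "n_transfer": 150,
        "n_intrinsic": 80,
        "n_cm": 10,
        "reps_per_group": 3,
    },
    "thresholds": {
        "lfc_min": 2.0,
        "adj_p_max": 0.05,
        "min_confidence": 0.4,
        "hops": 2,
        "auc_threshold": 0.85,
        "de_engine": "moderated",
        "normalization": "median_of_ratios",
    },
    "network": {"n_extra_nodes": 2500, "inter_layer_edges": 300},
    "refine": {"n_datasets": 2},
    "survival": {"n_patients": 200, "method": "step"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config must provide either 'simulate' or 'inputs'")
    if "inputs" in cfg:
        req = ("expression", "annotations")
        for key in req:
            if key not in cfg["inputs"]:
                raise ValueError(f"config inputs missing key {key!r}")
        if cfg.get("refine", {}).get("n_datasets", 0) and "simulate" not in cfg and "validation" not in cfg["inputs"]:
            raise ValueError("refinement requested without validation datasets")
    return cfg


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    With a ``simulate`` block the fixtures are generated (truth sidecar
    written but never read back); with an ``inputs`` block the named files
    are loaded instead. Any stage failure propagates after the partial
    manifest is flushed.
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "seed": cfg["seed"], "stages": {}, "sizes": {}}
    log_lines: list[str] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception:
                io.write_manifest(manifest, outdir / "manifest.json")
                raise
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            log_lines.append(f"{name}\t{dt:.3f}s")
            return result

        return wrap

    thr = cfg["thresholds"]
    sim_cfg = cfg.get("simulate")

    # --- stage: inputs -----------------------------------------------------
    if sim_cfg is not None and "inputs" not in cfg:
        truth = synthetic.default_truth(
            n_genes=sim_cfg["n_genes"],
            n_transfer=sim_cfg["n_transfer"],
            n_intrinsic=sim_cfg["n_intrinsic"],
            n_cm=sim_cfg["n_cm"],
            seed=cfg["seed"],
        )

        @stage("simulate")
        def _sim():
            expr = synthetic.simulate_coculture(
                truth, n_genes=sim_cfg["n_genes"], reps_per_group=sim_cfg["reps_per_group"]
            )
            protein = synthetic.simulate_proteome(expr, truth)
            edges = synthetic.simulate_network(
                truth,
                n_extra_nodes=cfg["network"]["n_extra_nodes"],
                inter_layer_edges=cfg["network"]["inter_layer_edges"],
            )
            truth.to_json(outdir / "truth_sidecar.json")
            io.write_expression(expr, outdir / "expression.tsv", outdir / "annotations.tsv")
            io.write_tsv(protein, outdir / "protein_de.tsv")
            io.write_edge_table(edges, outdir / "edges.tsv")
            return expr, protein, edges, truth

        expr, protein_table, edge_table, truth = _sim
    else:
        truth = None

        @stage("load")
        def _load():
            paths = cfg["inputs"]
            expr = io.read_expression(paths["expression"], paths["annotations"])
            protein = pd.read_csv(paths["protein"], sep="\t") if "protein" in paths else None
            edges = (
                io.read_edge_table(paths["edges"], thr["min_confidence"])
                if "edges" in paths
                else None
            )
            manifest["input_digests"] = {k: _digest(Path(v)) for k, v in paths.items()}
            return expr, protein, edges

        expr, protein_table, edge_table = _load

    # --- stage: differential expression ------------------------------------
    @stage("deg")
    def _deg():
        libs = (
            differential.effective_library_sizes(expr)
            if thr["normalization"] == "median_of_ratios"
            else None
        )
        log2 = differential.normalize_log2cpm(expr, library_sizes=libs)
        engine = thr["de_engine"]
        donor = expr.samples_where(condition="donor_mono")
        rmono = expr.samples_where(condition="recipient_mono")
        cc = expr.samples_where(condition="recipient_cc")
        cm = expr.samples_where(condition="recipient_cm")
        de_donor = differential.de_test(log2, rmono, donor, engine)  # up = donor-high
        de_cc = differential.de_test(log2, rmono, cc, engine)  # up = contact-induced
        de_cm = differential.de_test(log2, rmono, cm, engine)
        for name, res in (("donor_vs_mono", de_donor), ("cc_vs_mono", de_cc), ("cm_vs_mono", de_cm)):
            res.write_tsv(outdir / f"de_{name}.tsv", thr["lfc_min"], thr["adj_p_max"])
        return log2, de_donor, de_cc, de_cm

    log2, de_donor, de_cc, de_cm = _deg

    # --- stage: triage ------------------------------------------------------
    @stage("triage")
    def _triage():
        msc_high = triage.build_msc_high_catalog(de_donor, thr["lfc_min"], thr["adj_p_max"])
        rna_up_cc = differential.filter_deg(de_cc, thr["lfc_min"], thr["adj_p_max"], "up", "rna_up_cc")
        rna_up_cm = differential.filter_deg(de_cm, thr["lfc_min"], thr["adj_p_max"], "up", "rna_up_cm")
        if protein_table is not None and len(protein_table):
            prot_up = io.GeneSet(
                "protein_up_cc",
                frozenset(
                    protein_table.loc[
                        (protein_table["log2_fc"] >= thr["lfc_min"])
                        & (protein_table["adj_p"] < thr["adj_p_max"]),
                        "gene",
                    ]
                ),
            )
        else:
            prot_up = io.GeneSet("protein_up_cc", frozenset())
        up_cc, prov = triage.union_evidence(rna_up_cc, prot_up)
        part = triage.classify_induced(up_cc, rna_up_cm, msc_high, prov)
        overlap = triage.cross_platform_overlap(rna_up_cc, prot_up)
        part.export(outdir / "triage.gmt", outdir / "triage.tsv")
        sizes = part.sizes()
        sizes["rna_protein_overlap"] = len(overlap)
        assert sizes["borrowed"] == len(part.borrowed)
        manifest["sizes"].update(sizes)
        return part, overlap

    partition, overlap_sig = _triage

    # --- stage: network -----------------------------------------------------
    if edge_table is not None and len(overlap_sig.genes) > 0:

        @stage("network")
        def _network():
            seeds = overlap_sig if len(overlap_sig.genes) else partition.borrowed
            net = net_mod.build_seed_network(seeds, edge_table, thr["min_confidence"], thr["hops"])
            net, rep_b = net_mod.project_layer(net, partition.borrowed, "borrowed")
            net, rep_i = net_mod.project_layer(net, partition.intrinsic, "intrinsic")
            test = net_mod.layer_connectivity_test(net)
            summary = net_mod.export_network(net, outdir)
            summary["connectivity"] = {
                "universe_n": test.universe_n,
                "layer1_k": test.layer1_k,
                "layer2_n": test.layer2_n,
                "overlap_k": test.overlap_k,
                "p_value": test.p_value,
            }
            assert summary["n_nodes"] == net.n_nodes()
            manifest["sizes"]["network"] = summary
            return net, test

        network_obj, conn_test = _network
    else:
        logger.info("network stage skipped (no edge table or empty seed set)")
        network_obj = conn_test = None

    # --- stage: refinement ---------------------------------------------------
    n_val = cfg.get("refine", {}).get("n_datasets", 0)
    if truth is not None and n_val:

        @stage("refine")
        def _refine():
            datasets = [
                synthetic.simulate_validation_dataset(
                    truth,
                    n_genes=sim_cfg["n_genes"],
                    reps_per_group=sim_cfg["reps_per_group"],
                    seed=cfg["seed"] + 101 + i,
                )
                for i in range(n_val)
            ]
            refined, auc_tab = signature.refine_by_auc(
                partition.borrowed, datasets, thr["auc_threshold"]
            )
            io.write_tsv(auc_tab, outdir / "auc_table.tsv")
            io.write_gmt([refined], outdir / "refined.gmt")
            manifest["sizes"]["refined"] = len(refined)
            return refined

        refined_sig = _refine
    else:
        refined_sig = None

    # --- stage: signature scoring --------------------------------------------
    @stage("score")
    def _score():
        sig = overlap_sig if len(overlap_sig.genes) else partition.borrowed
        scores = signature.composite_score(log2, sig)
        stats = signature.anova_tukey(scores)
        clust = signature.hierarchical_cluster(log2, sig)
        io.write_tsv(scores.table.reset_index(names="sample"), outdir / "scores.tsv")
        (outdir / "dendrogram.nwk").write_text(clust["newick"] + "\n")
        manifest["sizes"]["signature_n"] = len(sig)
        return scores, stats, clust

    scores, group_stats, clustering = _score
    manifest["anova"] = {"F": group_stats["F"], "p": group_stats["p"]}

    # --- stage: survival -------------------------------------------------------
    surv_cfg = cfg.get("survival")
    if surv_cfg:

        @stage("survival")
        def _surv():
            sig = refined_sig if refined_sig and len(refined_sig.genes) else overlap_sig
            if truth is not None:
                cohort, _state = synthetic.simulate_cohort(
                    truth, sig, n_patients=surv_cfg["n_patients"]
                )
                io.write_cohort(cohort, outdir / "cohort.csv")
            else:
                cohort = io.read_cohort(cfg["inputs"]["cohort"])
            strat = survival.stratified_survival(cohort, sig, surv_cfg.get("method", "step"))
            out = {
                "threshold": strat["threshold"],
                "group_sizes": strat["group_sizes"],
                "logrank": strat["logrank"],
            }
            (outdir / "survival.json").write_text(json.dumps(out, indent=2) + "\n")
            return out

        manifest["survival"] = _surv
    else:
        logger.info("survival stage skipped (no survival config)")

    io.write_manifest(manifest, outdir / "manifest.json")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# printed-count verification against user-supplied supplementary tables


VERIFY_TARGETS = (
    "denominator",
    "borrowed",
    "intrinsic",
    "cm_unique",
    "rna_protein_overlap",
    "network_nodes",
    "borrowed_layer",
    "intrinsic_layer",
    "shared_nodes",
    "borrowed_tagged",
    "intrinsic_tagged",
)


def _read_gene_list(path: Path) -> frozenset[str]:
    return frozenset(
        line.strip().upper() for line in path.read_text().splitlines() if line.strip()
    )


def verify_supplementary(counts_config: dict, tables: dict) -> pd.DataFrame:
    """Recompute printed set/network sizes from supplementary tables.

    ``counts_config`` maps target name -> expected count;
    ``tables`` maps table name -> path. Gene-list tables (one symbol per
    line): msc_high, up_cc_rna, up_cc_protein, up_cm. Network tables:
    nodes (TSV: node, layer, is_seed), edges (TSV: node_a, node_b,
    confidence). Each target is recomputed via the triage/network set
    operations when its tables are present, else marked not evaluable.
    """
    paths = {k: Path(v) for k, v in tables.items() if v is not None}
    observed: dict[str, int] = {}

    have_sets = all(k in paths for k in ("msc_high", "up_cc_rna", "up_cc_protein", "up_cm"))
    if have_sets:
        msc = io.GeneSet("msc_high", _read_gene_list(paths["msc_high"]))
        rna = io.GeneSet("up_cc_rna", _read_gene_list(paths["up_cc_rna"]))
        prot = io.GeneSet("up_cc_protein", _read_gene_list(paths["up_cc_protein"]))
        cm = io.GeneSet("up_cm", _read_gene_list(paths["up_cm"]))
        up_cc, prov = triage.union_evidence(rna, prot)
        part = triage.classify_induced(up_cc, cm, msc, prov)
        observed["denominator"] = len(msc)
        observed["borrowed"] = len(part.borrowed)
        observed["intrinsic"] = len(part.intrinsic)
        observed["cm_unique"] = len(part.cm_unique)
        observed["rna_protein_overlap"] = len(triage.cross_platform_overlap(rna, prot))

    if "nodes" in paths:
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        observed["network_nodes"] = len(nodes)
        observed["borrowed_tagged"] = int(nodes["layer"].isin(["borrowed", "both"]).sum())
        observed["intrinsic_tagged"] = int(nodes["layer"].isin(["intrinsic", "both"]).sum())
        if "edges" in paths:
            import networkx as nx

            edges = pd.read_csv(paths["edges"], sep="\t")
            g = nx.Graph()
            g.add_nodes_from(nodes["node"])
            g.add_edges_from(zip(edges["node_a"], edges["node_b"]))
            hoods = {}
            for layer in ("borrowed", "intrinsic"):
                members = set(nodes.loc[nodes["layer"].isin([layer, "both"]), "node"])
                hood = set(members)
                for n in members:
                    hood.update(g.neighbors(n))
                hoods[layer] = hood
            observed["borrowed_layer"] = len(hoods["borrowed"])
            observed["intrinsic_layer"] = len(hoods["intrinsic"])
            observed["shared_nodes"] = len(hoods["borrowed"] & hoods["intrinsic"])

    rows = []
    for target in VERIFY_TARGETS:
        if target not in counts_config:
            continue
        expected = counts_config[target]
        if target in observed:
            rows.append(
                {
                    "target": target,
                    "expected": expected,
                    "observed": observed[target],
                    "status": "match" if observed[target] == expected else "mismatch",
                }
            )
        else:
            rows.append(
                {"target": target, "expected": expected, "observed": None, "status": "not evaluable"}
            )
    return pd.DataFrame(rows, columns=["target", "expected", "observed", "status"])
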
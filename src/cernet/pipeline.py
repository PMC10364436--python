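"""End-to-end orchestration: simulate -> filter -> DE -> co-expression ->
regulatory pairs -> ceRNA triads -> enrichment, with a machine-readable run
summary.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so stages can be re-run in isolation.  The
run summary JSON holds per-stage counts, the config echo and the seed, and
is byte-identical across repeated runs with the same config and seed; stage
wall-times go to a separate ``timings.json`` so the summary stays
deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cerna as cerna_mod
from . import coexpression as coex
from . import diffexpr, enrichment, regnet
from . import simulate as sim
from .io import (Config, export_network, filter_low_expression, read_annotation,
                 read_counts, read_sample_table, read_targets, read_term_map,
                 write_annotation, write_counts, write_sample_table,
                 write_targets)

logger = logging.getLogger("cernet")

STAGES = ("simulate", "filter", "de", "wgcna", "regnet", "cerna", "enrich")


def stage_seed(seed: int, stage: str) -> int:
    """Stable child seed (< 2**31) for a named stage."""
    ss = np.random.SeedSequence([seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_all(config: Config, outdir: str | Path | None = None) -> dict:
    """Execute every stage in order, writing all intermediate tables.

    Returns the run summary dict (also written to ``summary.json``).
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict = {}
    summary: dict = {"seed": config.seed, "config": asdict(config), "stages": {}}

    try:
        t0 = time.perf_counter()
        cm, samples, truth, ann, targets, term_map = _load_or_simulate(config, outdir)
        timings["simulate"] = time.perf_counter() - t0

        # --- low-expression filter, per RNA class
        t0 = time.perf_counter()
        kept = []
        for cls in ("lncRNA", "circRNA", "miRNA", "mRNA"):
            sub = filter_low_expression(cm.subset_class(cls),
                                        config.low_expression_zero_fraction)
            kept.extend(sub.feature_ids)
        cm_f = cm.subset_features([f for f in cm.feature_ids if f in set(kept)])
        write_counts(cm_f, outdir / "counts_filtered.tsv")
        summary["stages"]["filter"] = {
            "features_in": int(cm.counts.shape[0]),
            "features_retained": int(cm_f.counts.shape[0]),
            "retained_per_class": {cls: int((cm_f.rna_class == cls).sum())
                                   for cls in ("lncRNA", "circRNA", "miRNA", "mRNA")},
        }
        timings["filter"] = time.perf_counter() - t0

        # --- differential expression
        t0 = time.perf_counter()
        nf = diffexpr.tmm_factors(cm_f)
        nf.to_csv(outdir / "norm_factors.tsv", sep="\t", index=False)
        de = diffexpr.call_de(cm_f, samples, config=config)
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
        de_counts = {}
        for cls in ("lncRNA", "circRNA", "miRNA", "mRNA"):
            sub = de[de["rna_class"] == cls]
            de_counts[cls] = {
                "union_de": int(sub.loc[sub["union_de"], "feature_id"].nunique()),
                "per_contrast": {int(t): int((grp["direction"] != "ns").sum())
                                 for t, grp in sub.groupby("contrast")},
            }
        summary["stages"]["de"] = de_counts
        timings["de"] = time.perf_counter() - t0

        # --- WGCNA on union-DE mRNAs (log2(FPKM + 1))
        t0 = time.perf_counter()
        de_mrna = diffexpr.union_de_ids(de, "mRNA")
        expr_all = np.log2(diffexpr.fpkm(cm_f) + 1.0)
        expr_all.to_csv(outdir / "log2_fpkm.tsv", sep="\t")
        result = coex.run_wgcna(expr_all.loc[de_mrna], samples, config)
        labels_df = result.labels.rename("module").to_frame()
        labels_df["color"] = [coex.module_color(m) for m in result.labels]
        labels_df.to_csv(outdir / "modules.tsv", sep="\t")
        result.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
        result.gs.to_csv(outdir / "gene_significance.tsv", sep="\t")
        result.mm.to_csv(outdir / "module_membership.tsv", sep="\t")
        result.hub_genes.to_csv(outdir / "hub_genes.tsv", sep="\t", index=False)
        summary["stages"]["wgcna"] = {
            "n_genes": int(len(result.labels)),
            "soft_power": int(result.soft_power),
            "removed_samples": result.removed_samples,
            "module_sizes": {int(m): int((result.labels == m).sum())
                             for m in sorted(set(result.labels))},
            "key_modules": {int(t): int(m) for t, m in result.key_modules.items()},
            "n_hub_genes": int(len(result.hub_genes)),
        }
        timings["wgcna"] = time.perf_counter() - t0

        # --- regulatory pairs (on the outlier-pruned sample set)
        t0 = time.perf_counter()
        expr = expr_all.drop(columns=result.removed_samples)
        de_lnc = diffexpr.union_de_ids(de, "lncRNA")
        de_circ = diffexpr.union_de_ids(de, "circRNA")
        hubs = set(result.hub_genes["gene_id"])
        cis = regnet.cis_pairs(ann, de_lnc, de_circ, de_mrna, expr, config)
        trans = regnet.trans_pairs(de_lnc, de_mrna, expr, config, ann)
        parent = regnet.parent_pairs(ann, de_circ, expr)
        tables = [regnet.core_filter(t, hubs) for t in (cis, trans, parent)]
        tables = [t for t in tables if len(t)] or tables[:1]
        pairs = pd.concat(tables, ignore_index=True)
        pairs.to_csv(outdir / "pair_table.tsv", sep="\t", index=False)
        core = pairs[pairs["is_core"]]
        _export_pair_networks(core, cm_f.rna_class, result.labels, outdir)
        summary["stages"]["regnet"] = {
            "cis_pairs": int((pairs["pair_type"] == "cis").sum()),
            "trans_pairs": int((pairs["pair_type"] == "trans").sum()),
            "parent_pairs": int((pairs["pair_type"] == "parent").sum()),
            "core_cis_pairs": int((core["pair_type"] == "cis").sum()),
            "core_trans_pairs": int((core["pair_type"] == "trans").sum()),
            "core_parent_pairs": int((core["pair_type"] == "parent").sum()),
        }
        timings["regnet"] = time.perf_counter() - t0

        # --- ceRNA triads
        t0 = time.perf_counter()
        cand = cerna_mod.candidate_triads(targets, de, hubs, config)
        triads = cerna_mod.filter_triads(cand, expr, config)
        triads.to_csv(outdir / "triad_table.tsv", sep="\t", index=False)
        networks = cerna_mod.build_core_networks(
            triads, cm_f.rna_class, result.labels,
            out_prefix=str(outdir / "cerna_core"))
        summary["stages"]["cerna"] = {
            "candidates": int(len(cand)),
            "triads": int(len(triads)),
            "per_class": {cls: networks[cls]["summary"] for cls in networks},
        }
        timings["cerna"] = time.perf_counter() - t0

        # --- enrichment (universe: filtered mRNAs)
        t0 = time.perf_counter()
        universe = cm_f.rna_class.index[cm_f.rna_class == "mRNA"]
        queries = {
            "hub_genes": hubs,
            "cis_targets": set(cis["target_id"]),
            "trans_targets": set(trans["target_id"]),
            "parent_genes": set(parent["target_id"]),
        }
        enrich_summary = {}
        for name, query in queries.items():
            table = enrichment.enrich(query & set(universe), term_map, universe, config)
            table.to_csv(outdir / f"enrich_{name}.tsv", sep="\t", index=False)
            enrich_summary[name] = {
                "query_size": int(len(query & set(universe))),
                "terms_tested": int(len(table)),
                "terms_significant": int(table["significant"].sum()) if len(table) else 0,
            }
        summary["stages"]["enrich"] = enrich_summary
        timings["enrich"] = time.perf_counter() - t0
    except Exception as exc:  # tag partial outputs and re-raise with stage name
        stage = _current_stage(timings)
        for f in sorted(outdir.glob("*.tsv")):
            f.rename(f.with_suffix(f.suffix + ".partial"))
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    # normalize to JSON-safe types/keys so the returned dict equals the file
    summary = json.loads(json.dumps(summary, sort_keys=True))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "timings.json", "w") as fh:
        json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=1,
                  sort_keys=True)
    return summary


def _current_stage(timings: dict) -> str:
    done = set(timings)
    for stage in STAGES:
        if stage not in done:
            return stage
    return STAGES[-1]


def _load_or_simulate(config: Config, outdir: Path):
    if config.simulate:
        params = sim.SimParams(seed=stage_seed(config.seed, "simulate"),
                               **config.sim_overrides)
        cm, samples, truth, ann = sim.simulate_counts(params)
        targets = sim.simulate_targets(truth, params)
        term_map = sim.simulate_term_map(truth)
        write_counts(cm, outdir / "counts.tsv")
        write_sample_table(samples, outdir / "samples.tsv")
        write_annotation(ann, outdir / "annotation.tsv")
        write_targets(targets, outdir / "targets.tsv")
        term_map.to_csv(outdir / "term_map.tsv", sep="\t", index=False)
        truth.to_json(outdir / "truth.json")
        return cm, samples, truth, ann, targets, term_map
    for field in ("counts_path", "samples_path", "annotation_path", "targets_path",
                  "term_map_path"):
        if getattr(config, field) is None:
            raise ValueError(f"config field '{field}' is required when simulate=false")
    ann = read_annotation(config.annotation_path)
    cm = read_counts(config.counts_path, ann)
    samples = read_sample_table(config.samples_path)
    targets = read_targets(config.targets_path, ann)
    term_map = read_term_map(config.term_map_path)
    return cm, samples, None, ann, targets, term_map


def _export_pair_networks(core: pd.DataFrame, rna_class: pd.Series,
                          labels: pd.Series, outdir: Path) -> None:
    for pair_type in ("cis", "trans"):
        sub = core[core["pair_type"] == pair_type]
        edges = sub.rename(columns={"regulator_id": "source", "target_id": "target"})
        edges = edges[["source", "target"]].copy()
        edges["interaction"] = pair_type
        node_ids = sorted(set(edges["source"]) | set(edges["target"]))
        nodes = pd.DataFrame({"id": node_ids})
        nodes["rna_class"] = [rna_class.get(i, "") for i in node_ids]
        nodes["module"] = [int(labels.get(i, 0)) for i in node_ids]
        export_network(nodes, edges, outdir / f"core_{pair_type}")
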
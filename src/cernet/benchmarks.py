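"""Named benchmark configurations and recovery scoring.

Each benchmark fixes one generator configuration and the truth-based score
for one pipeline stage:

* ``de_benchmark`` — default generator; recall / empirical FDR of union-DE
  calls against the planted DE features.
* ``module_benchmark`` — default generator, mRNAs only (4 planted modules of
  100 genes + 600 unplanted genes, 30 samples); adjusted Rand index of the
  recovered labels against the planted assignment.
* ``hub_benchmark`` — low-noise variant (dispersion 0.02, module latent sd
  0.3, no isolated DE mRNAs) so the planted module members are the
  unambiguous hub truth; precision / recall of the selected hub set.
* ``cis_benchmark`` — default generator with truth DE sets; recall of the
  planted cis pairs and the count of reported pairs outside the genomic
  window.
* ``triad_benchmark`` — the ceRNA triad filter scored on planted triads
  mixed with declared-target decoy candidates whose expression is random;
  recall and false discovery proportion.

Every function takes a seed so the whole battery can be replayed under a
different random stream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import cerna as cerna_mod
from . import coexpression as coex
from . import diffexpr, regnet
from .io import Config
from .simulate import SimParams, simulate_counts


def de_benchmark(seed: int = 0) -> dict:
    """Union-DE recall and empirical FDR against the planted truth."""
    params = SimParams(seed=seed)
    cm, samples, truth, _ = simulate_counts(params)
    cm = _filter(cm)
    de = diffexpr.call_de(cm, samples)
    called = set(de.loc[de["union_de"], "feature_id"])
    true_de = set(truth.union_de) & set(cm.feature_ids)
    tp = len(called & true_de)
    return {
        "recall": tp / len(true_de),
        "fdr": (len(called) - tp) / max(1, len(called)),
        "n_called": len(called),
        "n_true": len(true_de),
    }


def module_benchmark(seed: int = 0) -> dict:
    """Adjusted Rand index of module recovery on the raw mRNA matrix."""
    params = SimParams(seed=seed)
    cm, samples, truth, _ = simulate_counts(params)
    expr = np.log2(diffexpr.fpkm(cm.subset_class("mRNA")) + 1.0)
    result = coex.run_wgcna(expr, samples, Config())
    planted = truth.module_truth.reindex(result.labels.index).fillna(0).astype(int)
    return {
        "ari": float(adjusted_rand_score(planted, result.labels)),
        "n_modules": int(result.labels.max()),
        "soft_power": result.soft_power,
    }


def hub_params(seed: int = 0) -> SimParams:
    """Low-noise configuration isolating the hub-selection stage.

    Only the module program is planted (no isolated DE mRNAs, no ceRNA
    triads), so the planted members are exactly the genes that satisfy the
    hub definition in the noiseless limit.
    """
    iso = {"mRNA": 0, "lncRNA": 40, "circRNA": 10, "miRNA": 20}
    return SimParams(seed=seed, dispersion=0.02, module_latent_sd=0.3,
                     n_isolated_de=iso, n_lnc_triads=0, n_circ_triads=0,
                     n_triad_mirnas=0, n_cis_pairs=0)


def hub_benchmark(seed: int = 0) -> dict:
    """Hub-gene precision/recall at low noise; truth = planted members."""
    params = hub_params(seed)
    cm, samples, truth, _ = simulate_counts(params)
    expr = np.log2(diffexpr.fpkm(cm.subset_class("mRNA")) + 1.0)
    result = coex.run_wgcna(expr, samples, Config())
    hubs = set(result.hub_genes["gene_id"])
    members = set(truth.module_truth.index[truth.module_truth > 0])
    tp = len(hubs & members)
    return {
        "recall": tp / len(members),
        "precision": tp / max(1, len(hubs)),
        "n_hubs": len(hubs),
    }


def cis_benchmark(seed: int = 0) -> dict:
    """Recall of planted cis pairs; window violations among reported pairs."""
    params = SimParams(seed=seed)
    cm, samples, truth, ann = simulate_counts(params)
    config = Config()
    expr = np.log2(diffexpr.fpkm(cm) + 1.0)
    de_truth = truth.de_truth
    union = de_truth.index[(de_truth != 0).any(axis=1)]
    cls = cm.rna_class
    de_lnc = [f for f in union if cls[f] == "lncRNA"]
    de_circ = [f for f in union if cls[f] == "circRNA"]
    de_mrna = [f for f in union if cls[f] == "mRNA"]
    pairs = regnet.cis_pairs(ann, de_lnc, de_circ, de_mrna, expr, config)
    lnc_pairs = {(a, b) for a, b, c in zip(pairs["regulator_id"], pairs["target_id"],
                                           pairs["regulator_id"])
                 if cls[a] == "lncRNA"}
    tp = len(lnc_pairs & truth.cis_truth)
    idx = ann.set_index("feature_id")
    violations = 0
    for a, b in zip(pairs["regulator_id"], pairs["target_id"]):
        ra, rb = idx.loc[a], idx.loc[b]
        gap = regnet.interval_gap(ra["start"], ra["end"], rb["start"], rb["end"])
        if ra["chromosome"] != rb["chromosome"] or gap > config.cis_window_bp:
            violations += 1
    return {
        "recall": tp / len(truth.cis_truth),
        "out_of_window": violations,
        "n_pairs": int(len(pairs)),
    }


def triad_benchmark(seed: int = 0, n_decoys: int = 5000) -> dict:
    """ceRNA filter recall/FDP: planted triads among random-expression decoys.

    Decoy candidates pair the planted DE miRNAs, ceRNAs and module mRNAs at
    random with *unplanted* (pure-noise) features standing in for their
    expression partners, emulating spurious declared-target links; a decoy
    passing the sign-constrained Spearman filter is a false discovery.
    """
    params = SimParams(seed=seed)
    cm, samples, truth, _ = simulate_counts(params)
    expr = np.log2(diffexpr.fpkm(cm) + 1.0)
    rng = np.random.default_rng(seed + 977)

    planted = sorted(truth.triad_truth)
    cls = cm.rna_class
    null_cerna = [f for f in cm.feature_ids
                  if cls[f] in ("lncRNA", "circRNA")
                  and not (truth.de_truth.loc[f] != 0).any()]
    null_mirna = [f for f in cm.feature_ids if cls[f] == "miRNA"
                  and not (truth.de_truth.loc[f] != 0).any()]
    null_mrna = [f for f in cm.feature_ids if cls[f] == "mRNA"
                 and truth.module_truth[f] == 0
                 and not (truth.de_truth.loc[f] != 0).any()]
    decoys = set()
    while len(decoys) < n_decoys:
        decoys.add((str(rng.choice(null_cerna)), str(rng.choice(null_mirna)),
                    str(rng.choice(null_mrna))))
    decoys = sorted(decoys)
    cand = pd.DataFrame(planted + decoys, columns=["cerna_id", "mirna_id", "mrna_id"])
    kept = cerna_mod.filter_triads(cand, expr, Config())
    kept_set = set(map(tuple, kept[["cerna_id", "mirna_id", "mrna_id"]].itertuples(index=False)))
    tp = len(kept_set & set(map(tuple, planted)))
    return {
        "recall": tp / len(planted),
        "fdp": (len(kept_set) - tp) / max(1, len(kept_set)),
        "n_kept": len(kept_set),
    }


def _filter(cm):
    from .io import filter_low_expression
    return filter_low_expression(cm)
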
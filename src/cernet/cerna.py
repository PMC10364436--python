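"""ceRNA triad inference: shared miRNA targets + sign-constrained Spearman.

A candidate triad (ceRNA, miRNA, mRNA) requires a DE miRNA with declared
binding to both a DE lncRNA/circRNA and a hub-gene mRNA.  The competing
endogenous RNA hypothesis predicts that the ceRNA and the mRNA are
positively correlated while the miRNA is negatively correlated with both;
candidates are kept when all three Spearman coefficients carry the right
sign and each correlation test is significant (p < 0.05 by default).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import Config, export_network

TRIAD_COLUMNS = ["cerna_id", "mirna_id", "mrna_id", "rho_cm", "rho_mic", "rho_mim",
                 "p_cm", "p_mic", "p_mim"]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value: two-sided t approximation for n > 10, exhaustive permutation
    over all orderings for n <= 10.  Constant input gives (0, 1) with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5 or len(y) != n:
        raise ValueError("need >= 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector in spearman; returning rho=0, p=1",
                      stacklevel=2)
        return 0.0, 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > 10:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    else:
        p = _exact_permutation_p(rx, ry, rho)
    return rho, min(1.0, p)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = len(rx)
    zx = (rx - rx.mean()) / rx.std(ddof=0)
    zy = (ry - ry.mean()) / ry.std(ddof=0)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        rho = float(zx @ zy[list(perm)]) / n
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def combine_target_sources(targets: pd.DataFrame, how: str = "union") -> pd.DataFrame:
    """Collapse the per-source target rows into unique (miRNA, target) links."""
    if how == "union":
        return targets[["mirna_id", "target_id"]].drop_duplicates()
    if how == "intersection":
        by_pair = targets.groupby(["mirna_id", "target_id"])["source"].nunique()
        keep = by_pair[by_pair >= 2].index
        return pd.DataFrame(list(keep), columns=["mirna_id", "target_id"])
    raise ValueError(f"unknown combination rule: {how}")


def candidate_triads(targets: pd.DataFrame, de: pd.DataFrame, hub_genes,
                     config: Config | None = None) -> pd.DataFrame:
    """All (ceRNA, miRNA, mRNA) triples sharing a DE miRNA's binding sites.

    ``de`` is the long-format DE table; the ceRNA must be a union-DE
    lncRNA/circRNA, the miRNA union-DE, and the mRNA a hub gene.  Both the
    (miRNA, ceRNA) and (miRNA, mRNA) links must appear in the target table
    (sources combined per config).
    """
    config = config or Config()
    links = combine_target_sources(targets, config.target_combine)
    de_union = de[de["union_de"]]
    de_mirna = set(de_union.loc[de_union["rna_class"] == "miRNA", "feature_id"])
    de_cerna = set(de_union.loc[de_union["rna_class"].isin(["lncRNA", "circRNA"]),
                                "feature_id"])
    hubs = set(hub_genes)
    links = links[links["mirna_id"].isin(de_mirna)]
    rows = []
    for mirna, sub in links.groupby("mirna_id"):
        tgts = set(sub["target_id"])
        cernas = sorted(tgts & de_cerna)
        mrnas = sorted(tgts & hubs)
        for c in cernas:
            for g in mrnas:
                rows.append((c, mirna, g))
    return pd.DataFrame(rows, columns=["cerna_id", "mirna_id", "mrna_id"]) \
        .sort_values(["cerna_id", "mirna_id", "mrna_id"]).reset_index(drop=True)


def _spearman_pairs(expr: pd.DataFrame, pairs: set) -> dict:
    """Spearman rho/p for a set of (feature, feature) pairs, vectorized.

    For n > 10 samples, ranks are z-scored once and rho comes from dot
    products with a t-approximation p; small n falls back to the exact
    scalar routine.
    """
    n = expr.shape[1]
    features = sorted({f for pair in pairs for f in pair})
    if n <= 10:
        return {pair: spearman(expr.loc[pair[0]], expr.loc[pair[1]]) for pair in pairs}
    sub = expr.loc[features].to_numpy(float)
    ranks = np.apply_along_axis(stats.rankdata, 1, sub)
    sd = ranks.std(axis=1, ddof=0)
    sd[sd == 0] = np.inf  # constant rows get rho 0
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]
    pos = {f: i for i, f in enumerate(features)}
    out = {}
    for a, b in pairs:
        rho = float(np.clip(z[pos[a]] @ z[pos[b]] / n, -1.0, 1.0))
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        out[(a, b)] = (rho, min(1.0, p))
    return out


def filter_triads(candidates: pd.DataFrame, expr: pd.DataFrame,
                  config: Config | None = None) -> pd.DataFrame:
    """Keep candidates with rho_cm > 0, rho_mic < 0, rho_mim < 0 and all
    three correlations passing the significance filter.

    With ``config.spearman_filter_on == "p"`` (default) the filter is
    correlation-test p < spearman_p; the alternative ``"rho"`` reading keeps
    triads whose |rho| exceeds ``spearman_p`` instead.
    """
    config = config or Config()
    if candidates.empty:
        return pd.DataFrame(columns=TRIAD_COLUMNS)
    pairs = set()
    for c, m, g in candidates[["cerna_id", "mirna_id", "mrna_id"]].itertuples(index=False):
        pairs.update({(c, g), (m, c), (m, g)})
    missing = {f for pair in pairs for f in pair} - set(expr.index)
    if missing:
        raise KeyError(f"candidates missing from expression matrix: {sorted(missing)[:10]}")
    table = _spearman_pairs(expr, pairs)
    rows = []
    for c, m, g in candidates[["cerna_id", "mirna_id", "mrna_id"]].itertuples(index=False):
        rho_cm, p_cm = table[(c, g)]
        rho_mic, p_mic = table[(m, c)]
        rho_mim, p_mim = table[(m, g)]
        if not (rho_cm > 0 and rho_mic < 0 and rho_mim < 0):
            continue
        if config.spearman_filter_on == "p":
            ok = max(p_cm, p_mic, p_mim) < config.spearman_p
        else:
            ok = min(abs(rho_cm), abs(rho_mic), abs(rho_mim)) > config.spearman_p
        if ok:
            rows.append((c, m, g, rho_cm, rho_mic, rho_mim, p_cm, p_mic, p_mim))
    return pd.DataFrame(rows, columns=TRIAD_COLUMNS) \
        .sort_values(["cerna_id", "mirna_id", "mrna_id"]).reset_index(drop=True)


def build_core_networks(triads: pd.DataFrame, rna_class: pd.Series,
                        module_of: pd.Series | None = None,
                        out_prefix: str | None = None) -> dict:
    """Split triads by ceRNA class into two tripartite networks.

    Returns, per class, a dict with node/edge tables and summary counts
    (unique ceRNAs, miRNAs, mRNAs); when ``out_prefix`` is given the
    networks are exported as GraphML + SIF.
    """
    networks = {}
    for cls in ("lncRNA", "circRNA"):
        sub = triads[[rna_class.get(c) == cls for c in triads["cerna_id"]]] \
            if len(triads) else triads
        edges = []
        for c, m, g in sub[["cerna_id", "mirna_id", "mrna_id"]].itertuples(index=False) \
                if len(sub) else []:
            edges.append((m, c, "mirna_cerna"))
            edges.append((m, g, "mirna_mrna"))
        edges = pd.DataFrame(edges, columns=["source", "target", "interaction"]) \
            .drop_duplicates().reset_index(drop=True)
        node_ids = sorted(set(edges["source"]) | set(edges["target"])) if len(edges) else []
        nodes = pd.DataFrame({"id": node_ids})
        nodes["rna_class"] = [rna_class.get(i, "") for i in node_ids]
        if module_of is not None:
            nodes["module"] = [int(module_of.get(i, 0)) for i in node_ids]
        summary = {
            "n_cerna": sub["cerna_id"].nunique() if len(sub) else 0,
            "n_mirna": sub["mirna_id"].nunique() if len(sub) else 0,
            "n_mrna": sub["mrna_id"].nunique() if len(sub) else 0,
            "n_triads": int(len(sub)),
        }
        networks[cls] = {"nodes": nodes, "edges": edges, "summary": summary}
        if out_prefix is not None:
            export_network(nodes, edges, f"{out_prefix}_{cls}")
    return networks
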
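"""cis / trans / parent regulatory pairing of lncRNAs and circRNAs with mRNAs.

cis candidates are DE regulator-mRNA pairs on the same chromosome whose
interval gap is at most the cis window (100 kb by default, boundary
inclusive; overlapping intervals count as distance 0), kept when
|Pearson r| exceeds the cis threshold.  trans pairs are all DE lncRNA-mRNA
pairs above the (higher) trans threshold, with window-eligible pairs
excluded by default so the two networks stay disjoint.  Parent pairs link
each DE circRNA to its annotated host mRNA with no correlation threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import Config

PAIR_COLUMNS = ["regulator_id", "target_id", "pair_type", "distance_bp", "r", "p",
                "is_core"]


def pearson_matrix(expr_a: pd.DataFrame, expr_b: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (rows of a vs rows of b) with two-sided t-test p."""
    if list(expr_a.columns) != list(expr_b.columns):
        raise ValueError("sample columns must match")
    n = expr_a.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    za = _zscore_rows(expr_a.to_numpy(float))
    zb = _zscore_rows(expr_b.to_numpy(float))
    r = np.clip(za @ zb.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return (pd.DataFrame(r, index=expr_a.index, columns=expr_b.index),
            pd.DataFrame(p, index=expr_a.index, columns=expr_b.index))


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=0)
    out = np.zeros_like(x, dtype=float)
    ok = sd > 0
    out[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    return out


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap between two half-open intervals; overlap or adjacency gives 0."""
    return max(0, start_a - end_b, start_b - end_a)


def _coords(ann: pd.DataFrame, ids) -> pd.DataFrame:
    idx = ann.set_index("feature_id")
    present = [i for i in ids if i in idx.index]
    missing = set(ids) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} features lack coordinates and are skipped",
                      stacklevel=3)
    return idx.loc[present, ["chromosome", "start", "end"]]


def cis_pairs(ann: pd.DataFrame, de_lnc, de_circ, de_mrna, expr: pd.DataFrame,
              config: Config | None = None) -> pd.DataFrame:
    """Window-candidate regulator-mRNA pairs passing the |r| > r_cis filter."""
    config = config or Config()
    rows = []
    mrna_coords = _coords(ann, list(de_mrna))
    for regulators in (list(de_lnc), list(de_circ)):
        reg_coords = _coords(ann, regulators)
        for reg, rrow in reg_coords.iterrows():
            same_chrom = mrna_coords[mrna_coords["chromosome"] == rrow["chromosome"]]
            for g, grow in same_chrom.iterrows():
                gap = interval_gap(rrow["start"], rrow["end"], grow["start"], grow["end"])
                if gap <= config.cis_window_bp:
                    rows.append((reg, g, gap))
    if not rows:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    cand = pd.DataFrame(rows, columns=["regulator_id", "target_id", "distance_bp"])
    r, p = pearson_matrix(expr.loc[cand["regulator_id"].unique()],
                          expr.loc[cand["target_id"].unique()])
    cand["r"] = [r.loc[a, b] for a, b in zip(cand["regulator_id"], cand["target_id"])]
    cand["p"] = [p.loc[a, b] for a, b in zip(cand["regulator_id"], cand["target_id"])]
    cand = cand[cand["r"].abs() > config.r_cis].copy()
    cand["pair_type"] = "cis"
    cand["is_core"] = False
    return cand[PAIR_COLUMNS].sort_values(["regulator_id", "target_id"]).reset_index(drop=True)


def trans_pairs(de_lnc, de_mrna, expr: pd.DataFrame, config: Config | None = None,
                ann: pd.DataFrame | None = None) -> pd.DataFrame:
    """All DE lncRNA-mRNA pairs with |r| > r_trans.

    When ``config.trans_excludes_cis`` and an annotation is supplied,
    window-eligible (cis-candidate) pairs are excluded so cis and trans
    outputs are disjoint.
    """
    config = config or Config()
    de_lnc, de_mrna = list(de_lnc), list(de_mrna)
    if not de_lnc or not de_mrna:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    r, p = pearson_matrix(expr.loc[de_lnc], expr.loc[de_mrna])
    window = set()
    if config.trans_excludes_cis and ann is not None:
        lnc_coords = _coords(ann, de_lnc)
        mrna_coords = _coords(ann, de_mrna)
        for reg, rrow in lnc_coords.iterrows():
            same = mrna_coords[mrna_coords["chromosome"] == rrow["chromosome"]]
            for g, grow in same.iterrows():
                if interval_gap(rrow["start"], rrow["end"],
                                grow["start"], grow["end"]) <= config.cis_window_bp:
                    window.add((reg, g))
    rows = []
    for a in de_lnc:
        for b in de_mrna:
            if abs(r.loc[a, b]) > config.r_trans and (a, b) not in window:
                rows.append((a, b, "trans", pd.NA, float(r.loc[a, b]),
                             float(p.loc[a, b]), False))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS) \
        .sort_values(["regulator_id", "target_id"]).reset_index(drop=True)


def parent_pairs(ann: pd.DataFrame, de_circ, expr: pd.DataFrame | None = None
                 ) -> pd.DataFrame:
    """One pair per DE circRNA with an annotated host mRNA (no r threshold)."""
    idx = ann.set_index("feature_id")
    rows = []
    for c in de_circ:
        host = idx.at[c, "host_gene_id"] if c in idx.index else None
        if host is None or (isinstance(host, float) and np.isnan(host)):
            warnings.warn(f"circRNA {c} has no host annotation; skipped", stacklevel=2)
            continue
        r_val, p_val = np.nan, np.nan
        if expr is not None and c in expr.index and host in expr.index:
            rm, pm = pearson_matrix(expr.loc[[c]], expr.loc[[host]])
            r_val, p_val = float(rm.iloc[0, 0]), float(pm.iloc[0, 0])
        rows.append((c, host, "parent", pd.NA, r_val, p_val, False))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS) \
        .sort_values(["regulator_id", "target_id"]).reset_index(drop=True)


def core_filter(pairs: pd.DataFrame, hub_genes) -> pd.DataFrame:
    """Mark pairs whose target is a hub gene; the core network is that subset."""
    pairs = pairs.copy()
    hubs = set(hub_genes)
    pairs["is_core"] = pairs["target_id"].isin(hubs)
    return pairs
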
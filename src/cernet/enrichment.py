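"""Hypergeometric over-representation analysis with BH-FDR correction.

Gene sets (hub genes, regulatory-pair targets, circRNA parent genes) are
tested against user-supplied term-gene maps.  The p-value for a term is the
upper tail P(X >= k) of Hypergeometric(N, K, n): k query genes hit a term
of K universe genes, with a query of size n drawn from a universe of N.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Config

ENRICH_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p", "fdr", "rank",
                  "significant"]


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query, term_map: pd.DataFrame, universe,
           config: Config | None = None) -> pd.DataFrame:
    """Over-representation of ``query`` genes in each term of ``term_map``.

    ``term_map`` needs columns term_id / gene_id (term_name optional).
    Genes outside the universe are dropped with a warning; only terms with
    at least one query hit are reported, ranked by p (ties by term id).
    """
    config = config or Config()
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    tm = term_map.copy()
    if "term_name" not in tm.columns:
        tm["term_name"] = tm["term_id"]
    outside = ~tm["gene_id"].isin(universe)
    if outside.any():
        warnings.warn(f"dropping {int(outside.sum())} term-map genes outside the universe",
                      stacklevel=2)
        tm = tm[~outside]
    if not query:
        return pd.DataFrame(columns=ENRICH_COLUMNS)

    N = len(universe)
    n = len(query)
    rows = []
    for term_id, sub in tm.groupby("term_id"):
        genes = set(sub["gene_id"])
        k = len(genes & query)
        if k == 0:
            continue
        K = len(genes)
        rows.append((term_id, sub["term_name"].iloc[0], k, K, n, N,
                     hypergeom_test(k, K, n, N)))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if out.empty:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    out["fdr"] = fdr_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["significant"] = out["fdr"] < config.fdr_enrich
    return out[ENRICH_COLUMNS]
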
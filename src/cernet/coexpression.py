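"""Weighted co-expression network analysis built from first principles.

Pipeline: sample outlier removal (hierarchical clustering), soft-threshold
selection by scale-free topology fit, unsigned adjacency |cor|^beta ->
topological overlap, average-linkage tree cutting into modules with a size
floor and eigengene-based merging, module eigengenes (first principal
component), module-trait correlation with per-time-point indicator traits,
key-module selection, gene significance (GS) / module membership (MM), and
hub-gene selection (|MM| > 0.8 and |GS| > 0.5, strict, within key modules).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .io import Config

# cosmetic color-style names for module labels (label 0 = unassigned/grey)
_COLORS = ["grey", "turquoise", "blue", "brown", "yellow", "green", "red",
           "black", "pink", "magenta", "purple"]


def module_color(label: int) -> str:
    return _COLORS[label] if 0 <= label < len(_COLORS) else f"module{label}"


@dataclass
class ModuleResult:
    """Everything the downstream stages need from the co-expression step."""

    labels: pd.Series                 # gene -> module label (0 = unassigned)
    eigengenes: pd.DataFrame          # modules x samples, unit variance rows
    module_trait_r: pd.DataFrame      # modules x time points
    module_trait_p: pd.DataFrame
    key_modules: dict                 # time point -> module label
    gs: pd.DataFrame                  # genes x time points
    mm: pd.DataFrame                  # genes x modules
    hub_genes: pd.DataFrame           # columns: gene_id, module, mm, gs, trait
    soft_power: int
    fit_table: pd.DataFrame
    removed_samples: list


# ---------------------------------------------------------------------------


def remove_outlier_samples(expr: pd.DataFrame, cut_height: float | None = None
                           ) -> tuple[pd.DataFrame, list]:
    """Drop samples that detach above ``cut_height`` in a sample dendrogram.

    Average-linkage clustering on Euclidean distances of the per-gene
    standardized expression matrix (genes x samples).  Default cut height:
    mean + 2.5 sd of the dendrogram merge heights.  A sample is removed when
    it is still a singleton at the cut, i.e. it only joins the rest of the
    tree above ``cut_height``; grouped samples (e.g. a coherent time-point
    block) are never flagged.  Flagging more than 20% of samples is treated
    as an error requiring manual review.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples for outlier screening")
    x = expr.to_numpy(float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    link = hierarchy.linkage(z.T, method="average", metric="euclidean")
    heights = link[:, 2]
    if cut_height is None:
        cut_height = float(heights.mean() + 2.5 * heights.std(ddof=0))
    clusters = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    counts = np.bincount(clusters)
    removed = [s for s, c in zip(expr.columns, clusters) if counts[c] == 1]
    if len(removed) > 0.2 * expr.shape[1]:
        raise ValueError(
            f"outlier screening flagged {len(removed)} of {expr.shape[1]} samples; "
            "review the data manually")
    return expr.drop(columns=removed), removed


def _correlation_matrix(expr: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    x = expr.to_numpy(float)
    sd = x.std(axis=1, ddof=0)
    constant = expr.index[sd == 0]
    if len(constant):
        warnings.warn(f"excluding {len(constant)} constant genes from the network",
                      stacklevel=3)
        expr = expr.drop(index=constant)
        x = expr.to_numpy(float)
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    return r, expr.index


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned weighted adjacency a_ij = |cor(x_i, x_j)|^beta, zero diagonal."""
    r, index = _correlation_matrix(expr)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=index, columns=index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index from the connectivity distribution.

    The connectivities are split into ``n_bins`` equal-occupancy bins; a
    density (bin fraction / bin width) is regressed on mean connectivity in
    log10-log10 space, and the index is -sign(slope) * R^2.
    """
    k = np.sort(np.asarray(k, dtype=float))
    chunks = np.array_split(k, n_bins)
    xs, ys = [], []
    n = len(k)
    for chunk in chunks:
        if len(chunk) == 0:
            continue
        width = chunk.max() - chunk.min()
        mean_k = chunk.mean()
        if width <= 0 or mean_k <= 0:
            continue
        density = (len(chunk) / n) / width
        xs.append(np.log10(mean_k))
        ys.append(np.log10(density))
    if len(xs) < 3:
        return 0.0
    slope, _, r_value, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r_value ** 2)


def pick_soft_threshold(expr: pd.DataFrame, powers=range(1, 21),
                        target_fit: float = 0.85,
                        mean_k_window: tuple | None = (1.0, 2.5)
                        ) -> tuple[int, pd.DataFrame]:
    """Choose the soft power from the scale-free fit and connectivity.

    The constant-height tree cut downstream needs the adjacency compressed
    until background topological overlap is negligible, but not so far that
    the network empties; the fit index alone guarantees neither.  Candidate
    powers are therefore those whose mean connectivity falls inside
    ``mean_k_window`` (roughly one to a few retained neighbours per gene);
    among them the smallest power reaching ``target_fit`` wins, else the
    candidate with the best fit.  If no power lands in the window, the rule
    degrades to smallest-power-reaching-target, then to argmax fit.  Returns
    the chosen power and the full fit table (power, fit index,
    mean/median/max connectivity).
    """
    if expr.shape[1] < 8:
        raise ValueError("need at least 8 samples to pick a soft threshold")
    r, _ = _correlation_matrix(expr)
    absr = np.abs(r)
    np.fill_diagonal(absr, 0.0)
    rows = []
    for beta in powers:
        a = absr ** beta
        k = a.sum(axis=1)
        rows.append((beta, scale_free_fit(k), k.mean(), np.median(k), k.max()))
    table = pd.DataFrame(rows, columns=["power", "fit", "mean_k", "median_k", "max_k"])
    if mean_k_window is not None:
        in_window = table[(table["mean_k"] >= mean_k_window[0])
                          & (table["mean_k"] <= mean_k_window[1])]
        if len(in_window):
            reaching = in_window[in_window["fit"] >= target_fit]
            pick = reaching if len(reaching) else \
                in_window[in_window["fit"] == in_window["fit"].max()]
            return int(pick["power"].iloc[0]), table
    reaching = table[table["fit"] >= target_fit]
    beta = int(reaching["power"].iloc[0]) if len(reaching) else \
        int(table.loc[table["fit"].idxmax(), "power"])
    return beta, table


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    ``l_ij`` counts shared neighbours, ``sum_u a_iu a_uj``; the diagonal is 1.
    Input must be symmetric with zero diagonal and entries in [0, 1].
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    l = a @ a  # diagonal of a is zero, so this already skips u = i and u = j
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cut_modules(diss: np.ndarray, expr: pd.DataFrame | None = None,
                min_size: int = 30, merge_height: float = 0.25,
                cut_height: float = 0.99, kme_to_stay: float = 0.6) -> np.ndarray:
    """Average-linkage tree cut with a size floor and eigengene merging.

    Initial modules come from a constant-height cut of the TOM-dissimilarity
    dendrogram; clusters below ``min_size`` are unassigned (label 0).  When
    ``expr`` is given, three refinement stages mirror the hybrid
    dynamic-tree-cut algorithm: (1) deep split — every module is recursively
    bisected along its own subtree while both halves keep ``min_size`` genes
    (over-splitting is harmless because stage 2 reunites coherent halves);
    (2) modules whose eigengenes correlate above ``1 - merge_height`` are
    merged iteratively; (3) a PAM-like pass re-attaches each gene to the
    module whose eigengene it correlates with most strongly when that
    correlation exceeds ``kme_to_stay`` (and releases it to the unassigned
    pool otherwise).  Labels are renumbered by decreasing module size.
    """
    diss = np.asarray(diss, dtype=float)
    if diss.shape[0] != diss.shape[1] or not np.allclose(diss, diss.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    d = diss.copy()
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    next_label = 1
    for cl in np.unique(raw):
        members = raw == cl
        if members.sum() >= min_size:
            labels[members] = next_label
            next_label += 1
    if labels.max() == 0:
        warnings.warn("all genes unassigned after tree cut", stacklevel=2)
        return labels

    if expr is not None and merge_height > 0:
        labels = _deep_split(labels, d, min_size)
        labels = _merge_by_eigengene(labels, expr, merge_height)
        labels = _reassign_by_eigengene(labels, expr, kme_to_stay)
    return _renumber_by_size(labels)


def _deep_split(labels: np.ndarray, diss: np.ndarray, min_size: int) -> np.ndarray:
    """Recursively bisect each module along its own average-linkage subtree.

    A mixture of two expression programs that stayed attached below the
    global cut separates here; halves of a genuinely coherent module are
    re-merged afterwards by the eigengene-merge stage.
    """
    labels = labels.copy()
    next_label = labels.max() + 1
    queue = [m for m in np.unique(labels) if m != 0]
    while queue:
        m = queue.pop()
        members = np.flatnonzero(labels == m)
        if len(members) < 2 * min_size:
            continue
        sub = diss[np.ix_(members, members)]
        sub_link = hierarchy.linkage(squareform(sub, checks=False), method="average")
        # leaf counts per internal node, then the highest junction whose two
        # children BOTH hold >= min_size leaves: the meeting point of two
        # sub-programs.  Loosely attached stragglers above it keep the old
        # label and are dealt with by the PAM stage.
        n = len(members)
        leaf_sets: list = [frozenset([i]) for i in range(n)]
        junction = None
        for a, b, height, _ in sub_link:
            la, lb = leaf_sets[int(a)], leaf_sets[int(b)]
            leaf_sets.append(la | lb)
            if len(la) >= min_size and len(lb) >= min_size:
                junction = (la, lb)  # later merges are higher: keep the last
        if junction is None:
            continue
        la, lb = junction
        labels[members[sorted(lb)]] = next_label
        queue.extend([m, next_label])
        next_label += 1
    return labels


def _reassign_by_eigengene(labels: np.ndarray, expr: pd.DataFrame,
                           kme_to_stay: float) -> np.ndarray:
    """PAM-like stage of the hybrid tree cut, both directions.

    Every gene is assigned to the module whose eigengene it correlates with
    most strongly, provided |cor| exceeds ``kme_to_stay``; genes below the
    threshold for every module are released to the unassigned pool.  This
    both rescues stragglers the constant-height cut orphaned and evicts
    weakly attached genes.
    """
    present = [m for m in np.unique(labels) if m != 0]
    if not present:
        return labels
    eig = module_eigengene(expr, pd.Series(labels, index=expr.index))
    r, _ = _cor_with_p(expr.to_numpy(float), eig.to_numpy())
    best = np.argmax(np.abs(r), axis=1)
    best_r = np.abs(r)[np.arange(len(labels)), best]
    new = np.where(best_r > kme_to_stay, np.asarray(eig.index)[best], 0)
    return new.astype(int)


def _merge_by_eigengene(labels: np.ndarray, expr: pd.DataFrame,
                        merge_height: float) -> np.ndarray:
    while True:
        present = [m for m in np.unique(labels) if m != 0]
        if len(present) < 2:
            break
        eig = module_eigengene(expr, pd.Series(labels, index=expr.index))
        r = np.corrcoef(eig.to_numpy())
        best, best_r = None, 1.0 - merge_height
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                if r[i, j] > best_r:
                    best, best_r = (present[i], present[j]), r[i, j]
        if best is None:
            break
        labels = np.where(labels == best[1], best[0], labels)
    return labels


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    sizes = {m: (labels == m).sum() for m in np.unique(labels) if m != 0}
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    remap = {m: i + 1 for i, m in enumerate(order)}
    remap[0] = 0
    return np.vectorize(remap.get)(labels)


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module, unit variance, sign-oriented.

    The module submatrix is standardized per gene before the SVD; the
    eigengene sign is chosen so its mean correlation with member genes is
    positive.  A single-gene module falls back to the standardized gene.
    """
    eigengenes = {}
    for m in sorted(set(labels) - {0}):
        genes = labels.index[labels == m]
        sub = expr.loc[genes].to_numpy(float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if len(genes) == 1:
            warnings.warn(f"module {m} has a single gene; eigengene = that gene",
                          stacklevel=2)
            e = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            e = vt[0]
        e = e / e.std(ddof=1)
        member_cor = np.array([np.corrcoef(e, row)[0, 1] for row in z])
        if member_cor.mean() < 0:
            e = -e
        eigengenes[m] = e
    return pd.DataFrame(eigengenes, index=expr.columns).T


def trait_indicators(samples: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """One binary indicator row per time point, columns = samples."""
    st = samples.set_index("sample_id").loc[list(sample_ids)]
    tps = sorted(st["time_point_hours"].unique())
    data = {t: (st["time_point_hours"] == t).astype(float).to_numpy() for t in tps}
    return pd.DataFrame(data, index=sample_ids).T


def _cor_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r between rows of x and rows of y, plus two-sided p."""
    n = x.shape[1]
    zx = _rowwise_z(x)
    zy = _rowwise_z(y)
    r = np.clip(zx @ zy.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def _rowwise_z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1, ddof=0)
    out = np.zeros_like(x)
    ok = sd > 0
    out[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    return out


def module_trait_and_keys(eigengenes: pd.DataFrame, samples: pd.DataFrame,
                          labels: pd.Series | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pearson module-trait correlations and the key module per time point.

    Traits are per-time-point binary indicators.  The key module for a time
    point is the one with the largest |r|; ties break by smaller p, then by
    larger module size (when ``labels`` is given), then by label.
    """
    traits = trait_indicators(samples, eigengenes.columns)
    if (traits.sum(axis=1) < 2).any():
        raise ValueError("every time point needs at least 2 samples")
    r, p = _cor_with_p(eigengenes.to_numpy(), traits.to_numpy())
    r_df = pd.DataFrame(r, index=eigengenes.index, columns=traits.index)
    p_df = pd.DataFrame(p, index=eigengenes.index, columns=traits.index)
    sizes = labels.value_counts() if labels is not None else pd.Series(dtype=int)
    key = {}
    for t in traits.index:
        stats_t = pd.DataFrame({
            "absr": r_df[t].abs(), "p": p_df[t],
            "size": [sizes.get(m, 0) for m in r_df.index],
        })
        stats_t = stats_t.sort_values(by=["absr", "p", "size"],
                                      ascending=[False, True, False],
                                      kind="mergesort")
        key[t] = int(stats_t.index[0])
    return r_df, p_df, key


def gene_significance_membership(expr: pd.DataFrame, eigengenes: pd.DataFrame,
                                 samples: pd.DataFrame
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GS = cor(gene, time-point indicator); MM = cor(gene, module eigengene)."""
    traits = trait_indicators(samples, expr.columns)
    x = expr.to_numpy(float)
    if (expr.std(axis=1, ddof=0) == 0).any():
        warnings.warn("constant genes get GS/MM = 0", stacklevel=2)
    gs, _ = _cor_with_p(x, traits.to_numpy())
    mm, _ = _cor_with_p(x, eigengenes.to_numpy())
    return (pd.DataFrame(gs, index=expr.index, columns=traits.index),
            pd.DataFrame(mm, index=expr.index, columns=eigengenes.index))


def select_hub_genes(result: "ModuleResult", config: Config | None = None) -> pd.DataFrame:
    """Hub genes: key-module members with |MM| > mm_hub and |GS| > gs_hub.

    Both inequalities are strict.  The GS trait of a gene is the trait its
    module is key for; if a module is key for several time points, the one
    with the largest |module-trait r| is used.
    """
    config = config or Config()
    module_trait = {}
    for t, m in result.key_modules.items():
        if m not in module_trait or \
                abs(result.module_trait_r.loc[m, t]) > \
                abs(result.module_trait_r.loc[m, module_trait[m]]):
            module_trait[m] = t
    rows = []
    for m, trait in sorted(module_trait.items()):
        genes = result.labels.index[result.labels == m]
        for g in genes:
            mm = result.mm.loc[g, m]
            gs = result.gs.loc[g, trait]
            if abs(mm) > config.mm_hub and abs(gs) > config.gs_hub:
                rows.append((g, m, float(mm), float(gs), trait))
    return pd.DataFrame(rows, columns=["gene_id", "module", "mm", "gs", "trait"])


# ---------------------------------------------------------------------------


def run_wgcna(expr: pd.DataFrame, samples: pd.DataFrame,
              config: Config | None = None) -> ModuleResult:
    """Full co-expression analysis of an expression matrix (genes x samples)."""
    config = config or Config()
    expr, removed = remove_outlier_samples(expr)
    samples = samples[samples["sample_id"].isin(expr.columns)]
    if config.soft_power == "auto":
        beta, fit_table = pick_soft_threshold(expr, target_fit=config.scale_free_target)
    else:
        beta = int(config.soft_power)
        _, fit_table = pick_soft_threshold(expr, powers=[beta])
    adj = adjacency_matrix(expr, beta)
    expr = expr.loc[adj.index]  # constant genes were dropped
    tom = tom_similarity(adj.to_numpy())
    labels = cut_modules(1.0 - tom, expr=expr, min_size=config.min_module_size,
                         merge_height=config.merge_height,
                         cut_height=config.module_cut_height)
    labels = pd.Series(labels, index=expr.index, name="module")
    if labels.max() == 0:
        raise ValueError("no co-expression modules found")
    eig = module_eigengene(expr, labels)
    r_df, p_df, keys = module_trait_and_keys(eig, samples, labels)
    gs, mm = gene_significance_membership(expr, eig, samples)
    result = ModuleResult(labels=labels, eigengenes=eig, module_trait_r=r_df,
                          module_trait_p=p_df, key_modules=keys, gs=gs, mm=mm,
                          hub_genes=pd.DataFrame(), soft_power=beta,
                          fit_table=fit_table, removed_samples=removed)
    result.hub_genes = select_hub_genes(result, config)
    return result
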
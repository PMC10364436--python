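"""Normalization and negative-binomial differential expression.

TPM / FPKM / TMM normalization plus a conditional negative-binomial exact
test against the 0 h baseline, one contrast per proliferative time point.
A feature is "union DE" if it is called in at least one contrast.  Class
thresholds: |log2FC| > log2(1.5) for lncRNA/miRNA/mRNA, |log2FC| > log2(1)
(= 0, so the p criterion alone decides) for circRNA, raw p < p_de in both
cases.  p-values are deliberately not multiplicity-adjusted for DE calls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import Config, CountMatrix

DE_COLUMNS = ["feature_id", "rna_class", "contrast", "log2fc", "p_value",
              "direction", "union_de"]


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized, columns sum to 1e6."""
    rate = cm.counts.div(cm.length, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum.index[colsum == 0]
    if len(zero):
        raise ValueError(f"zero column sum in samples: {zero.tolist()}")
    return rate.div(colsum, axis=1) * 1e6


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads."""
    lib = cm.counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size in samples: {zero.tolist()}")
    return (cm.counts * 1e9).div(cm.length, axis=0).div(lib, axis=1)


def tmm_factors(cm: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: upper-quartile CPM closest to the mean upper quartile.
    Per gene (zeros in either sample excluded): M = log2 ratio of relative
    abundances vs the reference, A = mean log2 relative abundance.  The 30%
    tails on M and the 5% tails on A are trimmed; the factor is
    2**(weighted mean M) with inverse asymptotic-variance (delta-method
    binomial) weights, and factors are rescaled to geometric mean 1.

    Returns a DataFrame with sample_id, library_size, tmm_factor and
    effective_size = library_size * tmm_factor.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    cpm = counts.div(lib, axis=1) * 1e6
    uq = cpm.quantile(0.75, axis=0)
    ref = (uq - uq.mean()).abs().idxmin()

    factors = {}
    for sample in counts.columns:
        factors[sample] = _tmm_pair(counts[sample].to_numpy(float), lib[sample],
                                    counts[ref].to_numpy(float), lib[ref])
    f = pd.Series(factors)
    f = f / np.exp(np.log(f).mean())  # geometric mean 1
    out = pd.DataFrame({
        "sample_id": counts.columns,
        "library_size": lib.values.astype(np.int64),
        "tmm_factor": f[counts.columns].values,
    })
    out["effective_size"] = out["library_size"] * out["tmm_factor"]
    return out


def _tmm_pair(y: np.ndarray, n: float, y_ref: np.ndarray, n_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    keep = (y > 0) & (y_ref > 0)
    y, y_ref = y[keep], y_ref[keep]
    if y.size == 0:
        warnings.warn("no usable genes for TMM; factor set to 1", stacklevel=3)
        return 1.0
    p, p_ref = y / n, y_ref / n_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() < 2:
        warnings.warn("fewer than 2 genes left after TMM trimming; factor 1",
                      stacklevel=3)
        return 1.0
    w = 1.0 / ((n - y[keep]) / (n * y[keep]) + (n_ref - y_ref[keep]) / (n_ref * y_ref[keep]))
    return float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))


# ---------------------------------------------------------------------------
# exact test


def nb_exact_test(group_a, group_b, dispersion: float) -> float:
    """Two-sided conditional NB exact test on group sums.

    Counts are assumed already rescaled to a common effective library size.
    Conditioning on the total, the probability of each (sum_a, sum_b) split
    is computed under NB group sums (size n_g / phi) with the null per-sample
    mean total/(n_a+n_b); the p-value sums the probabilities of all splits no
    more probable than the observed one.  phi = 0 reduces to the conditional
    binomial (Poisson) test.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    sa = int(round(a.sum()))
    sb = int(round(b.sum()))
    total = sa + sb
    if total == 0:
        return 1.0
    n_a, n_b = len(a), len(b)
    mu = total / (n_a + n_b)
    s = np.arange(total + 1)
    if dispersion == 0:
        log_w = stats.poisson.logpmf(s, n_a * mu) + stats.poisson.logpmf(total - s, n_b * mu)
    else:
        p = 1.0 / (1.0 + mu * dispersion)  # shared success prob, sizes n_g/phi
        log_w = (stats.nbinom.logpmf(s, n_a / dispersion, p)
                 + stats.nbinom.logpmf(total - s, n_b / dispersion, p))
    log_w -= log_w.max()
    w = np.exp(log_w)
    w /= w.sum()
    return float(min(1.0, w[w <= w[sa] * (1 + 1e-12)].sum()))


def estimate_common_dispersion(counts: CountMatrix | pd.DataFrame, groups,
                               method: str = "cml") -> float:
    """Common NB dispersion across genes from replicated groups.

    ``groups`` maps each group label to its sample columns.  Counts are
    rescaled to a common effective library size (TMM) first.  Two
    estimators:

    * ``"cml"`` (default): maximize the summed conditional log-likelihood of
      the counts given their group sums — well calibrated for the exact test;
    * ``"moments"``: per-gene method-of-moments phi = max(0, (s2-m)/m^2)
      (chi-square median-bias corrected), pooled across genes by the median.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    groups = {k: list(v) for k, v in groups.items()}
    replicated = {k: v for k, v in groups.items() if len(v) >= 2}
    if not replicated:
        raise ValueError("no replicated group: supply a dispersion explicitly")
    nf = tmm_factors(df)
    eff = nf.set_index("sample_id")["effective_size"]
    geo = np.exp(np.log(eff).mean())
    scaled = df * (geo / eff)

    if method == "moments":
        return _dispersion_moments(scaled, replicated)
    if method == "cml":
        return _dispersion_cml(scaled, replicated)
    raise ValueError(f"unknown dispersion method: {method}")


def _dispersion_moments(scaled: pd.DataFrame, groups: dict) -> float:
    per_gene = []
    for _, row in scaled.iterrows():
        est, dfs = [], []
        for cols in groups.values():
            x = row[cols].to_numpy(float)
            m = x.mean()
            if m <= 0:
                continue
            nu = len(x) - 1
            c = (1 - 2 / (9 * nu)) ** 3  # median of chi2_nu / nu
            est.append((x.var(ddof=1) / c - m) / m ** 2)
            dfs.append(nu)
        if est:
            per_gene.append(max(0.0, float(np.average(est, weights=dfs))))
    if not per_gene:
        return 0.0
    return float(np.median(per_gene))


def _dispersion_cml(scaled: pd.DataFrame, groups: dict) -> float:
    """Maximize sum over genes/groups of log P(counts | group sum) under NB."""
    mats = [np.asarray(scaled[cols], dtype=float) for cols in groups.values()]

    def neg_cond_loglik(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        total = 0.0
        for mat in mats:
            n = mat.shape[1]
            sums = mat.sum(axis=1)
            total += float(
                np.sum(special.gammaln(mat + r))
                + np.sum(special.gammaln(n * r) - special.gammaln(sums + n * r))
                - mat.shape[0] * n * special.gammaln(r)
            )
        return -total

    res = optimize.minimize_scalar(neg_cond_loglik, bounds=(np.log(1e-6), np.log(20.0)),
                                   method="bounded", options={"xatol": 1e-6})
    phi = float(np.exp(res.x))
    return 0.0 if phi <= 2e-6 else phi


# ---------------------------------------------------------------------------
# DE calling


def call_de(cm: CountMatrix, samples: pd.DataFrame, dispersion: float | None = None,
            config: Config | None = None) -> pd.DataFrame:
    """Per-time-point NB exact test vs the 0 h group with class thresholds.

    log2 fold changes are computed from TMM-normalized group-mean CPM with a
    pseudo-count of 0.5 per group mean.  Returns the long-format DE table
    (one row per feature per contrast) with the per-feature union flag.
    """
    config = config or Config()
    st = samples.set_index("sample_id")
    if 0 not in set(st["time_point_hours"]):
        raise ValueError("missing 0 h baseline group")
    nf = tmm_factors(cm)
    eff = nf.set_index("sample_id")["effective_size"]
    geo = np.exp(np.log(eff).mean())
    scaled = cm.counts * (geo / eff)
    cpm = cm.counts.div(eff, axis=1) * 1e6

    groups = {t: st.index[st["time_point_hours"] == t].tolist()
              for t in sorted(st["time_point_hours"].unique())}
    if dispersion is None:
        dispersion = estimate_common_dispersion(cm, groups)

    base_cols = groups[0]
    contrasts = [t for t in groups if t != 0]
    log2_thr = {cls: np.log2(config.fc_circ) if cls == "circRNA"
                else np.log2(config.fc_lnc_mi_mrna)
                for cls in cm.rna_class.unique()}

    records = []
    scaled_np = scaled.to_numpy()
    col_idx = {c: i for i, c in enumerate(scaled.columns)}
    base_idx = [col_idx[c] for c in base_cols]
    mean_base = cpm[base_cols].mean(axis=1)
    for t in contrasts:
        cols = groups[t]
        idx = [col_idx[c] for c in cols]
        mean_t = cpm[cols].mean(axis=1)
        log2fc = np.log2((mean_t + 0.5) / (mean_base + 0.5))
        for i, feature in enumerate(cm.feature_ids):
            p = nb_exact_test(scaled_np[i, base_idx], scaled_np[i, idx], dispersion)
            cls = cm.rna_class[feature]
            thr = log2_thr[cls]
            lfc = float(log2fc.iloc[i])
            if lfc > thr and p < config.p_de:
                direction = "up"
            elif lfc < -thr and p < config.p_de:
                direction = "down"
            else:
                direction = "ns"
            records.append((feature, cls, t, lfc, p, direction))

    de = pd.DataFrame(records, columns=["feature_id", "rna_class", "contrast",
                                        "log2fc", "p_value", "direction"])
    union = de[de["direction"] != "ns"]["feature_id"].unique()
    de["union_de"] = de["feature_id"].isin(set(union))
    return de


def union_de_ids(de: pd.DataFrame, rna_class: str | None = None) -> pd.Index:
    sub = de[de["union_de"]]
    if rna_class is not None:
        sub = sub[sub["rna_class"] == rna_class]
    return pd.Index(sub["feature_id"].unique())
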
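"""Synthetic multi-class RNA-seq generator with planted, recoverable structure.

Emulates a liver-regeneration-style time course: five time points
(0, 12, 24, 48, 72 h) with six replicates each, count matrices for four RNA
classes, genomic annotation, and miRNA-target tables.  The generator plants

* co-expression modules of mRNAs tied to time-point archetype profiles
  (high at 0 h; peaks at 12 / 48 / 72 h), driven by a shared per-sample
  latent factor on top of the profile;
* differentially expressed features in every class (module members plus
  isolated DE features with a single perturbed time point);
* cis neighbours: lncRNAs placed within the 100-kb genomic window of a
  module-member mRNA and sharing its expression profile;
* ceRNA triads (ceRNA, miRNA, mRNA) with the sign structure the ceRNA
  hypothesis predicts: the miRNA loads negatively on the latent factor the
  ceRNA and the mRNA load positively on.

Counts are negative binomial with mean ``s_j * mu_gj`` and variance
``mu + phi * mu**2`` (gamma-Poisson mixture), with per-sample library-size
factors drawn log-uniformly.  All planted assignments are returned in a
:class:`TruthBundle` so every downstream stage can be scored for recovery
without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CountMatrix, TARGET_COLUMNS

TIME_POINTS = (0, 12, 24, 48, 72)

# module archetype profiles in units of de_log2fc, baseline 0 h = 0
_ARCHETYPES = [
    ("high_at_0h", np.array([0.0, -1, -1, -1, -1])),
    ("peak_12h", np.array([0.0, 1, 0, 0, 0])),
    ("peak_48h", np.array([0.0, 0, 0, 1, 0])),
    ("peak_72h", np.array([0.0, 0, 0, 0, 1])),
    ("peak_24h", np.array([0.0, 0, 1, 0, 0])),
]


@dataclass
class SimParams:
    """Generator settings.  Defaults define the package's benchmark dataset.

    The study-design constants (five time points, six replicates, dispersion
    0.1, planted effect 1.5 on the log2 scale, library factors in [0.5, 2])
    mirror the replicated hepatectomy time-course design the pipeline is
    aimed at; the class sizes are a desk-scale stand-in for a whole
    transcriptome.
    """

    n_mrna: int = 1000
    n_lnc: int = 200
    n_circ: int = 40
    n_mirna: int = 80
    n_replicates: int = 6
    dispersion: float = 0.1
    de_log2fc: float = 1.5
    n_modules: int = 4
    module_size: int = 100
    module_latent_sd: float = 0.6
    n_isolated_de: dict = field(default_factory=lambda: {
        "mRNA": 100, "lncRNA": 40, "circRNA": 10, "miRNA": 20})
    n_cis_pairs: int = 20
    cis_latent_sd: float = 0.6
    n_lnc_triads: int = 40
    n_circ_triads: int = 10
    n_triad_mirnas: int = 25
    triad_latent_sd: float = 0.75
    base_mean_range: dict = field(default_factory=lambda: {
        "mRNA": (50, 500), "lncRNA": (20, 200), "circRNA": (10, 100),
        "miRNA": (50, 500)})
    library_size_range: tuple = (0.5, 2.0)
    background_target_density: float = 0.05
    cis_window_bp: int = 100_000
    outlier_sample: str | None = None
    outlier_gene_frac: float = 0.3
    outlier_fold: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_modules > len(_ARCHETYPES):
            raise ValueError(f"at most {len(_ARCHETYPES)} module archetypes available")
        if self.n_modules * self.module_size > self.n_mrna:
            raise ValueError("module genes exceed n_mrna")
        for cls, (lo, hi) in self.base_mean_range.items():
            if lo < 1:
                raise ValueError(f"base means must be >= 1 ({cls})")

    @property
    def time_points(self) -> tuple:
        return TIME_POINTS

    @property
    def n_samples(self) -> int:
        return len(TIME_POINTS) * self.n_replicates


@dataclass
class TruthBundle:
    """Planted ground truth for recovery scoring.

    ``de_truth``: features x contrasts (12/24/48/72 vs 0 h) with values in
    {+1 up, -1 down, 0 null}.  ``module_truth``: mRNA -> module id (0 =
    unplanted/noise).  ``cis_truth``: set of (lncRNA, mRNA) pairs.
    ``triad_truth``: set of (ceRNA, miRNA, mRNA) triples.
    """

    de_truth: pd.DataFrame
    module_truth: pd.Series
    cis_truth: set
    triad_truth: set
    params: SimParams

    @property
    def union_de(self) -> pd.Index:
        mask = (self.de_truth != 0).any(axis=1)
        return self.de_truth.index[mask]

    def to_json(self, path) -> None:
        payload = {
            "de_truth": {f: row.tolist() for f, row in self.de_truth.iterrows()},
            "de_contrasts": [int(c) for c in self.de_truth.columns],
            "module_truth": {g: int(m) for g, m in self.module_truth.items()},
            "cis_truth": sorted(map(list, self.cis_truth)),
            "triad_truth": sorted(map(list, self.triad_truth)),
            "params": _params_to_jsonable(self.params),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _params_to_jsonable(params: SimParams) -> dict:
    out = asdict(params)
    out["library_size_range"] = list(out["library_size_range"])
    out["base_mean_range"] = {k: list(v) for k, v in out["base_mean_range"].items()}
    return out


# ---------------------------------------------------------------------------
# feature bookkeeping


def _feature_ids(params: SimParams) -> dict:
    return {
        "mRNA": [f"mRNA_{i:05d}" for i in range(params.n_mrna)],
        "lncRNA": [f"lnc_{i:05d}" for i in range(params.n_lnc)],
        "circRNA": [f"circ_{i:05d}" for i in range(params.n_circ)],
        "miRNA": [f"miR_{i:05d}" for i in range(params.n_mirna)],
    }


@dataclass
class _Plan:
    """Internal planted-role assignment, derived deterministically from seed."""

    ids: dict
    module_of: dict          # mRNA/lncRNA id -> module (1-based) for latent sharing
    module_truth: pd.Series  # mRNA -> module id (0 noise)
    profiles: dict           # feature id -> profile vector (log2 units, absolute)
    cis_pairs: list          # (lnc, mrna)
    triads: list             # (cerna, mirna, mrna)
    triad_mirna_module: dict  # mirna -> module whose profile it opposes
    triad_latent_member: dict  # feature id -> (mirna anchor, loading)
    cis_latent_member: dict  # feature id -> cis pair index (shared pair factor)
    well_expressed: set      # planted regulators kept above the class median


def _plan(params: SimParams, rng: np.random.Generator) -> _Plan:
    ids = _feature_ids(params)
    profiles: dict = {}
    module_of: dict = {}

    module_profiles = {
        m + 1: _ARCHETYPES[m][1] * params.de_log2fc for m in range(params.n_modules)
    }

    # --- mRNA roles: module members, isolated DE, null
    mrna = list(ids["mRNA"])
    rng.shuffle(mrna)
    cursor = 0
    module_truth = pd.Series(0, index=pd.Index(ids["mRNA"], name="feature_id"), dtype=int)
    members_by_module: dict = {}
    for m in range(1, params.n_modules + 1):
        members = mrna[cursor:cursor + params.module_size]
        cursor += params.module_size
        members_by_module[m] = members
        for g in members:
            module_truth[g] = m
            module_of[g] = m
            profiles[g] = module_profiles[m]
    iso_mrna = mrna[cursor:cursor + params.n_isolated_de["mRNA"]]
    cursor += len(iso_mrna)
    _assign_isolated_profiles(iso_mrna, params, rng, profiles)

    # --- cis pairs: lncRNA shadows a module-member mRNA
    lnc = list(ids["lncRNA"])
    rng.shuffle(lnc)
    all_members = [g for m in members_by_module.values() for g in m]
    if params.n_cis_pairs > min(len(all_members), len(lnc)):
        raise ValueError("requested cis pairs exceed available features")
    cis_partners = list(rng.choice(all_members, size=params.n_cis_pairs, replace=False))
    cis_lnc = lnc[:params.n_cis_pairs]
    cis_pairs = list(zip(cis_lnc, cis_partners))
    cis_latent_member: dict = {}
    for i, (l, g) in enumerate(cis_pairs):
        module_of[l] = module_of[g]
        profiles[l] = profiles[g]
        # a pair-private shared factor: cis co-regulation beyond the module
        # program, keeping the planted pair tightly co-expressed
        cis_latent_member[l] = i
        cis_latent_member[g] = i

    # --- triads: miRNA anti-loads against module-profiled ceRNA and mRNA
    n_triads = params.n_lnc_triads + params.n_circ_triads
    circ = list(ids["circRNA"])
    rng.shuffle(circ)
    triad_lnc = lnc[params.n_cis_pairs:params.n_cis_pairs + params.n_lnc_triads]
    triad_circ = circ[:params.n_circ_triads]
    if len(triad_lnc) < params.n_lnc_triads or len(triad_circ) < params.n_circ_triads:
        raise ValueError("not enough lncRNAs/circRNAs for requested triads")
    mirna = list(ids["miRNA"])
    rng.shuffle(mirna)
    triad_mirnas = mirna[:params.n_triad_mirnas]
    if n_triads > len(all_members) - len(cis_partners):
        raise ValueError("not enough module mRNAs for requested triads")
    triads = []
    triad_mirna_module: dict = {}
    triad_latent_member: dict = {}
    cernas = triad_lnc + triad_circ
    # each triad miRNA opposes one module's profile; all its triads stay on
    # that module so the miRNA's own time profile is coherent
    for idx, mir in enumerate(triad_mirnas):
        triad_mirna_module[mir] = (idx % params.n_modules) + 1
        profiles[mir] = -module_profiles[triad_mirna_module[mir]]
    used_g = set(cis_partners)
    for i, c in enumerate(cernas):
        m = triad_mirnas[i % len(triad_mirnas)]
        mod = triad_mirna_module[m]
        g = _member_from_module(members_by_module, mod, exclude=used_g)
        used_g.add(g)
        module_of[c] = mod
        profiles[c] = module_profiles[mod]
        triads.append((c, m, g))
        triad_latent_member[c] = (m, 1.0)
        triad_latent_member[g] = (m, 1.0)
        triad_latent_member[m] = (m, -1.0)

    # --- isolated DE for the remaining classes
    iso_lnc = lnc[params.n_cis_pairs + params.n_lnc_triads:
                  params.n_cis_pairs + params.n_lnc_triads + params.n_isolated_de["lncRNA"]]
    _assign_isolated_profiles(iso_lnc, params, rng, profiles)
    iso_circ = circ[params.n_circ_triads:
                    params.n_circ_triads + params.n_isolated_de["circRNA"]]
    _assign_isolated_profiles(iso_circ, params, rng, profiles)
    iso_mir = mirna[params.n_triad_mirnas:
                    params.n_triad_mirnas + params.n_isolated_de["miRNA"]]
    _assign_isolated_profiles(iso_mir, params, rng, profiles)

    # planted regulators must be expressed well enough for their
    # correlations to be observable; counts near zero would break the
    # "planted with high co-expression" contract
    well_expressed = {l for l, _ in cis_pairs}
    for c, m, g in triads:
        well_expressed.update((c, m))
    return _Plan(ids, module_of, module_truth, profiles, cis_pairs, triads,
                 triad_mirna_module, triad_latent_member, cis_latent_member,
                 well_expressed)


def _member_from_module(members_by_module, module, exclude):
    for g in members_by_module[module]:
        if g not in exclude:
            return g
    raise ValueError("module exhausted while assigning triad mRNAs")


def _assign_isolated_profiles(features, params, rng, profiles) -> None:
    """Single perturbed proliferative time point, random sign."""
    for f in features:
        t = rng.integers(1, len(TIME_POINTS))
        sign = rng.choice([-1.0, 1.0])
        prof = np.zeros(len(TIME_POINTS))
        prof[t] = sign * params.de_log2fc
        profiles[f] = prof


# ---------------------------------------------------------------------------
# public operations


def simulate_annotation(params: SimParams, rng: np.random.Generator | None = None,
                        plan: _Plan | None = None) -> pd.DataFrame:
    """Place features on two synthetic chromosomes.

    Non-cis features sit on a 300-kb grid, so every unplanted lncRNA-mRNA
    gap exceeds the 100-kb cis window.  Each planted cis lncRNA is placed
    downstream of its partner mRNA with a gap drawn uniformly in
    [0, cis_window_bp].  circRNAs are placed inside their host mRNA.
    """
    if plan is None:
        rng = rng if rng is not None else np.random.default_rng(params.seed)
        plan = _plan(params, np.random.default_rng(rng.integers(2**31)))
    grid_rng = np.random.default_rng(params.seed + 101)

    cis_lnc = {l for l, _ in plan.cis_pairs}
    rows = []
    spacing = 300_000
    cursors = {"chr1": 1_000_000, "chr2": 1_000_000}
    chrom_of: dict = {}
    placed: dict = {}

    lengths = {
        "mRNA": lambda: int(grid_rng.integers(2_000, 20_000)),
        "lncRNA": lambda: int(grid_rng.integers(500, 10_000)),
        "miRNA": lambda: int(grid_rng.integers(60, 120)),
    }
    grid_features = (
        [(g, "mRNA") for g in plan.ids["mRNA"]]
        + [(l, "lncRNA") for l in plan.ids["lncRNA"] if l not in cis_lnc]
        + [(m, "miRNA") for m in plan.ids["miRNA"]]
    )
    for i, (fid, cls) in enumerate(grid_features):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        start = cursors[chrom]
        end = start + lengths[cls]()
        cursors[chrom] = start + spacing
        strand = "+" if grid_rng.random() < 0.5 else "-"
        chrom_of[fid] = chrom
        placed[fid] = (start, end)
        rows.append((fid, chrom, start, end, strand, cls, None))

    for l, g in plan.cis_pairs:
        g_start, g_end = placed[g]
        gap = int(grid_rng.integers(0, params.cis_window_bp + 1))
        start = g_end + gap
        end = start + int(grid_rng.integers(500, 10_000))
        rows.append((l, chrom_of[g], start, end,
                     "+" if grid_rng.random() < 0.5 else "-", "lncRNA", None))

    hosts = grid_rng.choice(plan.ids["mRNA"], size=len(plan.ids["circRNA"]), replace=False)
    for c, host in zip(plan.ids["circRNA"], hosts):
        h_start, h_end = placed[host]
        start = h_start
        end = min(h_end, start + int(grid_rng.integers(300, 3_000)))
        rows.append((c, chrom_of[host], start, max(end, start + 200), "+", "circRNA", host))

    ann = pd.DataFrame(rows, columns=["feature_id", "chromosome", "start", "end",
                                      "strand", "rna_class", "host_gene_id"])
    return ann.sort_values(["chromosome", "start", "feature_id"]).reset_index(drop=True)


def simulate_counts(params: SimParams, annotation: pd.DataFrame | None = None
                    ) -> tuple[CountMatrix, pd.DataFrame, TruthBundle, pd.DataFrame]:
    """Draw the count matrix; returns (counts, samples, truth, annotation).

    The mean model on the log2 scale is
    ``log2 mu = log2(base) + profile(t) + z_module + loading * w_triad``
    with per-module and per-miRNA-anchored latent factors drawn per sample;
    counts are NB with per-sample library factors ``s_j``.
    """
    master = np.random.default_rng(params.seed)
    plan = _plan(params, np.random.default_rng(master.integers(2**31)))
    if annotation is None:
        annotation = simulate_annotation(params, plan=plan)
    noise_rng = np.random.default_rng(master.integers(2**31))

    tps = np.repeat(TIME_POINTS, params.n_replicates)
    reps = np.tile(np.arange(1, params.n_replicates + 1), len(TIME_POINTS))
    sample_ids = [f"T{t:02d}_r{r}" for t, r in zip(tps, reps)]
    samples = pd.DataFrame({"sample_id": sample_ids, "time_point_hours": tps,
                            "replicate": reps})
    n_samples = len(sample_ids)
    tp_index = {t: i for i, t in enumerate(TIME_POINTS)}
    tp_of_sample = np.array([tp_index[t] for t in tps])

    feature_ids = [f for cls in ("lncRNA", "circRNA", "miRNA", "mRNA")
                   for f in plan.ids[cls]]
    cls_of = {f: cls for cls in plan.ids for f in plan.ids[cls]}

    # latent factors
    module_latent = {
        m: noise_rng.normal(0.0, params.module_latent_sd, size=n_samples)
        for m in range(1, params.n_modules + 1)
    }
    triad_latent = {
        mir: noise_rng.normal(0.0, params.triad_latent_sd, size=n_samples)
        for mir in plan.triad_mirna_module
    }
    cis_latent = {
        i: noise_rng.normal(0.0, params.cis_latent_sd, size=n_samples)
        for i in range(len(plan.cis_pairs))
    }
    lib = np.exp(noise_rng.uniform(np.log(params.library_size_range[0]),
                                   np.log(params.library_size_range[1]),
                                   size=n_samples))

    log2mu = np.zeros((len(feature_ids), n_samples))
    base = np.empty(len(feature_ids))
    for i, f in enumerate(feature_ids):
        lo, hi = params.base_mean_range[cls_of[f]]
        if f in plan.well_expressed:
            lo = np.sqrt(lo * hi)  # upper half of the class range, log scale
        base[i] = np.exp(noise_rng.uniform(np.log(lo), np.log(hi)))
        row = np.log2(base[i]) * np.ones(n_samples)
        prof = plan.profiles.get(f)
        if prof is not None:
            row = row + prof[tp_of_sample]
        m = plan.module_of.get(f)
        if m is not None:
            row = row + module_latent[m]
        anchor = plan.triad_latent_member.get(f)
        if anchor is not None:
            mir, loading = anchor
            row = row + loading * triad_latent[mir]
        pair = plan.cis_latent_member.get(f)
        if pair is not None:
            row = row + cis_latent[pair]
        log2mu[i] = row

    mu = lib[None, :] * 2.0 ** log2mu
    counts = _nb_draw(mu, params.dispersion, noise_rng)

    cm_df = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                         columns=sample_ids)
    if params.outlier_sample is not None:
        if params.outlier_sample not in cm_df.columns:
            raise ValueError(f"unknown outlier sample: {params.outlier_sample}")
        pick = noise_rng.random(len(feature_ids)) < params.outlier_gene_frac
        col = cm_df[params.outlier_sample].to_numpy().astype(float)
        col[pick] = np.round(col[pick] * params.outlier_fold)
        cm_df[params.outlier_sample] = col.astype(np.int64)

    ann_idx = annotation.set_index("feature_id")
    lengths = (ann_idx["end"] - ann_idx["start"]).reindex(feature_ids)
    rna_class = ann_idx["rna_class"].reindex(feature_ids)
    cm = CountMatrix(cm_df, rna_class, lengths)

    contrasts = [t for t in TIME_POINTS if t != 0]
    de_truth = pd.DataFrame(0, index=pd.Index(feature_ids, name="feature_id"),
                            columns=contrasts, dtype=int)
    for f, prof in plan.profiles.items():
        delta = prof[1:] - prof[0]
        de_truth.loc[f] = np.sign(delta).astype(int)

    truth = TruthBundle(
        de_truth=de_truth,
        module_truth=plan.module_truth,
        cis_truth=set(plan.cis_pairs),
        triad_truth=set(plan.triads),
        params=params,
    )
    return cm, samples, truth, annotation


def _nb_draw(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mean mu, var mu + phi mu^2) via the gamma-Poisson mixture."""
    if phi == 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mu * phi)
    return rng.poisson(lam)


def simulate_targets(truth: TruthBundle, params: SimParams | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """miRNA-target table: planted triad links plus Bernoulli background.

    Every planted triad (c, m, g) contributes rows (m -> c) and (m -> g);
    background rows are added independently with probability
    ``background_target_density`` over all non-planted (miRNA, target)
    combinations, with the source drawn uniformly from the two emulated
    prediction tools.
    """
    params = params if params is not None else truth.params
    rng = rng if rng is not None else np.random.default_rng(params.seed + 7)
    ids = _feature_ids(params)
    targets = ids["lncRNA"] + ids["circRNA"] + ids["mRNA"]

    planted = set()
    for c, m, g in sorted(truth.triad_truth):
        planted.add((m, c))
        planted.add((m, g))

    rows = [(m, t, "starbase_like" if rng.random() < 0.5 else "miranda_like",
             round(float(rng.uniform(0.5, 1.0)), 4))
            for m, t in sorted(planted)]

    if params.background_target_density > 0:
        mirnas = ids["miRNA"]
        mask = rng.random((len(mirnas), len(targets))) < params.background_target_density
        for i, m in enumerate(mirnas):
            for j in np.flatnonzero(mask[i]):
                pair = (m, targets[j])
                if pair in planted:
                    continue
                rows.append((m, targets[j],
                             "starbase_like" if rng.random() < 0.5 else "miranda_like",
                             round(float(rng.uniform(0.0, 1.0)), 4)))

    tt = pd.DataFrame(rows, columns=TARGET_COLUMNS)
    return tt.sort_values(["mirna_id", "target_id", "source"]).reset_index(drop=True)


def simulate_term_map(truth: TruthBundle, n_terms: int = 40,
                      term_size_range: tuple = (10, 80),
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic term-gene map over the mRNA universe.

    Most terms are random draws; one term per planted module is built from
    that module's members so over-representation of hub genes is recoverable.
    """
    params = truth.params
    rng = rng if rng is not None else np.random.default_rng(params.seed + 13)
    universe = list(truth.module_truth.index)
    rows = []
    modules = sorted(set(truth.module_truth) - {0})
    for m in modules:
        members = truth.module_truth.index[truth.module_truth == m]
        pick = rng.choice(members, size=min(40, len(members)), replace=False)
        for g in sorted(pick):
            rows.append((f"TERM_module{m}", g, f"planted module {m} program"))
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        for g in sorted(rng.choice(universe, size=size, replace=False)):
            rows.append((f"TERM_{t:03d}", g, f"random gene set {t}"))
    return pd.DataFrame(rows, columns=["term_id", "gene_id", "term_name"])
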
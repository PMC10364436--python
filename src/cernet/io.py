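"""Readers, writers and core tabular types shared by every pipeline stage.

The pipeline operates on four RNA classes (lncRNA, circRNA, miRNA, mRNA)
profiled over a multi-time-point replicated design.  All on-disk formats are
plain TSV/YAML/GraphML/SIF so that fixtures and outputs stay text-only and
diffable.  Genomic coordinates are stored internally as 0-based half-open
intervals; GTF-style input (1-based, inclusive) is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

RNA_CLASSES = ("lncRNA", "circRNA", "miRNA", "mRNA")

ANNOTATION_COLUMNS = [
    "feature_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "rna_class",
    "host_gene_id",
]

TARGET_COLUMNS = ["mirna_id", "target_id", "source", "score"]

TARGET_SOURCES = ("starbase_like", "miranda_like")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad columns, wrong dtypes)."""


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, tagged by RNA class.

    ``counts`` is a features-by-samples integer DataFrame; ``rna_class`` and
    ``length`` are Series aligned to ``counts.index``.  Lengths are feature
    lengths in nucleotides, used for TPM/FPKM.
    """

    counts: pd.DataFrame
    rna_class: pd.Series
    length: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.rna_class = self.rna_class.reindex(self.counts.index)
        self.length = self.length.reindex(self.counts.index)
        if self.rna_class.isna().any():
            missing = self.rna_class.index[self.rna_class.isna()].tolist()
            raise KeyError(f"features missing rna_class: {missing[:10]}")
        bad = set(self.rna_class.unique()) - set(RNA_CLASSES)
        if bad:
            raise ValueError(f"unknown rna_class values: {sorted(bad)}")
        if self.length.isna().any() or (self.length <= 0).any():
            raise ValueError("all feature lengths must be positive")
        self.length = self.length.astype(np.int64)

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_features(self, ids) -> "CountMatrix":
        ids = pd.Index(ids)
        return CountMatrix(self.counts.loc[ids], self.rna_class.loc[ids], self.length.loc[ids])

    def subset_class(self, rna_class: str) -> "CountMatrix":
        keep = self.rna_class.index[self.rna_class == rna_class]
        return self.subset_features(keep)


@dataclass
class Config:
    """Run configuration: the analysis thresholds and pipeline options.

    Default thresholds: fold-change 1.5 for lncRNA/miRNA/mRNA and 1.0 for
    circRNA (applied as ``|log2FC| > log2(threshold)``), raw p < 0.05 for DE
    calls, a 100-kb cis window, |r| > 0.6 (cis) and |r| > 0.9 (trans) Pearson
    cutoffs, hub-gene rules |MM| > 0.8 and |GS| > 0.5, Spearman p < 0.05 for
    ceRNA triads, and FDR < 0.05 for enrichment.
    """

    fc_lnc_mi_mrna: float = 1.5
    fc_circ: float = 1.0
    p_de: float = 0.05
    cis_window_bp: int = 100_000
    r_cis: float = 0.6
    r_trans: float = 0.9
    mm_hub: float = 0.8
    gs_hub: float = 0.5
    spearman_p: float = 0.05
    fdr_enrich: float = 0.05
    # "auto" picks the soft power from the scale-free fit table.
    soft_power: int | str = "auto"
    min_module_size: int = 30
    merge_height: float = 0.25
    module_cut_height: float = 0.99
    scale_free_target: float = 0.85
    # zero-fraction at/above which a feature is dropped by the expression filter
    low_expression_zero_fraction: float = 0.25
    # exclude cis-window-eligible pairs from the trans network
    trans_excludes_cis: bool = True
    # combine the two target sources by "union" or "intersection"
    target_combine: str = "union"
    # Spearman triad filter reads "p" (correlation-test p < spearman_p) or
    # "rho" (|rho| < spearman_p); "p" is the default interpretation.
    spearman_filter_on: str = "p"
    seed: int = 0
    # file paths (used by the CLI / run-all); None means "simulate"
    simulate: bool = True
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    targets_path: str | None = None
    term_map_path: str | None = None
    output_dir: str = "cernet_run"
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("fc_lnc_mi_mrna", "fc_circ", "p_de", "cis_window_bp", "r_cis",
                     "r_trans", "mm_hub", "gs_hub", "spearman_p", "fdr_enrich"):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.spearman_filter_on not in ("p", "rho"):
            raise ValueError("spearman_filter_on must be 'p' or 'rho'")
        if self.target_combine not in ("union", "intersection"):
            raise ValueError("target_combine must be 'union' or 'intersection'")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers


def read_annotation(path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a feature annotation table.

    ``fmt='tsv'`` expects the simplified 7-column layout
    (feature_id, chromosome, start, end, strand, rna_class, host_gene_id)
    with 0-based half-open coordinates.  ``fmt='gtf'`` accepts GTF-like
    9-column input (1-based inclusive; feature_id/rna_class/host_gene_id
    parsed from the attributes field) and converts coordinates on read.
    """
    if fmt == "tsv":
        ann = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, keep_default_na=True)
        missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        ann = ann[ANNOTATION_COLUMNS]
    elif fmt == "gtf":
        raw = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chromosome", "source", "feature", "start", "end",
                   "score", "strand", "frame", "attributes"],
            dtype={"chromosome": str},
        )

        def attr(s, key):
            for part in s.rstrip(";").split(";"):
                k, _, v = part.strip().partition(" ")
                if k == key:
                    return v.strip().strip('"')
            return None

        ann = pd.DataFrame({
            "feature_id": raw["attributes"].map(lambda s: attr(s, "gene_id")),
            "chromosome": raw["chromosome"],
            "start": raw["start"].astype(np.int64) - 1,  # GTF is 1-based inclusive
            "end": raw["end"].astype(np.int64),
            "strand": raw["strand"],
            "rna_class": raw["attributes"].map(lambda s: attr(s, "gene_biotype")),
            "host_gene_id": raw["attributes"].map(lambda s: attr(s, "host_gene_id")),
        })
    else:
        raise ValueError(f"unknown annotation format: {fmt}")
    validate_annotation(ann)
    return ann.reset_index(drop=True)


def validate_annotation(ann: pd.DataFrame) -> None:
    if ann["feature_id"].duplicated().any():
        dups = ann.loc[ann["feature_id"].duplicated(), "feature_id"].tolist()
        raise FormatError(f"duplicate feature ids in annotation: {dups[:10]}")
    if not (ann["start"] < ann["end"]).all():
        bad = ann.loc[~(ann["start"] < ann["end"]), "feature_id"].tolist()
        raise ValueError(f"start must be < end: {bad[:10]}")
    if not ann["strand"].isin(["+", "-", "."]).all():
        raise ValueError("strand must be one of +, -, .")
    bad = set(ann["rna_class"].unique()) - set(RNA_CLASSES)
    if bad:
        raise ValueError(f"unknown rna_class values: {sorted(bad)}")
    has_host = ann["host_gene_id"].notna()
    if (ann.loc[has_host, "rna_class"] != "circRNA").any():
        raise ValueError("host_gene_id is only valid for circRNAs")
    mrna_ids = set(ann.loc[ann["rna_class"] == "mRNA", "feature_id"])
    bad_hosts = set(ann.loc[has_host, "host_gene_id"]) - mrna_ids
    if bad_hosts:
        raise ValueError(f"host_gene_id must name an mRNA feature: {sorted(bad_hosts)[:10]}")


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path, annotation: pd.DataFrame) -> CountMatrix:
    """Read a counts TSV (first column feature ids, header sample ids).

    RNA class and feature length are joined from ``annotation``; feature
    lengths are taken as ``end - start``.  Order of the file is preserved.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen, dups = set(), []
    for s in samples:
        if s in seen:
            dups.append(s)
        seen.add(s)
    if dups:
        raise FormatError(f"duplicate sample columns: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = samples
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids: {dups}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("counts must be numeric")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    ann = annotation.set_index("feature_id")
    missing = df.index.difference(ann.index)
    if len(missing):
        raise KeyError(f"features absent from annotation: {missing.tolist()[:20]}")
    lengths = (ann["end"] - ann["start"]).reindex(df.index)
    return CountMatrix(df.astype(np.int64), ann["rna_class"].reindex(df.index), lengths)


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    st = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "time_point_hours", "replicate"} - set(st.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    validate_sample_table(st)
    return st


def validate_sample_table(st: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    if st["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in sample table")
    counts_per_tp = st.groupby("time_point_hours").size()
    if (counts_per_tp < 2).any():
        bad = counts_per_tp.index[counts_per_tp < 2].tolist()
        raise ValueError(f"every time point needs >= 2 replicates; offenders: {bad}")
    if counts is not None and set(st["sample_id"]) != set(counts.columns):
        raise ValueError("sample table does not match count matrix columns")


def write_sample_table(st: pd.DataFrame, path) -> None:
    st.to_csv(path, sep="\t", index=False)


def read_targets(path, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    tt = pd.read_csv(path, sep="\t")
    missing = set(TARGET_COLUMNS[:3]) - set(tt.columns)
    if missing:
        raise FormatError(f"target table missing columns: {sorted(missing)}")
    if "score" not in tt.columns:
        tt["score"] = np.nan
    if tt.duplicated(subset=["mirna_id", "target_id", "source"]).any():
        raise FormatError("duplicate (mirna_id, target_id, source) rows in target table")
    if not tt["source"].isin(TARGET_SOURCES).all():
        raise ValueError(f"target source must be one of {TARGET_SOURCES}")
    if annotation is not None:
        cls = annotation.set_index("feature_id")["rna_class"]
        if (cls.reindex(tt["mirna_id"]) != "miRNA").any():
            raise ValueError("all mirna_id entries must have rna_class miRNA")
        if (cls.reindex(tt["target_id"]) == "miRNA").any():
            raise ValueError("target_id entries must not be miRNAs")
    return tt[TARGET_COLUMNS]


def write_targets(tt: pd.DataFrame, path) -> None:
    tt[TARGET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_term_map(path) -> pd.DataFrame:
    tm = pd.read_csv(path, sep="\t")
    if not {"term_id", "gene_id"} <= set(tm.columns):
        raise FormatError("term map needs term_id and gene_id columns")
    if "term_name" not in tm.columns:
        tm["term_name"] = tm["term_id"]
    return tm[["term_id", "gene_id", "term_name"]]


# ---------------------------------------------------------------------------
# expression filter


def filter_low_expression(cm: CountMatrix, zero_fraction: float = 0.25) -> CountMatrix:
    """Drop features whose zero-count fraction is >= ``zero_fraction``.

    A feature with zeros in exactly 25% of samples is excluded (strict
    boundary).  Idempotent.  An empty result raises a warning, not an error.
    """
    frac_zero = (cm.counts == 0).mean(axis=1)
    keep = cm.counts.index[frac_zero < zero_fraction]
    if len(keep) == 0:
        warnings.warn("no features pass the low-expression filter", stacklevel=2)
    return cm.subset_features(keep)


# ---------------------------------------------------------------------------
# network export


def export_network(nodes: pd.DataFrame, edges: pd.DataFrame, prefix) -> tuple[Path, Path]:
    """Write a network as GraphML and SIF with deterministic ordering.

    ``nodes`` must have an ``id`` column plus attribute columns (e.g.
    rna_class, module); ``edges`` must have ``source`` and ``target`` and may
    carry an ``interaction`` column (defaults to ``"pp"``) plus numeric edge
    attributes.  Every edge endpoint must appear in ``nodes``.
    """
    prefix = Path(prefix)
    node_ids = set(nodes["id"])
    dangling = (set(edges["source"]) | set(edges["target"])) - node_ids if len(edges) else set()
    if dangling:
        raise ValueError(f"edge endpoints missing from node table: {sorted(dangling)[:10]}")

    g = nx.Graph()
    attr_cols = [c for c in nodes.columns if c != "id"]
    for _, row in nodes.sort_values("id").iterrows():
        g.add_node(row["id"], **{c: _graphml_safe(row[c]) for c in attr_cols})
    edges = edges.copy()
    if "interaction" not in edges.columns:
        edges["interaction"] = "pp"
    edge_attr_cols = [c for c in edges.columns if c not in ("source", "target")]
    edges = edges.sort_values(["source", "target"]).reset_index(drop=True)
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"],
                   **{c: _graphml_safe(row[c]) for c in edge_attr_cols})

    graphml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    sif_path = prefix.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['source']}\t{row['interaction']}\t{row['target']}\n")
    return graphml_path, sif_path


def _graphml_safe(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return value
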
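"""Typed on-disk artifacts shared by the synthetic and real-data paths.

Every artifact is a plain TSV (UTF-8, '.' decimal, no quoting): matrices are
gene-by-sample tables with a sidecar sample→group map, copy-number calls follow
the GISTIC "thresholded by genes" layout, mutations are a minimal MAF-like
table, and the functional-linkage network is a 3-column weighted edge list.
Readers enforce the type invariants and fail loudly rather than dropping rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CALLS = frozenset({-2, -1, 0, 1, 2})
DEFAULT_SILENT_CLASSES = frozenset({"Silent"})

ER_LEVELS = {"pos", "neg", "unknown"}
STAGE_LEVELS = {"early", "late", "unknown"}
AGE_LEVELS = {"young", "old"}


class OmicsIOError(ValueError):
    """Raised when an on-disk artifact violates its contract."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise OmicsIOError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """log2-scale expression, genes × samples, with tumor/normal labels."""

    values: pd.DataFrame  # index = genes, columns = samples
    group: pd.Series  # sample -> {"tumor", "normal"}

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        missing = set(self.values.columns) - set(self.group.index)
        if missing:
            raise OmicsIOError(f"samples without group label: {sorted(missing)[:5]}")
        bad = set(self.group.loc[list(self.values.columns)]) - {"tumor", "normal"}
        if bad:
            raise OmicsIOError(f"unknown group label(s): {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise OmicsIOError("non-finite expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tumor_samples(self) -> list[str]:
        g = self.group.loc[list(self.values.columns)]
        return list(g.index[g == "tumor"])

    def normal_samples(self) -> list[str]:
        g = self.group.loc[list(self.values.columns)]
        return list(g.index[g == "normal"])


@dataclass
class MethylationMatrix:
    """Promoter-level methylation beta values in [0, 1], genes × samples."""

    beta: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.beta.index, "gene")
        _check_unique(self.beta.columns, "sample")
        arr = self.beta.to_numpy()
        if not np.isfinite(arr).all():
            raise OmicsIOError("non-finite beta values")
        if (arr < 0).any() or (arr > 1).any():
            r, c = np.argwhere((arr < 0) | (arr > 1))[0]
            raise OmicsIOError(
                f"beta outside [0,1] at gene {self.beta.index[r]!r}, "
                f"sample {self.beta.columns[c]!r}"
            )
        missing = set(self.beta.columns) - set(self.group.index)
        if missing:
            raise OmicsIOError(f"samples without group label: {sorted(missing)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.beta.index)

    def tumor_samples(self) -> list[str]:
        g = self.group.loc[list(self.beta.columns)]
        return list(g.index[g == "tumor"])


@dataclass
class CnaCalls:
    """GISTIC-style per-gene integer copy-number calls plus region gene lists."""

    call: pd.DataFrame  # genes × tumor samples, entries in {-2..2}
    amp_genes: set[str] = field(default_factory=set)
    del_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        _check_unique(self.call.index, "gene")
        _check_unique(self.call.columns, "sample")
        arr = self.call.to_numpy()
        if not np.equal(np.mod(arr, 1), 0).all():
            raise OmicsIOError("copy-number calls must be integral")
        bad = set(np.unique(arr).astype(int)) - VALID_CALLS
        if bad:
            raise OmicsIOError(f"call value(s) outside {{-2..2}}: {sorted(bad)}")
        self.amp_genes = set(self.amp_genes)
        self.del_genes = set(self.del_genes)


@dataclass
class MutationTable:
    """Somatic mutation records (gene, sample, variant_class)."""

    records: pd.DataFrame  # columns: gene, sample, variant_class

    def __post_init__(self) -> None:
        required = {"gene", "sample", "variant_class"}
        if not required.issubset(self.records.columns):
            raise OmicsIOError(f"mutation table needs columns {sorted(required)}")
        if self.records.duplicated().any():
            raise OmicsIOError("exact duplicate mutation records")
        bad = set(self.records["variant_class"]) - {"silent", "nonsilent"}
        if bad:
            raise OmicsIOError(f"unknown variant class(es): {sorted(bad)}")

    def nonsilent(self) -> pd.DataFrame:
        return self.records[self.records["variant_class"] == "nonsilent"]

    def nonsilent_sample_counts(self) -> pd.Series:
        """Distinct mutated samples per gene, silent records removed."""
        ns = self.nonsilent()
        return ns.groupby("gene")["sample"].nunique()


@dataclass
class ClinicalTable:
    """Per-tumor-sample survival outcome and binary clinical covariates."""

    table: pd.DataFrame  # index = sample; os_time, os_event, age_group, er, pr, stage

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample")
        required = {"os_time", "os_event", "age_group", "er", "pr", "stage"}
        if not required.issubset(t.columns):
            raise OmicsIOError(f"clinical table needs columns {sorted(required)}")
        if (t["os_time"] <= 0).any():
            raise OmicsIOError("os_time must be > 0")
        if not set(t["os_event"]).issubset({0, 1}):
            raise OmicsIOError("os_event must be 0/1")
        for col, levels in (
            ("age_group", AGE_LEVELS),
            ("er", ER_LEVELS),
            ("pr", ER_LEVELS),
            ("stage", STAGE_LEVELS),
        ):
            bad = set(t[col]) - levels
            if bad:
                raise OmicsIOError(f"invalid {col} value(s): {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DrgAnnotation:
    """Drug-response genes with the drug each annotates."""

    records: pd.DataFrame  # columns: gene, drug

    def __post_init__(self) -> None:
        if not {"gene", "drug"}.issubset(self.records.columns):
            raise OmicsIOError("DRG annotation needs columns gene, drug")
        if len(self.records) == 0:
            raise OmicsIOError("DRG annotation must contain at least one record")
        if self.records.duplicated(["gene", "drug"]).any():
            raise OmicsIOError("duplicate (gene, drug) record")

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])


# ---------------------------------------------------------------------------
# matrices


def _read_group(path) -> pd.Series:
    g = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    _check_unique(g["sample"], "sample")
    return g.set_index("sample")["group"]


def write_group(group: pd.Series, path) -> None:
    group.rename_axis("sample").to_csv(path, sep="\t", header=False)


def read_matrix(path, kind: str, group_path) -> ExpressionMatrix | MethylationMatrix:
    """Read a gene × sample TSV plus its sample→group sidecar.

    ``kind`` selects the invariants enforced: ``"expression"`` (finite log2
    values) or ``"methylation"`` (beta in [0, 1]).
    """
    if kind not in {"expression", "methylation"}:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise OmicsIOError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    group = _read_group(group_path)
    if kind == "expression":
        return ExpressionMatrix(values=df, group=group)
    return MethylationMatrix(beta=df, group=group)


def write_matrix(mat: ExpressionMatrix | MethylationMatrix, path, group_path) -> None:
    df = mat.values if isinstance(mat, ExpressionMatrix) else mat.beta
    df.rename_axis("gene").to_csv(path, sep="\t", float_format="%.10g")
    write_group(mat.group, group_path)


# ---------------------------------------------------------------------------
# CNA


def read_cna(path_calls, path_amp, path_del) -> CnaCalls:
    calls = pd.read_csv(path_calls, sep="\t", index_col=0)
    try:
        calls = calls.astype(int)
    except ValueError as exc:
        raise OmicsIOError(f"non-integer call in {path_calls}: {exc}") from exc
    calls.index = calls.index.astype(str)
    amp = _read_gene_list(path_amp)
    dele = _read_gene_list(path_del)
    return CnaCalls(call=calls, amp_genes=amp, del_genes=dele)


def _read_gene_list(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_cna(cna: CnaCalls, path_calls, path_amp, path_del) -> None:
    cna.call.rename_axis("gene").to_csv(path_calls, sep="\t")
    for genes, path in ((cna.amp_genes, path_amp), (cna.del_genes, path_del)):
        with open(path, "w", encoding="utf-8") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")


# ---------------------------------------------------------------------------
# mutations


def read_mutations(path, silent_classes=DEFAULT_SILENT_CLASSES) -> MutationTable:
    """Read a minimal MAF-like TSV.

    Variant classes in ``silent_classes`` map to ``silent``; everything else is
    ``nonsilent`` (the configurable boundary for "removing silent mutations").
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    if not required.issubset(df.columns):
        raise OmicsIOError(f"mutation file needs columns {sorted(required)}")
    out = pd.DataFrame(
        {
            "gene": df["Hugo_Symbol"],
            "sample": df["Tumor_Sample_Barcode"],
            "variant_class": np.where(
                df["Variant_Classification"].isin(list(silent_classes)),
                "silent",
                "nonsilent",
            ),
        }
    )
    out = out.drop_duplicates(ignore_index=True)
    return MutationTable(records=out)


def write_mutations(mut: MutationTable, path) -> None:
    df = pd.DataFrame(
        {
            "Hugo_Symbol": mut.records["gene"],
            "Tumor_Sample_Barcode": mut.records["sample"],
            "Variant_Classification": np.where(
                mut.records["variant_class"] == "silent", "Silent", "Missense_Mutation"
            ),
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df["os_time"] = df["os_time"].astype(float)
    df["os_event"] = df["os_event"].astype(int)
    for col, levels in (("er", ER_LEVELS), ("pr", ER_LEVELS), ("stage", STAGE_LEVELS)):
        unknown = ~df[col].isin(list(levels))
        if unknown.any():
            logger.warning(
                "%d unrecognized %s value(s) mapped to 'unknown'", unknown.sum(), col
            )
            df.loc[unknown, col] = "unknown"
    return ClinicalTable(table=df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.table.rename_axis("sample").to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# DRG annotation


def read_drg(path) -> DrgAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "drug"}.issubset(df.columns):
        raise OmicsIOError("DRG file needs columns gene, drug")
    return DrgAnnotation(records=df)


def write_drg(drg: DrgAnnotation, path) -> None:
    drg.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network


def read_network(path) -> nx.Graph:
    """Read a weighted undirected edge list (geneA, geneB, weight).

    Weights must lie in (0, 1]; self-loops and duplicate undirected edges are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "w"], dtype=str)
    g = nx.Graph()
    seen: set[tuple[str, str]] = set()
    for i, (a, b, w) in enumerate(df.itertuples(index=False), start=1):
        if a == b:
            raise OmicsIOError(f"self-loop on gene {a!r} at line {i}")
        w = float(w)
        if not 0 < w <= 1:
            raise OmicsIOError(f"weight {w} outside (0,1] at line {i}")
        key = (a, b) if a < b else (b, a)
        if key in seen:
            raise OmicsIOError(f"duplicate undirected edge {key} at line {i}")
        seen.add(key)
        g.add_edge(a, b, weight=w)
    return g


def write_network(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\t{graph[a][b]['weight']:.10g}\n")
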
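"""Readers and writers for the external formats the pipeline touches.

Count matrices, sample sheets, STRING-style edge lists and GMT gene-set
collections all arrive as plain TSV; every reader validates its invariants
eagerly so downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleAnnotation",
    "PPINetwork",
    "PathwayDB",
    "read_counts",
    "read_sample_sheet",
    "read_string_edges",
    "read_gmt",
    "write_table",
]

_TB_LEVELS = ("low", "intermediate", "high")


@dataclass
class CountMatrix:
    """Integer expression counts, genes (or probes) x samples.

    ``level`` distinguishes probe-level matrices (duplicate gene symbols
    allowed, e.g. 22,537 probes collapsing to 19,703 genes on a targeted
    whole-transcriptome panel) from collapsed gene-level matrices where
    symbols must be unique.
    """

    row_ids: list[str]
    gene_symbols: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    level: str = "gene"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        n_rows, n_samples = self.counts.shape
        if n_rows != len(self.row_ids) or n_samples != len(self.sample_ids):
            raise ValueError("counts shape does not match row/sample ids")
        if len(self.gene_symbols) != n_rows:
            raise ValueError("one gene symbol required per row")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative count")
        if len(set(self.row_ids)) != n_rows:
            dup = pd.Index(self.row_ids)
            dup = dup[dup.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dup}")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")
        if self.level not in ("probe", "gene"):
            raise ValueError("level must be 'probe' or 'gene'")
        if self.level == "gene" and len(set(self.gene_symbols)) != n_rows:
            raise ValueError("gene-level matrix requires unique gene symbols")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Per-sample tumor-budding level plus the derived binary class.

    ``class_label`` is 1 for high-TB, 0 for low-TB and absent (NaN) for
    intermediate samples, which are excluded from the two-class contrast.
    """

    table: pd.DataFrame  # columns: sample_id, tb_level, class_label

    def __post_init__(self) -> None:
        required = {"sample_id", "tb_level", "class_label"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation must have columns {sorted(required)}")
        bad = set(self.table["tb_level"]) - set(_TB_LEVELS)
        if bad:
            raise ValueError(f"unknown tb_level token(s): {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in annotation")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def labeled(self) -> pd.DataFrame:
        """Rows with a defined binary class (low or high TB)."""
        return self.table.dropna(subset=["class_label"])

    def class_vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Binary class for the given samples; raises if any is unlabeled."""
        lut = self.table.set_index("sample_id")["class_label"]
        y = lut.reindex(list(sample_ids))
        if y.isna().any():
            missing = y.index[y.isna()].tolist()
            raise ValueError(f"samples without binary class label: {missing}")
        return y.to_numpy(dtype=int)


@dataclass
class PPINetwork:
    """Undirected weighted protein-interaction graph (no self-loops)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(a == b for a, b in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        for a, b, w in self.graph.edges(data="weight"):
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({a},{b}) weight {w} outside (0,1]")

    @classmethod
    def from_edges(cls, edges: Sequence[tuple[str, str, float]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b, w in edges:
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], float(w))
            else:
                g.add_edge(a, b, weight=float(w))
        return cls(g)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        for a, b, w in self.graph.edges(data="weight"):
            a2, b2 = sorted((a, b))
            out.append((a2, b2, w))
        return sorted(out)


@dataclass
class PathwayDB:
    """Named gene sets (GO/KEGG-style collections)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_counts(path: str | Path, level: str = "gene") -> CountMatrix:
    """Read a counts TSV: first column row id, optional second column gene
    symbol (header named gene/symbol/gene_symbol), remaining columns samples.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str,
                         on_bad_lines="error", engine="c")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged rows in {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError("counts TSV needs a row-id column and >=1 sample")
    row_ids = df.iloc[:, 0].astype(str).tolist()
    second = df.columns[1].strip().lower()
    if second in ("gene", "symbol", "gene_symbol"):
        symbols = df.iloc[:, 1].astype(str).tolist()
        data = df.iloc[:, 2:]
    else:
        symbols = list(row_ids)
        data = df.iloc[:, 1:]
    sample_ids = [str(c) for c in data.columns]
    try:
        values = data.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in {path}: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError("missing count value")
    if (values < 0).any():
        raise ValueError("negative count")
    if not np.allclose(values, np.round(values)):
        raise ValueError("non-integer count")
    return CountMatrix(row_ids, symbols, sample_ids,
                       values.astype(np.int64), level=level)


def read_sample_sheet(path: str | Path) -> SampleAnnotation:
    """Read a sample sheet TSV with columns sample_id and tb_level.

    tb_level tokens are case-insensitive; high maps to class 1, low to 0,
    intermediate to no class label.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "tb_level"}.issubset(df.columns):
        raise ValueError("sample sheet needs columns sample_id, tb_level")
    levels = df["tb_level"].str.strip().str.lower()
    bad = set(levels) - set(_TB_LEVELS)
    if bad:
        raise ValueError(f"unknown tb_level token(s): {sorted(bad)}")
    mapping = {"high": 1.0, "low": 0.0, "intermediate": np.nan}
    out = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "tb_level": levels,
        "class_label": levels.map(mapping),
    })
    return SampleAnnotation(out)


def read_string_edges(path: str | Path, min_score: float = 0.4) -> PPINetwork:
    """Read a STRING ``protein.links``-style edge list.

    Scores may be on the published 0-999 integer scale or already on 0-1;
    any value > 1 switches the whole file to the 0-999 interpretation
    (divide by 1000), so a file already on 0-1 is never rescaled. Edges are
    kept only with weight strictly greater than ``min_score``; duplicate
    undirected pairs keep the maximum weight; self-loops are dropped.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.index[scores.isna()][0]) + 2  # header is line 1
        raise ValueError(f"malformed combined_score at line {line}")
    w = scores.to_numpy(dtype=float)
    if (w > 1.0).any():
        w = w / 1000.0
    edges = []
    for a, b, wi in zip(df["protein1"], df["protein2"], w):
        if a == b or wi <= min_score:
            continue
        edges.append((str(a), str(b), float(wi)))
    return PPINetwork.from_edges(edges)


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT file: name, description, then tab-separated member genes.

    Duplicate genes within a line are dropped (set size counts unique genes).
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
            desc[name] = description
    return PathwayDB(sets, desc)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with lossless float formatting."""
    records.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.to_frame().reset_index().rename(columns={"index": "row_id"})
    if cm.level == "probe" or cm.gene_symbols != cm.row_ids:
        df.insert(1, "gene_symbol", cm.gene_symbols)
    df.to_csv(path, sep="\t", index=False)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.sets.items():
            desc = db.descriptions.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_string_edges(net: PPINetwork, path: str | Path) -> None:
    """Emit a STRING-style edge list on the 0-1 scale (read back unchanged)."""
    rows = net.edge_list()
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")
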
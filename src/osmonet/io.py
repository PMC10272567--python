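"""Data model and readers/writers for the tables the pipeline touches.

Tabular files are TSV by default; a comma delimiter is autodetected from the
header line. Factor levels in design tables are case-normalized so that
``Control`` and ``control`` build the same contrast.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("sample_id", "genotype", "organ", "treatment", "replicate")

#: scale tags an ExpressionMatrix may carry; transitions happen only through
#: explicit transform operations.
SCALE_TAGS = ("raw", "log2", "log2p1", "standardized")


class OsmonetError(ValueError):
    """Base class for data-validation errors raised by this package."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet: one row per hybridized sample.

    ``table`` is indexed by ``sample_id`` and has columns
    ``genotype, organ, treatment, replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise OsmonetError(f"duplicate sample_id(s): {dupes}")
        missing = [c for c in DESIGN_COLUMNS[1:] if c not in self.table.columns]
        if missing:
            raise OsmonetError(f"design missing column(s): {missing}")
        if len(self.table) == 0:
            raise OsmonetError("no samples")
        sizes = self.table.groupby(["genotype", "organ", "treatment"], observed=True).size()
        small = sizes[sizes < 2]
        if len(small):
            raise OsmonetError(
                "each genotype x organ x treatment cell needs >=2 replicates "
                f"for variance estimation; undersized cells: {small.to_dict()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique())

    @property
    def organs(self) -> list[str]:
        return sorted(self.table["organ"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.table["treatment"].unique())

    def samples_where(self, **levels: str) -> list[str]:
        """Sample ids matching all given factor=level constraints."""
        mask = pd.Series(True, index=self.table.index)
        for factor, level in levels.items():
            if factor not in self.table.columns:
                raise OsmonetError(f"unknown design factor: {factor}")
            mask &= self.table[factor] == level
        return list(self.table.index[mask])

    def cells(self) -> list[tuple[str, str, str]]:
        """Distinct (genotype, organ, treatment) cells, sorted."""
        return sorted(
            set(
                zip(
                    self.table["genotype"],
                    self.table["organ"],
                    self.table["treatment"],
                )
            )
        )


@dataclass
class ExpressionMatrix:
    """Probes-or-genes x samples intensity table, the pipeline's carrier.

    ``values`` is indexed by row id (probe TC id or gene id) with sample ids
    as columns. ``scale_tag`` records the current scale and changes only via
    explicit transforms (see :mod:`osmonet.diffexpr` / :mod:`osmonet.clustering`).
    """

    values: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise OsmonetError(f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}")
        if self.values.index.has_duplicates:
            raise OsmonetError("duplicate row ids in expression matrix")
        if self.scale_tag == "raw" and (self.values.to_numpy() < 0).any():
            raise OsmonetError("raw intensities must be non-negative")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, rows: Iterable[str] | None = None, cols: Iterable[str] | None = None) -> "ExpressionMatrix":
        v = self.values
        if rows is not None:
            rows = list(rows)
            missing = set(rows) - set(v.index)
            if missing:
                raise OsmonetError(f"rows absent from matrix: {sorted(missing)[:5]}")
            v = v.loc[rows]
        if cols is not None:
            cols = list(cols)
            missing = set(cols) - set(v.columns)
            if missing:
                raise OsmonetError(f"samples absent from matrix: {sorted(missing)[:5]}")
            v = v[cols]
        return ExpressionMatrix(v.copy(), self.scale_tag)


@dataclass(frozen=True)
class ProbeGeneMap:
    """Probe→gene hit table in BLAST-tabular style.

    Columns: ``probe_id, gene_id, identity_pct, score``. Before best-hit
    resolution a probe may appear several times.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        ident = self.table["identity_pct"]
        bad = self.table[(ident < 0) | (ident > 100)]
        if len(bad):
            raise OsmonetError(
                f"identity_pct outside [0,100] for probe(s): {bad['probe_id'].tolist()[:5]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def gene_for(self, probe_id: str) -> str | None:
        hits = self.table.loc[self.table["probe_id"] == probe_id, "gene_id"]
        return None if hits.empty else hits.iloc[0]


@dataclass(frozen=True)
class TFAnnotation:
    """gene_id → TF family lookup."""

    table: pd.DataFrame  # columns: gene_id, tf_family

    def __post_init__(self) -> None:
        if self.table["gene_id"].duplicated().any():
            dupes = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].tolist()
            raise OsmonetError(f"duplicate gene_id(s) in TF annotation: {dupes[:5]}")

    @property
    def gene_ids(self) -> set[str]:
        return set(self.table["gene_id"])

    def family_of(self, gene_id: str) -> str | None:
        hit = self.table.loc[self.table["gene_id"] == gene_id, "tf_family"]
        return None if hit.empty else hit.iloc[0]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["tf_family"]))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if not header.strip():
        return "\t"
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample design table (TSV/CSV with the four factor columns).

    Factor levels are lower-cased for ``organ`` and ``treatment`` so contrast
    construction is case-robust; genotype case is preserved.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise OsmonetError("no samples") from None
    if df.empty:
        raise OsmonetError("no samples")
    df.columns = [c.strip().lower() for c in df.columns]
    unknown = [c for c in df.columns if c not in DESIGN_COLUMNS]
    if unknown:
        raise OsmonetError(f"unknown design column(s): {unknown}")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise OsmonetError(f"design missing column(s): {missing}")
    for col in ("organ", "treatment"):
        df[col] = df[col].str.strip().str.lower()
    df["genotype"] = df["genotype"].str.strip()
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise OsmonetError("replicate must be a positive integer")
    df = df.set_index("sample_id")
    design = SampleDesign(df)
    logger.info("read design: %d samples, %d cells", len(df), len(design.cells()))
    return design


def read_matrix(path: str | Path, design: SampleDesign) -> ExpressionMatrix:
    """Read an intensity matrix and align its columns to the design order.

    Extra non-design columns are dropped with a warning; a design sample
    missing from the matrix is a hard error.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise OsmonetError(f"design sample(s) missing from matrix: {missing}")
    extra = [c for c in df.columns if c not in design.sample_ids]
    if extra:
        logger.warning("dropping %d non-design column(s): %s", len(extra), extra[:5])
    df = df[design.sample_ids]
    if (df.to_numpy() < 0).any():
        raise OsmonetError("negative raw intensity in matrix")
    m = ExpressionMatrix(df, scale_tag="raw")
    logger.info("read matrix: %d rows x %d samples", *m.shape)
    return m


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="id")


def read_probe_gene_map(path: str | Path, min_identity: float = 90.0) -> ProbeGeneMap:
    """Read a BLAST-tabular hit file and drop hits below ``min_identity``.

    Assumes the standard 12-column tabular layout: query and subject ids in
    columns 1-2, percent identity in column 3, bit score in column 12. Files
    with exactly four columns are read as ``probe_id, gene_id, identity_pct,
    score``. The identity rule is inclusive: a hit at exactly ``min_identity``
    is retained.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] >= 12:
        df = df.iloc[:, [0, 1, 2, 11]]
    elif df.shape[1] == 4:
        pass
    else:
        raise OsmonetError(
            f"expected 4 or >=12 columns in probe-gene map, got {df.shape[1]}"
        )
    df.columns = ["probe_id", "gene_id", "identity_pct", "score"]
    # a header line, if present, will fail numeric conversion — strip it
    if not np.issubdtype(df["identity_pct"].dtype, np.number):
        first = df.iloc[0]
        try:
            float(first["identity_pct"])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        df["identity_pct"] = df["identity_pct"].astype(float)
        df["score"] = df["score"].astype(float)
    df["probe_id"] = df["probe_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    pg = ProbeGeneMap(df.reset_index(drop=True))
    return filter_identity(pg, min_identity)


def filter_identity(pg: ProbeGeneMap, min_identity: float = 90.0) -> ProbeGeneMap:
    """Drop hits with identity strictly below ``min_identity`` (idempotent)."""
    keep = pg.table["identity_pct"] >= min_identity
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("identity filter removed %d hit(s) below %.4g%%", n_removed, min_identity)
    return ProbeGeneMap(pg.table[keep].reset_index(drop=True))


def read_tf_annotation(path: str | Path) -> TFAnnotation:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"gene_id", "tf_family"} <= set(df.columns):
        raise OsmonetError("TF annotation needs columns gene_id, tf_family")
    return TFAnnotation(df[["gene_id", "tf_family"]].reset_index(drop=True))


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a co-expression network as GraphML or a 3-column edge list.

    GraphML carries node attributes (``is_tf``, ``cluster``, ``degree``,
    ``is_hub``) and edge attributes (``r``, ``p``); the edge list is a
    TSV with columns ``gene_a, gene_b, r``.
    """
    path = Path(path)
    if format == "graphml":
        g = net.copy()
        for _, data in g.nodes(data=True):
            for k, v in list(data.items()):
                if v is None:
                    data[k] = ""
        nx.write_graphml(g, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for a, b, data in sorted(net.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data.get('r', float('nan')):.6g}\n")
    else:
        raise OsmonetError(f"unknown network format {format!r}")
    logger.info("wrote %s network: %d nodes, %d edges -> %s",
                format, net.number_of_nodes(), net.number_of_edges(), path)


def read_network(path: str | Path) -> nx.Graph:
    """Read back a GraphML export (round-trips :func:`write_network`)."""
    return nx.read_graphml(Path(path))
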
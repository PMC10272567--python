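"""Consolidate probe-level rows to gene-level rows.

Best-hit selection keeps one gene per probe; probes sharing a gene are merged
by averaging their raw intensities; genes whose probes disagree in
differential-expression direction beyond the fold-change threshold are
discarded outright.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OsmonetError, ProbeGeneMap

logger = logging.getLogger(__name__)


@dataclass
class MappingReport:
    """Bookkeeping of the probe→gene consolidation."""

    n_probes_in: int
    n_probes_mapped: int
    n_genes_out: int
    merged_groups: list[tuple[str, list[str]]] = field(default_factory=list)
    discarded_genes: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_probes_in": self.n_probes_in,
            "n_probes_mapped": self.n_probes_mapped,
            "n_genes_out": self.n_genes_out,
            "merged_groups": [
                {"gene_id": g, "probe_ids": probes} for g, probes in self.merged_groups
            ],
            "discarded_genes": [
                {"gene_id": g, "reason": why} for g, why in self.discarded_genes
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def best_hit(pg: ProbeGeneMap) -> ProbeGeneMap:
    """Resolve multi-hit probes to a single gene each.

    The hit with maximal score wins; ties break by higher identity, then by
    lexicographically smallest gene id. An empty map passes through.
    """
    df = pg.table
    if df.empty:
        return ProbeGeneMap(df.copy())
    ranked = df.sort_values(
        ["probe_id", "score", "identity_pct", "gene_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    resolved = ranked.drop_duplicates("probe_id", keep="first")
    return ProbeGeneMap(resolved.reset_index(drop=True))


def merge_probes_to_genes(
    m: ExpressionMatrix, pg: ProbeGeneMap
) -> tuple[ExpressionMatrix, MappingReport]:
    """Collapse a probe-level raw matrix to one row per gene.

    When k probes map to a gene, the gene's intensity in each sample is the
    arithmetic mean of the k raw probe intensities. Unmapped probes are
    dropped and counted; map entries for probes absent from the matrix are
    ignored with a warning.
    """
    if m.scale_tag != "raw":
        raise OsmonetError(f"merge operates on raw intensities, got scale {m.scale_tag!r}")
    resolved = pg.table
    if resolved["probe_id"].duplicated().any():
        raise OsmonetError("probe map is not best-hit resolved (duplicate probe ids)")

    present = resolved["probe_id"].isin(m.values.index)
    n_ghost = int((~present).sum())
    if n_ghost:
        logger.warning("%d map entr(ies) reference probes absent from the matrix; ignored", n_ghost)
    resolved = resolved[present]

    gene_of = dict(zip(resolved["probe_id"], resolved["gene_id"]))
    mapped_mask = m.values.index.to_series().isin(gene_of)
    n_mapped = int(mapped_mask.sum())

    sub = m.values.loc[mapped_mask]
    genes = sub.index.map(gene_of)
    merged = sub.groupby(genes.values).mean()
    merged = merged.sort_index()

    groups = [
        (gene, sorted(sub.index[genes == gene]))
        for gene in merged.index
        if int((genes == gene).sum()) > 1
    ]
    report = MappingReport(
        n_probes_in=m.shape[0],
        n_probes_mapped=n_mapped,
        n_genes_out=merged.shape[0],
        merged_groups=groups,
    )
    logger.info(
        "merged %d/%d probes into %d genes (%d multi-probe groups)",
        n_mapped, m.shape[0], merged.shape[0], len(groups),
    )
    return ExpressionMatrix(merged, scale_tag="raw"), report


def conflict_filter(
    tc_results: pd.DataFrame,
    pg: ProbeGeneMap,
    lfc_min: float = 1.0,
) -> set[str]:
    """Genes whose probes show opposite strong fold changes in some contrast.

    ``tc_results`` is a probe-level DE table with columns
    ``gene_id`` (here: probe id), ``contrast``, ``lfc``. A gene is returned
    when, within any single contrast, at least one of its probes has
    LFC <= -lfc_min and another has LFC >= +lfc_min. Returned genes are
    excluded from all downstream gene-level results.
    """
    gene_of = dict(zip(pg.table["probe_id"], pg.table["gene_id"]))
    df = tc_results.copy()
    df["__gene"] = df["gene_id"].map(gene_of)
    df = df.dropna(subset=["__gene"])
    flags = df.groupby(["__gene", "contrast"], observed=True)["lfc"].agg(
        lambda v: (v <= -lfc_min).any() and (v >= lfc_min).any()
    )
    conflicted = {gene for (gene, _contrast), bad in flags.items() if bad}
    if conflicted:
        logger.info("conflict filter discarded %d gene(s)", len(conflicted))
    return conflicted
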
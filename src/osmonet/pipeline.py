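"""End-to-end orchestration: probe map → merge → DE → clusters → GCNs →
hubs → switch genes, plus the DET count bookkeeping report.

Context networks are defined by groups of clusters. Because k-means cluster
numbers are arbitrary run to run, clusters are mapped to canonical pattern
labels by correlating each centroid with a standardized template of each
configured archetype; the context definitions then name archetypes, not
cluster numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clustering, diffexpr, network, probe_mapping, switch_genes
from .io import ExpressionMatrix, OsmonetError, ProbeGeneMap, SampleDesign, TFAnnotation
from .synthetic import DEFAULT_ARCHETYPES, Archetype

logger = logging.getLogger(__name__)

DEFAULT_CONTEXTS: dict[str, tuple[str, ...]] = {
    "common_leaf_root": ("down_both", "up_both"),
    "root_specific": ("root_down", "root_up", "root_strong_down"),
    "leaf_specific": ("leaf_up",),
}

#: which organ's samples feed each context's correlations; None = all samples
CONTEXT_ORGAN: dict[str, str | None] = {
    "common_leaf_root": None,
    "root_specific": "root",
    "leaf_specific": "leaf",
}


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    lfc_min: float = 1.0
    min_identity: float = 90.0
    k: int | None = None  # None -> use select_k recommendation (CH fallback)
    k_range: tuple[int, int] = (2, 12)
    restarts: int = 25
    min_score: float = 0.8
    r_min: float = 0.9
    corr_alpha: float = 0.05
    contexts: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_CONTEXTS))
    context_organ: dict[str, str | None] = field(default_factory=lambda: dict(CONTEXT_ORGAN))
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    swim: switch_genes.SwimConfig | None = field(default_factory=switch_genes.SwimConfig)
    seed: int = 0


# ---------------------------------------------------------------------------
# cluster -> archetype matching
# ---------------------------------------------------------------------------


def archetype_templates(
    archetypes: tuple[Archetype, ...], columns: list[str]
) -> pd.DataFrame:
    """Standardized expected profile of each archetype over condition columns.

    Columns are ``{organ}_{genotype}_{treatment}`` names as produced by
    :func:`osmonet.clustering.condition_means`.
    """
    rows = {}
    for a in archetypes:
        vals = []
        for col in columns:
            organ, _genotype, treatment = col.split("_", 2)[0], None, col.rsplit("_", 1)[1]
            v = a.root_offset if col.startswith("root") else 0.0
            if treatment == "peg":
                v += a.effect("leaf" if col.startswith("leaf") else "root")
            vals.append(v)
        v = np.asarray(vals, dtype=float)
        sd = v.std()
        if sd == 0:
            raise OsmonetError(f"archetype {a.name} has a flat template; cannot match")
        rows[a.name] = (v - v.mean()) / sd
    return pd.DataFrame(rows, index=columns).T


def match_clusters_to_archetypes(
    result: clustering.ClusterResult, archetypes: tuple[Archetype, ...]
) -> dict[int, str]:
    """Best-correlated archetype label per cluster centroid."""
    templates = archetype_templates(archetypes, list(result.centroids.columns))
    mapping = {}
    t = templates.to_numpy()
    tc = t - t.mean(axis=1, keepdims=True)
    for cid in result.centroids.index:
        c = result.centroids.loc[cid].to_numpy(float)
        cc = c - c.mean()
        denom = np.linalg.norm(tc, axis=1) * np.linalg.norm(cc)
        r = tc @ cc / np.where(denom == 0, np.nan, denom)
        mapping[int(cid)] = templates.index[int(np.nanargmax(r))]
    logger.info("cluster -> archetype mapping: %s", mapping)
    return mapping


# ---------------------------------------------------------------------------
# count bookkeeping
# ---------------------------------------------------------------------------


def report_counts(de: pd.DataFrame) -> pd.DataFrame:
    """DET bookkeeping per organ and genotype.

    For each organ, a gene is *common* when it is a DET in both genotypes
    with the same direction; otherwise it is specific to each genotype in
    which it is a DET (opposite-direction genes count as specific on both
    sides, flagged in the log). Returns one row per organ x genotype with
    columns ``n_total, n_common, n_specific, n_specific_up,
    n_specific_down`` plus ``organ='all'`` aggregate rows; the identities
    ``n_total = n_common + n_specific`` and ``n_specific = n_specific_up +
    n_specific_down`` hold by construction.
    """
    rows = []
    genotypes = sorted(de["genotype"].unique())
    for organ in sorted(de["organ"].unique()):
        sub = de[(de["organ"] == organ) & de["is_det"]]
        dir_by_geno = {
            g: sub[sub["genotype"] == g].set_index("gene_id")["direction"]
            for g in genotypes
        }
        for g in genotypes:
            mine = dir_by_geno[g]
            others = [dir_by_geno[h] for h in genotypes if h != g]
            if others:
                other = others[0]
                common_mask = mine.index.isin(other.index) & (
                    mine == other.reindex(mine.index)
                )
            else:
                common_mask = pd.Series(False, index=mine.index)
            n_common = int(common_mask.sum())
            specific = mine[~common_mask]
            opposite = [
                gene for gene in specific.index
                if others and gene in others[0].index
            ]
            if opposite:
                logger.info(
                    "%s/%s: %d gene(s) DET in both genotypes with opposite "
                    "direction counted as specific on both sides",
                    organ, g, len(opposite),
                )
            rows.append(
                {
                    "organ": organ,
                    "genotype": g,
                    "n_total": len(mine),
                    "n_common": n_common,
                    "n_specific": len(specific),
                    "n_specific_up": int((specific == "up").sum()),
                    "n_specific_down": int((specific == "down").sum()),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["organ", "genotype", "n_total", "n_common", "n_specific",
                     "n_specific_up", "n_specific_down"]
        )
    totals = (
        out.groupby("genotype", as_index=False)[
            ["n_total", "n_common", "n_specific", "n_specific_up", "n_specific_down"]
        ]
        .sum()
        .assign(organ="all")
    )
    return pd.concat([out, totals[out.columns]], ignore_index=True)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_all(
    probe_matrix: ExpressionMatrix,
    design: SampleDesign,
    probe_map: ProbeGeneMap,
    tf: TFAnnotation,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Execute the full pipeline; returns a bundle of named results.

    Stages: best-hit mapping → probe merge → DE at probe and gene level →
    conflict discard → k-means clustering with scores → score-filtered
    context GCNs with TF hubs → switch-gene stage → count report. Row
    counts are logged at every stage.
    """
    bundle: dict = {"config": config}

    resolved = probe_mapping.best_hit(probe_map)
    gene_matrix, map_report = probe_mapping.merge_probes_to_genes(probe_matrix, resolved)
    bundle["mapping_report"] = map_report

    contrasts = diffexpr.standard_contrasts(design)
    if not contrasts:
        raise OsmonetError("stage diffexpr failed: no treated-vs-control contrasts in design")
    probe_de = diffexpr.run_de(probe_matrix, contrasts, config.alpha, config.lfc_min)
    gene_de = diffexpr.run_de(gene_matrix, contrasts, config.alpha, config.lfc_min)

    conflicted = probe_mapping.conflict_filter(probe_de, resolved, config.lfc_min)
    map_report.discarded_genes = [(g, "probe-level fold-change conflict") for g in sorted(conflicted)]
    map_report.n_genes_out = gene_matrix.shape[0] - len(conflicted)
    gene_de = gene_de[~gene_de["gene_id"].isin(conflicted)].reset_index(drop=True)
    gene_matrix = ExpressionMatrix(
        gene_matrix.values.drop(index=[g for g in conflicted if g in gene_matrix.values.index]),
        scale_tag="raw",
    )
    bundle["probe_de"] = probe_de
    bundle["de"] = gene_de
    bundle["gene_matrix"] = gene_matrix

    dets = sorted(gene_de.loc[gene_de["is_det"], "gene_id"].unique())
    logger.info("DET union across contrasts: %d genes", len(dets))
    if not dets:
        raise OsmonetError("stage clustering failed: no DETs to cluster")

    cm = clustering.condition_means(gene_matrix, design, dets)
    profiles = clustering.standardize_rows(clustering.normalize_log2p1(cm))
    lo, hi = config.k_range
    diags, recommended = clustering.select_k(
        profiles, range(lo, hi + 1), seed=config.seed, restarts=config.restarts
    )
    k = config.k or recommended
    if k is None:
        # SSE elbow and CH disagree: fall back to the CH argmax
        k = max(diags, key=lambda d: (d.ch if d.ch == d.ch else -np.inf)).k
        logger.warning("k selection did not converge; falling back to CH argmax k=%d", k)
    clusters = clustering.kmeans_cluster(profiles, k, seed=config.seed, restarts=config.restarts)
    bundle["k_diagnostics"] = diags
    bundle["clusters"] = clusters

    cluster_labels = match_clusters_to_archetypes(clusters, config.archetypes)
    bundle["cluster_archetypes"] = cluster_labels

    log_matrix = ExpressionMatrix(
        np.log2(gene_matrix.values + 1.0), scale_tag="log2p1"
    )
    networks: dict = {}
    hubs: dict = {}
    for context, wanted in config.contexts.items():
        cluster_ids = [cid for cid, label in cluster_labels.items() if label in wanted]
        if not cluster_ids:
            logger.warning("context %s: no cluster matched archetypes %s", context, wanted)
            continue
        genes = clustering.select_cluster_genes(clusters, cluster_ids, config.min_score)
        organ = config.context_organ.get(context)
        samples = design.samples_where(organ=organ) if organ else design.sample_ids
        pairs = network.correlation_matrix(log_matrix, genes, samples)
        net = network.build_gcn(
            pairs, config.r_min, config.corr_alpha, context,
            tf=tf, clusters=clusters.assignments,
        )
        networks[context] = net
        hubs[context] = network.call_hubs(net, tf)
    bundle["networks"] = networks
    bundle["hubs"] = hubs

    bundle["tf_summary"] = pd.concat(
        [network.summarize_tf_classes(gene_de, tf, organ) for organ in design.organs],
        ignore_index=True,
    )

    if config.swim is not None:
        bundle["swim"] = switch_genes.run_swim(
            gene_matrix, design, config.swim, seed=config.seed
        )
    else:
        logger.warning("swim section missing from config; stage skipped")

    bundle["counts"] = report_counts(gene_de)
    return bundle
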
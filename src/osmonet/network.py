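"""Thresholded gene co-expression networks, TF hub calling, TF class summaries.

Edges connect gene pairs whose Pearson correlation across the selected
samples reaches |r| >= r_min (anti-correlated pairs retained, signed) at
p <= alpha. Hubs are the transcription-factor nodes in the upper 20th
percentile of the degree values.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, OsmonetError, TFAnnotation

logger = logging.getLogger(__name__)


def correlation_matrix(
    m: ExpressionMatrix, genes: list[str] | set[str] | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs Pearson r and p across the selected samples.

    Rows are expected on the log2(x+1) scale. p is two-sided from
    ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 df; |r| = 1 gives p = 0.
    Constant genes have undefined correlations and are dropped with a
    warning. Returns a long frame with columns ``gene_a, gene_b, r, p``
    (gene_a < gene_b).
    """
    genes = sorted(genes) if genes is not None else list(m.values.index)
    sub = m.values.loc[genes]
    if samples is not None:
        sub = sub[list(samples)]
    n = sub.shape[1]
    if n < 3:
        raise OsmonetError("need >=3 samples for correlation p-values")
    x = sub.to_numpy(float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant gene(s) from correlation", int(constant.sum()))
        x = x[~constant]
        genes = [g for g, c in zip(genes, constant) if not c]
    if x.shape[0] < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "p"])
    r = np.corrcoef(x)
    iu, ju = np.triu_indices(len(genes), k=1)
    rv = np.clip(r[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rv) == 1.0] = 0.0
    return pd.DataFrame(
        {
            "gene_a": np.asarray(genes)[iu],
            "gene_b": np.asarray(genes)[ju],
            "r": rv,
            "p": p,
        }
    )


def build_gcn(
    pairs: pd.DataFrame,
    r_min: float = 0.9,
    alpha: float = 0.05,
    context: str = "network",
    tf: TFAnnotation | None = None,
    clusters: pd.Series | None = None,
) -> nx.Graph:
    """Build the co-expression graph from a pair table.

    Keeps edges with |r| >= r_min (inclusive) and p <= alpha (inclusive).
    Isolated genes are excluded from the node set. Node attributes ``is_tf``,
    ``tf_family`` and ``cluster`` are attached when annotations are given.
    """
    keep = (pairs["r"].abs() >= r_min) & (pairs["p"] <= alpha)
    g = nx.Graph(context=context)
    for row in pairs[keep].itertuples(index=False):
        if row.gene_a == row.gene_b:
            continue
        g.add_edge(row.gene_a, row.gene_b, r=float(row.r), p=float(row.p))
    if g.number_of_edges() == 0:
        logger.warning("GCN %s is empty at |r|>=%.3g, p<=%.3g", context, r_min, alpha)
    tf_genes = tf.gene_ids if tf is not None else set()
    fam = tf.as_dict() if tf is not None else {}
    for node in g.nodes:
        g.nodes[node]["is_tf"] = node in tf_genes
        if node in fam:
            g.nodes[node]["tf_family"] = fam[node]
        if clusters is not None and node in clusters.index:
            g.nodes[node]["cluster"] = int(clusters.loc[node])
    initial = len(set(pairs["gene_a"]) | set(pairs["gene_b"]))
    logger.info(
        "GCN %s: included %d of the initial %d selected genes, %d edges",
        context, g.number_of_nodes(), initial, g.number_of_edges(),
    )
    return g


def degrees(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree table, sorted by degree descending then id."""
    rows = [(n, d) for n, d in net.degree()]
    df = pd.DataFrame(rows, columns=["gene_id", "degree"])
    return df.sort_values(["degree", "gene_id"], ascending=[False, True]).reset_index(drop=True)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def call_hubs(net: nx.Graph, tf: TFAnnotation, top_frac: float = 0.2) -> pd.DataFrame:
    """TF hubs: the top-20% of TF nodes by degree.

    With n_TF TF-labeled nodes in the network, ``k_hub = round(top_frac *
    n_TF)`` (half away from zero, minimum 1); the k_hub highest-degree TFs
    are hubs, ties at the cut broken by lexicographically smaller gene id.
    Returns a table over TF nodes with ``gene_id, degree, hub_rank, is_hub,
    tf_family``.
    """
    tf_genes = tf.gene_ids
    fam = tf.as_dict()
    deg = degrees(net)
    tf_deg = deg[deg["gene_id"].isin(tf_genes)].reset_index(drop=True)
    if tf_deg.empty:
        logger.warning("no TF nodes in network; empty hub table")
        return pd.DataFrame(columns=["gene_id", "degree", "hub_rank", "is_hub", "tf_family"])
    n_tf = len(tf_deg)
    k_hub = max(1, _round_half_away(top_frac * n_tf))
    tf_deg = tf_deg.sort_values(["degree", "gene_id"], ascending=[False, True]).reset_index(drop=True)
    tf_deg["hub_rank"] = np.arange(1, n_tf + 1)
    tf_deg["is_hub"] = tf_deg["hub_rank"] <= k_hub
    tf_deg["tf_family"] = tf_deg["gene_id"].map(fam)
    logger.info("hub calling: %d of %d TF nodes in the upper %.0f%%",
                k_hub, n_tf, 100 * top_frac)
    return tf_deg


def summarize_tf_classes(
    de: pd.DataFrame, tf: TFAnnotation, organ: str
) -> pd.DataFrame:
    """Per-TF-family counts of up/down DETs for one organ.

    A gene counts for the organ if it is a DET in either genotype there
    (union semantics); a gene up in one genotype and down in the other is
    counted in both directions (logged). DET TF genes without a family are
    grouped under ``unclassified``.
    """
    fam = tf.as_dict()
    sub = de[(de["organ"] == organ) & de["is_det"]]
    sub = sub[sub["gene_id"].isin(tf.gene_ids)]
    if sub.empty:
        return pd.DataFrame(columns=["organ", "tf_family", "n_up", "n_down"])
    per_gene = sub.groupby("gene_id")["direction"].agg(set)
    both = [g for g, dirs in per_gene.items() if {"up", "down"} <= dirs]
    if both:
        logger.info("%d TF gene(s) up in one genotype and down in the other", len(both))
    rows: dict[str, list[int]] = {}
    for gene, dirs in per_gene.items():
        family = fam.get(gene)
        if family is None or (isinstance(family, float) and math.isnan(family)):
            family = "unclassified"
        entry = rows.setdefault(family, [0, 0])
        if "up" in dirs:
            entry[0] += 1
        if "down" in dirs:
            entry[1] += 1
    out = pd.DataFrame(
        [(organ, family, up, down) for family, (up, down) in sorted(rows.items())],
        columns=["organ", "tf_family", "n_up", "n_down"],
    )
    return out
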
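"""Switch-gene analysis: filtering, module cartography and hub roles.

A lightweight reimplementation of the switch-gene workflow: expression
filtering (zeros, IQR, fold change, FDR), a correlation network thresholded
at a percentile of the |r| distribution, k-means modules, heat-cartography
statistics (within-module degree z-score z_g and clusterphobic coefficient
K_pi = 1 - (k_within/k_total)^2), the average Pearson correlation with first
neighbors (APCC), and the party/date/fight-club role assignment. Switch
genes are the many-module connectors (high K_pi, low z_g) that anti-correlate
with their neighborhood (APCC < 0).

The switch thresholds ``z_max = 2.5`` and ``kpi_min = 0.8`` follow the
original method's conventions and are exposed in :class:`SwimConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .clustering import standardize_rows
from .diffexpr import bh_adjust
from .io import ExpressionMatrix, OsmonetError, SampleDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwimConfig:
    """Parameters of the switch-gene stage."""

    max_zero_frac: float = 0.75
    min_iqr_percentile: float = 11.0
    fc_min: float = 2.0  # linear fold change
    fdr_max: float = 0.05
    corr_percentile: float = 85.0
    k_modules: int = 3
    kmeans_max_iter: int = 100
    kmeans_replicates: int = 5
    k_scree_max: int = 10
    z_max: float = 2.5
    kpi_min: float = 0.8
    hub_top_frac: float = 0.2


def swim_filter(
    m: ExpressionMatrix,
    design: SampleDesign,
    cfg: SwimConfig = SwimConfig(),
    treated: str = "peg",
    control: str = "control",
) -> set[str]:
    """Expression filter ahead of network construction.

    Drops genes with more than ``max_zero_frac`` zero intensities, genes
    below the ``min_iqr_percentile``-th percentile of the across-sample IQR
    distribution of log2(x+1) values, and keeps genes with linear
    |fold change| >= fc_min between treated and control means (per organ,
    either organ qualifying) at a BH FDR <= fdr_max from a two-sample t-test
    on log2(x+1) values.
    """
    vals = m.values
    zero_frac = (vals == 0).mean(axis=1)
    keep = zero_frac <= cfg.max_zero_frac
    logv = np.log2(vals.loc[keep] + 1.0)

    iqr = logv.quantile(0.75, axis=1) - logv.quantile(0.25, axis=1)
    if len(iqr):
        cutoff = np.percentile(iqr, cfg.min_iqr_percentile)
        logv = logv.loc[iqr >= cutoff]
        logv = logv.loc[logv.std(axis=1) > 0]

    selected: set[str] = set()
    for organ in design.organs:
        a = design.samples_where(organ=organ, treatment=treated)
        b = design.samples_where(organ=organ, treatment=control)
        if len(a) < 2 or len(b) < 2:
            continue
        raw_a = vals.loc[logv.index, a].mean(axis=1)
        raw_b = vals.loc[logv.index, b].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(raw_b > 0, raw_a / raw_b, np.inf)
            fc = np.where(ratio >= 1, ratio, np.where(ratio > 0, 1.0 / ratio, np.inf))
        t, p = stats.ttest_ind(
            logv[a].to_numpy(float), logv[b].to_numpy(float), axis=1
        )
        p = np.nan_to_num(p, nan=1.0)
        fdr = bh_adjust(p)
        hit = (fc >= cfg.fc_min) & (fdr <= cfg.fdr_max)
        selected |= set(logv.index[hit])
    logger.info("swim filter: %d of %d genes retained", len(selected), m.shape[0])
    return selected


def swim_network(
    m: ExpressionMatrix, genes: set[str] | list[str], cfg: SwimConfig = SwimConfig()
) -> tuple[nx.Graph, float]:
    """|r|-percentile-thresholded correlation graph over the filtered genes.

    The numeric cutoff is the ``corr_percentile``-th percentile (linear
    interpolation) of the all-pairs |r| distribution; edges keep signed r.
    Returns the graph and the realized cutoff (logged so it can be compared
    with the value observed on real data).
    """
    genes = sorted(genes)
    if len(genes) < 2:
        raise OsmonetError("need >=2 genes to build a network")
    logv = np.log2(m.values.loc[genes] + 1.0).to_numpy(float)
    sd = logv.std(axis=1)
    keep = sd > 0
    genes = [g for g, k in zip(genes, keep) if k]
    logv = logv[keep]
    r = np.corrcoef(logv)
    iu, ju = np.triu_indices(len(genes), k=1)
    rv = r[iu, ju]
    cutoff = float(np.percentile(np.abs(rv), cfg.corr_percentile))
    logger.info("swim network: realized |r| cutoff at percentile %.4g = %.4g",
                cfg.corr_percentile, cutoff)
    g = nx.Graph(realized_cutoff=cutoff)
    g.add_nodes_from(genes)
    sel = np.abs(rv) >= cutoff
    for i, j, rij in zip(iu[sel], ju[sel], rv[sel]):
        g.add_edge(genes[i], genes[j], r=float(rij))
    return g, cutoff


def swim_modules(
    m: ExpressionMatrix,
    genes: set[str] | list[str],
    cfg: SwimConfig = SwimConfig(),
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means modules on standardized log2(x+1) profiles, plus scree table."""
    if cfg.k_modules < 2:
        raise OsmonetError("cartography undefined for k < 2")
    genes = sorted(genes)
    if cfg.k_modules > len(genes):
        raise OsmonetError(f"k={cfg.k_modules} exceeds gene count ({len(genes)})")
    logv = np.log2(m.values.loc[genes] + 1.0)
    z = standardize_rows(logv)
    x = z.to_numpy(float)
    scree = []
    for k in range(2, min(cfg.k_scree_max, len(z) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=cfg.kmeans_replicates,
                    max_iter=cfg.kmeans_max_iter, random_state=seed).fit(x)
        scree.append((k, float(km.inertia_)))
    km = KMeans(n_clusters=cfg.k_modules, n_init=cfg.kmeans_replicates,
                max_iter=cfg.kmeans_max_iter, random_state=seed).fit(x)
    modules = pd.Series(km.labels_ + 1, index=z.index, name="module")
    return modules, pd.DataFrame(scree, columns=["k", "sse"])


def cartography(net: nx.Graph, modules: pd.Series) -> pd.DataFrame:
    """Per-node within-module degree z-score and clusterphobic coefficient.

    ``k_within`` counts edges to same-module nodes; ``z_g`` standardizes
    k_within within the module (sd 0 → z_g = 0); ``K_pi = 1 -
    (k_within/k_total)^2``. Isolated nodes have K_pi undefined and are
    excluded (logged).
    """
    missing = [n for n in net.nodes if n not in modules.index]
    if missing:
        raise OsmonetError(f"node(s) without a module: {missing[:5]}")
    rows = []
    isolated = 0
    for node in net.nodes:
        k_total = net.degree(node)
        if k_total == 0:
            isolated += 1
            continue
        mod = modules.loc[node]
        k_within = sum(1 for nb in net.neighbors(node) if modules.loc[nb] == mod)
        rows.append((node, int(mod), k_total, k_within))
    if isolated:
        logger.info("excluded %d isolated node(s) from cartography", isolated)
    df = pd.DataFrame(rows, columns=["gene_id", "module", "k_total", "k_within"]).set_index("gene_id")
    z = np.zeros(len(df))
    for mod, grp in df.groupby("module"):
        sd = grp["k_within"].std(ddof=0)
        if sd > 0:
            z[df["module"].to_numpy() == mod] = (
                (grp["k_within"] - grp["k_within"].mean()) / sd
            ).to_numpy()
    df["z_g"] = z
    df["K_pi"] = 1.0 - (df["k_within"] / df["k_total"]) ** 2
    return df


def apcc(net: nx.Graph, m: ExpressionMatrix | None = None) -> pd.Series:
    """Average signed Pearson correlation of each node with its neighbors.

    Edge ``r`` attributes are used when present; otherwise correlations are
    computed from ``m`` on the log2(x+1) scale. Isolated nodes are excluded.
    """
    logv = None
    if m is not None:
        logv = np.log2(m.values + 1.0)
    out = {}
    for node in net.nodes:
        nbrs = list(net.neighbors(node))
        if not nbrs:
            continue
        rs = []
        for nb in nbrs:
            data = net.edges[node, nb]
            if "r" in data:
                rs.append(data["r"])
            elif logv is not None:
                rs.append(float(np.corrcoef(logv.loc[node], logv.loc[nb])[0, 1]))
            else:
                raise OsmonetError("edge lacks r attribute and no expression given")
        out[node] = float(np.mean(rs))
    return pd.Series(out, name="apcc")


def classify_switch(
    carto: pd.DataFrame,
    apcc_values: pd.Series,
    cfg: SwimConfig = SwimConfig(),
) -> pd.DataFrame:
    """Assign hub roles and flag switch genes.

    Hubs are the top ``hub_top_frac`` of nodes by total degree (half-away
    rounding, minimum 1). Hub roles follow APCC: party (APCC >= 0.5), date
    (0 <= APCC < 0.5), fight-club (APCC < 0). A node is a switch gene when
    K_pi > kpi_min, z_g < z_max and APCC < 0; switch genes are fight-club
    hubs by construction (they connect many modules with negative
    neighborhood correlation).
    """
    df = carto.join(apcc_values.rename("apcc"), how="inner").copy()
    n = len(df)
    if n == 0:
        return df.assign(role=pd.Series(dtype=str), is_switch=pd.Series(dtype=bool))
    k_hub = max(1, int(np.floor(cfg.hub_top_frac * n + 0.5)))
    ranked = df.sort_index().sort_values("k_total", ascending=False, kind="mergesort")
    hub_ids = set(ranked.index[:k_hub])
    df["is_switch"] = (df["K_pi"] > cfg.kpi_min) & (df["z_g"] < cfg.z_max) & (df["apcc"] < 0)
    roles = []
    for gene, row in df.iterrows():
        is_hub = gene in hub_ids
        if row["is_switch"] or (is_hub and row["apcc"] < 0):
            roles.append("fight_club_hub")
        elif is_hub and row["apcc"] >= 0.5:
            roles.append("party_hub")
        elif is_hub:
            roles.append("date_hub")
        else:
            roles.append("non_hub")
    df["role"] = roles
    logger.info("switch classification: %d switch gene(s) of %d nodes",
                int(df["is_switch"].sum()), n)
    return df


def run_swim(
    m: ExpressionMatrix,
    design: SampleDesign,
    cfg: SwimConfig = SwimConfig(),
    seed: int = 0,
    treated: str = "peg",
    control: str = "control",
) -> dict:
    """Full switch-gene stage; returns a dict of intermediate results."""
    genes = swim_filter(m, design, cfg, treated=treated, control=control)
    if len(genes) < max(2, cfg.k_modules):
        logger.warning("swim filter left %d gene(s); stage skipped", len(genes))
        return {"genes": genes, "result": pd.DataFrame()}
    net, cutoff = swim_network(m, genes, cfg)
    modules, scree = swim_modules(m, genes, cfg, seed=seed)
    carto = cartography(net, modules)
    ap = apcc(net, m)
    result = classify_switch(carto, ap, cfg)
    return {
        "genes": genes,
        "network": net,
        "realized_cutoff": cutoff,
        "modules": modules,
        "scree": scree,
        "cartography": carto,
        "apcc": ap,
        "result": result,
    }
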
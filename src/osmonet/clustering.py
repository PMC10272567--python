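"""K-means clustering of DET condition means with membership scores.

The pipeline: per-cell replicate means of raw intensity → log2(x+1) →
row standardization → Euclidean k-means (on standardized rows this induces
the same ordering as the centered-Pearson distance) → per-gene cluster
score (centered Pearson correlation with the assigned centroid). Genes with
a score at or above the cutoff feed network construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .io import ExpressionMatrix, OsmonetError, SampleDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KDiagnostics:
    k: int
    sse: float
    ch: float


@dataclass
class ClusterResult:
    """Cluster assignments (ids 1..k), centroids and membership scores.

    Cluster ids are canonical: clusters are relabeled by descending size,
    ties broken by the lexicographically smallest member gene id.
    """

    assignments: pd.Series  # gene -> cluster id (int, 1..k)
    centroids: pd.DataFrame  # cluster id x condition columns
    scores: pd.Series = field(default=None)  # gene -> score in [-1, 1]

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])


def condition_means(
    m: ExpressionMatrix, design: SampleDesign, dets: set[str] | list[str]
) -> pd.DataFrame:
    """Per-gene replicate means of raw intensity in each design cell.

    Returns a DET-rows-only frame with one column per genotype x organ x
    treatment cell, named ``{organ}_{genotype}_{treatment}``.
    """
    dets = sorted(dets)
    if not dets:
        raise OsmonetError("empty DET set: nothing to cluster")
    missing = set(dets) - set(m.values.index)
    if missing:
        raise OsmonetError(f"DET gene(s) absent from matrix: {sorted(missing)[:5]}")
    cols = {}
    for genotype, organ, treatment in design.cells():
        samples = design.samples_where(genotype=genotype, organ=organ, treatment=treatment)
        cols[f"{organ}_{genotype}_{treatment}"] = m.values.loc[dets, samples].mean(axis=1)
    return pd.DataFrame(cols)


def normalize_log2p1(df: pd.DataFrame) -> pd.DataFrame:
    """Element-wise log2(x + 1); values must be non-negative."""
    if (df.to_numpy() < 0).any():
        raise OsmonetError("log2(x+1) requires non-negative values")
    return np.log2(df + 1.0)


def standardize_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, sd 1 (population convention).

    Constant rows cannot be standardized and are dropped with a warning.
    Idempotent on already-standardized rows.
    """
    vals = df.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning("dropping %d constant row(s) before standardization", int(constant.sum()))
    keep = ~constant
    out = (vals[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(out, index=df.index[keep], columns=df.columns)


def _sse(x: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((x - centers[labels]) ** 2).sum())


def select_k(
    df: pd.DataFrame,
    k_range: range | list[int] = range(2, 13),
    seed: int = 0,
    restarts: int = 25,
) -> tuple[list[KDiagnostics], int | None]:
    """Scan candidate k and report SSE plus the Calinski-Harabasz index.

    The recommended k is the CH argmax when it coincides with the SSE elbow
    (maximal second difference of log SSE over k — the log scale makes the
    curvature criterion insensitive to the large early drops); otherwise
    ``None`` is returned and the caller decides from the diagnostics.
    """
    x = df.to_numpy(float)
    ks = [k for k in k_range if 2 <= k <= x.shape[0] - 1]
    if not ks:
        raise OsmonetError("no valid k in range for this matrix size")
    diags = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x)
        if len(np.unique(km.labels_)) < 2:
            ch = float("nan")
        else:
            ch = float(calinski_harabasz_score(x, km.labels_))
        diags.append(KDiagnostics(k=k, sse=float(km.inertia_), ch=ch))
    ch_vals = np.array([d.ch for d in diags])
    if np.isnan(ch_vals).all() or np.nanstd(ch_vals) == 0:
        logger.warning("CH index flat: k selection did not converge")
        return diags, None
    k_ch = diags[int(np.nanargmax(ch_vals))].k
    sse = np.array([d.sse for d in diags])
    if len(sse) >= 3 and (sse > 0).all():
        log_sse = np.log(sse)
        second_diff = log_sse[:-2] - 2 * log_sse[1:-1] + log_sse[2:]
        k_elbow = diags[int(np.argmax(second_diff)) + 1].k
    else:
        k_elbow = k_ch
    if k_ch == k_elbow:
        return diags, k_ch
    logger.info("CH argmax (k=%d) and SSE elbow (k=%d) disagree", k_ch, k_elbow)
    return diags, None


def kmeans_cluster(
    df: pd.DataFrame, k: int, seed: int = 0, restarts: int = 25
) -> ClusterResult:
    """Euclidean k-means on row-standardized profiles, best SSE of ``restarts``.

    Deterministic given ``seed``. Cluster ids are relabeled canonically
    (descending size, ties by smallest member id) so runs are comparable.
    """
    x = df.to_numpy(float)
    if k > x.shape[0]:
        raise OsmonetError(f"k={k} exceeds number of rows ({x.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x)
    labels = km.labels_
    # canonical relabeling
    order = sorted(
        range(k),
        key=lambda c: (-int((labels == c).sum()), min(df.index[labels == c], default="")),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    new_labels = np.array([relabel[c] for c in labels])
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=df.columns
    )
    assignments = pd.Series(new_labels, index=df.index, name="cluster")
    result = ClusterResult(assignments=assignments, centroids=centroids)
    result.scores = cluster_scores(df, result)
    return result


def cluster_scores(df: pd.DataFrame, result: ClusterResult) -> pd.Series:
    """Centered Pearson correlation of each gene's profile with its centroid."""
    scores = np.empty(df.shape[0])
    x = df.to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    for cid in result.centroids.index:
        c = result.centroids.loc[cid].to_numpy(float)
        cc = c - c.mean()
        c_norm = np.linalg.norm(cc)
        if c_norm == 0:
            raise OsmonetError(f"cluster {cid} has a zero-variance centroid; score undefined")
        mask = (result.assignments == cid).to_numpy()
        sub = xc[mask]
        norms = np.linalg.norm(sub, axis=1)
        if (norms == 0).any():
            raise OsmonetError("zero-variance gene profile; score undefined")
        scores[mask] = sub @ cc / (norms * c_norm)
    return pd.Series(scores, index=df.index, name="score")


def select_cluster_genes(
    result: ClusterResult, cluster_ids: set[int] | list[int], min_score: float = 0.8
) -> set[str]:
    """Genes in the named clusters with score >= ``min_score`` (inclusive)."""
    unknown = set(cluster_ids) - set(result.centroids.index)
    if unknown:
        raise OsmonetError(f"unknown cluster id(s): {sorted(unknown)}")
    if result.scores is None:
        raise OsmonetError("cluster scores not computed")
    in_clusters = result.assignments.isin(list(cluster_ids))
    passing = result.scores >= min_score
    return set(result.assignments.index[in_clusters & passing])
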
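"""Gene-wise two-group differential expression with variance moderation.

Each contrast (PEG vs control within one organ x genotype) is fit as an
independent two-group comparison on log2 intensities. Gene-wise residual
variances are shrunk toward a common prior estimated by moment-matching the
log-variances (digamma/trigamma relations), and the moderated t-statistic is
referred to a t distribution with augmented degrees of freedom. Multiplicity
is handled with the Benjamini-Hochberg step-up procedure; a transcript is
called differentially expressed (DET) when the adjusted p-value is below
``alpha`` (strict) and |log2 fold change| reaches ``lfc_min`` (inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix, OsmonetError, SampleDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: ``group_a`` (treated) vs ``group_b`` (control)."""

    name: str
    organ: str
    genotype: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise OsmonetError(f"contrast {self.name}: groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise OsmonetError(f"contrast {self.name}: each group needs >=2 samples")

    def reversed(self) -> "Contrast":
        return Contrast(
            name=self.name + "_rev",
            organ=self.organ,
            genotype=self.genotype,
            group_a=self.group_b,
            group_b=self.group_a,
        )


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior for gene-wise variances.

    ``d0`` is the prior degrees of freedom (``inf`` when gene variances are
    homogeneous) and ``s0_sq`` the prior variance.
    """

    d0: float
    s0_sq: float


def standard_contrasts(
    design: SampleDesign,
    treated: str = "peg",
    control: str = "control",
) -> list[Contrast]:
    """One treated-vs-control contrast per organ x genotype cell."""
    contrasts = []
    for organ in design.organs:
        for genotype in design.genotypes:
            a = design.samples_where(organ=organ, genotype=genotype, treatment=treated)
            b = design.samples_where(organ=organ, genotype=genotype, treatment=control)
            if not a or not b:
                continue
            contrasts.append(
                Contrast(
                    name=f"{organ}_{genotype}_{treated}_vs_{control}",
                    organ=organ,
                    genotype=genotype,
                    group_a=tuple(a),
                    group_b=tuple(b),
                )
            )
    return contrasts


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2; requires strictly positive raw values."""
    if m.scale_tag != "raw":
        raise OsmonetError(f"log2_transform expects raw scale, got {m.scale_tag!r}")
    vals = m.values.to_numpy()
    if (vals <= 0).any():
        raise OsmonetError(
            "log2 undefined for zero/negative intensities; use the log2(x+1) "
            "variant (clustering scale) or add an offset"
        )
    return ExpressionMatrix(np.log2(m.values), scale_tag="log2")


# ---------------------------------------------------------------------------
# per-gene linear fit
# ---------------------------------------------------------------------------


def fit_contrast(m: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Per-gene two-group fit on a log2 matrix.

    Returns a frame with columns ``lfc`` (mean(a) - mean(b)), ``s_sq``
    (pooled residual variance on n_a + n_b - 2 df), ``df_resid`` and
    ``stderr_unit`` (= sqrt(1/n_a + 1/n_b)).
    """
    if m.scale_tag != "log2":
        raise OsmonetError(f"fit_contrast expects log2 scale, got {m.scale_tag!r}")
    a = m.values[list(contrast.group_a)].to_numpy(float)
    b = m.values[list(contrast.group_b)].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = na + nb - 2
    s_sq = ss / df_resid
    return pd.DataFrame(
        {
            "lfc": lfc,
            "s_sq": s_sq,
            "df_resid": float(df_resid),
            "stderr_unit": math.sqrt(1.0 / na + 1.0 / nb),
        },
        index=m.values.index,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration (rel tol 1e-8)."""
    if y <= 0:
        raise OsmonetError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def moderate_variances(
    s_sq: np.ndarray | pd.Series, df_resid: float
) -> tuple[ModerationParams, np.ndarray]:
    """Estimate the variance prior and return per-gene posterior variances.

    Hyperparameters are moment-matched on log(s_sq): the excess spread of the
    log variances over trigamma(df/2) determines ``d0`` via the trigamma
    equation; when the spread does not exceed trigamma(df/2) the prior is
    degenerate (``d0 = inf``) and every posterior variance equals ``s0_sq``.
    Zero variances are excluded from estimation but still shrunk.
    """
    s = np.asarray(s_sq, dtype=float)
    if np.all(s <= 0):
        raise OsmonetError("all gene variances are zero: degenerate data")
    pos = s[s > 0]
    if pos.size < 2:
        raise OsmonetError("need >=2 positive gene variances to moderate")
    z = np.log(pos)
    df2 = df_resid / 2.0
    e_mean = z.mean()
    e_var = z.var(ddof=1)
    excess = e_var - special.polygamma(1, df2)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        log_s0 = (
            e_mean
            - special.psi(df2)
            + math.log(df2)
            + special.psi(d0 / 2.0)
            - math.log(d0 / 2.0)
        )
    else:
        # homogeneous variances: the prior absorbs everything and the
        # arithmetic mean of s^2 is the unbiased estimate of s0^2 (it also
        # reduces to the common value when all s^2 are identical)
        d0 = math.inf
        log_s0 = math.log(float(np.mean(s)))
    s0_sq = float(np.exp(log_s0))
    params = ModerationParams(d0=float(d0), s0_sq=s0_sq)
    if math.isinf(d0):
        posterior = np.full_like(s, s0_sq)
    else:
        posterior = (d0 * s0_sq + df_resid * s) / (d0 + df_resid)
    return params, posterior


def moderated_t(
    lfc: np.ndarray | pd.Series,
    stderr_unit: float | np.ndarray,
    posterior_var: np.ndarray | pd.Series,
    d0: float,
    df_resid: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistic and two-sided p-value.

    ``t = lfc / (sqrt(posterior_var) * stderr_unit)`` referred to a t
    distribution with ``d0 + df_resid`` degrees of freedom, or the normal
    when ``d0`` is infinite.
    """
    lfc = np.asarray(lfc, dtype=float)
    pv = np.asarray(posterior_var, dtype=float)
    if (pv <= 0).any():
        raise OsmonetError("posterior variances must be positive")
    t = lfc / (np.sqrt(pv) * stderr_unit)
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + df_resid)
    return t, np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise OsmonetError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def call_dets(
    results: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Flag DETs: adj_p < alpha (strict) and |lfc| >= lfc_min (inclusive)."""
    out = results.copy()
    out["is_det"] = (out["adj_p"] < alpha) & (out["lfc"].abs() >= lfc_min)
    direction = np.where(out["lfc"] >= lfc_min, "up", np.where(out["lfc"] <= -lfc_min, "down", "none"))
    out["direction"] = np.where(out["is_det"], direction, "none")
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_de(
    m_raw: ExpressionMatrix,
    contrasts: list[Contrast],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Full DE pass: log2, fit, moderate, test, adjust, call — per contrast.

    Moderation hyperparameters are estimated independently within each
    contrast. Returns a long frame with one row per gene x contrast and
    columns ``gene_id, contrast, lfc, s_sq, df_resid, t_mod, p, adj_p,
    is_det, direction``.
    """
    logm = log2_transform(m_raw)
    frames = []
    for c in contrasts:
        fit = fit_contrast(logm, c)
        params, posterior = moderate_variances(fit["s_sq"].to_numpy(), fit["df_resid"].iloc[0])
        t, p = moderated_t(
            fit["lfc"].to_numpy(),
            fit["stderr_unit"].iloc[0],
            posterior,
            params.d0,
            fit["df_resid"].iloc[0],
        )
        res = pd.DataFrame(
            {
                "gene_id": fit.index,
                "contrast": c.name,
                "organ": c.organ,
                "genotype": c.genotype,
                "lfc": fit["lfc"].to_numpy(),
                "s_sq": fit["s_sq"].to_numpy(),
                "df_resid": fit["df_resid"].to_numpy(),
                "t_mod": t,
                "p": p,
                "adj_p": bh_adjust(p),
            }
        )
        res = call_dets(res, alpha=alpha, lfc_min=lfc_min)
        logger.info(
            "contrast %s: d0=%.3g s0^2=%.3g, %d DETs",
            c.name, params.d0, params.s0_sq, int(res["is_det"].sum()),
        )
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
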
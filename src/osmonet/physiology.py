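"""Closed-form physiological stress indices and the qPCR relative-expression
formula.

RWC (relative water content) and EL (electrolyte leakage) are percentage
indices computed from weights and conductivities of leaf samples; relative
transcript abundance comes from the 2^-ddCt method. Group comparisons use a
pooled-variance Student's t-test (Welch available via flag).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .io import OsmonetError

logger = logging.getLogger(__name__)


def rwc(fw: float, tw: float, dw: float) -> float:
    """Relative water content: (FW - DW)/(TW - DW) x 100.

    ``TW == DW`` is an error; FW outside [DW, TW] warns (measurement noise)
    but the value is still returned.
    """
    if tw == dw:
        raise OsmonetError("RWC undefined: turgid weight equals dry weight")
    if not (dw <= fw <= tw):
        logger.warning("FW=%.4g outside [DW=%.4g, TW=%.4g]; RWC out of [0,100]", fw, dw, tw)
    return (fw - dw) / (tw - dw) * 100.0


def el(ci: float, cmax: float) -> float:
    """Electrolyte leakage: Ci/Cmax x 100.

    ``Cmax == 0`` is an error; Ci > Cmax warns but the value is returned.
    """
    if cmax == 0:
        raise OsmonetError("EL undefined: Cmax is zero")
    if ci > cmax:
        logger.warning("Ci=%.4g exceeds Cmax=%.4g; EL above 100%%", ci, cmax)
    return ci / cmax * 100.0


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise OsmonetError("Ct values must be finite")
    dd = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-dd)


def two_sample_t(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance by default).

    Zero pooled variance with equal means gives (0, 1); with unequal means
    it is an error (infinite statistic).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise OsmonetError("each sample needs >=2 observations")
    if not welch:
        pooled = (a.var(ddof=1) * (a.size - 1) + b.var(ddof=1) * (b.size - 1)) / (
            a.size + b.size - 2
        )
        if pooled == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            raise OsmonetError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
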
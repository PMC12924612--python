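"""Binormal ROC model: parameterization, (partial) AUC, and variance constants.

The binormal model assumes the diagnostic scores of controls and cases are
both normally distributed.  Writing the case distribution as N(mu+, sd+^2)
and the control distribution as N(mu-, sd-^2), the ROC curve is fully
described by two dimensionless parameters::

    A = (mu+ - mu-) / sd+        (location: separation between the groups)
    B = sd- / sd+                (scale ratio)

The area under the curve over a false-positive-rate window (fpr_lo, fpr_hi)
is the integral of Phi(A + B v) against the standard normal density between
the corresponding z-thresholds; over the full window (0, 1) it collapses to
the closed form Phi(A / sqrt(1 + B^2)).

This module also evaluates the intermediate constants (f, g, E1..E4) that
feed the rating-data variance formulas for correlated AUC estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "BinormalCurve",
    "RocConstants",
    "auc_from_params",
    "params_from_auc",
    "roc_constants",
    "a_from_rates",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class BinormalCurve:
    """Binormal ROC curve parameters with an FPR integration window.

    Parameters
    ----------
    a : float
        Location parameter (mu+ - mu-) / sd+.
    b : float
        Scale ratio sd- / sd+; must be positive.
    fpr_lo, fpr_hi : float
        False-positive-rate integration limits, 0 <= fpr_lo < fpr_hi <= 1.
        The default (0, 1) covers the full ROC curve.
    """

    a: float
    b: float = 1.0
    fpr_lo: float = 0.0
    fpr_hi: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("binormal parameters must be finite")
        if self.b <= 0:
            raise ValueError(f"scale ratio B must be positive, got {self.b}")
        if not (0.0 <= self.fpr_lo < self.fpr_hi <= 1.0):
            raise ValueError(
                f"FPR limits must satisfy 0 <= lo < hi <= 1, got ({self.fpr_lo}, {self.fpr_hi})"
            )

    @property
    def full_range(self) -> bool:
        return self.fpr_lo == 0.0 and self.fpr_hi == 1.0


@dataclass(frozen=True)
class RocConstants:
    """Intermediate constants of the rating-data variance formulas.

    ``e2 = 1 + B^2`` always; over the full FPR window ``e3 = 1`` and
    ``e4 = 0`` exactly, and ``f`` reduces to the normal density of the
    AUC-determining deviate A / sqrt(1 + B^2) scaled by 1/sqrt(E2).
    """

    f: float
    g: float
    e1: float
    e2: float
    e3: float
    e4: float
    c1: float
    c2: float


def auc_from_params(curve: BinormalCurve) -> float:
    """(Partial) area under the binormal ROC curve.

    Integrates Phi(A + B v) phi(v) dv between the z-thresholds
    c_j = Phi^-1(fpr_j).  For the full FPR window the closed form
    Phi(A / sqrt(1 + B^2)) is returned directly; the adaptive quadrature
    agrees with it to better than 1e-10.
    """
    if curve.full_range:
        return float(norm.cdf(curve.a / math.sqrt(1.0 + curve.b**2)))
    c1 = norm.ppf(curve.fpr_lo)  # -inf when fpr_lo == 0
    c2 = norm.ppf(curve.fpr_hi)
    val, _ = integrate.quad(
        lambda v: norm.cdf(curve.a + curve.b * v) * norm.pdf(v),
        c1,
        c2,
        epsabs=1e-12,
        limit=200,
    )
    return float(val)


def params_from_auc(auc: float, b: float = 1.0) -> BinormalCurve:
    """Invert the full-range closed form: A = sqrt(1 + B^2) Phi^-1(auc).

    Designs are usually stated in terms of a full-range AUC; this maps the
    AUC back to the location parameter for a given scale ratio.  Round-trips
    with :func:`auc_from_params` to machine precision.
    """
    if not 0.0 < auc < 1.0:
        raise ValueError(f"AUC must lie strictly inside (0, 1), got {auc}")
    if b <= 0:
        raise ValueError(f"scale ratio B must be positive, got {b}")
    a = math.sqrt(1.0 + b**2) * norm.ppf(auc)
    return BinormalCurve(a=float(a), b=float(b))


def a_from_rates(tnr: float, fpr: float, b: float = 1.0) -> float:
    """Location parameter from one (TNR, FPR) operating point.

    A = B Phi^-1(TNR) - Phi^-1(FPR).  Boundary rates (0 or 1) have
    infinite normal deviates and are rejected.
    """
    if not (0.0 < tnr < 1.0 and 0.0 < fpr < 1.0):
        raise ValueError("TNR and FPR must lie strictly inside (0, 1)")
    if b <= 0:
        raise ValueError(f"scale ratio B must be positive, got {b}")
    return float(b * norm.ppf(tnr) - norm.ppf(fpr))


def _threshold(fpr: float, a: float, b: float) -> float:
    """z-scale threshold for the variance constants.

    Embeds the location/scale adjustment
    c = (Phi^-1(FPR) + A B / (1 + B^2)) / sqrt(1 + B^2);
    boundary FPRs map to infinite thresholds.
    """
    if fpr <= 0.0:
        return -math.inf
    if fpr >= 1.0:
        return math.inf
    return (norm.ppf(fpr) + a * b / (1.0 + b**2)) / math.sqrt(1.0 + b**2)


def roc_constants(curve: BinormalCurve) -> RocConstants:
    """Evaluate f, g and E1..E4 for a binormal curve.

    E1 = exp(-A^2 / (2 + 2 B^2)),  E2 = 1 + B^2,
    E3 = Phi(c2) - Phi(c1),        E4 = exp(-c1^2/2) - exp(-c2^2/2),
    f  = E1 E3 / sqrt(2 pi E2),
    g  = E1 E4 / sqrt(2 pi E2) - A B E1 E3 / sqrt(2 pi E2^3).

    Over the full FPR window E3 = 1 and E4 = 0 exactly (the thresholds are
    infinite), so g is proportional to -A.
    """
    a, b = curve.a, curve.b
    e1 = math.exp(-(a**2) / (2.0 + 2.0 * b**2))
    e2 = 1.0 + b**2
    c1 = _threshold(curve.fpr_lo, a, b)
    c2 = _threshold(curve.fpr_hi, a, b)
    if curve.full_range:
        e3, e4 = 1.0, 0.0
    else:
        e3 = float(norm.cdf(c2) - norm.cdf(c1))
        exp1 = math.exp(-(c1**2) / 2.0) if math.isfinite(c1) else 0.0
        exp2 = math.exp(-(c2**2) / 2.0) if math.isfinite(c2) else 0.0
        e4 = exp1 - exp2
    f = e1 * e3 / (_SQRT_2PI * math.sqrt(e2))
    g = e1 * e4 / (_SQRT_2PI * math.sqrt(e2)) - a * b * e1 * e3 / (
        _SQRT_2PI * math.sqrt(e2**3)
    )
    return RocConstants(f=f, g=g, e1=e1, e2=e2, e3=e3, e4=e4, c1=c1, c2=c2)
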
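"""Obuchowski–McClish variances for correlated AUCs from rating data.

For ordinal (rating-scale) diagnostic scores the variance of a single
binormal AUC estimate, the covariance of two paired estimates, and the
null/alternative variances of their difference have closed forms in the
binormal parameters (A_i, B_i), the control:case allocation ratio
R = N-/N+, and the within-group inter-test correlations r+ (cases) and
r- (controls).  All quantities here are scaled per positive case: divide
by N+ to get the variance of an estimate from N+ cases and R*N+ controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .binormal import BinormalCurve, roc_constants

__all__ = [
    "PairedDesignOM",
    "VarianceSet",
    "om_variance_single",
    "om_covariance",
    "om_variance_set",
]


@dataclass(frozen=True)
class PairedDesignOM:
    """Paired rating-data design: two binormal curves read on the same subjects.

    ``r_pos``/``r_neg`` are the inter-test score correlations among cases
    and controls respectively; the scenario grids evaluated here always tie
    them, but they are accepted separately.
    """

    curve1: BinormalCurve
    curve2: BinormalCurve
    r_pos: float
    r_neg: float
    ratio: float = 1.0

    def __post_init__(self) -> None:
        for name, r in (("r_pos", self.r_pos), ("r_neg", self.r_neg)):
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {r}")
        if self.ratio <= 0:
            raise ValueError(f"control:case ratio must be positive, got {self.ratio}")


@dataclass(frozen=True)
class VarianceSet:
    """Per-case-scaled variance components of a paired AUC comparison.

    ``v_null`` is the variance of the AUC difference under H0 (both tests at
    the first test's accuracy), ``v_alt`` under H1 (each test at its own).
    """

    v1: float
    v2: float
    cov: float
    v_null: float
    v_alt: float

    def __post_init__(self) -> None:
        if self.v1 <= 0 or self.v2 <= 0:
            raise ValueError("single-AUC variances must be positive")
        if self.v_null < 0 or self.v_alt < 0:
            raise ValueError(
                "negative variance of the AUC difference; the correlation "
                "parameters are outside the supported regime"
            )
        if abs(self.cov) > math.sqrt(self.v1 * self.v2) + 1e-12:
            raise ValueError("covariance exceeds the Cauchy-Schwarz bound")


def om_variance_single(curve: BinormalCurve, ratio: float = 1.0) -> float:
    """Per-case-scaled variance of one rating-data AUC estimate.

    V = f^2 (1 + B^2/R + A^2/2) + g^2 B^2 (1 + R) / (2R).
    """
    if ratio <= 0:
        raise ValueError(f"control:case ratio must be positive, got {ratio}")
    k = roc_constants(curve)
    a, b = curve.a, curve.b
    return k.f**2 * (1.0 + b**2 / ratio + a**2 / 2.0) + k.g**2 * (
        b**2 * (1.0 + ratio) / (2.0 * ratio)
    )


def om_covariance(design: PairedDesignOM) -> float:
    """Per-case-scaled covariance of the two paired AUC estimates.

    Four-term expression in (f_i, g_i, A_i, B_i, r+, r-, R); every term
    carries a correlation factor, so independence (r+ = r- = 0) gives zero,
    and the expression is symmetric under swapping the two curves.
    """
    k1 = roc_constants(design.curve1)
    k2 = roc_constants(design.curve2)
    a1, b1 = design.curve1.a, design.curve1.b
    a2, b2 = design.curve2.a, design.curve2.b
    rp, rn, ratio = design.r_pos, design.r_neg, design.ratio
    return (
        k1.f * k2.f * (rp + rn * b1 * b2 / ratio + rp**2 * a1 * a2 / 2.0)
        + k1.g * k2.g * b1 * b2 * (rn**2 + ratio * rp**2) / (2.0 * ratio)
        + k1.f * k2.g * a1 * b2 * rp**2 / 2.0
        + k2.f * k1.g * a2 * b1 * rp**2 / 2.0
    )


def om_variance_set(design: PairedDesignOM) -> VarianceSet:
    """Null and alternative variances of the AUC difference.

    The null variance anchors *both* tests at the first curve's parameters:
    V0 = 2 [V(theta1) - C(theta1, theta1)].  This is the reading of the
    null-hypothesis variance that the published rating-data sample sizes
    pin down; anchoring at the mean of the two accuracies does not
    reproduce them.  The alternative variance uses each curve as specified:
    V_Alt = V1 + V2 - 2 C(theta1, theta2).
    """
    v1 = om_variance_single(design.curve1, design.ratio)
    v2 = om_variance_single(design.curve2, design.ratio)
    cov = om_covariance(design)
    null_design = PairedDesignOM(
        curve1=design.curve1,
        curve2=design.curve1,
        r_pos=design.r_pos,
        r_neg=design.r_neg,
        ratio=design.ratio,
    )
    cov_null = om_covariance(null_design)
    v_null = 2.0 * (v1 - cov_null)
    v_alt = v1 + v2 - 2.0 * cov
    return VarianceSet(v1=v1, v2=v2, cov=cov, v_null=v_null, v_alt=v_alt)
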
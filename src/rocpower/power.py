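"""Sample size and analytic power for paired ROC-area comparisons.

Given the null/alternative variances of the AUC difference (per positive
case), the required number of cases for a two-sided level-alpha Z test with
target power 1 - beta is

    N+ = ceil[ (z_{1-alpha/2} sqrt(V0) + z_{1-beta} sqrt(V_Alt))^2 / Delta^2 ]

with N- = ceil(R N+) controls.  Inverting the same relation gives the
analytic power at any case count.  Attrition is handled by inflating each
group to ceil(n / (1 - dropout)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from scipy.stats import norm

from .binormal import BinormalCurve, params_from_auc
from .continuous import AreaCorrelationTable, PairedDesignHM, hm_variance_set
from .discrete import PairedDesignOM, VarianceSet, om_variance_set

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "InfeasibleDesignError",
    "variance_set_for",
    "required_n",
    "power_at_n",
    "attrition_adjust",
]

# guards the integer ceiling against float noise at exact boundaries
_CEIL_EPS = 1e-9


class InfeasibleDesignError(ValueError):
    """Raised when no finite sample size can achieve the design's target."""


@dataclass(frozen=True)
class DesignSpec:
    """Complete parameterization of one power / sample-size question.

    ``data_type`` selects the variance engine: ``"discrete"`` uses the
    rating-data (binormal-constant) formulas, ``"continuous"`` the
    Wilcoxon-statistic formulas with the area-correlation table.  For the
    discrete engine ``rho_pos``/``rho_neg`` are the within-case and
    within-control inter-test correlations; the continuous engine averages
    them (they are usually specified tied).
    """

    data_type: Literal["discrete", "continuous"]
    auc1: float
    auc2: float
    rho_pos: float
    rho_neg: float | None = None
    b1: float = 1.0
    b2: float = 1.0
    ratio: float = 1.0
    alpha: float = 0.05
    sides: Literal[1, 2] = 2
    target_power: float = 0.80
    fpr_lo: float = 0.0
    fpr_hi: float = 1.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.data_type not in ("discrete", "continuous"):
            raise ValueError(f"unknown data type {self.data_type!r}")
        if self.rho_neg is None:
            object.__setattr__(self, "rho_neg", self.rho_pos)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")
        if not self.alpha < self.target_power < 1.0:
            raise ValueError(
                f"target power must lie in (alpha, 1), got {self.target_power}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(
                f"dropout rate must lie in [0, 1), got {self.dropout_rate}"
            )

    @property
    def delta(self) -> float:
        return self.auc2 - self.auc1

    @property
    def z_alpha(self) -> float:
        q = 1.0 - self.alpha / 2.0 if self.sides == 2 else 1.0 - self.alpha
        return float(norm.ppf(q))

    def curve(self, which: int) -> BinormalCurve:
        auc, b = (self.auc1, self.b1) if which == 1 else (self.auc2, self.b2)
        base = params_from_auc(auc, b)
        return replace(base, fpr_lo=self.fpr_lo, fpr_hi=self.fpr_hi)


@dataclass(frozen=True)
class SampleSizeResult:
    """Group sizes with attrition-adjusted enrollment figures.

    ``ed_*`` are expected dropouts, ``diss_*`` the dropout-inflated
    enrollment (DISS); per group diss = n + ed.  ``achieved_power`` is the
    analytic power at the integer group size, hence >= the requested
    ``target_power``.
    """

    n_pos: int
    n_neg: int
    n_total: int
    target_power: float
    achieved_power: float
    ed_pos: int
    ed_neg: int
    ed_total: int
    diss_pos: int
    diss_neg: int
    diss_total: int


def variance_set_for(design: DesignSpec) -> VarianceSet:
    """Dispatch to the engine matching the design's data type."""
    if design.data_type == "discrete":
        om = PairedDesignOM(
            curve1=design.curve(1),
            curve2=design.curve(2),
            r_pos=design.rho_pos,
            r_neg=design.rho_neg,
            ratio=design.ratio,
        )
        return om_variance_set(om)
    rho = (design.rho_pos + design.rho_neg) / 2.0
    hm = PairedDesignHM(
        auc1=design.auc1, auc2=design.auc2, rho=rho, ratio=design.ratio
    )
    return hm_variance_set(hm)


def attrition_adjust(n: int, dropout_rate: float) -> tuple[int, int]:
    """Expected dropouts and dropout-inflated enrollment for one group.

    diss = ceil(n / (1 - dropout)), ed = diss - n.
    """
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError(f"dropout rate must lie in [0, 1), got {dropout_rate}")
    diss = math.ceil(n / (1.0 - dropout_rate) - _CEIL_EPS)
    return diss - n, diss


def required_n(design: DesignSpec) -> SampleSizeResult:
    """Smallest integer group sizes achieving the design's target power."""
    if design.auc1 == design.auc2:
        raise InfeasibleDesignError(
            "equal AUCs: no finite sample size can detect a null difference"
        )
    vs = variance_set_for(design)
    z_a = design.z_alpha
    z_b = float(norm.ppf(design.target_power))
    n_real = (
        (z_a * math.sqrt(vs.v_null) + z_b * math.sqrt(vs.v_alt)) / abs(design.delta)
    ) ** 2
    n_pos = max(2, math.ceil(n_real - _CEIL_EPS))
    n_neg = math.ceil(design.ratio * n_pos - _CEIL_EPS)
    achieved = power_at_n(design, n_pos, _variances=vs)
    ed_pos, diss_pos = attrition_adjust(n_pos, design.dropout_rate)
    ed_neg, diss_neg = attrition_adjust(n_neg, design.dropout_rate)
    return SampleSizeResult(
        n_pos=n_pos,
        n_neg=n_neg,
        n_total=n_pos + n_neg,
        target_power=design.target_power,
        achieved_power=achieved,
        ed_pos=ed_pos,
        ed_neg=ed_neg,
        ed_total=ed_pos + ed_neg,
        diss_pos=diss_pos,
        diss_neg=diss_neg,
        diss_total=diss_pos + diss_neg,
    )


def power_at_n(
    design: DesignSpec, n_pos: int, *, _variances: VarianceSet | None = None
) -> float:
    """Analytic power of the Z test at ``n_pos`` cases (and R n_pos controls).

    power = Phi( (|Delta| sqrt(N+) - z_alpha sqrt(V0)) / sqrt(V_Alt) ).
    """
    if n_pos < 2:
        raise ValueError(f"need at least 2 cases, got {n_pos}")
    vs = _variances if _variances is not None else variance_set_for(design)
    z_a = design.z_alpha
    num = abs(design.delta) * math.sqrt(n_pos) - z_a * math.sqrt(vs.v_null)
    return float(norm.cdf(num / math.sqrt(vs.v_alt)))
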
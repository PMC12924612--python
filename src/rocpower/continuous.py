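"""Hanley–McNeil variances for correlated AUCs from continuous scores.

For continuous diagnostic measurements the AUC is read as a Wilcoxon
(Mann–Whitney) statistic and its sampling variance has the closed form

    V(theta) = theta / (R (2 - theta)) + 2 theta^2 / (1 + theta)
               - theta^2 (1 + R) / R

per positive case, with R = N-/N+ the control:case ratio.  The covariance
of two AUC estimates from the same subjects is r * sqrt(V1 V2), where r is
the correlation between the two *areas* — not the raw score correlation the
user knows.  The score correlation rho is converted to r through a lookup
table indexed by (rho, average area); see :class:`AreaCorrelationTable`.

Only the full false-positive-rate range is supported on this path; partial
windows are a rating-data (binormal-constant) facility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .discrete import VarianceSet

__all__ = [
    "PairedDesignHM",
    "AreaCorrelationTable",
    "hm_variance_single",
    "rho_to_area_correlation",
    "hm_variance_set",
]


@dataclass(frozen=True)
class PairedDesignHM:
    """Paired continuous-data design stated directly in AUC terms."""

    auc1: float
    auc2: float
    rho: float
    ratio: float = 1.0

    def __post_init__(self) -> None:
        for name, auc in (("auc1", self.auc1), ("auc2", self.auc2)):
            if not 0.0 < auc < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1), got {auc}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.ratio <= 0:
            raise ValueError(f"control:case ratio must be positive, got {self.ratio}")


class AreaCorrelationTable:
    """Score-correlation -> area-correlation lookup with bilinear interpolation.

    The packaged default grid is a synthetic reconstruction: its anchor rows
    (rho = 0.3, 0.5, 0.8) were calibrated against published scenario tables
    for continuous-data AUC comparisons at a baseline area of 0.80, and the
    remaining rows are monotone interpolants between r = 0 at rho = 0 and
    r = 1 at rho = 1.  Lookups outside the tabulated (rho, area) rectangle
    raise rather than extrapolate.
    """

    def __init__(self, rhos: np.ndarray, areas: np.ndarray, values: np.ndarray):
        rhos = np.asarray(rhos, dtype=float)
        areas = np.asarray(areas, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.shape != (rhos.size, areas.size):
            raise ValueError("table shape does not match its axes")
        if np.any(np.diff(rhos) <= 0) or np.any(np.diff(areas) <= 0):
            raise ValueError("table axes must be strictly increasing")
        if np.any((values < 0) | (values >= 1)):
            raise ValueError("area correlations must lie in [0, 1)")
        if np.any(np.diff(values, axis=0) < 0):
            raise ValueError("r must be nondecreasing in the score correlation")
        self.rhos = rhos
        self.areas = areas
        self.values = values
        self._interp = RegularGridInterpolator(
            (rhos, areas), values, method="linear", bounds_error=True
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AreaCorrelationTable":
        df = pd.read_csv(path, comment="#")
        rhos = df["rho"].to_numpy(dtype=float)
        areas = np.array([float(c) for c in df.columns[1:]])
        return cls(rhos, areas, df.iloc[:, 1:].to_numpy(dtype=float))

    @classmethod
    def default(cls) -> "AreaCorrelationTable":
        ref = resources.files("rocpower.data").joinpath(
            "area_correlation_synthetic.csv"
        )
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def lookup(self, rho: float, mean_area: float) -> float:
        if not self.rhos[0] <= rho <= self.rhos[-1]:
            raise ValueError(
                f"score correlation {rho} outside table support "
                f"[{self.rhos[0]}, {self.rhos[-1]}]"
            )
        if not self.areas[0] <= mean_area <= self.areas[-1]:
            raise ValueError(
                f"mean area {mean_area} outside table support "
                f"[{self.areas[0]}, {self.areas[-1]}]"
            )
        return float(self._interp([rho, mean_area])[0])


_DEFAULT_TABLE: AreaCorrelationTable | None = None


def default_table() -> AreaCorrelationTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AreaCorrelationTable.default()
    return _DEFAULT_TABLE


def hm_variance_single(auc: float, ratio: float = 1.0) -> float:
    """Per-case-scaled Wilcoxon-AUC variance.

    Equivalent to the classic Q1/Q2 form with Q1 = theta/(2 - theta) and
    Q2 = 2 theta^2 / (1 + theta); vanishes as the area approaches 1.
    """
    if not 0.0 < auc < 1.0:
        raise ValueError(f"AUC must lie strictly inside (0, 1), got {auc}")
    if ratio <= 0:
        raise ValueError(f"control:case ratio must be positive, got {ratio}")
    return (
        auc / (ratio * (2.0 - auc))
        + 2.0 * auc**2 / (1.0 + auc)
        - auc**2 * (1.0 + ratio) / ratio
    )


def rho_to_area_correlation(
    rho: float, mean_area: float, table: AreaCorrelationTable | None = None
) -> float:
    """Convert a score correlation to the correlation between the two areas.

    r <= rho throughout the supported region: correlated scores induce less
    than perfectly proportional correlation between the AUC estimates.
    """
    if table is None:
        table = default_table()
    return table.lookup(rho, mean_area)


def hm_variance_set(
    design: PairedDesignHM, table: AreaCorrelationTable | None = None
) -> VarianceSet:
    """Null and alternative variances of the continuous-data AUC difference.

    cov = r sqrt(V1 V2) with r looked up at the average of the two areas.
    The null variance anchors both areas at auc1 (mirroring the rating-data
    engine): V0 = 2 V1 (1 - r).  V_Alt = V1 + V2 - 2 r sqrt(V1 V2), which
    is nonnegative for every r in [0, 1) by Cauchy–Schwarz.
    """
    v1 = hm_variance_single(design.auc1, design.ratio)
    v2 = hm_variance_single(design.auc2, design.ratio)
    r = rho_to_area_correlation(
        design.rho, (design.auc1 + design.auc2) / 2.0, table
    )
    cov = r * math.sqrt(v1 * v2)
    v_null = 2.0 * v1 * (1.0 - r)
    v_alt = v1 + v2 - 2.0 * cov
    return VarianceSet(v1=v1, v2=v2, cov=cov, v_null=v_null, v_alt=v_alt)
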
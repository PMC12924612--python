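"""Monte-Carlo validation of analytic power via simulated paired scores.

Each replication draws paired diagnostic scores from the bivariate binormal
model the analytic formulas assume: controls from a bivariate normal with
zero means, standard deviations (B1, B2) and correlation rho-, cases from a
bivariate normal with means (A1, A2), unit standard deviations and
correlation rho+.  The two empirical Mann–Whitney AUCs are compared with
the Z statistic using the design's analytic null variance (plug-in at the
baseline AUC), and the rejection proportion over replications estimates the
actual power.  The same machinery doubles as the test suite's synthetic
score generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .power import DesignSpec, variance_set_for

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_paired_scores",
    "empirical_auc",
    "estimate_actual_power",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One Monte-Carlo power estimation run.

    ``rating_levels`` switches on rating-data mode: latent continuous scores
    are discretized into that many ordinal categories (thresholds at
    equiprobable quantiles of each test's control distribution) before the
    empirical AUCs are computed.
    """

    design: DesignSpec
    n_pos: int
    n_neg: int
    replications: int = 1000
    seed: int = 0
    rating_levels: int | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if self.replications < 1:
            raise ValueError("need at least one replication")
        if self.rating_levels is not None and self.rating_levels < 2:
            raise ValueError("rating_levels must be >= 2 when set")


@dataclass(frozen=True)
class SimulationResult:
    """Empirical rejection rate with its binomial Monte-Carlo error."""

    rejection_rate: float
    mc_se: float
    mean_auc1: float
    mean_auc2: float
    replications: int
    seed: int
    rng_algorithm: str = "numpy PCG64, per-replication spawned substreams"


def _bivariate(rng: np.random.Generator, n: int, mean, sd, corr: float):
    cov = np.array(
        [
            [sd[0] ** 2, corr * sd[0] * sd[1]],
            [corr * sd[0] * sd[1], sd[1] ** 2],
        ]
    )
    return rng.multivariate_normal(mean, cov, size=n, method="cholesky")


def simulate_paired_scores(
    design: DesignSpec, n_pos: int, n_neg: int, seed: int | np.random.Generator
):
    """Draw one paired sample of case and control scores for both tests.

    Returns ``(cases, controls)``, each an array of shape (n, 2); column i
    holds test i's scores.  The marginal model per test i is
    controls ~ N(0, B_i^2), cases ~ N(A_i, 1), so the population AUC is
    Phi(A_i / sqrt(1 + B_i^2)) — exactly the design's AUC_i.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a1, a2 = design.curve(1).a, design.curve(2).a
    cases = _bivariate(rng, n_pos, [a1, a2], [1.0, 1.0], design.rho_pos)
    controls = _bivariate(
        rng, n_neg, [0.0, 0.0], [design.b1, design.b2], design.rho_neg
    )
    return cases, controls


def empirical_auc(case_scores, control_scores) -> float:
    """Mann–Whitney AUC estimate with ties counted one half.

    Equals the proportion of (case, control) pairs where the case scores
    higher, computed through midranks in O((m+n) log(m+n)).
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([x, y]))
    r_x = ranks[: x.size].sum()
    u = r_x - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def _discretize(scores: np.ndarray, b: tuple[float, float], levels: int) -> np.ndarray:
    """Bin latent scores of both tests into ordinal categories.

    Thresholds sit at equiprobable quantiles of each test's control
    distribution N(0, B_i^2); category labels preserve the latent ordering,
    which is all the rank-based AUC needs.
    """
    out = np.empty_like(scores)
    qs = norm.ppf(np.linspace(0.0, 1.0, levels + 1)[1:-1])
    for i in range(2):
        out[:, i] = np.searchsorted(qs * b[i], scores[:, i], side="right")
    return out


def estimate_actual_power(config: SimulationConfig) -> SimulationResult:
    """Rejection proportion of H0: AUC1 = AUC2 over Monte-Carlo replications.

    The per-replication statistic is Z = (th2_hat - th1_hat) / sqrt(V0/N+)
    with the analytic null variance V0 of the design (anchored at the
    baseline AUC); H0 is rejected when |Z| exceeds the design's critical
    value.  Reproducible for a fixed config: one root seed spawns one
    substream per replication.
    """
    design = config.design
    vs = variance_set_for(design)
    se_null = math.sqrt(vs.v_null / config.n_pos)
    z_crit = design.z_alpha
    root = np.random.default_rng(config.seed)
    streams = root.spawn(config.replications)
    rejections = 0
    auc1_sum = 0.0
    auc2_sum = 0.0
    levels = config.rating_levels
    b = (design.b1, design.b2)
    for rng in streams:
        cases, controls = simulate_paired_scores(
            design, config.n_pos, config.n_neg, rng
        )
        if levels is not None:
            cases = _discretize(cases, b, levels)
            controls = _discretize(controls, b, levels)
        th1 = empirical_auc(cases[:, 0], controls[:, 0])
        th2 = empirical_auc(cases[:, 1], controls[:, 1])
        auc1_sum += th1
        auc2_sum += th2
        if abs(th2 - th1) / se_null > z_crit:
            rejections += 1
    ap = rejections / config.replications
    return SimulationResult(
        rejection_rate=ap,
        mc_se=math.sqrt(ap * (1.0 - ap) / config.replications),
        mean_auc1=auc1_sum / config.replications,
        mean_auc2=auc2_sum / config.replications,
        replications=config.replications,
        seed=config.seed,
    )
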
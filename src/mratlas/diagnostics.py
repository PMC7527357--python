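"""Design-stage analytics: instrument heterogeneity, pleiotropy flagging and
analytic power for a binary outcome.

The power approximation treats the IVW estimate for a log-odds outcome as
normal with non-centrality ``sqrt(n * R2 * c * (1-c)) * |ln OR|``, where n is
the combined case-control sample size, c the case fraction and R2 the variance
in the exposure explained by the instruments.  Power for a two-sided test at
level alpha is then ``Phi(ncp - z_{1-alpha/2})``; the upper tail dominates so
the lower-tail term is dropped, which is conservative by at most alpha/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import HarmonisedInstrument, HeterogeneityStats, MrEstimate


@dataclass(frozen=True)
class PowerQuery:
    """Inputs for the analytic MR power calculation on a binary outcome."""

    n_total: float
    case_fraction: float
    r2: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.n_total > 0):
            raise ValueError("n_total must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must lie in (0, 1)")
        if not (self.odds_ratio > 0):
            raise ValueError("odds_ratio must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def mr_power_binary(q: PowerQuery) -> float:
    """Analytic power; symmetric in OR <-> 1/OR (depends on |ln OR| only)."""
    b = abs(np.log(q.odds_ratio))
    ncp = np.sqrt(q.n_total * q.r2 * q.case_fraction * (1.0 - q.case_fraction)) * b
    z = stats.norm.ppf(1.0 - q.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z))


def heterogeneity(
    insts: Sequence[HarmonisedInstrument], ivw_beta: float
) -> HeterogeneityStats:
    """Cochran's Q of the per-SNP ratio estimates around a given IVW estimate."""
    if len(insts) < 2:
        raise ValueError("heterogeneity undefined for fewer than 2 instruments")
    bx = np.array([i.beta_x for i in insts])
    by = np.array([i.beta_y for i in insts])
    sy = np.array([i.se_y for i in insts])
    w = bx**2 / sy**2
    theta = by / bx
    q = float((w * (theta - ivw_beta) ** 2).sum())
    return HeterogeneityStats(q=q, df=len(insts) - 1)


def pleiotropy_flag(egger_intercept: MrEstimate, alpha: float = 0.05) -> bool:
    """Possible horizontal pleiotropy: MR-Egger intercept p below alpha."""
    return egger_intercept.pvalue < alpha
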
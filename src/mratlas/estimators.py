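"""The two-sample MR estimator suite.

Implements the Wald ratio, fixed- and random-effects inverse-variance-weighted
(IVW) meta-analysis, the weighted median, MR-Egger regression and multivariable
IVW, all on summary statistics.  Notation: for instrument j, ``beta_x[j]`` and
``se_x[j]`` are the SNP-exposure estimate and SE, ``beta_y[j]`` and ``se_y[j]``
the SNP-outcome (log-odds) estimate and SE, and the per-SNP causal (Wald) ratio
is ``theta_j = beta_y[j] / beta_x[j]``.

Weights are first-order throughout: ``w_j = beta_x[j]^2 / se_y[j]^2``, i.e. the
inverse variance of ``theta_j`` ignoring uncertainty in ``beta_x``.  IVW is
then the weighted mean of the ratios — equivalently, weighted regression of
``beta_y`` on ``beta_x`` through the origin.  Random-effects IVW inflates the
fixed-effect SE multiplicatively by ``sqrt(max(1, Q/(n-1)))`` where Q is
Cochran's heterogeneity statistic; under the automatic policy random effects
are used iff the exposure has at least 3 instruments, fixed effects otherwise.

MR-Egger fits the same regression with an unconstrained intercept: the slope
estimates the causal effect under the InSiDE assumption, the intercept the
average directional pleiotropy, and the intercept p-value is the horizontal
pleiotropy test.  Multivariable IVW regresses ``beta_y`` jointly on two
exposures' genetic effects (no intercept) to estimate direct effects.

All p-values are two-tailed from the standard normal reference and all 95% CIs
are ``beta +/- 1.959964 * se``, matching the reporting convention of the
estimates this suite feeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import SnpAssociation  # noqa: F401  (re-exported context)

#: 97.5% standard-normal quantile used for every 95% CI.
Z_95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MrEstimate:
    """A single estimator's output on the log-odds-per-exposure-unit scale."""

    method: str
    beta: float
    se: float
    n_snps: int

    @property
    def ci_low(self) -> float:
        return self.beta - Z_95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z_95 * self.se

    @property
    def pvalue(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q across per-SNP ratio estimates and its transforms.

    ``i2`` is the proportion of variation beyond chance, ``max(0, (Q - df)/Q)``;
    ``phi`` the multiplicative overdispersion ``max(1, Q/df)`` applied to
    random-effects SEs.
    """

    q: float
    df: int

    @property
    def i2(self) -> float:
        if self.q <= 0 or self.df <= 0:
            return 0.0
        return max(0.0, (self.q - self.df) / self.q)

    @property
    def phi(self) -> float:
        if self.df <= 0:
            return 1.0
        return max(1.0, self.q / self.df)

    @property
    def pvalue(self) -> float:
        """Chi-squared tail probability of Q on df degrees of freedom."""
        if self.df <= 0:
            return 1.0
        return float(stats.chi2.sf(self.q, self.df))


@dataclass(frozen=True)
class HarmonisedInstrument:
    """A variant with exposure and outcome effects aligned to one effect allele.

    Orientation convention: the effect allele is the exposure-increasing allele,
    so ``beta_x >= 0`` always.
    """

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    is_proxy: bool = False
    proxy_r2: float | None = None
    #: oriented allele labels (effect allele = exposure-increasing), when known
    effect_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if self.beta_x < 0:
            raise ValueError(f"{self.variant_id}: beta_x must be >= 0 after harmonisation")
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.variant_id}: standard errors must be positive")


def _as_arrays(insts: Sequence[HarmonisedInstrument]) -> tuple[np.ndarray, ...]:
    bx = np.array([i.beta_x for i in insts], dtype=float)
    sx = np.array([i.se_x for i in insts], dtype=float)
    by = np.array([i.beta_y for i in insts], dtype=float)
    sy = np.array([i.se_y for i in insts], dtype=float)
    return bx, sx, by, sy


# ---------------------------------------------------------------------------
# Wald ratio and IVW


def wald_ratio(inst: HarmonisedInstrument) -> MrEstimate:
    """Single-instrument causal estimate beta_y/beta_x with first-order SE."""
    if inst.beta_x == 0:
        raise ZeroDivisionError(f"{inst.variant_id}: beta_x = 0, Wald ratio undefined")
    beta = inst.beta_y / inst.beta_x
    se = inst.se_y / abs(inst.beta_x)
    return MrEstimate(method="wald", beta=beta, se=se, n_snps=1)


def ivw_arrays(
    beta_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    effects_model: str = "auto",
) -> tuple[MrEstimate, HeterogeneityStats]:
    """IVW meta-analysis of Wald ratios on raw arrays.

    ``effects_model``: 'fixed', 'random', or 'auto' (random iff n >= 3).
    """
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = beta_x.size
    if n == 0:
        raise ValueError("IVW requires at least one instrument")
    if np.any(beta_x == 0):
        raise ZeroDivisionError("IVW requires beta_x != 0 for every instrument")
    if effects_model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown effects model {effects_model!r}")

    w = beta_x**2 / se_y**2
    theta = beta_y / beta_x
    sw = float(w.sum())
    beta = float((w * theta).sum() / sw)
    se_fixed = sw**-0.5
    q = float((w * (theta - beta) ** 2).sum()) if n > 1 else 0.0
    het = HeterogeneityStats(q=q, df=n - 1)

    model = effects_model
    if model == "auto":
        model = "random" if n >= 3 else "fixed"
    se = se_fixed * np.sqrt(het.phi) if model == "random" else se_fixed
    method = "ivw_random" if model == "random" else "ivw_fixed"
    return MrEstimate(method=method, beta=beta, se=float(se), n_snps=n), het


def ivw(
    insts: Sequence[HarmonisedInstrument], effects_model: str = "auto"
) -> tuple[MrEstimate, HeterogeneityStats]:
    bx, _, by, sy = _as_arrays(insts)
    return ivw_arrays(bx, by, sy, effects_model=effects_model)


# ---------------------------------------------------------------------------
# Weighted median


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    Sort theta; with normalised sorted weights w_(j) and running sums S_j the
    cumulative midpoints are p_j = (S_j - w_(j)/2) / S_n; the estimate is theta
    linearly interpolated against p at p = 0.5.
    """
    theta = np.asarray(theta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weights[order]
    s = np.cumsum(w)
    p = (s - w / 2.0) / s[-1]
    return float(np.interp(0.5, p, t))


def _weighted_median_rows(theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median (vectorised bootstrap kernel)."""
    order = np.argsort(theta, axis=1, kind="stable")
    t = np.take_along_axis(theta, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    s = np.cumsum(w, axis=1)
    p = (s - w / 2.0) / s[:, -1:]
    # index of first midpoint >= 0.5 per row
    hi = (p < 0.5).sum(axis=1)
    n = theta.shape[1]
    rows = np.arange(theta.shape[0])
    out = np.empty(theta.shape[0])
    at_low = hi == 0
    at_high = hi == n
    mid = ~(at_low | at_high)
    out[at_low] = t[at_low, 0]
    out[at_high] = t[at_high, -1]
    if mid.any():
        h = hi[mid]
        r = rows[mid]
        p_lo, p_hi = p[r, h - 1], p[r, h]
        t_lo, t_hi = t[r, h - 1], t[r, h]
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / np.where(p_hi > p_lo, p_hi - p_lo, 1.0), 0.0)
        out[mid] = t_lo + frac * (t_hi - t_lo)
    return out


def weighted_median_arrays(
    beta_x: np.ndarray,
    se_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted median estimator with parametric-bootstrap SE.

    The bootstrap resamples beta_x ~ N(beta_x, se_x) and beta_y ~ N(beta_y,
    se_y) per instrument, recomputes the point estimate ``n_boot`` times and
    takes the SD of the replicates as the SE; deterministic under a fixed seed.
    Requires >= 3 instruments (the method is not offered for 1–2-SNP
    exposures).
    """
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = beta_x.size
    if n < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    w = beta_x**2 / se_y**2
    beta = weighted_median_point(beta_y / beta_x, w)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for a bootstrap SE")
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(beta_x, se_x, size=(n_boot, n))
    by_b = rng.normal(beta_y, se_y, size=(n_boot, n))
    theta_b = by_b / bx_b
    w_b = bx_b**2 / se_y**2
    boot = _weighted_median_rows(theta_b, w_b)
    se = float(np.std(boot, ddof=1))
    return MrEstimate(method="weighted_median", beta=beta, se=se, n_snps=n)


def weighted_median(
    insts: Sequence[HarmonisedInstrument], n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    bx, sx, by, sy = _as_arrays(insts)
    return weighted_median_arrays(bx, sx, by, sy, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Weighted least squares core (Egger and multivariable IVW)


def _wls(
    design: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via normal equations.

    Returns (coefficients, covariance with multiplicative overdispersion
    max(1, Q_res/(n - p)), residual Q).
    """
    xtw = design.T * w
    a = xtw @ design
    try:
        a_inv = np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError("design matrix is singular (colinear instruments)") from exc
    coef = a_inv @ (xtw @ y)
    resid = y - design @ coef
    q_res = float((w * resid**2).sum())
    n, p = design.shape
    phi = max(1.0, q_res / (n - p)) if n > p else 1.0
    return coef, a_inv * phi, q_res


def mr_egger_arrays(
    beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: returns (slope estimate, intercept estimate).

    WLS of beta_y on beta_x with intercept, weights 1/se_y^2; SEs carry the
    multiplicative overdispersion max(1, Q_res/(n-2)).  Requires >= 3
    instruments and variation in beta_x; assumes the harmonisation convention
    beta_x >= 0 (Egger orientation requirement).
    """
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = beta_x.size
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    if np.ptp(beta_x) == 0:
        raise ValueError("MR-Egger slope unidentified: zero variance in beta_x")
    design = np.column_stack([np.ones(n), beta_x])
    coef, cov, _ = _wls(design, beta_y, 1.0 / se_y**2)
    slope = MrEstimate(method="egger_slope", beta=float(coef[1]), se=float(np.sqrt(cov[1, 1])), n_snps=n)
    intercept = MrEstimate(
        method="egger_intercept", beta=float(coef[0]), se=float(np.sqrt(cov[0, 0])), n_snps=n
    )
    return slope, intercept


def mr_egger(insts: Sequence[HarmonisedInstrument]) -> tuple[MrEstimate, MrEstimate]:
    bx, _, by, sy = _as_arrays(insts)
    return mr_egger_arrays(bx, by, sy)


def mvmr_ivw_arrays(
    beta_x1: np.ndarray, beta_x2: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> tuple[MrEstimate, MrEstimate]:
    """Multivariable IVW for two exposures: direct effects by joint WLS.

    Regression of beta_y on (beta_x1, beta_x2) without intercept, weights
    1/se_y^2, SEs inflated by max(1, Q_res/(n-2)).  The first coefficient is
    the exposure-of-interest effect adjusted for the second exposure.  When one
    exposure has no genetic effect at all (its column is identically zero) the
    fit degenerates gracefully to univariable IVW for the other exposure; the
    unidentified coefficient is reported as 0 with infinite SE.  Colinear
    nonzero columns raise an identifiability error.
    """
    beta_x1 = np.asarray(beta_x1, dtype=float)
    beta_x2 = np.asarray(beta_x2, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n = beta_x1.size
    if n < 3:
        raise ValueError("multivariable IVW requires at least 3 instruments")
    w = 1.0 / se_y**2
    zero1 = not np.any(beta_x1)
    zero2 = not np.any(beta_x2)
    if zero1 and zero2:
        raise ValueError("both exposure effect vectors are zero; nothing identified")
    if zero1 or zero2:
        x = beta_x2 if zero1 else beta_x1
        coef, cov, _ = _wls(x[:, None], beta_y, w)
        fitted = MrEstimate(
            method="mvmr_ivw", beta=float(coef[0]), se=float(np.sqrt(cov[0, 0])), n_snps=n
        )
        absent = MrEstimate(method="mvmr_ivw", beta=0.0, se=float("inf"), n_snps=n)
        return (absent, fitted) if zero1 else (fitted, absent)
    design = np.column_stack([beta_x1, beta_x2])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("exposure effect vectors are colinear; direct effects unidentified")
    coef, cov, _ = _wls(design, beta_y, w)
    est1 = MrEstimate(method="mvmr_ivw", beta=float(coef[0]), se=float(np.sqrt(cov[0, 0])), n_snps=n)
    est2 = MrEstimate(method="mvmr_ivw", beta=float(coef[1]), se=float(np.sqrt(cov[1, 1])), n_snps=n)
    return est1, est2


def mvmr_ivw(
    insts: Sequence[HarmonisedInstrument], beta_x2: Sequence[float]
) -> tuple[MrEstimate, MrEstimate]:
    """Multivariable IVW over harmonised instruments plus a second exposure's effects.

    ``beta_x2[j]`` must be the second exposure's effect for the same oriented
    effect allele as instrument j.
    """
    bx, _, by, sy = _as_arrays(insts)
    return mvmr_ivw_arrays(bx, np.asarray(beta_x2, dtype=float), by, sy)
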
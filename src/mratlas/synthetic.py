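"""Synthetic two-sample MR summary statistics with known ground truth.

The generator emulates the statistical structure of a large case-control
outcome GWAS (discovery and replication) paired with continuous-exposure
GWASs, at the summary level only:

* per-SNP effect-allele frequencies drawn uniformly on a MAF range;
* true SNP-exposure effects ``gamma_j`` drawn from a normal distribution whose
  spread equals its mean by default — GWAS instrument sets mix a few
  large-effect loci with many small ones, and this heterogeneity is also what
  makes MR-Egger regular (the spread of true effects must dominate their
  estimation error); exposure SEs follow the standardised-trait approximation
  ``se_x = 1/sqrt(2 maf (1-maf) n_exposure)``;
* SNP-outcome log-odds effects ``theta * gamma_j + alpha_j`` observed with the
  case-control SE ``se_y = 1/sqrt(2 maf (1-maf) n_total c (1-c))`` where c is
  the case fraction — the same approximation the analytic power formula uses,
  keeping generator and power module mutually consistent;
* ``alpha_j`` is the horizontal-pleiotropy effect: zero for valid instruments,
  drawn per regime (balanced: mean 0; directional: nonzero mean) for an
  ``invalid_fraction`` of SNPs, and shared between discovery and replication
  (pleiotropy is a property of the variant, not the cohort);
* optionally a fraction of SNPs is withheld from the discovery outcome table,
  with high-LD proxies (r² drawn in [0.8, 1], phase-concordant) emitted
  instead, to exercise the missing-SNP/proxy pathway.

Default sample sizes mirror the study conditions the pipeline targets: a
discovery outcome of 74,124 cases / 824,006 controls, a replication outcome of
11,006 cases / 82,655 controls, and exposure GWASs of 200,000 individuals.
Instrument selection is not conditioned on significance (no winner's curse) by
default; ``select_on_significance`` enables it for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import ExposureSpec, LdTable, associations_from_frame

_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy regime for invalid instruments.

    ``balanced`` draws alpha ~ N(0, sd); ``directional`` draws
    alpha ~ N(mean, sd) with mean != 0; ``none`` sets every alpha to 0.
    """

    kind: Literal["none", "balanced", "directional"] = "none"
    mean: float = 0.0
    sd: float = 0.0

    @staticmethod
    def none() -> "Pleiotropy":
        return Pleiotropy("none")

    @staticmethod
    def balanced(sd: float) -> "Pleiotropy":
        return Pleiotropy("balanced", 0.0, sd)

    @staticmethod
    def directional(mean: float, sd: float) -> "Pleiotropy":
        return Pleiotropy("directional", mean, sd)


@dataclass(frozen=True)
class SimScenario:
    """Full parameterisation of one synthetic two-sample MR dataset."""

    n_snps: int = 50
    maf_range: tuple[float, float] = (0.05, 0.45)
    gamma_mean: float = 0.04
    gamma_sd: float = 0.04
    n_exposure: int = 200_000
    n_outcome_cases: int = 74_124
    n_outcome_controls: int = 824_006
    n_replication_cases: int = 11_006
    n_replication_controls: int = 82_655
    theta: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    invalid_fraction: float = 0.0
    missing_fraction: float = 0.0
    proxy_fraction: float = 0.0
    palindrome_fraction: float = 1.0 / 3.0
    select_on_significance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        for n in (
            self.n_exposure,
            self.n_outcome_cases,
            self.n_outcome_controls,
            self.n_replication_cases,
            self.n_replication_controls,
        ):
            if n <= 0:
                raise ValueError("sample sizes must be positive")
        if not (0.0 <= self.missing_fraction <= 1.0 and 0.0 <= self.proxy_fraction <= 1.0):
            raise ValueError("missing_fraction and proxy_fraction must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset (per-SNP arrays)."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray
    maf: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray
    se_y_replication: np.ndarray
    beta_x_obs: np.ndarray
    beta_y_obs: np.ndarray
    beta_y_replication_obs: np.ndarray
    r2_total: float


@dataclass
class SimulatedDataset:
    """One simulated two-sample dataset in both array and table form."""

    scenario: SimScenario
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    replication: pd.DataFrame
    ld: LdTable
    truth: TruthRecord

    def exposure_records(self):
        return associations_from_frame(self.exposure)

    def outcome_records(self):
        return associations_from_frame(self.outcome)

    def replication_records(self):
        return associations_from_frame(self.replication)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _binary_se(maf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n = n_cases + n_controls
    c = n_cases / n
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * c * (1.0 - c))


def _stats_frame(
    ids: list[str],
    a1: list[str],
    a2: list[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": ids,
            "A1": a1,
            "A2": a2,
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": _pvalues(beta, se),
            "N": float(n),
        }
    )


def simulate_two_sample(s: SimScenario) -> SimulatedDataset:
    """Generate one dataset under the scenario; byte-identical under one seed."""
    rng = np.random.default_rng(s.seed)
    n = s.n_snps

    maf = rng.uniform(s.maf_range[0], s.maf_range[1], n)
    gamma = rng.normal(s.gamma_mean, s.gamma_sd, n)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * s.n_exposure)
    beta_x = rng.normal(gamma, se_x)

    n_invalid = int(round(s.invalid_fraction * n))
    valid = np.ones(n, dtype=bool)
    if n_invalid > 0:
        invalid_idx = rng.choice(n, size=n_invalid, replace=False)
        valid[invalid_idx] = False
    alpha = np.zeros(n)
    if s.pleiotropy.kind != "none" and n_invalid > 0:
        alpha[~valid] = rng.normal(s.pleiotropy.mean, s.pleiotropy.sd, n_invalid)

    se_y = _binary_se(maf, s.n_outcome_cases, s.n_outcome_controls)
    beta_y = rng.normal(s.theta * gamma + alpha, se_y)
    se_y_rep = _binary_se(maf, s.n_replication_cases, s.n_replication_controls)
    beta_y_rep = rng.normal(s.theta * gamma + alpha, se_y_rep)

    ids = [f"rs{j + 1:06d}" for j in range(n)]
    pal = rng.random(n) < s.palindrome_fraction
    pair_idx_np = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), n)
    pair_idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), n)
    a1 = [
        (_PALINDROMIC_PAIRS[pair_idx_p[j]] if pal[j] else _NON_PALINDROMIC_PAIRS[pair_idx_np[j]])[0]
        for j in range(n)
    ]
    a2 = [
        (_PALINDROMIC_PAIRS[pair_idx_p[j]] if pal[j] else _NON_PALINDROMIC_PAIRS[pair_idx_np[j]])[1]
        for j in range(n)
    ]

    exposure = _stats_frame(ids, a1, a2, maf, beta_x, se_x, s.n_exposure)
    if s.select_on_significance:
        keep = exposure["P"].to_numpy() < 5e-8
        # winner's-curse stress mode: only observed-significant SNPs are reported
        exposure = exposure.loc[keep].reset_index(drop=True)

    outcome = _stats_frame(ids, a1, a2, maf, beta_y, se_y, s.n_outcome_cases + s.n_outcome_controls)
    replication = _stats_frame(
        ids, a1, a2, maf, beta_y_rep, se_y_rep, s.n_replication_cases + s.n_replication_controls
    )

    ld = LdTable()
    n_missing = int(round(s.missing_fraction * n))
    if n_missing > 0:
        missing_idx = rng.choice(n, size=n_missing, replace=False)
        n_proxied = int(round(s.proxy_fraction * n_missing))
        proxied_idx = rng.choice(missing_idx, size=n_proxied, replace=False) if n_proxied else []
        proxy_rows = []
        for j in proxied_idx:
            pid = f"rs{j + 1:06d}p"
            r2 = float(rng.uniform(0.8, 1.0))
            ld.add(ids[j], pid, r2, phase_concordant=True)
            # proxy tags the index allele (phase-concordant, r2 near 1): the
            # outcome association is carried over unchanged
            proxy_rows.append(
                {
                    "SNP": pid,
                    "A1": a1[j],
                    "A2": a2[j],
                    "EAF": maf[j],
                    "BETA": beta_y[j],
                    "SE": se_y[j],
                    "P": float(_pvalues(np.array([beta_y[j]]), np.array([se_y[j]]))[0]),
                    "N": float(s.n_outcome_cases + s.n_outcome_controls),
                }
            )
        withheld = {ids[j] for j in missing_idx}
        outcome = outcome.loc[~outcome["SNP"].isin(withheld)].reset_index(drop=True)
        if proxy_rows:
            outcome = pd.concat([outcome, pd.DataFrame(proxy_rows)], ignore_index=True)

    r2_total = float(np.sum(2.0 * maf * (1.0 - maf) * gamma**2))
    truth = TruthRecord(
        theta=s.theta,
        gamma=gamma,
        alpha=alpha,
        valid=valid,
        maf=maf,
        se_x=se_x,
        se_y=se_y,
        se_y_replication=se_y_rep,
        beta_x_obs=beta_x,
        beta_y_obs=beta_y,
        beta_y_replication_obs=beta_y_rep,
        r2_total=r2_total,
    )
    return SimulatedDataset(
        scenario=s, exposure=exposure, outcome=outcome, replication=replication, ld=ld, truth=truth
    )


@dataclass
class AtlasBundle:
    """Multi-exposure input bundle for a full synthetic atlas screen."""

    registry: list[ExposureSpec]
    exposure_stats: dict[str, pd.DataFrame]
    outcome: pd.DataFrame
    replication: pd.DataFrame
    ld: LdTable
    causal: dict[str, float]  # exposure_id -> true theta


def simulate_atlas(
    n_exposures: int = 97,
    n_true_effects: int = 7,
    effect_size: float = 0.2,
    n_snps_per_exposure: int = 30,
    scenario: SimScenario | None = None,
    seed: int = 0,
) -> AtlasBundle:
    """Synthetic multi-exposure screen: shared discovery and replication outcome.

    The first ``n_true_effects`` exposures (after a seeded shuffle) receive the
    causal effect ``effect_size``; the rest are null.  Exposures use disjoint
    SNP sets, so a single outcome table serves the whole registry.
    """
    if n_true_effects > n_exposures:
        raise ValueError("n_true_effects cannot exceed the registry size")
    base = scenario if scenario is not None else SimScenario()
    base = replace(base, n_snps=n_snps_per_exposure)
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_exposures + 1)]
    shuffle_rng = np.random.default_rng(child_seeds[-1])
    causal_flags = np.zeros(n_exposures, dtype=bool)
    causal_flags[:n_true_effects] = True
    shuffle_rng.shuffle(causal_flags)

    registry: list[ExposureSpec] = []
    exposure_stats: dict[str, pd.DataFrame] = {}
    outcome_parts: list[pd.DataFrame] = []
    replication_parts: list[pd.DataFrame] = []
    ld = LdTable()
    causal: dict[str, float] = {}
    for k in range(n_exposures):
        theta = effect_size if causal_flags[k] else 0.0
        sub = replace(base, theta=theta, seed=child_seeds[k])
        ds = simulate_two_sample(sub)
        prefix = f"x{k + 1:03d}_"
        for df in (ds.exposure, ds.outcome, ds.replication):
            df["SNP"] = prefix + df["SNP"].astype(str)
        eid = f"exp{k + 1:03d}"
        registry.append(
            ExposureSpec(exposure_id=eid, label=f"synthetic exposure {k + 1}",
                         r2_explained=ds.truth.r2_total)
        )
        exposure_stats[eid] = ds.exposure
        outcome_parts.append(ds.outcome)
        replication_parts.append(ds.replication)
        causal[eid] = theta
    return AtlasBundle(
        registry=registry,
        exposure_stats=exposure_stats,
        outcome=pd.concat(outcome_parts, ignore_index=True),
        replication=pd.concat(replication_parts, ignore_index=True),
        ld=ld,
        causal=causal,
    )
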
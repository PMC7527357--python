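"""Atlas orchestration: run the estimator suite over a registry of exposures
against one outcome, control the false discovery rate across the screen,
classify associations, check replication in a second outcome dataset and
rescale ORs to reporting units.

Classification rules (alpha = 0.05 throughout, strict comparisons):

* **significant** — Benjamini–Hochberg adjusted primary (IVW) p < 0.05;
* **suggestive** — not significant, but IVW p < 0.05 or weighted-median
  p < 0.05, with the two estimates pointing in the same direction;
* **null** — otherwise.  Exposures with fewer than 3 SNPs have no weighted
  median, so they can only be significant or null.

Replication is attempted for exposures with discovery IVW p < 0.05: the same
discovery instruments are re-harmonised against the replication outcome,
IVW is rerun, and direction concordance plus p < 0.1 are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import instruments as instr
from .gwas_io import associations_from_frame
from .estimators import (
    HarmonisedInstrument,
    HeterogeneityStats,
    MrEstimate,
    Z_95,
    ivw,
    mr_egger,
    mvmr_ivw,
    weighted_median,
)
from .gwas_io import ExposureSpec, LdTable, SnpAssociation
from .instruments import InstrumentSet, build_instrument_set, harmonise

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AtlasConfig:
    """Pipeline thresholds; defaults are the atlas design's operating point."""

    p_threshold: float = instr.P_THRESHOLD
    clump_r2: float = instr.CLUMP_R2
    proxy_r2: float = instr.PROXY_R2
    max_missing_for_proxy: int = instr.MAX_MISSING_FOR_PROXY
    palindrome_band: tuple[float, float] = instr.PALINDROME_BAND
    alpha: float = 0.05
    replication_alpha: float = 0.1
    n_boot: int = 1000


@dataclass
class ReplicationResult:
    estimate: MrEstimate
    same_direction: bool
    p_below_threshold: bool
    n_dropped: int = 0


@dataclass
class ExposureResult:
    """Per-exposure bundle of estimates, diagnostics and classification."""

    exposure_id: str
    spec: ExposureSpec
    instrument_set: InstrumentSet
    primary: MrEstimate
    heterogeneity: HeterogeneityStats | None = None
    weighted_median_est: MrEstimate | None = None
    egger_slope: MrEstimate | None = None
    egger_intercept: MrEstimate | None = None
    p_adjusted: float | None = None
    classification: str = "null"
    replication: str = "none"  # none | attempted | unavailable
    replication_result: ReplicationResult | None = None
    bmi_adjusted: MrEstimate | None = None

    @property
    def egger_intercept_p(self) -> float | None:
        return None if self.egger_intercept is None else self.egger_intercept.pvalue

    @property
    def or_scaled(self) -> tuple[float, float, float]:
        return scale_to_unit(self.primary, self.spec.unit_scale)

    def report_rows(self) -> list[dict]:
        rows = []
        methods: list[tuple[str, MrEstimate | None]] = [
            (self.primary.method, self.primary),
            ("weighted_median", self.weighted_median_est),
            ("egger_slope", self.egger_slope),
            ("egger_intercept", self.egger_intercept),
        ]
        if self.bmi_adjusted is not None:
            methods.append(("mvmr_ivw_bmi_adjusted", self.bmi_adjusted))
        for name, est in methods:
            if est is None:
                continue
            or_, lo, hi = scale_to_unit(est, self.spec.unit_scale)
            rows.append(
                {
                    "exposure_id": self.exposure_id,
                    "method": name,
                    "n_snps": est.n_snps,
                    "beta": est.beta,
                    "se": est.se,
                    "or": or_,
                    "or_ci_low": lo,
                    "or_ci_high": hi,
                    "pvalue": est.pvalue,
                    "p_adjusted": self.p_adjusted if name == self.primary.method else np.nan,
                    "q_statistic": self.heterogeneity.q if self.heterogeneity else np.nan,
                    "i2": self.heterogeneity.i2 if self.heterogeneity else np.nan,
                    "egger_intercept_p": (
                        self.egger_intercept_p if self.egger_intercept_p is not None else np.nan
                    ),
                    "classification": self.classification,
                    "replication": self.replication,
                    "replication_same_direction": (
                        self.replication_result.same_direction if self.replication_result else None
                    ),
                    "replication_p": (
                        self.replication_result.estimate.pvalue if self.replication_result else np.nan
                    ),
                }
            )
        return rows


def scale_to_unit(est: MrEstimate, unit_scale: float) -> tuple[float, float, float]:
    """OR and 95% CI per reporting unit: rescale on log-odds, then exponentiate."""
    if not (unit_scale > 0):
        raise ValueError("unit_scale must be positive")
    b = est.beta * unit_scale
    half = Z_95 * est.se * unit_scale
    return float(np.exp(b)), float(np.exp(b - half)), float(np.exp(b + half))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    p_adjusted: float,
    primary: MrEstimate,
    weighted_median_est: MrEstimate | None,
    alpha: float = 0.05,
) -> str:
    """Apply the significant / suggestive / null rules (see module docstring)."""
    if p_adjusted < alpha:
        return "significant"
    if weighted_median_est is None:
        return "null"
    nominally = primary.pvalue < alpha or weighted_median_est.pvalue < alpha
    concordant = np.sign(primary.beta) == np.sign(weighted_median_est.beta)
    if nominally and concordant:
        return "suggestive"
    return "null"


def replicate(
    exposure_snps: Sequence[SnpAssociation],
    replication_stats: Mapping[str, SnpAssociation] | Sequence[SnpAssociation],
    discovery_beta: float,
    palindrome_band: tuple[float, float] = instr.PALINDROME_BAND,
    replication_alpha: float = 0.1,
) -> ReplicationResult | None:
    """Re-harmonise discovery instruments against a second outcome and rerun IVW.

    Instruments absent from the replication dataset are dropped (counted);
    returns None when none remain.
    """
    by_id: Mapping[str, SnpAssociation]
    if isinstance(replication_stats, Mapping):
        by_id = replication_stats
    else:
        by_id = {s.variant_id: s for s in replication_stats}
    insts: list[HarmonisedInstrument] = []
    n_dropped = 0
    for snp in exposure_snps:
        out = by_id.get(snp.variant_id)
        if out is None:
            n_dropped += 1
            continue
        h = harmonise(snp, out, palindrome_band)
        if h is None:
            n_dropped += 1
            continue
        insts.append(h)
    if not insts:
        return None
    est, _ = ivw(insts, effects_model="auto")
    return ReplicationResult(
        estimate=est,
        same_direction=bool(np.sign(est.beta) == np.sign(discovery_beta)),
        p_below_threshold=est.pvalue < replication_alpha,
        n_dropped=n_dropped,
    )


def _align_second_exposure(
    inst: HarmonisedInstrument, rec: SnpAssociation | None
) -> float:
    """Second exposure's effect for the instrument's oriented effect allele.

    Missing or irreconcilable records contribute 0 (no measured effect on the
    adjusting exposure).
    """
    if rec is None or inst.effect_allele is None:
        return 0.0
    ea, oa = inst.effect_allele, inst.other_allele
    c = instr.COMPLEMENT
    if (rec.effect_allele, rec.other_allele) == (ea, oa):
        return rec.beta
    if (rec.effect_allele, rec.other_allele) == (oa, ea):
        return -rec.beta
    if (c[rec.effect_allele], c[rec.other_allele]) == (ea, oa):
        return rec.beta
    if (c[rec.effect_allele], c[rec.other_allele]) == (oa, ea):
        return -rec.beta
    return 0.0


def _coerce_outcome(
    stats: Mapping[str, SnpAssociation] | Sequence[SnpAssociation] | pd.DataFrame,
) -> Mapping[str, SnpAssociation]:
    if isinstance(stats, Mapping):
        return stats
    if isinstance(stats, pd.DataFrame):
        stats = associations_from_frame(stats)
    return {s.variant_id: s for s in stats}


def run_atlas(
    registry: Sequence[ExposureSpec],
    exposure_stats: Mapping[str, Sequence[SnpAssociation]],
    outcome_stats: Mapping[str, SnpAssociation] | Sequence[SnpAssociation],
    replication_stats: Mapping[str, SnpAssociation] | Sequence[SnpAssociation] | None = None,
    ld: LdTable | None = None,
    config: AtlasConfig = AtlasConfig(),
    bmi_stats: Mapping[str, SnpAssociation] | Sequence[SnpAssociation] | None = None,
    seed: int = 0,
) -> list[ExposureResult]:
    """Run the full per-exposure analysis across the registry.

    BH adjustment is applied once, jointly across all analysable exposures'
    primary IVW p-values.  Deterministic under a fixed seed (the only
    stochastic step is the weighted-median bootstrap, seeded per exposure).
    Summary statistics may be given as record sequences, id->record mappings,
    or frames in the default column layout.
    """
    outcome_by_id = _coerce_outcome(outcome_stats)
    replication_stats = (
        None if replication_stats is None else _coerce_outcome(replication_stats)
    )
    bmi_by_id = None if bmi_stats is None else _coerce_outcome(bmi_stats)
    exposure_stats = {
        k: (associations_from_frame(v) if isinstance(v, pd.DataFrame) else v)
        for k, v in exposure_stats.items()
    }

    results: list[ExposureResult] = []
    for idx, spec in enumerate(registry):
        stats_x = exposure_stats.get(spec.exposure_id)
        if stats_x is None:
            logger.warning("no summary statistics for exposure %s; skipped", spec.exposure_id)
            continue
        iset = build_instrument_set(
            spec.exposure_id,
            stats_x,
            outcome_by_id,
            ld,
            p_threshold=config.p_threshold,
            clump_r2=config.clump_r2,
            proxy_r2=config.proxy_r2,
            max_missing_for_proxy=config.max_missing_for_proxy,
            palindrome_band=config.palindrome_band,
            r2_explained=spec.r2_explained,
        )
        if not iset.analysable:
            logger.warning("exposure %s has no usable instruments; non-analysable", spec.exposure_id)
            continue
        primary, het = ivw(iset.instruments, effects_model="auto")
        wm = egger_s = egger_i = None
        if iset.n_snps >= 3:
            wm_seed = (seed * 1_000_003 + idx) % 2**31
            wm = weighted_median(iset.instruments, n_boot=config.n_boot, seed=wm_seed)
            egger_s, egger_i = mr_egger(iset.instruments)
        results.append(
            ExposureResult(
                exposure_id=spec.exposure_id,
                spec=spec,
                instrument_set=iset,
                primary=primary,
                heterogeneity=het if iset.n_snps >= 2 else None,
                weighted_median_est=wm,
                egger_slope=egger_s,
                egger_intercept=egger_i,
            )
        )
    if not results:
        raise ValueError("no analysable exposures in the registry")

    adjusted = bh_adjust([r.primary.pvalue for r in results])
    for res, p_adj in zip(results, adjusted):
        res.p_adjusted = float(p_adj)
        res.classification = classify(
            res.p_adjusted, res.primary, res.weighted_median_est, config.alpha
        )

    exposure_records = {
        r.exposure_id: {s.variant_id: s for s in exposure_stats[r.exposure_id]} for r in results
    }
    for res in results:
        if res.primary.pvalue < config.alpha:
            if replication_stats is None:
                res.replication = "unavailable"
            else:
                recs = exposure_records[res.exposure_id]
                snps = [
                    recs[i.variant_id] for i in res.instrument_set.instruments
                    if i.variant_id in recs
                ]
                rep = replicate(
                    snps,
                    replication_stats,
                    res.primary.beta,
                    config.palindrome_band,
                    config.replication_alpha,
                )
                if rep is None:
                    res.replication = "unavailable"
                else:
                    res.replication = "attempted"
                    res.replication_result = rep

        if (
            res.spec.adjust_bmi
            and not res.spec.bmi_correlated
            and bmi_by_id is not None
            and res.primary.pvalue < config.alpha
            and res.instrument_set.n_snps >= 3
        ):
            beta_bmi = [
                _align_second_exposure(i, bmi_by_id.get(i.variant_id))
                for i in res.instrument_set.instruments
            ]
            try:
                est1, _ = mvmr_ivw(res.instrument_set.instruments, beta_bmi)
            except ValueError:
                logger.warning("BMI adjustment unidentified for %s", res.exposure_id)
            else:
                res.bmi_adjusted = est1
    return results
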
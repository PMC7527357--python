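"""Instrument construction: genome-wide selection, LD clumping, proxy
substitution, allele harmonisation and instrument-strength checks.

The pipeline mirrors standard two-sample MR practice: keep SNPs below the
genome-wide significance threshold (p < 5e-8), greedily prune to an
approximately independent set (exclude r² >= 0.01 with any kept SNP), join to
the outcome dataset by rsID, substitute high-LD proxies (r² >= 0.8) for
missing SNPs when the trait is missing at most 10 SNPs, and harmonise so the
effect allele is the exposure-increasing allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .estimators import HarmonisedInstrument
from .gwas_io import LdTable, SnpAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default pipeline thresholds.
P_THRESHOLD = 5e-8
CLUMP_R2 = 0.01
PROXY_R2 = 0.8
MAX_MISSING_FOR_PROXY = 10
PALINDROME_BAND = (0.42, 0.58)


@dataclass
class InstrumentSet:
    """A harmonised instrument set for one exposure, with bookkeeping counts."""

    exposure_id: str
    instruments: list[HarmonisedInstrument]
    n_requested: int
    n_missing: int
    n_proxied: int
    n_dropped_harmonisation: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)
    f_statistic: float | None = None

    @property
    def n_snps(self) -> int:
        return len(self.instruments)

    @property
    def analysable(self) -> bool:
        return len(self.instruments) > 0

    @property
    def strong(self) -> bool | None:
        if self.f_statistic is None:
            return None
        return self.f_statistic > 10.0


def select_instruments(
    snps: Iterable[SnpAssociation], p_threshold: float = P_THRESHOLD
) -> list[SnpAssociation]:
    """SNPs with p strictly below the significance threshold."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must lie in (0, 1]")
    return [s for s in snps if s.pvalue < p_threshold]


def clump(
    snps: Sequence[SnpAssociation], ld: LdTable, r2_max: float = CLUMP_R2
) -> list[SnpAssociation]:
    """Greedy LD pruning in ascending p-value order.

    A SNP is kept iff its recorded r² with every already-kept SNP is below
    ``r2_max``; unknown pairs count as r² = 0.  Ties in p broken by variant id,
    so the output depends only on (p, id, LD), not input order.
    """
    if not (0.0 <= r2_max <= 1.0):
        raise ValueError("r2_max must lie in [0, 1]")
    ordered = sorted(snps, key=lambda s: (s.pvalue, s.variant_id))
    kept: list[SnpAssociation] = []
    for snp in ordered:
        if all(ld.r2(snp.variant_id, k.variant_id) < r2_max for k in kept):
            kept.append(snp)
    return kept


def find_proxy(
    index: SnpAssociation | str,
    outcome_variants: set[str],
    ld: LdTable,
    r2_min: float = PROXY_R2,
) -> tuple[str, float, bool | None] | None:
    """Best available proxy for a SNP missing from the outcome dataset.

    Among outcome-present variants with r² >= ``r2_min`` to the index SNP,
    returns ``(proxy_id, r2, phase_concordant)`` for the highest-r² candidate,
    ties broken by lexicographically smallest variant id; None if no candidate.
    """
    if not (0.0 < r2_min <= 1.0):
        raise ValueError("r2_min must lie in (0, 1]")
    index_id = index if isinstance(index, str) else index.variant_id
    best: tuple[float, str, bool | None] | None = None
    for cand, (r2, phase) in ld.partners(index_id).items():
        if cand not in outcome_variants or r2 < r2_min:
            continue
        if best is None or r2 > best[0] or (r2 == best[0] and cand < best[1]):
            best = (r2, cand, phase)
    if best is None:
        return None
    return best[1], best[0], best[2]


def _oriented(snp: SnpAssociation) -> SnpAssociation:
    """Flip alleles/sign so beta >= 0 (effect allele = exposure-increasing)."""
    if snp.beta >= 0:
        return snp
    return SnpAssociation(
        variant_id=snp.variant_id,
        effect_allele=snp.other_allele,
        other_allele=snp.effect_allele,
        beta=-snp.beta,
        se=snp.se,
        pvalue=snp.pvalue,
        eaf=None if snp.eaf is None else 1.0 - snp.eaf,
        n=snp.n,
        chrom=snp.chrom,
        pos=snp.pos,
    )


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def harmonise(
    exposure: SnpAssociation,
    outcome: SnpAssociation,
    palindrome_eaf_band: tuple[float, float] = PALINDROME_BAND,
    is_proxy: bool = False,
    proxy_r2: float | None = None,
) -> HarmonisedInstrument | None:
    """Align exposure and outcome effects to the exposure-increasing allele.

    Steps: (1) orient the exposure record so beta_x >= 0; (2) match the outcome
    alleles to the oriented exposure alleles directly, with a sign flip if the
    labels are swapped, or after strand complement if neither matches; (3) drop
    palindromic (A/T, C/G) SNPs whose EAF falls inside the ambiguity band in
    either dataset — strand cannot be resolved there; palindromes outside the
    band are additionally frequency-checked (EAFs on opposite sides of 0.5 flip
    the outcome sign).  Returns None when the instrument must be dropped.
    """
    exp = _oriented(exposure)
    ea, oa = exp.effect_allele, exp.other_allele
    palindromic = _is_palindromic(ea, oa)

    if palindromic:
        lo, hi = palindrome_eaf_band
        for eaf in (exp.eaf, outcome.eaf):
            if eaf is not None and lo <= eaf <= hi:
                return None  # ambiguous palindrome

    out_ea, out_oa = outcome.effect_allele, outcome.other_allele
    if (out_ea, out_oa) == (ea, oa):
        beta_y = outcome.beta
        out_eaf = outcome.eaf
    elif (out_ea, out_oa) == (oa, ea):
        beta_y = -outcome.beta
        out_eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
    else:
        c_ea, c_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
        if (c_ea, c_oa) == (ea, oa):
            beta_y = outcome.beta
            out_eaf = outcome.eaf
        elif (c_ea, c_oa) == (oa, ea):
            beta_y = -outcome.beta
            out_eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
        else:
            return None  # irreconcilable alleles

    if palindromic and exp.eaf is not None and out_eaf is not None:
        # Label match is strand-ambiguous for palindromes: trust frequencies.
        if (exp.eaf - 0.5) * (out_eaf - 0.5) < 0:
            beta_y = -beta_y

    return HarmonisedInstrument(
        variant_id=exp.variant_id,
        beta_x=exp.beta,
        se_x=exp.se,
        beta_y=beta_y,
        se_y=outcome.se,
        is_proxy=is_proxy,
        proxy_r2=proxy_r2,
        effect_allele=ea,
        other_allele=oa,
    )


def f_statistic(r2: float, n: float, k: int) -> tuple[float, bool]:
    """Instrument-strength F-statistic for k SNPs explaining R² in n samples.

    F = (R²/(1-R²)) * (n-k-1)/k; an instrument is conventionally 'strong' when
    F > 10 (strictly).
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must lie in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("F-statistic undefined: n must exceed k + 1")
    f = (r2 / (1.0 - r2)) * (n - k - 1) / k
    return f, f > 10.0


def approx_r2_from_instruments(insts: Sequence[SnpAssociation]) -> float | None:
    """Aggregate variance explained, 2*eaf*(1-eaf)*beta² summed over SNPs.

    Valid for a standardised continuous trait; returns None when any SNP lacks
    an allele frequency.
    """
    total = 0.0
    for s in insts:
        if s.eaf is None:
            return None
        total += 2.0 * s.eaf * (1.0 - s.eaf) * s.beta**2
    return total


def build_instrument_set(
    exposure_id: str,
    exposure_stats: Sequence[SnpAssociation],
    outcome_stats: Mapping[str, SnpAssociation] | Sequence[SnpAssociation],
    ld: LdTable | None = None,
    p_threshold: float = P_THRESHOLD,
    clump_r2: float = CLUMP_R2,
    proxy_r2: float = PROXY_R2,
    max_missing_for_proxy: int = MAX_MISSING_FOR_PROXY,
    palindrome_band: tuple[float, float] = PALINDROME_BAND,
    r2_explained: float | None = None,
    n_exposure: float | None = None,
) -> InstrumentSet:
    """Full instrument pipeline: select -> clump -> join -> proxy -> harmonise.

    Proxies are substituted only when the trait is missing at most
    ``max_missing_for_proxy`` SNPs from the outcome dataset; otherwise missing
    SNPs are dropped.  Proxy effects are aligned with the LD table's phase
    flag; with no phase information a proxy is used only when its allele labels
    match the index SNP's.  An empty result marks the exposure non-analysable
    rather than raising.
    """
    ld = ld if ld is not None else LdTable()
    outcome_by_id: Mapping[str, SnpAssociation]
    if isinstance(outcome_stats, Mapping):
        outcome_by_id = outcome_stats
    else:
        outcome_by_id = {s.variant_id: s for s in outcome_stats}

    significant = select_instruments(exposure_stats, p_threshold)
    clumped = clump(significant, ld, clump_r2)
    n_requested = len(clumped)

    present = [s for s in clumped if s.variant_id in outcome_by_id]
    missing = [s for s in clumped if s.variant_id not in outcome_by_id]
    n_missing = len(missing)

    pairs: list[tuple[SnpAssociation, SnpAssociation, bool, float | None]] = [
        (s, outcome_by_id[s.variant_id], False, None) for s in present
    ]
    n_proxied = 0
    if 0 < n_missing <= max_missing_for_proxy:
        outcome_ids = set(outcome_by_id)
        for snp in missing:
            hit = find_proxy(snp, outcome_ids, ld, proxy_r2)
            if hit is None:
                continue
            proxy_id, r2, phase = hit
            proxy_rec = outcome_by_id[proxy_id]
            aligned = _align_proxy_outcome(snp, proxy_rec, phase)
            if aligned is None:
                continue
            pairs.append((snp, aligned, True, r2))
            n_proxied += 1

    instruments: list[HarmonisedInstrument] = []
    drop_reasons: dict[str, int] = {}
    for exp_snp, out_snp, is_proxy, r2 in pairs:
        inst = harmonise(exp_snp, out_snp, palindrome_band, is_proxy=is_proxy, proxy_r2=r2)
        if inst is None:
            reason = (
                "ambiguous_palindrome"
                if _is_palindromic(exp_snp.effect_allele, exp_snp.other_allele)
                else "allele_mismatch"
            )
            drop_reasons[reason] = drop_reasons.get(reason, 0) + 1
            continue
        instruments.append(inst)

    f_stat: float | None = None
    k = len(instruments)
    if k > 0:
        r2_agg = r2_explained
        if r2_agg is None:
            kept_ids = {i.variant_id for i in instruments}
            r2_agg = approx_r2_from_instruments([s for s in clumped if s.variant_id in kept_ids])
        n_eff = n_exposure
        if n_eff is None:
            ns = [s.n for s in clumped if s.n is not None]
            n_eff = min(ns) if ns else None
        if r2_agg is not None and n_eff is not None and n_eff > k + 1:
            f_stat, _ = f_statistic(r2_agg, n_eff, k)

    return InstrumentSet(
        exposure_id=exposure_id,
        instruments=instruments,
        n_requested=n_requested,
        n_missing=n_missing,
        n_proxied=n_proxied,
        n_dropped_harmonisation=sum(drop_reasons.values()),
        drop_reasons=drop_reasons,
        f_statistic=f_stat,
    )


def _align_proxy_outcome(
    index: SnpAssociation, proxy: SnpAssociation, phase_concordant: bool | None
) -> SnpAssociation | None:
    """Express a proxy's outcome effect in terms of the index SNP's alleles.

    With a phase flag, the proxy's effect allele tags the index effect allele
    (concordant) or the index other allele (discordant).  Without phase
    information the proxy is usable only when its allele labels are identical
    to the index SNP's (then taken at face value).
    """
    if phase_concordant is None:
        if (proxy.effect_allele, proxy.other_allele) != (index.effect_allele, index.other_allele):
            return None
        ea, oa = proxy.effect_allele, proxy.other_allele
    elif phase_concordant:
        ea, oa = index.effect_allele, index.other_allele
    else:
        ea, oa = index.other_allele, index.effect_allele
    return SnpAssociation(
        variant_id=index.variant_id,
        effect_allele=ea,
        other_allele=oa,
        beta=proxy.beta,
        se=proxy.se,
        pvalue=proxy.pvalue,
        eaf=proxy.eaf,
        n=proxy.n,
    )
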
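"""Reading and writing GWAS summary-statistic tables, LD references and atlas reports.

All joins in the pipeline are by rsID; genomic coordinates, when present, are
carried but never required.  Summary statistics are plain delimited text with a
header, in the common GWAS summary format (``SNP A1 A2 EAF BETA SE P N``) or any
header that a column map can translate to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: Default column mapping: canonical field -> column name in the file.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")


class SummaryStatsError(ValueError):
    """Configuration or content problem in a summary-statistics table."""


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's association summary in one GWAS.

    ``beta`` is the additive per-effect-allele estimate: trait units for a
    continuous exposure, log-odds for a binary trait.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.variant_id}: nonpositive SE")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: p-value outside (0, 1]")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: EAF outside (0, 1)")
        if self.n is not None and not (self.n > 0):
            raise ValueError(f"{self.variant_id}: nonpositive sample size")


@dataclass(frozen=True)
class ExposureSpec:
    """Registry entry for one exposure trait.

    ``unit_scale`` multiplies the log-odds estimate before exponentiation so the
    reported OR refers to the unit the trait is conventionally expressed in
    (for example per SD rather than per GWAS unit).  ``r2_explained`` is the
    variance in the exposure explained by the instrument set, used for the
    F-statistic and power calculations when supplied.
    """

    exposure_id: str
    label: str = ""
    trait_type: str = "continuous"
    unit_scale: float = 1.0
    r2_explained: float | None = None
    category: str = ""
    adjust_bmi: bool = False
    bmi_correlated: bool = False

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if not (self.unit_scale > 0):
            raise ValueError("unit_scale must be positive")
        if self.r2_explained is not None and not (0.0 <= self.r2_explained < 1.0):
            raise ValueError("r2_explained must lie in [0, 1)")


class LdTable:
    """Symmetric lookup of pairwise r² (and optional phase concordance).

    Unknown pairs have r² = 0.  Duplicate entries keep the larger r².
    ``phase(a, b)`` is True when the effect alleles of the two variants sit on
    the same haplotype, the information needed to orient a proxy's effect.
    """

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, tuple[float, bool | None]]] = {}

    def add(self, a: str, b: str, r2: float, phase_concordant: bool | None = None) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 outside [0, 1]: {r2}")
        if a == b:
            return
        prev = self._adj.get(a, {}).get(b)
        if prev is not None and prev[0] >= r2:
            return
        self._adj.setdefault(a, {})[b] = (r2, phase_concordant)
        self._adj.setdefault(b, {})[a] = (r2, phase_concordant)

    def r2(self, a: str, b: str) -> float:
        entry = self._adj.get(a, {}).get(b)
        return 0.0 if entry is None else entry[0]

    def phase(self, a: str, b: str) -> bool | None:
        entry = self._adj.get(a, {}).get(b)
        return None if entry is None else entry[1]

    def partners(self, a: str) -> dict[str, tuple[float, bool | None]]:
        return dict(self._adj.get(a, {}))

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    lenient: bool = False,
) -> tuple[list[SnpAssociation], list[tuple[int, str]]]:
    """Read a delimited summary-statistics table.

    Returns ``(records, rejected)`` where ``rejected`` lists ``(row_index,
    reason)`` for rows violating the data model.  Unless ``lenient``, any
    rejected row raises :class:`SummaryStatsError` (naming the first reasons).
    Alleles are upper-cased on the way in.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_delimited(path)
    missing = [cmap[f] for f in _MANDATORY if cmap[f] not in df.columns]
    if missing:
        raise SummaryStatsError(f"{path}: missing mandatory column(s) {missing}")
    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns

    records: list[SnpAssociation] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            eaf = float(row_d[cmap["eaf"]]) if has_eaf else None
            if eaf is not None and math.isnan(eaf):
                eaf = None
            n = float(row_d[cmap["n"]]) if has_n else None
            if n is not None and math.isnan(n):
                n = None
            se = float(row_d[cmap["se"]])
            if not se > 0:
                raise ValueError("nonpositive SE")
            rec = SnpAssociation(
                variant_id=str(row_d[cmap["variant_id"]]),
                effect_allele=str(row_d[cmap["effect_allele"]]).upper(),
                other_allele=str(row_d[cmap["other_allele"]]).upper(),
                beta=float(row_d[cmap["beta"]]),
                se=se,
                pvalue=float(row_d[cmap["pvalue"]]),
                eaf=eaf,
                n=n,
            )
        except (ValueError, TypeError) as exc:
            rejected.append((i, str(exc)))
            continue
        records.append(rec)
    if rejected and not lenient:
        raise SummaryStatsError(
            f"{path}: {len(rejected)} rejected row(s); first: row {rejected[0][0]}: {rejected[0][1]}"
        )
    return records, rejected


def write_summary_stats(records: Iterable[SnpAssociation], path: str | Path) -> None:
    """Write records in the default column layout (tab-delimited)."""
    df = summary_stats_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def summary_stats_frame(records: Iterable[SnpAssociation]) -> pd.DataFrame:
    rows = [
        {
            "SNP": r.variant_id,
            "A1": r.effect_allele,
            "A2": r.other_allele,
            "EAF": r.eaf,
            "BETA": r.beta,
            "SE": r.se,
            "P": r.pvalue,
            "N": r.n,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["SNP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"])


def associations_from_frame(df: pd.DataFrame) -> list[SnpAssociation]:
    """Convert an in-memory frame in the default layout to records (strict)."""
    out = []
    for row in df.itertuples(index=False):
        eaf = getattr(row, "EAF", None)
        n = getattr(row, "N", None)
        out.append(
            SnpAssociation(
                variant_id=str(row.SNP),
                effect_allele=str(row.A1).upper(),
                other_allele=str(row.A2).upper(),
                beta=float(row.BETA),
                se=float(row.SE),
                pvalue=float(row.P),
                eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
                n=None if n is None or pd.isna(n) else float(n),
            )
        )
    return out


def read_ld_table(path: str | Path) -> LdTable:
    """Read a delimited LD pair list (``a b r2 [phase]``) into a symmetric table."""
    df = _read_delimited(path)
    if df.shape[1] < 3:
        raise SummaryStatsError(f"{path}: LD table needs at least 3 columns")
    table = LdTable()
    cols = list(df.columns)
    for row in df.itertuples(index=False):
        r2 = float(getattr(row, cols[2]) if hasattr(row, cols[2]) else row[2])
        phase = None
        if df.shape[1] >= 4:
            raw = row[3]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                phase = bool(raw) if isinstance(raw, (bool,)) else str(raw).lower() in ("1", "true", "t", "yes")
        table.add(str(row[0]), str(row[1]), r2, phase)
    return table


def write_ld_table(table: LdTable, path: str | Path) -> None:
    seen = set()
    rows = []
    for a, partners in table._adj.items():
        for b, (r2, phase) in partners.items():
            key = tuple(sorted((a, b)))
            if key in seen:
                continue
            seen.add(key)
            rows.append({"variant_a": key[0], "variant_b": key[1], "r2": r2, "phase_concordant": phase})
    pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2", "phase_concordant"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_registry(path: str | Path) -> list[ExposureSpec]:
    """Read the exposure registry (delimited, one row per exposure)."""
    df = _read_delimited(path)
    specs = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        specs.append(
            ExposureSpec(
                exposure_id=str(d["exposure_id"]),
                label=str(d.get("label", "")),
                trait_type=str(d.get("trait_type", "continuous")),
                unit_scale=float(d.get("unit_scale", 1.0)),
                r2_explained=(None if pd.isna(d.get("r2_explained", float("nan"))) else float(d["r2_explained"])),
                category=str(d.get("category", "")),
                adjust_bmi=bool(d.get("adjust_bmi", False)),
                bmi_correlated=bool(d.get("bmi_correlated", False)),
            )
        )
    return specs


_REPORT_COLUMNS = [
    "exposure_id",
    "method",
    "n_snps",
    "beta",
    "se",
    "or",
    "or_ci_low",
    "or_ci_high",
    "pvalue",
    "p_adjusted",
    "q_statistic",
    "i2",
    "egger_intercept_p",
    "classification",
    "replication",
    "replication_same_direction",
    "replication_p",
]


def write_atlas_report(results: Sequence, path: str | Path) -> None:
    """Write one row per (exposure, method); see the atlas module for the row model.

    Floats are written at 10 significant digits so a round-trip read reproduces
    every estimate well within 6 significant figures.
    """
    if len(results) == 0:
        raise ValueError("refusing to write an empty atlas report")
    rows = []
    for res in results:
        rows.extend(res.report_rows())
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_atlas_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
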
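"""GWAS summary-statistic tables: reading, validation, scale conversion.

Association records carry, per variant: the effect and other allele, the
effect-allele frequency (EAF), the estimated effect ``beta`` with standard
error ``se``, the two-sided p-value, and the analysed sample size.  For
binary traits ``beta`` is a log odds ratio; for rank-inverse-normalised
quantitative traits it is in phenotypic SD units per allele.

The module also implements the approximate conversion of linear-mixed-model
(LMM) case-control association statistics to the logistic scale, which is
needed when an outcome GWAS analysed a 0/1 disease indicator with a linear
model (as large biobank LMM scans do).  Under Hardy-Weinberg equilibrium the
genotype variance is ``varG = 2 p (1 - p)``, and the logistic-scale standard
error is approximated by

    SE_logit = 1 / sqrt(varG * N * pr * (1 - pr))

where ``pr`` is the cohort disease prevalence.  The Z statistic is recovered
from the two-sided p-value (with the sign of the linear-scale beta) and the
logistic-scale effect is ``beta_logit = Z * SE_logit``, so the conversion
preserves the p-value exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pqtlmr")

__all__ = [
    "VariantAssociation",
    "CohortMeta",
    "GWASTable",
    "SummaryStatsFormatError",
    "ValidationError",
    "DEFAULT_COLUMN_MAP",
    "read_summary_stats",
    "write_summary_stats",
    "compute_prevalence",
    "lmm_to_logistic",
    "z_from_pvalue",
]

#: Canonical column name -> accepted synonyms (case-insensitive) in input files.
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "id", "markername"),
    "chromosome": ("chromosome", "chr", "chrom", "#chrom"),
    "position": ("position", "pos", "bp", "base_pair_location"),
    "effect_allele": ("effect_allele", "a1", "ea", "alt", "allele1"),
    "other_allele": ("other_allele", "a2", "oa", "nea", "ref", "allele0", "allele2"),
    "eaf": ("eaf", "af", "effect_allele_frequency", "freq", "maf_ea"),
    "beta": ("beta", "b", "effect", "beta_hat"),
    "se": ("se", "standard_error", "sebeta"),
    "pvalue": ("pvalue", "p", "pval", "p_value", "p-value"),
    "n": ("n", "samplesize", "n_total", "sample_size"),
    "z": ("z", "zscore", "z_score", "tstat"),
}

REQUIRED_COLUMNS = (
    "variant_id", "chromosome", "position", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)


class SummaryStatsFormatError(ValueError):
    """A summary-statistics file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Input values violate a stated invariant (e.g. duplicate variant IDs)."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record for one trait."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    z: float | None = None  # optional exact Z, carried when supplied

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty means valid)."""
        problems = []
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not np.isfinite(self.beta):
            problems.append("beta not finite")
        if not (self.se > 0 and np.isfinite(self.se)):
            problems.append("se not positive")
        if not (0.0 < self.eaf < 1.0):
            problems.append("eaf outside (0,1)")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append("pvalue outside (0,1]")
        if not self.n > 0:
            problems.append("n not positive")
        return problems

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class CohortMeta:
    """Cohort descriptors: total size and, for case-control traits, counts."""

    name: str
    n_total: int
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases is not None and self.n_controls is not None:
            if self.n_cases + self.n_controls != self.n_total:
                raise ValidationError(
                    f"cohort {self.name!r}: n_cases + n_controls "
                    f"({self.n_cases} + {self.n_controls}) != n_total ({self.n_total})"
                )

    @property
    def prevalence(self) -> float:
        return compute_prevalence(self)


@dataclass
class GWASTable:
    """A validated collection of :class:`VariantAssociation` for one trait."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    cohort: CohortMeta
    records: dict[str, VariantAssociation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and self.cohort.n_cases is None:
            raise ValidationError(
                f"binary trait {self.trait_id!r} requires cohort case/control counts"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        return self.records[variant_id]

    def add(self, record: VariantAssociation) -> None:
        if record.variant_id in self.records:
            raise ValidationError(f"duplicate variant_id {record.variant_id!r}")
        self.records[record.variant_id] = record

    def variant_ids(self) -> list[str]:
        return list(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id, "chromosome": r.chromosome,
                "position": r.position, "effect_allele": r.effect_allele,
                "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
                "se": r.se, "pvalue": r.pvalue, "n": r.n,
            }
            | ({"z": r.z} if any(x.z is not None for x in self.records.values()) else {})
            for r in self.records.values()
        ]
        cols = list(REQUIRED_COLUMNS)
        if rows and "z" in rows[0]:
            cols.append("z")
        return pd.DataFrame(rows, columns=cols)


def _resolve_columns(
    header: Iterable[str], column_map: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lower = {h.lower(): h for h in header}
    resolved = {}
    for canonical, synonyms in column_map.items():
        for syn in synonyms:
            if syn in lower:
                resolved[canonical] = lower[syn]
                break
    missing = [c for c in REQUIRED_COLUMNS if c not in resolved]
    if missing:
        raise SummaryStatsFormatError(
            f"missing required column(s): {', '.join(missing)}"
        )
    return resolved


def read_summary_stats(
    path: str | Path,
    trait_id: str,
    trait_type: str,
    cohort: CohortMeta,
    column_map: Mapping[str, tuple[str, ...]] | None = None,
) -> GWASTable:
    """Read a tab-separated summary-statistics file into a :class:`GWASTable`.

    Rows violating per-record invariants are dropped with a logged count;
    duplicate variant IDs are a hard error naming the offending ID.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(
        path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip"
    )
    resolved = _resolve_columns(df.columns, cmap)
    table = GWASTable(trait_id=trait_id, trait_type=trait_type, cohort=cohort)
    n_rejected = 0
    for _, row in df.iterrows():
        z_col = resolved.get("z")
        record = VariantAssociation(
            variant_id=str(row[resolved["variant_id"]]),
            chromosome=str(row[resolved["chromosome"]]),
            position=int(row[resolved["position"]]),
            effect_allele=str(row[resolved["effect_allele"]]).upper(),
            other_allele=str(row[resolved["other_allele"]]).upper(),
            eaf=float(row[resolved["eaf"]]),
            beta=float(row[resolved["beta"]]),
            se=float(row[resolved["se"]]),
            pvalue=float(row[resolved["pvalue"]]),
            n=float(row[resolved["n"]]),
            z=float(row[z_col]) if z_col is not None and pd.notna(row[z_col]) else None,
        )
        problems = record.validate()
        if problems:
            n_rejected += 1
            logger.warning(
                "rejecting %s: %s", record.variant_id, "; ".join(problems)
            )
            continue
        table.add(record)
    if n_rejected:
        logger.warning(
            "%s: rejected %d invalid row(s), kept %d", trait_id, n_rejected, len(table)
        )
    return table


def write_summary_stats(table: GWASTable, path: str | Path) -> None:
    """Write a table back to tab-separated text (full float precision)."""
    # pandas' default float formatting is the shortest round-trip repr,
    # so write->read is exact on valid tables
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False)


def compute_prevalence(cohort: CohortMeta) -> float:
    """Case fraction ``n_cases / n_total`` of a case-control cohort."""
    if cohort.n_cases is None:
        raise ValidationError(f"cohort {cohort.name!r} has no case count")
    if not 0 < cohort.n_cases < cohort.n_total:
        raise ValidationError(
            f"cohort {cohort.name!r}: need 0 < n_cases < n_total, "
            f"got {cohort.n_cases}/{cohort.n_total}"
        )
    return cohort.n_cases / cohort.n_total


def z_from_pvalue(pvalue: float, sign: float) -> float:
    """Signed Z recovered from a two-sided p-value.

    Raises on p-values that underflow to 0 in double precision; such
    records must carry an exact Z instead.
    """
    if pvalue <= 0.0 or stats.norm.isf(max(pvalue, 5e-324) / 2.0) == np.inf:
        raise ValidationError(
            "pvalue underflows double precision; supply the Z statistic directly"
        )
    if pvalue > 1.0:
        raise ValidationError(f"pvalue {pvalue} outside (0,1]")
    return float(np.sign(sign) * stats.norm.isf(pvalue / 2.0))


def lmm_to_logistic(
    record: VariantAssociation, cohort: CohortMeta
) -> VariantAssociation:
    """Convert a linear-mixed-model case-control record to the logistic scale.

    Uses ``SE_logit = 1/sqrt(2 p (1-p) * N * pr * (1-pr))`` with HWE genotype
    variance, Z from the two-sided p-value (sign of the linear beta; an
    exact Z on the record takes precedence), and ``beta_logit = Z * SE_logit``.
    The p-value is unchanged, so ``|beta/se|`` reproduces ``|Z|`` exactly.
    """
    pr = compute_prevalence(cohort)
    if not 0.0 < pr < 1.0:
        raise ValidationError(f"prevalence {pr} outside (0,1)")
    p = record.eaf
    if not 0.0 < p < 1.0:
        raise ValidationError(f"eaf {p} outside (0,1)")
    var_g = 2.0 * p * (1.0 - p)
    se_logit = 1.0 / np.sqrt(var_g * cohort.n_total * pr * (1.0 - pr))
    if record.z is not None:
        z = record.z
    else:
        z = z_from_pvalue(record.pvalue, np.sign(record.beta))
    return replace(record, beta=float(z * se_logit), se=float(se_logit), z=float(z))
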
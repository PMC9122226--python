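"""Instrument selection and harmonization for two-sample MR.

The selection protocol mirrors the standard pQTL-instrument workflow:

1. intersect the two exposure GWASs on shared variants;
2. drop variants with minor-allele frequency below a floor (default 0.05);
3. keep variants genome-wide significant (default p < 5e-8) in *both*
   exposure GWASs with a concordant direction of effect after aligning
   effect alleles between the two tables — the cross-GWAS replication
   requirement;
4. greedy LD clumping: rank by p-value (from a caller-chosen table),
   retain the best variant per LD region (default r^2 > 0.001 within a
   10,000 kb window).

Proxy search substitutes a high-LD variant (default r^2 >= 0.8) when an
instrument is absent from an outcome GWAS, using the stored allele-phase
sign to map the proxy allele onto the target's effect allele.
Harmonization aligns an outcome record onto the exposure effect allele,
resolving palindromic (A/T, C/G) variants by allele-frequency concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_stats import GWASTable, ValidationError, VariantAssociation

__all__ = [
    "LDMatrix",
    "ClumpConfig",
    "IVSet",
    "ProxyResult",
    "HarmonizedInstrument",
    "ProxyNotFoundError",
    "HarmonizationError",
    "intersect_and_filter",
    "ld_clump",
    "find_proxy",
    "harmonize",
    "read_ld_long",
    "read_ld_square",
    "write_ld_long",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ProxyNotFoundError(LookupError):
    """No variant in sufficient LD with the target is available."""


class HarmonizationError(ValueError):
    """Exposure and outcome allele sets cannot be reconciled."""


@dataclass
class LDMatrix:
    """Pairwise squared correlations plus allele-phase signs.

    ``phase[i, j] = +1`` when the stored effect alleles of variants *i* and
    *j* are positively correlated haplotypically, ``-1`` when the effect
    allele of one travels with the other allele of the other.
    """

    variant_ids: list[str]
    r2: np.ndarray
    phase: np.ndarray
    positions: dict[str, tuple[str, int]]  # variant_id -> (chromosome, position)

    def __post_init__(self) -> None:
        k = len(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.r2.shape != (k, k) or self.phase.shape != (k, k):
            raise ValidationError("LD matrix shape does not match variant list")
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("r2 matrix not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("r2 diagonal must be 1")
        if not np.allclose(self.phase, self.phase.T) or not np.all(
            np.diag(self.phase) == 1
        ):
            raise ValidationError("phase matrix must be symmetric with +1 diagonal")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} absent from LD matrix") from None

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self.index(a), self.index(b)])

    def phase_between(self, a: str, b: str) -> int:
        return int(self.phase[self.index(a), self.index(b)])


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds for instrument selection and LD clumping."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    maf_min: float = 0.05
    palindrome_maf_max: float = 0.42

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ValidationError("r2_threshold must be in (0,1)")
        if min(self.p_threshold, self.window_kb, self.maf_min) <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass
class IVSet:
    """Clumping result: retained instruments plus a per-variant disposition log.

    ``selection_log[variant_id]`` is ``"kept"`` or
    ``"removed-by-clump(<index variant>)"``; variants dropped upstream carry
    ``"failed-filter(<reason>)"``.
    """

    instruments: list[str]
    selection_log: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ProxyResult:
    """A stand-in variant for an instrument missing from an outcome GWAS."""

    target_id: str
    proxy_id: str
    r2: float
    phase: int  # +1: proxy effect allele tracks target effect allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects expressed on a shared effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float  # exposure effect-allele frequency
    n_exposure: float
    n_outcome: float
    eaf_outcome: float | None = None  # outcome EAF after alignment
    proxy_id: str | None = None

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValidationError("standard errors must be positive")


# ---------------------------------------------------------------------------
# LD matrix file formats: long (id_a, id_b, r2, phase) or square + sidecar.
# ---------------------------------------------------------------------------

def read_ld_long(path: str | Path, positions: dict[str, tuple[str, int]]) -> LDMatrix:
    """Read tab-separated long-format LD: columns id_a, id_b, r2, phase_sign."""
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    ids = sorted(set(df["id_a"]) | set(df["id_b"]))
    k = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    r2 = np.eye(k)
    phase = np.ones((k, k))
    for row in df.itertuples(index=False):
        i, j = idx[row.id_a], idx[row.id_b]
        r2[i, j] = r2[j, i] = row.r2
        phase[i, j] = phase[j, i] = row.phase_sign
    return LDMatrix(ids, r2, phase, positions)


def read_ld_square(
    matrix_path: str | Path,
    ids_path: str | Path,
    positions: dict[str, tuple[str, int]],
    phase_path: str | Path | None = None,
) -> LDMatrix:
    """Read a whitespace-separated square r^2 matrix with a sidecar ID list."""
    r2 = np.loadtxt(matrix_path)
    ids = Path(ids_path).read_text().split()
    phase = np.loadtxt(phase_path) if phase_path else np.ones_like(r2)
    return LDMatrix(ids, np.atleast_2d(r2), np.atleast_2d(phase), positions)


def write_ld_long(ld: LDMatrix, path: str | Path) -> None:
    rows = []
    k = len(ld.variant_ids)
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                (ld.variant_ids[i], ld.variant_ids[j],
                 ld.r2[i, j], int(ld.phase[i, j]))
            )
    pd.DataFrame(rows, columns=["id_a", "id_b", "r2", "phase_sign"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# Selection protocol
# ---------------------------------------------------------------------------

def _align_between_exposures(
    a: VariantAssociation, b: VariantAssociation
) -> VariantAssociation | None:
    """Express record *b* on the effect allele of record *a* (no palindrome
    resolution here: identical or swapped allele labels only)."""
    if (b.effect_allele, b.other_allele) == (a.effect_allele, a.other_allele):
        return b
    if (b.other_allele, b.effect_allele) == (a.effect_allele, a.other_allele):
        return replace(
            b,
            effect_allele=b.other_allele,
            other_allele=b.effect_allele,
            beta=-b.beta,
            eaf=1.0 - b.eaf,
            z=None if b.z is None else -b.z,
        )
    return None


def intersect_and_filter(
    exposure_a: GWASTable,
    exposure_b: GWASTable,
    config: ClumpConfig | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Candidate instruments shared by two exposure GWASs.

    Keeps variants present in both tables with MAF >= ``maf_min`` in both,
    p < ``p_threshold`` in both, and a concordant effect direction after
    aligning the effect alleles of the two tables.  Returns the surviving
    variant IDs (in ``exposure_a`` order) and a disposition log for the rest.
    """
    config = config or ClumpConfig()
    survivors: list[str] = []
    log: dict[str, str] = {}
    for vid, rec_a in exposure_a.records.items():
        if vid not in exposure_b:
            log[vid] = "failed-filter(absent-from-other-exposure)"
            continue
        rec_b = _align_between_exposures(rec_a, exposure_b[vid])
        if rec_b is None:
            log[vid] = "failed-filter(allele-mismatch)"
            continue
        if rec_a.maf < config.maf_min or rec_b.maf < config.maf_min:
            log[vid] = "failed-filter(maf)"
            continue
        if not (rec_a.pvalue < config.p_threshold and rec_b.pvalue < config.p_threshold):
            log[vid] = "failed-filter(pvalue)"
            continue
        if rec_a.beta * rec_b.beta <= 0:
            log[vid] = "failed-filter(direction-discordant)"
            continue
        survivors.append(vid)
        log[vid] = "kept"
    return survivors, log


def ld_clump(
    candidates: dict[str, float],
    ld: LDMatrix,
    config: ClumpConfig | None = None,
    prior_log: dict[str, str] | None = None,
) -> IVSet:
    """Greedy LD clumping of ``{variant_id: pvalue}`` candidates.

    Variants are visited in ascending p-value (ties broken by lexicographic
    variant ID, so the result is independent of input ordering).  Each
    visited variant becomes an index; remaining variants on the same
    chromosome within ``window_kb`` with r^2 > ``r2_threshold`` to it are
    removed and logged against that index.
    """
    config = config or ClumpConfig()
    for vid in candidates:
        if vid not in ld:
            raise KeyError(f"candidate {vid!r} absent from LD matrix")
    order = sorted(candidates, key=lambda v: (candidates[v], v))
    log: dict[str, str] = dict(prior_log or {})
    remaining = list(order)
    instruments: list[str] = []
    while remaining:
        index_variant = remaining.pop(0)
        instruments.append(index_variant)
        log[index_variant] = "kept"
        chrom_i, pos_i = ld.positions[index_variant]
        kept_remaining = []
        for vid in remaining:
            chrom_j, pos_j = ld.positions[vid]
            same_region = (
                chrom_j == chrom_i
                and abs(pos_j - pos_i) <= config.window_kb * 1000.0
            )
            if same_region and ld.r2_between(index_variant, vid) > config.r2_threshold:
                log[vid] = f"removed-by-clump({index_variant})"
            else:
                kept_remaining.append(vid)
        remaining = kept_remaining
    return IVSet(instruments=instruments, selection_log=log)


def find_proxy(
    target: str,
    outcome: GWASTable,
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> ProxyResult:
    """Best available LD proxy for an instrument missing from an outcome GWAS.

    Returns the outcome-table variant with maximal r^2 to ``target``
    provided r^2 >= ``r2_min``; the phase sign says whether the proxy's
    stored effect allele tracks the target's.
    """
    if target in outcome:
        raise ValidationError(f"{target!r} is present in the outcome table; no proxy needed")
    i = ld.index(target)
    best_id, best_r2 = None, -1.0
    for vid in outcome.variant_ids():
        if vid == target or vid not in ld:
            continue
        r2 = float(ld.r2[i, ld.index(vid)])
        if r2 > best_r2 or (r2 == best_r2 and (best_id is None or vid < best_id)):
            best_id, best_r2 = vid, r2
    if best_id is None or best_r2 < r2_min:
        raise ProxyNotFoundError(
            f"no proxy for {target!r} at r2 >= {r2_min} "
            f"(best available r2 = {max(best_r2, 0.0):.4g})"
        )
    return ProxyResult(
        target_id=target,
        proxy_id=best_id,
        r2=best_r2,
        phase=ld.phase_between(target, best_id),
    )


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return a1 in _COMPLEMENT and _COMPLEMENT[a1] == a2


def harmonize(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_maf_max: float = 0.42,
    drop_palindromic: bool = False,
    proxy_id: str | None = None,
) -> HarmonizedInstrument | None:
    """Align an outcome record to the exposure effect allele.

    Matching allele labels are copied; swapped labels flip the outcome beta
    and EAF.  Palindromic variants (A/T or C/G) are orientation-ambiguous:
    they are kept only when both EAFs are informative (MAF below
    ``palindrome_maf_max``), using frequency concordance to decide whether
    the reported outcome allele is the same allele or its strand complement.
    Returns ``None`` when a palindromic variant must be dropped.
    Irreconcilable allele sets raise :class:`HarmonizationError`.
    """
    exp_alleles = (exposure.effect_allele, exposure.other_allele)
    out_alleles = (outcome.effect_allele, outcome.other_allele)

    def build(beta_y: float, eaf_y: float, se_y: float) -> HarmonizedInstrument:
        if exposure.beta == 0:
            raise ValidationError(
                f"{exposure.variant_id!r}: zero exposure effect cannot instrument a ratio"
            )
        return HarmonizedInstrument(
            variant_id=exposure.variant_id,
            effect_allele=exposure.effect_allele,
            other_allele=exposure.other_allele,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=beta_y,
            se_outcome=se_y,
            eaf=exposure.eaf,
            n_exposure=exposure.n,
            n_outcome=outcome.n,
            eaf_outcome=eaf_y,
            proxy_id=proxy_id,
        )

    if _is_palindromic(*exp_alleles):
        if drop_palindromic:
            return None
        if out_alleles not in (exp_alleles, exp_alleles[::-1]):
            raise HarmonizationError(
                f"{exposure.variant_id!r}: alleles {out_alleles} vs {exp_alleles}"
            )
        if (
            min(exposure.eaf, 1 - exposure.eaf) >= palindrome_maf_max
            or min(outcome.eaf, 1 - outcome.eaf) >= palindrome_maf_max
        ):
            return None  # ambiguous palindrome
        # Same-orientation reading: frequency of the exposure effect allele.
        eaf_out_same = (
            outcome.eaf if out_alleles == exp_alleles else 1.0 - outcome.eaf
        )
        beta_out_same = (
            outcome.beta if out_alleles == exp_alleles else -outcome.beta
        )
        concordant = (exposure.eaf < 0.5) == (eaf_out_same < 0.5)
        if concordant:
            return build(beta_out_same, eaf_out_same, outcome.se)
        # Opposite strand: the reported allele is the complement of ours.
        return build(-beta_out_same, 1.0 - eaf_out_same, outcome.se)

    if out_alleles == exp_alleles:
        return build(outcome.beta, outcome.eaf, outcome.se)
    if out_alleles == exp_alleles[::-1]:
        return build(-outcome.beta, 1.0 - outcome.eaf, outcome.se)
    # Strand-flip reading for non-palindromic variants.
    comp = tuple(_COMPLEMENT.get(a, a) for a in out_alleles)
    if comp == exp_alleles:
        return build(outcome.beta, outcome.eaf, outcome.se)
    if comp == exp_alleles[::-1]:
        return build(-outcome.beta, 1.0 - outcome.eaf, outcome.se)
    raise HarmonizationError(
        f"{exposure.variant_id!r}: irreconcilable alleles "
        f"{out_alleles} vs {exp_alleles}"
    )


def _align_record(
    record: VariantAssociation, reference: VariantAssociation
) -> VariantAssociation:
    """Express ``record`` on ``reference``'s allele order (same variant).

    Handles identical, swapped, and (for non-palindromic variants)
    strand-complemented allele labels; raises on irreconcilable sets.
    """
    rec_alleles = (record.effect_allele, record.other_allele)
    ref_alleles = (reference.effect_allele, reference.other_allele)
    candidates = {rec_alleles: False, rec_alleles[::-1]: True}
    if not _is_palindromic(*rec_alleles):
        comp = tuple(_COMPLEMENT.get(a, a) for a in rec_alleles)
        candidates.setdefault(comp, False)
        candidates.setdefault(comp[::-1], True)
    for alleles, flipped in candidates.items():
        if alleles == ref_alleles:
            if not flipped:
                return replace(
                    record,
                    effect_allele=ref_alleles[0],
                    other_allele=ref_alleles[1],
                )
            return replace(
                record,
                effect_allele=ref_alleles[0],
                other_allele=ref_alleles[1],
                beta=-record.beta,
                eaf=1.0 - record.eaf,
                z=None if record.z is None else -record.z,
            )
    raise HarmonizationError(
        f"{record.variant_id!r}: alleles {rec_alleles} vs reference {ref_alleles}"
    )


def apply_proxy(
    proxy: ProxyResult,
    outcome_record: VariantAssociation,
    proxy_reference: VariantAssociation | None = None,
    target_reference: VariantAssociation | None = None,
) -> VariantAssociation:
    """Express a proxy's outcome record as if it were the target variant.

    The phase sign is defined between the variants' effect alleles in the
    LD reference: with +1 the proxy effect allele stands in for the
    target's effect allele directly; with -1 the correlated allele is the
    proxy's *other* allele, so beta flips sign and EAF reflects.  When
    ``proxy_reference``/``target_reference`` records are supplied (e.g.
    from the exposure GWAS the LD panel matches), the outcome record is
    first aligned onto the reference allele order and the result carries
    the target's reference alleles; otherwise the outcome record is
    assumed to already follow the LD reference convention.
    """
    aligned = (
        _align_record(outcome_record, proxy_reference)
        if proxy_reference is not None
        else outcome_record
    )
    if proxy.phase == 1:
        mapped = replace(aligned, variant_id=proxy.target_id)
    else:
        mapped = replace(
            aligned,
            variant_id=proxy.target_id,
            effect_allele=aligned.other_allele,
            other_allele=aligned.effect_allele,
            beta=-aligned.beta,
            eaf=1.0 - aligned.eaf,
            z=None if aligned.z is None else -aligned.z,
        )
    if target_reference is not None:
        mapped = replace(
            mapped,
            effect_allele=target_reference.effect_allele,
            other_allele=target_reference.other_allele,
            chromosome=target_reference.chromosome,
            position=target_reference.position,
        )
    return mapped
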
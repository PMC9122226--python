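"""End-to-end orchestration: select instruments, harmonize, estimate, judge.

The pipeline reproduces a cross-cohort MR replication workflow:

1. intersect two exposure GWASs and filter candidates (MAF, dual
   significance, direction concordance);
2. greedy LD clumping on a chosen exposure's p-values;
3. per outcome cohort: convert linear-mixed-model statistics to the
   logistic scale where flagged, substitute LD proxies for missing
   instruments, and harmonize onto the exposure effect allele;
4. per-cohort IVW estimate (a single-instrument cohort reports its Wald
   ratio under the IVW label, as is conventional);
5. fixed-effects meta-analysis of the non-primary cohorts and of all
   cohorts, with Cochran's Q and pairwise estimate-comparison tests;
6. the four-criterion replication verdict against the primary (largest)
   cohort and the non-primary meta-analysis.

Results are returned in memory and can be written as TSV files plus a
plain-text report (two-decimal betas/SEs, two-significant-figure p-values,
full precision alongside).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import HeterogeneityResult, MREstimate, ivw_fixed
from .iv_selection import (
    ClumpConfig,
    HarmonizedInstrument,
    IVSet,
    LDMatrix,
    ProxyNotFoundError,
    apply_proxy,
    find_proxy,
    harmonize,
    intersect_and_filter,
    ld_clump,
    read_ld_long,
)
from .replication import (
    CohortResult,
    ReplicationVerdict,
    beta_comparison_test,
    evaluate_replication,
    meta_fixed,
)
from .summary_stats import (
    CohortMeta,
    GWASTable,
    ValidationError,
    lmm_to_logistic,
    read_summary_stats,
)

logger = logging.getLogger("pqtlmr")

__all__ = [
    "OutcomeSpec",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "load_config",
    "run_pipeline_from_config",
    "write_report",
]


@dataclass
class OutcomeSpec:
    """One outcome GWAS entering the pipeline."""

    name: str
    table: GWASTable
    convert_from_lmm: bool = False


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the data tables."""

    clump: ClumpConfig = field(default_factory=ClumpConfig)
    clump_pvalue_source: str = "a"  # which exposure supplies clumping p-values
    primary_cohort: str | None = None  # default: largest outcome cohort
    prior_sign: int = 1
    p1_threshold: float = 1.1e-5
    p2_threshold: float = 0.025
    proxy_r2_min: float = 0.8
    methods: tuple[str, ...] = ("ivw",)
    n_boot: int = 1000
    seed: int = 0


@dataclass
class PipelineResult:
    iv_set: IVSet
    harmonized: dict[str, list[HarmonizedInstrument]]
    per_cohort: list[CohortResult]
    meta_secondary: MREstimate
    het_secondary: HeterogeneityResult
    meta_all: MREstimate
    het_all: HeterogeneityResult
    comparisons: dict[tuple[str, str], float]
    verdict: ReplicationVerdict
    notes: list[str]


def _harmonize_cohort(
    instruments: list[str],
    exposure: GWASTable,
    outcome: GWASTable,
    ld: LDMatrix,
    config: PipelineConfig,
    notes: list[str],
) -> list[HarmonizedInstrument]:
    out: list[HarmonizedInstrument] = []
    for vid in instruments:
        exp_rec = exposure[vid]
        proxy_id = None
        if vid in outcome:
            out_rec = outcome[vid]
        else:
            proxy = find_proxy(vid, outcome, ld, r2_min=config.proxy_r2_min)
            out_rec = apply_proxy(
                proxy, outcome[proxy.proxy_id],
                proxy_reference=exposure.records.get(proxy.proxy_id),
                target_reference=exp_rec,
            )
            proxy_id = proxy.proxy_id
            notes.append(
                f"{outcome.trait_id}: {proxy.proxy_id} used as proxy for {vid} "
                f"(r2={proxy.r2:.3g}, phase={proxy.phase:+d})"
            )
        harm = harmonize(
            exp_rec, out_rec,
            palindrome_maf_max=config.clump.palindrome_maf_max,
            proxy_id=proxy_id,
        )
        if harm is None:
            notes.append(
                f"{outcome.trait_id}: {vid} dropped (ambiguous palindrome)"
            )
            continue
        out.append(harm)
    return out


def run_pipeline(
    exposure_a: GWASTable,
    exposure_b: GWASTable,
    outcomes: list[OutcomeSpec],
    ld: LDMatrix,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full replication workflow on in-memory tables.

    ``exposure_b`` is the exposure GWAS whose effect sizes enter the MR
    (conventionally the larger proteome GWAS); ``clump_pvalue_source``
    chooses which exposure ranks variants during clumping.
    """
    config = config or PipelineConfig()
    notes: list[str] = []

    candidates, filter_log = intersect_and_filter(exposure_a, exposure_b, config.clump)
    p_source = exposure_a if config.clump_pvalue_source == "a" else exposure_b
    pvals = {vid: p_source[vid].pvalue for vid in candidates}
    iv_set = ld_clump(pvals, ld, config.clump, prior_log=filter_log)
    if not iv_set.instruments:
        raise ValidationError("no instruments survive selection")
    logger.info("selected %d instrument(s): %s",
                len(iv_set.instruments), ", ".join(iv_set.instruments))

    per_cohort: list[CohortResult] = []
    harmonized: dict[str, list[HarmonizedInstrument]] = {}
    for spec in outcomes:
        table = spec.table
        if spec.convert_from_lmm:
            converted = GWASTable(
                trait_id=table.trait_id, trait_type=table.trait_type,
                cohort=table.cohort,
            )
            for rec in table.records.values():
                converted.add(lmm_to_logistic(rec, table.cohort))
            table = converted
            notes.append(f"{spec.name}: converted from LMM to logistic scale")
        ivs = _harmonize_cohort(
            iv_set.instruments, exposure_b, table, ld, config, notes
        )
        if not ivs:
            raise ValidationError(f"cohort {spec.name}: no usable instruments")
        est = ivw_fixed(ivs)
        if est.n_iv == 1:
            notes.append(
                f"{spec.name}: single instrument; IVW reduces to the Wald ratio"
            )
        per_cohort.append(
            CohortResult(spec.name, est, n_outcome=table.cohort.n_total)
        )
        harmonized[spec.name] = ivs

    primary_name = config.primary_cohort or max(
        per_cohort, key=lambda r: r.n_outcome
    ).cohort
    primary = next(r for r in per_cohort if r.cohort == primary_name)
    secondary = [r for r in per_cohort if r.cohort != primary_name]
    if len(secondary) < 2:
        # with a single secondary cohort the "meta" is that cohort itself
        meta_sec, het_sec = secondary[0].estimate, HeterogeneityResult(0.0, 0, 1.0)
        notes.append("single secondary cohort: meta-analysis is that cohort")
    else:
        meta_sec, het_sec = meta_fixed(secondary)
    meta_all, het_all = meta_fixed(per_cohort)

    comparisons = {
        (a.cohort, b.cohort): beta_comparison_test(
            (a.estimate.beta, a.estimate.se), (b.estimate.beta, b.estimate.se)
        )
        for a, b in itertools.combinations(per_cohort, 2)
    }

    verdict = evaluate_replication(
        primary, meta_sec, config.prior_sign,
        p1_threshold=config.p1_threshold, p2_threshold=config.p2_threshold,
    )
    return PipelineResult(
        iv_set=iv_set,
        harmonized=harmonized,
        per_cohort=per_cohort,
        meta_secondary=meta_sec,
        het_secondary=het_sec,
        meta_all=meta_all,
        het_all=het_all,
        comparisons=comparisons,
        verdict=verdict,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Config-file front end
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON pipeline configuration file."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def _cohort_from_block(block: dict) -> CohortMeta:
    return CohortMeta(
        name=block["name"],
        n_total=int(block["n_total"]),
        n_cases=int(block["n_cases"]) if "n_cases" in block else None,
        n_controls=int(block["n_controls"]) if "n_controls" in block else None,
    )


def run_pipeline_from_config(cfg: dict, out_dir: str | Path | None = None) -> PipelineResult:
    """File-driven pipeline: read tables and LD named in ``cfg``, run, report.

    Expected keys: ``exposure_a``/``exposure_b`` (path, cohort block),
    ``outcomes`` (list of path, cohort block, optional ``lmm: true``),
    ``ld`` (long-format path), optional ``clump``, ``replication`` blocks.
    """
    def read_block(block: dict, trait_type: str) -> GWASTable:
        p = Path(block["path"])
        if not p.exists():
            raise FileNotFoundError(f"summary-statistics file not found: {p}")
        return read_summary_stats(
            p, trait_id=block.get("trait_id", p.stem), trait_type=trait_type,
            cohort=_cohort_from_block(block["cohort"]),
        )

    exposure_a = read_block(cfg["exposure_a"], "quantitative")
    exposure_b = read_block(cfg["exposure_b"], "quantitative")
    outcomes = [
        OutcomeSpec(
            name=block["cohort"]["name"],
            table=read_block(block, "binary"),
            convert_from_lmm=bool(block.get("lmm", False)),
        )
        for block in cfg["outcomes"]
    ]
    ld_path = Path(cfg["ld"])
    if not ld_path.exists():
        raise FileNotFoundError(f"LD matrix file not found: {ld_path}")
    positions = {}
    for table in (exposure_a, exposure_b):
        for rec in table.records.values():
            positions[rec.variant_id] = (rec.chromosome, rec.position)
    for spec in outcomes:
        for rec in spec.table.records.values():
            positions.setdefault(rec.variant_id, (rec.chromosome, rec.position))
    ld = read_ld_long(ld_path, positions)

    clump_cfg = ClumpConfig(**cfg.get("clump", {}))
    rep = cfg.get("replication", {})
    config = PipelineConfig(
        clump=clump_cfg,
        clump_pvalue_source=cfg.get("clump_pvalue_source", "a"),
        primary_cohort=rep.get("primary_cohort"),
        prior_sign=int(rep.get("prior_sign", 1)),
        p1_threshold=float(rep.get("p1", 1.1e-5)),
        p2_threshold=float(rep.get("p2", 0.025)),
        proxy_r2_min=float(cfg.get("proxy_r2_min", 0.8)),
        seed=int(cfg.get("seed", 0)),
    )
    result = run_pipeline(exposure_a, exposure_b, outcomes, ld, config)
    if out_dir is not None:
        write_report(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _sig2(p: float) -> str:
    return f"{p:.2g}"


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write TSV result tables and a rounded plain-text report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per = pd.DataFrame(
        [
            {
                "cohort": r.cohort, "method": r.estimate.method,
                "n_iv": r.estimate.n_iv, "beta": r.estimate.beta,
                "se": r.estimate.se, "pvalue": r.estimate.pvalue,
                "n_outcome": r.n_outcome,
            }
            for r in result.per_cohort
        ]
    )
    per.to_csv(out / "per_cohort.tsv", sep="\t", index=False, float_format="%.10g")

    meta = pd.DataFrame(
        [
            {"analysis": "meta_secondary", "beta": result.meta_secondary.beta,
             "se": result.meta_secondary.se, "pvalue": result.meta_secondary.pvalue,
             "Q": result.het_secondary.Q, "Q_df": result.het_secondary.df,
             "Q_pvalue": result.het_secondary.pvalue},
            {"analysis": "meta_all", "beta": result.meta_all.beta,
             "se": result.meta_all.se, "pvalue": result.meta_all.pvalue,
             "Q": result.het_all.Q, "Q_df": result.het_all.df,
             "Q_pvalue": result.het_all.pvalue},
        ]
    )
    meta.to_csv(out / "meta.tsv", sep="\t", index=False, float_format="%.10g")

    comp = pd.DataFrame(
        [{"cohort_a": a, "cohort_b": b, "pvalue": p}
         for (a, b), p in result.comparisons.items()]
    )
    comp.to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format="%.10g")

    sel = pd.DataFrame(
        sorted(result.iv_set.selection_log.items()),
        columns=["variant_id", "disposition"],
    )
    sel.to_csv(out / "selection_log.tsv", sep="\t", index=False)

    v = result.verdict
    (out / "verdict.json").write_text(
        json.dumps(
            {
                "criterion_1a": v.criterion_1a, "criterion_1b": v.criterion_1b,
                "criterion_2a": v.criterion_2a, "criterion_2b": v.criterion_2b,
                "overall": v.overall, "observed": v.observed,
                "thresholds": v.thresholds,
            },
            indent=2, sort_keys=True,
        )
        + "\n"
    )

    lines = ["MR replication report", "=" * 21, ""]
    lines.append("Per-cohort IVW estimates (beta (SE), p):")
    for r in result.per_cohort:
        e = r.estimate
        lines.append(
            f"  {r.cohort:<12s} n_iv={e.n_iv}  "
            f"{e.beta:.2f} ({e.se:.2f})  p={_sig2(e.pvalue)}"
        )
    lines.append("")
    for label, m, h in (
        ("Meta-analysis (secondary cohorts)", result.meta_secondary, result.het_secondary),
        ("Meta-analysis (all cohorts)", result.meta_all, result.het_all),
    ):
        lines.append(
            f"{label}: {m.beta:.2f} ({m.se:.2f})  p={_sig2(m.pvalue)}  "
            f"Q p={_sig2(h.pvalue)}"
        )
    lines.append("")
    lines.append("Pairwise estimate comparisons (z-test p):")
    for (a, b), p in result.comparisons.items():
        lines.append(f"  {a} vs {b}: {_sig2(p)}")
    lines.append("")
    lines.append("Replication verdict:")
    for crit in ("1a", "1b", "2a", "2b"):
        ok = getattr(v, f"criterion_{crit}")
        lines.append(f"  {crit}: {'PASS' if ok else 'FAIL'}")
    lines.append(f"  overall: {'PASS' if v.overall else 'FAIL'}")
    lines.append("")
    if result.notes:
        lines.append("Notes:")
        lines.extend(f"  - {n}" for n in result.notes)
        lines.append("")
    lines.append(
        "Betas/SEs rounded to two decimals and p-values to two significant "
        "figures; full precision in the TSV files."
    )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
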
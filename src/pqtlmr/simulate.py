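"""Seeded synthetic GWAS summary statistics with pQTL-style architecture.

The generator emulates the statistical structure the MR pipeline assumes,
at the summary level: a protein exposure measured in two modest cohorts
(defaults 1,000 and 3,301 — a typical pair of plasma-proteome GWASs), with
one strong pQTL explaining a large share of the protein's variance (default
40%) plus weaker loci; and binary outcome GWASs in large case-control
cohorts with low prevalence, optionally emitted on the linear-mixed-model
scale to exercise the logistic-scale conversion.

Effect sizes are drawn from per-locus variance-explained targets:
``gamma = sqrt(h2 / (2 p (1-p)))`` in SD units per allele.  Estimated
effects are the truth plus Gaussian noise at the analytic standard error —
``1/sqrt(2p(1-p) N)`` for a rank-normalised quantitative trait and
``1/sqrt(2p(1-p) N pr (1-pr))`` on the logistic scale for a binary trait of
prevalence ``pr``.  LD is block-diagonal: within a block every pair has the
configured correlation, tag variants inherit attenuated marginal effects
(``r`` times the causal effect, with the stored-allele phase sign), and
noise is independent across variants (a deliberate simplification noted in
the package documentation).

A small individual-level generator is included for validating the
linear-to-logistic conversion against a genotype-level simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .iv_selection import LDMatrix
from .summary_stats import CohortMeta, GWASTable, ValidationError, VariantAssociation

__all__ = [
    "OutcomeCohortConfig",
    "ScenarioConfig",
    "simulate_exposure_pair",
    "simulate_outcome",
    "simulate_ld",
    "simulate_scenario",
    "simulate_individual_level_linear",
]

# Non-palindromic allele pairs cycled over variants; palindromic pairs are
# injected only on request.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


@dataclass(frozen=True)
class OutcomeCohortConfig:
    """One binary-outcome cohort: size, case count, reporting scale."""

    name: str
    n_total: int
    n_cases: int
    scale: str = "logistic"  # "logistic" | "lmm"

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n_total

    def meta(self) -> CohortMeta:
        return CohortMeta(
            name=self.name,
            n_total=self.n_total,
            n_cases=self.n_cases,
            n_controls=self.n_total - self.n_cases,
        )


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic replication scenario.

    Defaults mirror the replication design this package was built around:
    two exposure GWASs of 1,000 and 3,301 samples; a strong pQTL at 40%
    variance explained plus one weaker locus at 5%; three outcome cohorts
    sized 452,264 / 128,698 / 48,429 with prevalences 2.7% / 8.6% / 12%,
    the largest reported on the linear-mixed-model scale; and a true causal
    log-OR of 0.07 per SD of the exposure.
    """

    n_snps: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    architecture: tuple[float, ...] = (0.40, 0.05)
    true_beta: float = 0.07
    pleiotropy: str = "none"  # "none" | "directional" | "balanced"
    pleiotropy_mean: float = 0.05
    pleiotropy_sd: float = 0.02
    n_exposure_a: int = 1000
    n_exposure_b: int = 3301
    outcome_cohorts: tuple[OutcomeCohortConfig, ...] = (
        OutcomeCohortConfig("ukbb", 452_264, 12_021, scale="lmm"),
        OutcomeCohortConfig("finngen", 128_698, 11_006),
        OutcomeCohortConfig("emerge", 48_429, 5_800),
    )
    ld_block_size: int = 4
    ld_block_r: float = 0.6
    allele_flip_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.architecture) >= 1.0:
            raise ValidationError("per-locus variance explained must sum below 1")
        for c in self.outcome_cohorts:
            if not 0.0 < c.prevalence < 1.0:
                raise ValidationError(f"cohort {c.name}: prevalence outside (0,1)")
        if len(self.architecture) * self.ld_block_size > self.n_snps:
            raise ValidationError("not enough SNPs for the causal blocks")


@dataclass
class _Truth:
    """Internal ground truth shared between exposure and outcome tables."""

    variant_ids: list[str]
    chromosomes: list[str]
    positions: list[int]
    effect_alleles: list[str]
    other_alleles: list[str]
    maf: np.ndarray
    gamma: np.ndarray  # marginal exposure effects (SD units per allele)
    alpha: np.ndarray  # marginal direct (pleiotropic) outcome effects
    blocks: list[list[int]]
    orientation: np.ndarray  # per-variant stored-allele sign, phase_ij = s_i s_j
    r_within: float


def _layout(config: ScenarioConfig, rng: np.random.Generator) -> _Truth:
    n = config.n_snps
    maf = rng.uniform(*config.maf_range, size=n)
    block_size = config.ld_block_size
    blocks = [list(range(i, min(i + block_size, n))) for i in range(0, n, block_size)]
    # One causal variant at the head of each of the first len(architecture)
    # blocks; remaining blocks are null.
    causal = np.zeros(n)
    for h2, block in zip(config.architecture, blocks):
        causal[block[0]] = h2
    orientation = rng.choice([-1.0, 1.0], size=n)
    orientation[0::block_size] = 1.0  # causal/lead variants on reference phase
    gamma = np.zeros(n)
    alpha = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=len(blocks))
    for b_idx, block in enumerate(blocks):
        lead = block[0]
        h2 = causal[lead]
        if h2 == 0:
            continue
        g_lead = sign[b_idx] * np.sqrt(h2 / (2 * maf[lead] * (1 - maf[lead])))
        if config.pleiotropy == "directional":
            a_lead = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd)
        elif config.pleiotropy == "balanced":
            a_lead = rng.normal(0.0, config.pleiotropy_sd)
        else:
            a_lead = 0.0
        for j in block:
            r = 1.0 if j == lead else config.ld_block_r
            phase = orientation[lead] * orientation[j]
            gamma[j] = phase * r * g_lead
            alpha[j] = phase * r * a_lead
    chroms, positions, ea, oa = [], [], [], []
    for b_idx, block in enumerate(blocks):
        chrom = str(b_idx % 2 + 1)
        base = 1_000_000 + (b_idx // 2) * 50_000_000  # blocks far apart
        for k, j in enumerate(block):
            chroms.append(chrom)
            positions.append(base + k * 50_000)  # members within the clump window
            pair = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
            ea.append(pair[0])
            oa.append(pair[1])
    ids = [f"rs{100000 + i}" for i in range(n)]
    return _Truth(
        ids, chroms, positions, ea, oa, maf, gamma, alpha,
        blocks, orientation, config.ld_block_r,
    )


def _emit_table(
    truth: _Truth,
    true_effects: np.ndarray,
    se: np.ndarray,
    trait_id: str,
    trait_type: str,
    cohort: CohortMeta,
    rng: np.random.Generator,
    flip_prob: float,
    lmm_scale_factor: float | None = None,
) -> GWASTable:
    n = len(truth.variant_ids)
    beta_hat = true_effects + rng.normal(0.0, se)
    flips = rng.random(n) < flip_prob
    z_all = beta_hat / se
    p_all = np.clip(2.0 * stats.norm.sf(np.abs(z_all)), 5e-324, 1.0)
    table = GWASTable(trait_id=trait_id, trait_type=trait_type, cohort=cohort)
    for i in range(n):
        beta, s, eaf = beta_hat[i], se[i], truth.maf[i]
        ea, oa = truth.effect_alleles[i], truth.other_alleles[i]
        z, p = z_all[i], float(p_all[i])
        if flips[i]:
            beta, eaf, ea, oa, z = -beta, 1.0 - eaf, oa, ea, -z
        if lmm_scale_factor is not None:
            beta, s = beta * lmm_scale_factor, s * lmm_scale_factor
        table.add(
            VariantAssociation(
                variant_id=truth.variant_ids[i],
                chromosome=truth.chromosomes[i],
                position=truth.positions[i],
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf),
                beta=float(beta),
                se=float(s),
                pvalue=p,
                n=float(cohort.n_total),
                z=float(z),
            )
        )
    return table


def _truth_for(config: ScenarioConfig, seed: int | None = None) -> _Truth:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _layout(config, rng)


def simulate_exposure_pair(
    config: ScenarioConfig,
) -> tuple[GWASTable, GWASTable, _Truth]:
    """Two exposure GWAS tables sharing the same per-SNP true effects."""
    rng = np.random.default_rng(config.seed)
    truth = _layout(config, rng)
    var_g = 2 * truth.maf * (1 - truth.maf)
    tables = []
    for label, n_cohort, flip in (
        ("exposure_a", config.n_exposure_a, 0.0),
        ("exposure_b", config.n_exposure_b, config.allele_flip_prob),
    ):
        se = 1.0 / np.sqrt(var_g * n_cohort)
        cohort = CohortMeta(name=label, n_total=n_cohort)
        tables.append(
            _emit_table(
                truth, truth.gamma, se, label, "quantitative", cohort, rng, flip
            )
        )
    return tables[0], tables[1], truth


def simulate_outcome(
    config: ScenarioConfig,
    truth: _Truth,
    cohort_config: OutcomeCohortConfig,
    rng: np.random.Generator,
    drop_variants: tuple[str, ...] = (),
) -> GWASTable:
    """One binary-outcome GWAS table given the shared exposure ground truth.

    True per-SNP log odds ratios are ``true_beta * gamma + alpha``.  With
    ``scale="lmm"`` the table is emitted on the linear-mixed-model scale
    (beta and SE multiplied by ``pr (1-pr)``, identical Z and p-value), so
    downstream code must convert it back with ``lmm_to_logistic``.
    """
    pr = cohort_config.prevalence
    var_g = 2 * truth.maf * (1 - truth.maf)
    true_logor = config.true_beta * truth.gamma + truth.alpha
    se = 1.0 / np.sqrt(var_g * cohort_config.n_total * pr * (1 - pr))
    factor = pr * (1 - pr) if cohort_config.scale == "lmm" else None
    table = _emit_table(
        truth, true_logor, se, f"outcome_{cohort_config.name}", "binary",
        cohort_config.meta(), rng, config.allele_flip_prob,
        lmm_scale_factor=factor,
    )
    for vid in drop_variants:
        table.records.pop(vid, None)
    return table


def simulate_ld(config: ScenarioConfig, truth: _Truth | None = None) -> LDMatrix:
    """Block-diagonal LD matching the generator's tagging structure."""
    truth = truth if truth is not None else _truth_for(config)
    n = len(truth.variant_ids)
    r2 = np.eye(n)
    phase = np.ones((n, n))
    for block in truth.blocks:
        for a in block:
            for b in block:
                if a != b:
                    r2[a, b] = truth.r_within**2
                phase[a, b] = truth.orientation[a] * truth.orientation[b]
    positions = {
        vid: (truth.chromosomes[i], truth.positions[i])
        for i, vid in enumerate(truth.variant_ids)
    }
    return LDMatrix(list(truth.variant_ids), r2, phase, positions)


def simulate_scenario(
    config: ScenarioConfig,
    drop_variants: dict[str, tuple[str, ...]] | None = None,
) -> dict:
    """Full scenario bundle: two exposures, all outcomes, LD, and the truth.

    ``drop_variants`` maps cohort name -> variant IDs to omit from that
    outcome table (to exercise proxy substitution).
    """
    exposure_a, exposure_b, truth = simulate_exposure_pair(config)
    rng = np.random.default_rng((config.seed, 1))
    outcomes = {}
    for cc in config.outcome_cohorts:
        dropped = (drop_variants or {}).get(cc.name, ())
        outcomes[cc.name] = simulate_outcome(config, truth, cc, rng, dropped)
    return {
        "exposure_a": exposure_a,
        "exposure_b": exposure_b,
        "outcomes": outcomes,
        "ld": simulate_ld(config, truth),
        "truth": truth,
    }


def simulate_individual_level_linear(
    n: int,
    maf: float,
    log_or: float,
    prevalence: float,
    rng: np.random.Generator,
) -> tuple[VariantAssociation, CohortMeta]:
    """Genotype-level case-control draw analysed with a *linear* model.

    Simulates genotypes Binomial(2, maf), case status from a logistic model
    with per-allele log-OR ``log_or`` and intercept set to hit the target
    prevalence, then regresses the 0/1 indicator on genotype by OLS — the
    linear-scale analysis that ``lmm_to_logistic`` is designed to undo.
    """
    g = rng.binomial(2, maf, size=n).astype(float)
    intercept = np.log(prevalence / (1 - prevalence)) - log_or * 2 * maf
    p_case = 1.0 / (1.0 + np.exp(-(intercept + log_or * g)))
    y = (rng.random(n) < p_case).astype(float)
    gc = g - g.mean()
    slope = float(gc @ (y - y.mean()) / (gc @ gc))
    resid = y - y.mean() - slope * gc
    se = float(np.sqrt(resid @ resid / (n - 2) / (gc @ gc)))
    z = slope / se
    pval = float(np.clip(2.0 * stats.norm.sf(abs(z)), 5e-324, 1.0))
    n_cases = int(y.sum())
    cohort = CohortMeta(
        name="individual_level", n_total=n, n_cases=n_cases,
        n_controls=n - n_cases,
    )
    record = VariantAssociation(
        variant_id="rs_sim", chromosome="1", position=1_000_000,
        effect_allele="A", other_allele="G", eaf=float(g.mean() / 2),
        beta=slope, se=se, pvalue=pval, n=float(n),
    )
    return record, cohort
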
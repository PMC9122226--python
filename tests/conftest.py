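"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pqtlmr import CohortMeta, GWASTable, HarmonizedInstrument, VariantAssociation


def make_record(
    variant_id="rs1",
    chromosome="1",
    position=1_000_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    n=3301,
    z=None,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=variant_id, chromosome=chromosome, position=position,
        effect_allele=effect_allele, other_allele=other_allele, eaf=eaf,
        beta=beta, se=se, pvalue=pvalue, n=n, z=z,
    )


def make_iv(
    variant_id="rs1",
    beta_exposure=0.5,
    se_exposure=0.05,
    beta_outcome=0.035,
    se_outcome=0.010,
    eaf=0.3,
    n_exposure=3301,
    n_outcome=100_000,
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=variant_id, effect_allele="A", other_allele="G",
        beta_exposure=beta_exposure, se_exposure=se_exposure,
        beta_outcome=beta_outcome, se_outcome=se_outcome, eaf=eaf,
        n_exposure=n_exposure, n_outcome=n_outcome,
    )


def make_iv_set(
    rng: np.random.Generator,
    k: int = 10,
    beta: float = 0.2,
    bx_range=(0.1, 0.5),
    sx: float = 0.02,
    sy: float = 0.01,
    alpha: np.ndarray | None = None,
    noisy: bool = True,
) -> list[HarmonizedInstrument]:
    """Random instrument set under the linear causal model
    beta_Y = beta * beta_X (+ alpha direct effects)."""
    bx_true = rng.uniform(*bx_range, k)
    by_true = beta * bx_true + (alpha if alpha is not None else 0.0)
    bx = bx_true + (rng.normal(0, sx, k) if noisy else 0.0)
    by = by_true + (rng.normal(0, sy, k) if noisy else 0.0)
    return [
        make_iv(f"rs{i}", bx[i], sx, by[i], sy)
        for i in range(k)
    ]


def make_table(records, trait_id="exposure", trait_type="quantitative",
               cohort=None) -> GWASTable:
    table = GWASTable(
        trait_id=trait_id, trait_type=trait_type,
        cohort=cohort or CohortMeta(name=trait_id, n_total=3301),
    )
    for rec in records:
        table.add(rec)
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
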
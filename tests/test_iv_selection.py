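"""Instrument selection: filters, LD clumping, proxies, harmonization."""

import numpy as np
import pytest

from pqtlmr import (
    ClumpConfig,
    HarmonizationError,
    LDMatrix,
    ProxyNotFoundError,
    ScenarioConfig,
    ValidationError,
    apply_proxy,
    find_proxy,
    harmonize,
    intersect_and_filter,
    ivw_fixed,
    ld_clump,
    simulate_scenario,
)

from conftest import make_record, make_table


def simple_ld(ids, r2_pairs, positions=None, phase_pairs=None):
    """Build an LDMatrix from {frozenset({a,b}): r2} sparse entries."""
    k = len(ids)
    idx = {v: i for i, v in enumerate(ids)}
    r2 = np.eye(k)
    phase = np.ones((k, k))
    for (a, b), val in r2_pairs.items():
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = val
    for (a, b), val in (phase_pairs or {}).items():
        phase[idx[a], idx[b]] = phase[idx[b], idx[a]] = val
    positions = positions or {v: ("1", 1_000_000 + 10_000 * i) for i, v in enumerate(ids)}
    return LDMatrix(list(ids), r2, phase, positions)


class TestIntersectAndFilter:
    def test_filters_applied_jointly(self):
        """5 shared SNPs: one low-MAF, one sub-threshold in b, one discordant."""
        a_recs = [
            make_record("rs1", eaf=0.3, beta=0.5, pvalue=1e-10),
            make_record("rs2", eaf=0.02, beta=0.5, pvalue=1e-10),   # MAF fail
            make_record("rs3", eaf=0.3, beta=0.5, pvalue=1e-10),    # p fail in b
            make_record("rs4", eaf=0.3, beta=0.5, pvalue=1e-10),    # discordant
            make_record("rs5", eaf=0.3, beta=-0.4, pvalue=1e-9),
        ]
        b_recs = [
            make_record("rs1", eaf=0.31, beta=0.4, pvalue=1e-9, n=1000),
            make_record("rs2", eaf=0.02, beta=0.4, pvalue=1e-9, n=1000),
            make_record("rs3", eaf=0.3, beta=0.4, pvalue=1e-6, n=1000),
            make_record("rs4", eaf=0.3, beta=-0.4, pvalue=1e-9, n=1000),
            make_record("rs5", eaf=0.3, beta=-0.3, pvalue=1e-9, n=1000),
        ]
        kept, log = intersect_and_filter(make_table(a_recs), make_table(b_recs))
        assert kept == ["rs1", "rs5"]
        assert log["rs2"] == "failed-filter(maf)"
        assert log["rs3"] == "failed-filter(pvalue)"
        assert log["rs4"] == "failed-filter(direction-discordant)"

    def test_identical_tables_keep_everything(self):
        recs = [
            make_record(f"rs{i}", position=1000 * i, eaf=0.3, beta=0.5,
                        pvalue=1e-9)
            for i in range(4)
        ]
        kept, _ = intersect_and_filter(make_table(recs), make_table(recs))
        assert kept == [f"rs{i}" for i in range(4)]

    def test_direction_concordance_judged_after_allele_alignment(self):
        """A swapped-allele record with opposite sign is concordant once aligned."""
        a = make_table([make_record("rs1", effect_allele="A", other_allele="G",
                                    eaf=0.3, beta=0.5, pvalue=1e-10)])
        b = make_table([make_record("rs1", effect_allele="G", other_allele="A",
                                    eaf=0.7, beta=-0.5, pvalue=1e-10)])
        kept, _ = intersect_and_filter(a, b)
        assert kept == ["rs1"]

    def test_empty_intersection_warns_not_raises(self):
        a = make_table([make_record("rs1")])
        b = make_table([make_record("rs2")])
        kept, log = intersect_and_filter(a, b)
        assert kept == []
        assert "absent" in log["rs1"]

    def test_replication_scenario_selects_two_instruments(self):
        """The default two-locus pQTL scenario yields exactly two IVs
        (one strong trans-like, one weaker cis-like locus)."""
        bundle = simulate_scenario(ScenarioConfig(seed=11))
        kept, log = intersect_and_filter(bundle["exposure_a"], bundle["exposure_b"])
        pvals = {v: bundle["exposure_a"][v].pvalue for v in kept}
        iv_set = ld_clump(pvals, bundle["ld"], ClumpConfig(), prior_log=log)
        assert len(iv_set.instruments) == 2


def brute_force_clump(candidates, ld, config):
    """Exhaustive oracle: the unique subset S (over all 2^n) such that, in
    (p, id) order, a variant is in S iff no earlier member covers it."""
    import itertools

    order = sorted(candidates, key=lambda v: (candidates[v], v))

    def covers(a, b):
        ca, pa = ld.positions[a]
        cb, pb = ld.positions[b]
        return (
            ca == cb
            and abs(pa - pb) <= config.window_kb * 1000
            and ld.r2_between(a, b) > config.r2_threshold
        )

    solutions = []
    for mask in itertools.product([False, True], repeat=len(order)):
        s = [v for v, m in zip(order, mask) if m]
        ok = True
        for i, v in enumerate(order):
            earlier = [u for u in s if order.index(u) < i]
            should_keep = not any(covers(u, v) for u in earlier)
            if (v in s) != should_keep:
                ok = False
                break
        if ok:
            solutions.append(s)
    assert len(solutions) == 1
    return solutions[0]


class TestLdClump:
    def test_single_clump_keeps_lowest_p(self):
        ids = ["rsA", "rsB", "rsC", "rsD"]
        ld = simple_ld(ids, {(a, b): 0.9 for a in ids for b in ids if a < b})
        iv = ld_clump({"rsA": 1e-8, "rsB": 1e-12, "rsC": 1e-9, "rsD": 1e-10}, ld)
        assert iv.instruments == ["rsB"]
        assert iv.selection_log["rsA"] == "removed-by-clump(rsB)"

    def test_two_blocks_yield_two_instruments(self):
        ids = ["rs1", "rs2", "rs3", "rs4", "rs5"]
        pairs = {("rs1", "rs2"): 0.5, ("rs1", "rs3"): 0.5, ("rs2", "rs3"): 0.5,
                 ("rs4", "rs5"): 0.5}
        positions = {v: ("1", 1_000_000 + 10_000 * i) if i < 3
                     else ("2", 5_000_000 + 10_000 * i)
                     for i, v in enumerate(ids)}
        ld = simple_ld(ids, pairs, positions)
        cands = {"rs1": 1e-10, "rs2": 1e-9, "rs3": 1e-8, "rs4": 1e-11,
                 "rs5": 1e-9}
        config = ClumpConfig()
        iv = ld_clump(cands, ld, config)
        assert sorted(iv.instruments) == ["rs1", "rs4"]
        assert iv.instruments == brute_force_clump(cands, ld, config)

    def test_independent_snps_all_retained(self):
        ids = [f"rs{i}" for i in range(5)]
        ld = simple_ld(ids, {})
        cands = {v: 10 ** -(8 + i) for i, v in enumerate(ids)}
        iv = ld_clump(cands, ld)
        assert sorted(iv.instruments) == sorted(ids)

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        config = ClumpConfig(r2_threshold=0.3, window_kb=100)
        for trial in range(20):
            n = int(rng.integers(3, 8))
            ids = [f"rs{i}" for i in range(n)]
            r2 = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    r2[i, j] = r2[j, i] = rng.uniform(0, 1)
            positions = {
                v: ("1", int(1_000_000 + rng.integers(0, 300) * 1000))
                for v in ids
            }
            ld = LDMatrix(ids, r2, np.ones((n, n)), positions)
            cands = {v: float(rng.uniform(0, 1e-6)) for v in ids}
            assert ld_clump(cands, ld, config).instruments == brute_force_clump(
                cands, ld, config
            )

    def test_order_invariance_via_tie_break(self):
        ids = ["rsB", "rsA", "rsC"]
        ld = simple_ld(ids, {("rsB", "rsA"): 0.9})
        cands = {"rsB": 1e-9, "rsA": 1e-9, "rsC": 1e-9}
        iv1 = ld_clump(cands, ld)
        iv2 = ld_clump(dict(reversed(list(cands.items()))), ld)
        assert iv1.instruments == iv2.instruments == ["rsA", "rsC"]

    def test_removed_variants_correlate_with_their_index(self, rng):
        n = 10
        ids = [f"rs{i}" for i in range(n)]
        r2 = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r2[i, j] = r2[j, i] = rng.uniform(0, 1)
        ld = LDMatrix(ids, r2, np.ones((n, n)),
                      {v: ("1", 1_000_000 + i * 1000) for i, v in enumerate(ids)})
        config = ClumpConfig(r2_threshold=0.4)
        iv = ld_clump({v: float(rng.uniform(0, 1)) for v in ids}, ld, config)
        for vid, disposition in iv.selection_log.items():
            if disposition.startswith("removed-by-clump("):
                index_variant = disposition[len("removed-by-clump("):-1]
                assert ld.r2_between(vid, index_variant) > config.r2_threshold

    def test_candidate_absent_from_ld_is_named(self):
        ld = simple_ld(["rs1"], {})
        with pytest.raises(KeyError, match="rs99"):
            ld_clump({"rs99": 1e-9}, ld)


class TestLdReaders:
    def test_long_and_square_formats_agree(self, tmp_path):
        from pqtlmr import read_ld_long, read_ld_square, write_ld_long

        ids = ["rs1", "rs2", "rs3"]
        ld = simple_ld(ids, {("rs1", "rs2"): 0.8, ("rs2", "rs3"): 0.3},
                       phase_pairs={("rs1", "rs2"): -1})
        write_ld_long(ld, tmp_path / "ld.tsv")
        back = read_ld_long(tmp_path / "ld.tsv", ld.positions)
        np.savetxt(tmp_path / "sq.txt", ld.r2)
        np.savetxt(tmp_path / "ph.txt", ld.phase)
        (tmp_path / "ids.txt").write_text("\n".join(ids))
        square = read_ld_square(tmp_path / "sq.txt", tmp_path / "ids.txt",
                                ld.positions, phase_path=tmp_path / "ph.txt")
        for a, b in [("rs1", "rs2"), ("rs2", "rs3"), ("rs1", "rs3")]:
            assert back.r2_between(a, b) == pytest.approx(ld.r2_between(a, b))
            assert square.r2_between(a, b) == pytest.approx(ld.r2_between(a, b))
            assert back.phase_between(a, b) == ld.phase_between(a, b)
            assert square.phase_between(a, b) == ld.phase_between(a, b)


class TestFindProxy:
    def test_returns_highest_ld_proxy(self):
        ld = simple_ld(["rs505922", "rs576123", "rs_other"],
                       {("rs505922", "rs576123"): 0.97,
                        ("rs505922", "rs_other"): 0.5})
        outcome = make_table(
            [make_record("rs576123", effect_allele="C", other_allele="T"),
             make_record("rs_other")],
            trait_id="vv", trait_type="binary",
            cohort=__import__("pqtlmr").CohortMeta("f", 128_698, 11_006, 117_692),
        )
        proxy = find_proxy("rs505922", outcome, ld)
        assert proxy.proxy_id == "rs576123"
        assert proxy.r2 == pytest.approx(0.97)
        assert proxy.phase == 1
        mapped = apply_proxy(proxy, outcome["rs576123"])
        assert mapped.variant_id == "rs505922"
        assert mapped.effect_allele == "C"  # direct allele mapping at phase +1
        assert mapped.beta == outcome["rs576123"].beta

    def test_insufficient_ld_reports_best_available(self):
        ld = simple_ld(["rsT", "rsP"], {("rsT", "rsP"): 0.5})
        outcome = make_table([make_record("rsP")])
        with pytest.raises(ProxyNotFoundError, match="0.5"):
            find_proxy("rsT", outcome, ld, r2_min=0.8)

    def test_negative_phase_flips_downstream_sign(self, rng):
        """Regression oracle: with anti-phased alleles the proxy's marginal
        effect has the opposite sign; apply_proxy restores the target's."""
        n = 20_000
        g_t = rng.binomial(2, 0.3, n).astype(float)
        # proxy in near-perfect LD, anti-phased: its effect allele tracks the
        # target's OTHER allele (a few recombinant mismatches)
        g_p = 2.0 - g_t
        recomb = rng.random(n) < 0.01
        g_p[recomb] = rng.binomial(2, 0.7, recomb.sum())
        y = 0.5 * g_t + rng.normal(0, 1, n)
        slope = lambda g: float(np.cov(g, y)[0, 1] / np.var(g))
        assert slope(g_t) > 0 and slope(g_p) < 0  # raw proxy beta is flipped
        proxy_beta = slope(g_p)
        outcome_rec = make_record("rsP", effect_allele="A", other_allele="G",
                                  eaf=float(g_p.mean() / 2), beta=proxy_beta,
                                  se=0.01, pvalue=1e-6)
        ld = simple_ld(["rsT", "rsP"], {("rsT", "rsP"): 0.95},
                       phase_pairs={("rsT", "rsP"): -1})
        outcome = make_table([outcome_rec])
        proxy = find_proxy("rsT", outcome, ld)
        mapped = apply_proxy(proxy, outcome_rec)
        assert mapped.beta == -proxy_beta  # sign restored
        assert mapped.beta == pytest.approx(slope(g_t), abs=0.05)
        assert mapped.effect_allele == "G"

    def test_present_target_needs_no_proxy(self):
        ld = simple_ld(["rs1"], {})
        outcome = make_table([make_record("rs1")])
        with pytest.raises(ValidationError):
            find_proxy("rs1", outcome, ld)


class TestHarmonize:
    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp = make_record("rs1", effect_allele="A", other_allele="G",
                          eaf=0.30, beta=0.10)
        out = make_record("rs1", effect_allele="G", other_allele="A",
                          eaf=0.70, beta=-0.05)
        h = harmonize(exp, out)
        assert h.beta_outcome == pytest.approx(0.05)
        assert h.eaf_outcome == pytest.approx(0.30)
        assert h.effect_allele == "A"

    def test_palindrome_kept_when_frequencies_concordant(self):
        exp = make_record("rs1", effect_allele="A", other_allele="T",
                          eaf=0.30, beta=0.10)
        out = make_record("rs1", effect_allele="A", other_allele="T",
                          eaf=0.31, beta=0.05)
        h = harmonize(exp, out)
        assert h is not None
        assert h.beta_outcome == pytest.approx(0.05)

    def test_palindrome_near_half_frequency_dropped(self):
        exp = make_record("rs1", effect_allele="C", other_allele="G",
                          eaf=0.50, beta=0.10)
        out = make_record("rs1", effect_allele="C", other_allele="G",
                          eaf=0.49, beta=0.05)
        assert harmonize(exp, out) is None

    def test_palindrome_discordant_frequency_treated_as_strand_flip(self):
        exp = make_record("rs1", effect_allele="A", other_allele="T",
                          eaf=0.30, beta=0.10)
        out = make_record("rs1", effect_allele="A", other_allele="T",
                          eaf=0.70, beta=0.05)
        h = harmonize(exp, out)
        assert h.beta_outcome == pytest.approx(-0.05)
        assert h.eaf_outcome == pytest.approx(0.30)

    def test_irreconcilable_alleles_raise(self):
        exp = make_record("rs1", effect_allele="A", other_allele="G")
        out = make_record("rs1", effect_allele="A", other_allele="C")
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_aligned_pair_is_identity(self):
        exp = make_record("rs1", effect_allele="A", other_allele="G",
                          eaf=0.3, beta=0.10, se=0.02)
        out = make_record("rs1", effect_allele="A", other_allele="G",
                          eaf=0.32, beta=0.04, se=0.01)
        h = harmonize(exp, out)
        assert (h.beta_outcome, h.se_outcome, h.eaf_outcome) == (0.04, 0.01, 0.32)
        assert (h.beta_exposure, h.se_exposure) == (0.10, 0.02)

    def test_mr_invariant_to_stored_allele_flip(self):
        """Flipping the stored effect allele of an outcome record (beta and
        EAF jointly) must leave the IVW estimate unchanged."""
        exp = [
            make_record(f"rs{i}", effect_allele="A", other_allele="G",
                        eaf=0.3, beta=0.4 + 0.1 * i, se=0.02)
            for i in range(3)
        ]
        out = [
            make_record(f"rs{i}", effect_allele="A", other_allele="G",
                        eaf=0.3, beta=0.03 + 0.01 * i, se=0.01)
            for i in range(3)
        ]
        ivs = [harmonize(e, o) for e, o in zip(exp, out)]
        flipped = [
            make_record(r.variant_id, effect_allele="G", other_allele="A",
                        eaf=1 - r.eaf, beta=-r.beta, se=r.se)
            for r in out
        ]
        ivs_flipped = [harmonize(e, o) for e, o in zip(exp, flipped)]
        assert ivw_fixed(ivs).beta == pytest.approx(
            ivw_fixed(ivs_flipped).beta, abs=1e-12
        )
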
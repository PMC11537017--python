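"""Instrument selection: p-screen, LD clumping, F-statistics, Steiger filter."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from mrmediate import (
    InputError,
    LDMatrix,
    SimulationConfig,
    SummaryStats,
    f_statistic,
    filter_weak_instruments,
    harmonize,
    ld_clump,
    resolve_proxies,
    select_by_pvalue,
    simulate_triplet,
    steiger_filter,
    variance_explained,
)
from mrmediate.gwas_io import VariantRecord


def _stats(rows, label="t"):
    """rows: (vid, chrom, pos, pvalue) with fixed alleles/effects."""
    recs = [
        VariantRecord(vid, chrom, pos, "A", "G", 0.3, 0.1, 0.02, p, 5000)
        for vid, chrom, pos, p in rows
    ]
    return SummaryStats.from_records(label, "quantitative", recs)


class TestPvalueSelection:
    def test_direct_filter(self):
        s = _stats([("rs1", "1", 1, 1e-6), ("rs2", "1", 2, 1e-4)])
        assert select_by_pvalue(s, 1e-5).df["variant_id"].tolist() == ["rs1"]

    def test_threshold_one_keeps_everything(self):
        s = _stats([("rs1", "1", 1, 1e-6), ("rs2", "1", 2, 0.99)])
        assert len(select_by_pvalue(s, 1.0)) == 2

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        pvals = rng.uniform(size=1000)
        s = _stats([(f"rs{i}", "1", i + 1, p) for i, p in enumerate(pvals)])
        kept = select_by_pvalue(s, 0.05)
        expected = [f"rs{i}" for i, p in enumerate(pvals) if p < 0.05]
        assert kept.df["variant_id"].tolist() == expected


def brute_force_clump(records, ld, window_kb, r2_threshold):
    """Independent greedy clumper over VariantRecord lists."""
    pool = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
    kept = []
    while pool:
        idx = pool.pop(0)
        kept.append(idx.variant_id)
        pool = [
            c
            for c in pool
            if not (
                c.chromosome == idx.chromosome
                and abs(c.position - idx.position) <= window_kb * 1000
                and ld.pair_r2(c.variant_id, idx.variant_id) > r2_threshold
            )
        ]
    return kept


class TestLDClump:
    def test_single_block_keeps_best_pvalue(self):
        s = _stats([("rs1", "1", 100, 1e-8), ("rs2", "1", 200, 1e-7), ("rs3", "1", 300, 1e-6)])
        r2 = np.full((3, 3), 0.9)
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(["rs1", "rs2", "rs3"], r2)
        out = ld_clump(s, ld, window_kb=1, r2_threshold=0.001)
        assert out.df["variant_id"].tolist() == ["rs1"]

    def test_outside_window_both_kept(self):
        s = _stats([("rs1", "1", 1, 1e-8), ("rs2", "1", 20_000_001 + 1, 1e-7)])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        out = ld_clump(s, ld, window_kb=10_000, r2_threshold=0.001)
        assert len(out) == 2

    def test_malformed_ld_matrix_rejected(self):
        s = _stats([("rs1", "1", 1, 1e-8), ("rs2", "1", 2, 1e-7)])
        with pytest.raises(InputError):
            ld_clump(s, LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.1, 1.0]])))
        with pytest.raises(InputError):
            ld_clump(s, LDMatrix(["rs1", "rs2"], np.array([[0.9, 0.1], [0.1, 1.0]])))

    def test_matches_brute_force_on_ld_blocks(self):
        cfg = SimulationConfig(
            n_snps=50, n_snps_mediator=0, n_snps_outcome=0,
            ld_blocks=5, ld_r2=0.5, seed=21,
        )
        exp, _, _, _, ld = simulate_triplet(cfg)
        out = ld_clump(exp, ld, window_kb=10_000, r2_threshold=0.001)
        expected = brute_force_clump(exp.records(), ld, 10_000, 0.001)
        assert out.df["variant_id"].tolist() == sorted(
            expected, key=exp.df["variant_id"].tolist().index
        )

    def test_selected_set_is_independent_at_threshold(self):
        cfg = SimulationConfig(
            n_snps=60, n_snps_mediator=0, n_snps_outcome=0,
            ld_blocks=6, ld_r2=0.3, seed=5,
        )
        exp, _, _, _, ld = simulate_triplet(cfg)
        out = ld_clump(exp, ld, window_kb=10_000, r2_threshold=0.001)
        kept = out.records()
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a.chromosome == b.chromosome and abs(a.position - b.position) <= 1e7:
                    assert ld.pair_r2(a.variant_id, b.variant_id) <= 0.001


def _record(beta=0.1, se=0.02, eaf=0.5, n=10_000):
    return VariantRecord("rs1", "1", 1, "A", "G", eaf, beta, se, 1e-6, n)


class TestVarianceExplainedAndF:
    def test_zero_effect_explains_nothing(self):
        assert variance_explained(_record(beta=0.0), "eaf_beta") == 0.0

    def test_eaf_beta_arithmetic(self):
        assert variance_explained(_record(beta=0.1, eaf=0.5), "eaf_beta") == pytest.approx(0.005)

    def test_t_stat_arithmetic(self):
        r2 = variance_explained(_record(beta=0.1, se=0.02, n=10_000), "t_stat")
        assert r2 == pytest.approx(25 / (25 + 9998), rel=1e-12)

    def test_missing_eaf_falls_back_to_t_stat(self):
        rec = _record(beta=0.1, se=0.02, eaf=None, n=10_000)
        assert variance_explained(rec, "eaf_beta") == pytest.approx(25 / (25 + 9998))

    def test_f_statistic_values(self):
        assert f_statistic(0.0, 1000, 1) == 0.0
        assert f_statistic(0.01, 1000, 1) == pytest.approx(0.01 * 998 / 0.99, rel=1e-9)
        assert f_statistic(0.02, 5000, 10) == pytest.approx(0.02 * 4989 / (0.98 * 10), rel=1e-9)

    def test_f_requires_enough_samples(self):
        with pytest.raises(InputError):
            f_statistic(0.01, 11, 10)

    @given(
        r2=st.floats(1e-6, 0.5), n=st.integers(100, 100_000), k=st.integers(1, 20)
    )
    @settings(derandomize=True, max_examples=50)
    def test_f_monotone_in_r2_and_n(self, r2, n, k):
        assert f_statistic(min(r2 * 1.5, 0.9), n, k) > f_statistic(r2, n, k)
        assert f_statistic(r2, 2 * n, k) > f_statistic(r2, n, k)


class TestWeakInstrumentFilter:
    def _stats_with_f(self, f_targets, n=10_000):
        # per-SNP F = t^2-ish; choose beta/se so t^2/(t^2+n-2)*(n-2)/(1-R2) = F
        recs = []
        for i, f in enumerate(f_targets):
            t2 = f  # R2 = t2/(t2+n-2) => F = R2(n-2)/(1-R2) = t2 exactly
            beta = np.sqrt(t2) * 0.01
            recs.append(
                VariantRecord(f"rs{i}", "1", i + 1, "A", "G", np.nan, beta, 0.01, 1e-6, n)
            )
        return SummaryStats.from_records("t", "quantitative", recs)

    def test_threshold_rule_excludes_f_below_10(self):
        iv = filter_weak_instruments(self._stats_with_f([9.9, 10.1]), min_f=10)
        assert iv.selected == ["rs1"]
        assert iv.audit == [("rs0", "weak_instrument")]

    def test_min_f_zero_keeps_all(self):
        iv = filter_weak_instruments(self._stats_with_f([1.0, 2.0, 50.0]), min_f=0)
        assert len(iv.selected) == 3

    def test_matches_independent_per_snp_arithmetic(self):
        rng = np.random.default_rng(3)
        f_targets = rng.uniform(1, 30, size=20)
        stats = self._stats_with_f(f_targets)
        iv = filter_weak_instruments(stats, min_f=10)
        expected = [f"rs{i}" for i, f in enumerate(f_targets) if f >= 10]
        assert iv.selected == expected

    def test_all_weak_is_empty_not_error(self):
        iv = filter_weak_instruments(self._stats_with_f([1.0, 2.0]), min_f=10)
        assert iv.selected == [] and iv.f_stat == 0.0


class TestSteiger:
    def _harmonized(self, r2_exp_strong=True):
        from conftest import make_harmonized

        if r2_exp_strong:
            return make_harmonized([0.2], [0.01], [0.02], [0.01])
        return make_harmonized([0.02], [0.01], [0.2], [0.01])

    def test_stronger_exposure_retained(self):
        h = self._harmonized(True)
        assert len(steiger_filter(h)) == 1

    def test_stronger_outcome_dropped(self):
        h = self._harmonized(False)
        out = steiger_filter(h)
        assert len(out) == 0
        assert out.dropped[-1][1] == "steiger_fail"

    def test_equal_r2_dropped_strict_inequality(self):
        from conftest import make_harmonized

        h = make_harmonized([0.1], [0.01], [0.1], [0.01])
        assert len(steiger_filter(h)) == 0

    def test_idempotent(self, triplet):
        exp, _, out, _, _ = triplet
        h = harmonize(exp, out)
        once = steiger_filter(h)
        twice = steiger_filter(once)
        assert once.df["variant_id"].tolist() == twice.df["variant_id"].tolist()

    def test_true_causal_direction_retains_most_instruments(self):
        """With a true exposure->outcome effect and large n, Steiger should
        retain nearly all genuine instruments."""
        retained = total = 0
        for rep in range(200):
            cfg = SimulationConfig(
                n_snps=15, n_snps_mediator=0, n_snps_outcome=0,
                n_exposure=50_000, n_mediator=1_000, n_outcome=50_000,
                seed=1000 + rep,
            )
            exp, _, out, _, _ = simulate_triplet(cfg)
            sel = select_by_pvalue(exp, 1e-5)
            if len(sel) == 0:
                continue
            h = harmonize(sel, out)
            total += len(h)
            retained += len(steiger_filter(h))
        assert total > 0
        assert retained / total >= 0.95


class TestProxies:
    def test_missing_id_replaced_by_proxy(self):
        resolved, used = resolve_proxies(
            ["rs1", "rs2"], ["rs1", "rs9"], {"rs2": "rs9"}
        )
        assert resolved == ["rs1", "rs9"]
        assert used == {"rs2": "rs9"}

    def test_missing_without_proxy_omitted(self):
        resolved, used = resolve_proxies(["rs1", "rs2"], ["rs1"], None)
        assert resolved == ["rs1"] and used == {}
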
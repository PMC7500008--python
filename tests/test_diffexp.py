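import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsig import (
    DERecord,
    SyntheticSpec,
    bh_adjust,
    call_consensus_de,
    cpm,
    estimate_dispersions,
    generate_dataset,
    highlow_fractions,
    log2_fold_change,
    mann_whitney,
    nb_ql_test,
    tc_factors,
)
from mirsig.diffexp import N0_MIR, N1_MIR, NOT_SIG
from mirsig.errors import DomainError, GroupSizeError

from _oracles import bh_step_up, mw_enum_p, mw_u_naive


class TestMannWhitney:
    def test_complete_separation_small_n(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        x = [3.0, 1.0, 2.0]
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == 1.0

    def test_label_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=7)
        u_xy, p_xy = mann_whitney(x, y)
        u_yx, p_yx = mann_whitney(y, x)
        assert u_yx == pytest.approx(len(x) * len(y) - u_xy)
        assert p_yx == pytest.approx(p_xy)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7, 2)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        _, p = mann_whitney(x, y, mode="exact")
        assert p == pytest.approx(mw_enum_p(list(x), list(y)), abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0, 4.0]
        u, p = mann_whitney(x, y, mode="exact")
        assert u == pytest.approx(mw_u_naive(x, y))
        assert p == pytest.approx(mw_enum_p(x, y), abs=1e-12)

    def test_exact_vs_normal_at_boundary_size(self):
        # n = 12 per group: the normal approximation should track the exact law
        rng = np.random.default_rng(1)
        for _ in range(5):
            x, y = rng.normal(size=12), rng.normal(0.5, 1, size=12)
            _, p_exact = mann_whitney(x, y, mode="exact")
            _, p_normal = mann_whitney(x, y, mode="normal")
            assert abs(p_exact - p_normal) < 0.02

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=5)
            u, p = mann_whitney(x, y, mode="exact")
            ref = scipy.stats.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_group_size_guard(self):
        with pytest.raises(GroupSizeError):
            mann_whitney([1.0], [2.0, 3.0])

    def test_auto_switches_to_normal_on_ties(self):
        x = [1.0, 1.0, 2.0]
        y = [1.0, 3.0, 4.0]
        _, p_auto = mann_whitney(x, y, mode="auto")
        _, p_norm = mann_whitney(x, y, mode="normal")
        assert p_auto == p_norm


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_literal_definition_and_dominates_raw(self, pvals):
        q = bh_adjust(pvals)
        np.testing.assert_allclose(q, bh_step_up(pvals), atol=1e-12)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDispersions:
    def test_poisson_counts_give_near_zero_common(self):
        ds, _ = generate_dataset(
            SyntheticSpec(
                n_mirnas=2000, n_N0=50, n_N1=50, n_up=0, n_down=0,
                effect_beta=0.0, latent_sd=0.0, dispersion=0.0, seed=4,
            )
        )
        eff = ds.counts.values.sum(axis=0).astype(float)
        d = estimate_dispersions(ds.counts.values, eff, ds.node_status)
        assert d.common_dispersion <= 0.05

    def test_nb_dispersion_recovered(self):
        ds, _ = generate_dataset(
            SyntheticSpec(
                n_mirnas=2000, n_N0=50, n_N1=50, n_up=0, n_down=0,
                effect_beta=0.0, latent_sd=0.0, dispersion=0.4, seed=5,
            )
        )
        eff = ds.counts.values.sum(axis=0).astype(float)
        d = estimate_dispersions(ds.counts.values, eff, ds.node_status)
        assert 0.2 <= d.common_dispersion <= 0.6

    def test_full_shrinkage_collapses_to_common(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100, (50, 8))
        eff = y.sum(axis=0).astype(float)
        groups = np.array(["N0"] * 4 + ["N1"] * 4)
        d = estimate_dispersions(y, eff, groups, shrink_df=1e9)
        assert d.shrinkage_weight == 1.0
        np.testing.assert_allclose(d.tagwise_dispersion, d.common_dispersion)


class TestNbQlTest:
    def test_no_signal_gives_p_one(self):
        y = np.full((3, 8), 50)
        eff = np.full(8, 1000.0)
        groups = np.array(["N0"] * 4 + ["N1"] * 4)
        disp = estimate_dispersions(y, eff, groups)
        res = nb_ql_test(y, eff, groups, disp)
        np.testing.assert_allclose(res["F"], 0.0, atol=1e-8)
        np.testing.assert_allclose(res["p_qlf"], 1.0)

    def test_power_on_planted_fourfold_effect(self):
        ds, truth = generate_dataset(
            SyntheticSpec(
                n_mirnas=200, n_N0=10, n_N1=10, n_up=10, n_down=10,
                effect_beta=2.0, latent_sd=0.0, dispersion=0.1, seed=6,
            )
        )
        eff = ds.counts.values.sum(axis=0).astype(float)
        disp = estimate_dispersions(ds.counts.values, eff, ds.node_status)
        res = nb_ql_test(ds.counts.values, eff, ds.node_status, disp)
        planted = [ds.counts.mirna_ids.index(m) for m in (*truth.up_set, *truth.down_set)]
        assert (res["p_qlf"].to_numpy()[planted] < 0.01).mean() >= 0.95

    def test_glm_coef_sign_tracks_fold_change(self, default_dataset):
        ds, _ = default_dataset
        f = tc_factors(ds.counts)
        expr = cpm(ds.counts, f)
        eff = ds.counts.values.sum(axis=0).astype(float)
        disp = estimate_dispersions(ds.counts.values, eff, ds.node_status)
        res = nb_ql_test(ds.counts.values, eff, ds.node_status, disp)
        fc = log2_fold_change(expr, ds.node_status)
        big = np.abs(fc.to_numpy()) > 0.2
        agree = np.sign(res["coef_log2"].to_numpy()[big]) == np.sign(fc.to_numpy()[big])
        assert agree.mean() >= 0.99


class TestFoldChange:
    def test_equal_means_zero(self):
        df = pd.DataFrame([[10.0, 10.0, 10.0, 10.0]], index=["m"], columns=list("abcd"))
        groups = np.array(["N0", "N0", "N1", "N1"])
        assert log2_fold_change(df, groups).iloc[0] == 0.0

    def test_hand_arithmetic(self):
        df = pd.DataFrame([[10.0, 20, 30, 40, 50, 60]], index=["m"], columns=list("abcdef"))
        groups = np.array(["N0"] * 3 + ["N1"] * 3)
        expected = np.log2(50.5 / 20.5)
        assert log2_fold_change(df, groups, pseudocount=0.5).iloc[0] == pytest.approx(expected)


class TestConsensusCall:
    def _rec(self, fdr_mw, fdr_qlf, fc):
        return DERecord("m", fc, 5.0, 0.001, fdr_qlf, 0.001, fdr_mw)

    def test_both_tests_must_pass(self):
        (r,) = call_consensus_de([self._rec(0.04, 0.2, 2.0)])
        assert r.call == NOT_SIG

    def test_inclusive_fold_boundary(self):
        (r,) = call_consensus_de([self._rec(0.01, 0.01, np.log2(1.5))])
        assert r.call == N1_MIR

    def test_down_direction(self):
        (r,) = call_consensus_de([self._rec(0.01, 0.01, -1.0)])
        assert r.call == N0_MIR

    def test_order_invariance(self):
        recs = [self._rec(0.01, 0.01, 1.0), self._rec(0.5, 0.5, 0.0), self._rec(0.01, 0.01, -1.0)]
        calls_fwd = [r.call for r in call_consensus_de(list(recs))]
        calls_rev = [r.call for r in reversed(call_consensus_de(list(reversed(recs))))]
        assert calls_fwd == calls_rev


class TestHighLowFractions:
    def test_constant_row_unflagged(self):
        df = pd.DataFrame([[7.0] * 8], index=["m"], columns=[f"s{i}" for i in range(8)])
        groups = np.array(["N0"] * 4 + ["N1"] * 4)
        res = highlow_fractions(df, groups)
        assert res.loc["m", ["frac_high_N0", "frac_high_N1", "frac_low_N0", "frac_low_N1"]].tolist() == [0, 0, 0, 0]
        assert res.loc["m", "p_fraction_diff"] == 1.0

    def test_single_high_sample_flagged(self):
        # one sample at 2x the mean of the others: exactly that sample is high
        vals = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 3.0]
        df = pd.DataFrame([vals], index=["m"], columns=[f"s{i}" for i in range(8)])
        groups = np.array(["N0"] * 4 + ["N1"] * 4)
        res = highlow_fractions(df, groups)
        assert res.loc["m", "frac_high_N1"] == pytest.approx(0.25)
        assert res.loc["m", "frac_high_N0"] == 0.0

    def test_toy_fisher_table(self):
        # multiples of the mean: 0.4 in cohort N0, 1.6 in cohort N1 -> table [[0,4],[4,0]]
        df = pd.DataFrame([[0.5] * 4 + [2.0] * 4], index=["m"], columns=[f"s{i}" for i in range(8)])
        groups = np.array(["N0"] * 4 + ["N1"] * 4)
        res = highlow_fractions(df, groups, fold=1.5)
        assert res.loc["m", "frac_high_N1"] == 1.0
        assert res.loc["m", "frac_low_N0"] == 1.0
        assert res.loc["m", "p_fraction_diff"] == pytest.approx(2 / 70)

    def test_all_zero_row_skipped(self, caplog):
        import logging

        df = pd.DataFrame(
            [[0.0] * 8, [1, 1, 1, 1, 2, 2, 2, 2]], index=["z", "m"], columns=[f"s{i}" for i in range(8)]
        )
        groups = np.array(["N0"] * 4 + ["N1"] * 4)
        with caplog.at_level(logging.WARNING):
            res = highlow_fractions(df, groups)
        assert np.isnan(res.loc["z", "p_fraction_diff"])
        assert any("all-zero" in r.message for r in caplog.records)


def test_consensus_never_exceeds_single_test_calls():
    """The dual-test intersection can only shrink the QLF-alone call set."""
    ds, _ = generate_dataset(
        SyntheticSpec(n_mirnas=400, n_N0=10, n_N1=10, n_up=0, n_down=0, effect_beta=0.0, seed=8)
    )
    from mirsig import filter_by_cpm, run_differential_expression, tmm_factors

    f = tmm_factors(ds.counts)
    expr = cpm(ds.counts, f)
    ef = expr.subset_mirnas(filter_by_cpm(expr))
    recs = run_differential_expression(ds.counts, ef, f, ds.node_status)
    consensus = {r.mirna_id for r in recs if r.call != NOT_SIG}
    thr = np.log2(1.5)
    qlf_alone = {r.mirna_id for r in recs if r.fdr_qlf < 0.05 and abs(r.log2_fc) >= thr}
    mw_alone = {r.mirna_id for r in recs if r.fdr_mw < 0.05 and abs(r.log2_fc) >= thr}
    assert consensus <= qlf_alone
    assert consensus <= mw_alone
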
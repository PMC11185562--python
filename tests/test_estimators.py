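"""Entrapment FDP estimators: closed forms, paired counting, curves."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrapbench import (
    DiscoveryTable,
    EntrapmentModel,
    EstimatorInput,
    PairedCounts,
    combined_fdp,
    coverage_band,
    direct_fdp,
    fdp_curve,
    inflation_rate,
    k_matched_fdp,
    lower_bound_fdp,
    paired_counts,
    paired_fdp,
    sample_fdp,
)
from entrapbench.estimators import brute_force_paired_counts

from conftest import make_table


class TestClosedForms:
    @pytest.mark.parametrize("nt,ne,r,expected", [
        (96, 4, 1, 0.08),
        (96, 4, 5, 0.048),
        (10, 0, 1, 0.0),
    ])
    def test_combined(self, nt, ne, r, expected):
        assert combined_fdp(EstimatorInput(nt, ne, r)) == pytest.approx(expected)

    @pytest.mark.parametrize("nt,ne,expected", [
        (96, 4, 0.04),
        (0, 5, 1.0),
    ])
    def test_lower_bound(self, nt, ne, expected):
        assert lower_bound_fdp(EstimatorInput(nt, ne)) == pytest.approx(expected)

    @pytest.mark.parametrize("nt,ne,r,expected", [
        (96, 4, 1, 4 / 96),
        (96, 4, 2, 4 / 2 / 96),
        (50, 0, 1, 0.0),
    ])
    def test_sample(self, nt, ne, r, expected):
        assert sample_fdp(EstimatorInput(nt, ne, r)) == pytest.approx(expected)

    def test_sample_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            sample_fdp(EstimatorInput(0, 5, 1))

    def test_zero_discoveries(self):
        inp = EstimatorInput(0, 0, 1)
        assert combined_fdp(inp) == lower_bound_fdp(inp) == 0.0

    def test_invalid_r(self):
        with pytest.raises(ValueError, match="r"):
            EstimatorInput(5, 5, r=0)

    @given(st.integers(0, 10_000), st.integers(0, 10_000),
           st.floats(0.1, 20, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_combined_equals_lower_times_one_plus_inv_r(self, nt, ne, r):
        """Algebraic link before capping, for all counts and ratios."""
        if nt + ne == 0:
            return
        inp = EstimatorInput(nt, ne, r)
        assert combined_fdp(inp, cap=False) == pytest.approx(
            lower_bound_fdp(inp) * (1 + 1 / r))

    def test_r5_relative_excess_is_20_percent(self):
        """With r=5 the combined estimate exceeds the lower bound by 1/r."""
        inp = EstimatorInput(96, 4, r=5)
        lower = lower_bound_fdp(inp)
        excess = (combined_fdp(inp) - lower) / lower
        assert excess == pytest.approx(0.20, abs=1e-12)


class TestPairedCounting:
    def test_pair_target_below_cutoff(self):
        table = make_table([
            ("T1", "original", 9.0, 0.01, ""),
            ("T2", "original", 8.0, 0.01, ""),
            ("T3", "original", 7.5, 0.01, ""),
            ("T4", "original", 6.0, 0.5, ""),
            ("E4", "entrapment", 7.2, 0.01, "T4"),
        ])
        c = paired_counts(table, s=7.0)
        assert (c.n_entrap, c.n_e_ge_s_t_lt, c.n_e_gt_t_ge_s) == (1, 1, 0)
        assert paired_fdp(c, n_target=3) == pytest.approx(0.5)

    def test_pair_target_discovered_but_lower(self):
        table = make_table([
            ("T1", "original", 9.0, 0.01, ""),
            ("T2", "original", 8.0, 0.01, ""),
            ("E2", "entrapment", 8.5, 0.01, "T2"),
        ])
        c = paired_counts(table, s=7.0)
        assert (c.n_entrap, c.n_e_ge_s_t_lt, c.n_e_gt_t_ge_s) == (1, 0, 1)
        assert paired_fdp(c, n_target=2) == 1.0  # (1+0+2)/3, capped

    def test_no_entrapment_above_cutoff(self):
        table = make_table([
            ("T1", "original", 9.0, 0.01, ""),
            ("E1", "entrapment", 3.0, 0.9, "T1"),
        ])
        c = paired_counts(table, s=7.0)
        assert (c.n_entrap, c.n_e_ge_s_t_lt, c.n_e_gt_t_ge_s) == (0, 0, 0)
        assert paired_fdp(c, n_target=10) == 0.0

    def test_missing_paired_target_scores_minus_inf(self):
        table = make_table([
            ("E1", "entrapment", 5.0, 0.01, "T1"),
        ])
        c = paired_counts(table, s=1.0)
        assert c.n_e_ge_s_t_lt == 1

    def test_unresolvable_pair_key_raises(self):
        table = make_table([("E1", "entrapment", 5.0, 0.01, None)])
        with pytest.raises(ValueError, match="unresolvable"):
            paired_counts(table, s=1.0)

    def test_pairs_map_reverse_lookup(self):
        table = make_table([
            ("T1", "original", 2.0, 0.01, None),
            ("E1", "entrapment", 5.0, 0.01, None),
        ])
        c = paired_counts(table, pairs={"T1": ["E1"]}, s=1.0)
        assert c.n_e_gt_t_ge_s == 1

    def test_agrees_with_brute_force_on_random_tables(self,
                                                      random_table_factory):
        rng = np.random.default_rng(123)
        for i in range(100):
            table, pairs = random_table_factory(rng)
            s = float(rng.normal(0.5, 1.5))
            fast = paired_counts(table, pairs, s, seed=i)
            slow = brute_force_paired_counts(table, pairs, s, seed=i)
            assert (fast.n_entrap, fast.n_e_ge_s_t_lt, fast.n_e_gt_t_ge_s) \
                == (slow.n_entrap, slow.n_e_ge_s_t_lt, slow.n_e_gt_t_ge_s)


class TestKMatched:
    def test_k1_reduces_to_paired(self):
        c = PairedCounts(s=1.0, n_entrap=5, n_e_ge_s_t_lt=2,
                         n_e_gt_t_ge_s=1, k=1)
        assert k_matched_fdp(c, 20) == paired_fdp(c, 20)
        assert k_matched_fdp(c, 20) == pytest.approx((5 + 2 + 2) / 25)

    def test_k2_weighting_and_lower_bound_ordering(self):
        c = PairedCounts(s=1.0, n_entrap=6, n_e_ge_s_t_lt=6,
                         n_e_gt_t_ge_s=0, k=2)
        est = k_matched_fdp(c, 10)
        assert est == pytest.approx((6 + 3) / 16)
        assert est >= lower_bound_fdp(EstimatorInput(10, 6, r=2))

    def test_paired_fdp_rejects_k_not_1(self):
        c = PairedCounts(s=1.0, n_entrap=1, n_e_ge_s_t_lt=0,
                         n_e_gt_t_ge_s=0, k=2)
        with pytest.raises(ValueError, match="k_matched_fdp"):
            paired_fdp(c, 5)


class TestCurve:
    def test_single_threshold_matches_direct_calls(self, random_table_factory):
        rng = np.random.default_rng(5)
        table, pairs = random_table_factory(rng, n_pairs=80)
        curve = fdp_curve(table, pairs,
                          methods=("lower", "combined", "sample", "paired"),
                          thresholds=[0.3], r=1.0)
        disc = table.discoveries(0.3)
        nt = int((disc["label"] == "original").sum())
        ne = int((disc["label"] == "entrapment").sum())
        inp = EstimatorInput(nt, ne, 1.0)
        assert curve.estimates["lower"][0] == pytest.approx(lower_bound_fdp(inp))
        assert curve.estimates["combined"][0] == pytest.approx(
            min(combined_fdp(inp), 1.0))
        s = float(disc["score"].min())
        c = paired_counts(table, pairs, s)
        assert curve.estimates["paired"][0] == pytest.approx(
            paired_fdp(c, nt))

    def test_lower_le_paired_everywhere(self, random_table_factory):
        """Numerator dominance at r=1 on arbitrary tables."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            table, pairs = random_table_factory(rng)
            curve = fdp_curve(table, pairs, methods=("lower", "paired"),
                              thresholds=np.linspace(0.01, 1.0, 25))
            assert (curve.estimates["lower"]
                    <= curve.estimates["paired"] + 1e-12).all()

    def test_row_order_and_id_relabeling_invariance(self, random_table_factory):
        rng = np.random.default_rng(9)
        table, pairs = random_table_factory(rng, n_pairs=60)
        thr = np.linspace(0.05, 1.0, 10)
        base = fdp_curve(table, pairs, thresholds=thr)
        shuffled = DiscoveryTable(
            table.df.sample(frac=1, random_state=1, ignore_index=True))
        perm = fdp_curve(shuffled, pairs, thresholds=thr)
        rename = {i: f"x_{i}" for i in table.df["id"]}
        df2 = table.df.assign(
            id=table.df["id"].map(rename),
            pair_key=table.df["pair_key"].map(lambda k: rename.get(k, k)))
        pairs2 = {rename.get(t, t): [rename.get(e, e) for e in es]
                  for t, es in pairs.items()}
        relabeled = fdp_curve(DiscoveryTable(df2), pairs2, thresholds=thr)
        for m in base.estimates:
            np.testing.assert_allclose(perm.estimates[m], base.estimates[m])
            np.testing.assert_allclose(relabeled.estimates[m],
                                       base.estimates[m])

    def test_all_q_above_grid_gives_zero(self):
        table = make_table([("T1", "original", 5.0, 0.9, "")])
        curve = fdp_curve(table, methods=("lower", "combined"),
                          thresholds=[0.01, 0.1])
        assert (curve.estimates["lower"] == 0).all()
        assert (curve.n_target == 0).all()

    def test_discovery_counts_monotone(self, random_table_factory):
        rng = np.random.default_rng(2)
        table, pairs = random_table_factory(rng)
        curve = fdp_curve(table, pairs, thresholds=np.linspace(0.01, 1, 30))
        total = curve.n_target + curve.n_entrap
        assert (np.diff(total) >= 0).all()

    def test_empty_table_and_bad_method(self, random_table_factory):
        rng = np.random.default_rng(3)
        table, pairs = random_table_factory(rng, n_pairs=10)
        with pytest.raises(ValueError, match="empty"):
            fdp_curve(make_table([]), pairs)
        with pytest.raises(ValueError, match="unknown methods"):
            fdp_curve(table, pairs, methods=("bogus",))


class TestDerivedMetrics:
    def test_coverage_band_sqrt_n_reading(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.05, 0.01, 100)
        x = (x - x.mean()) / x.std(ddof=1) * 0.01 + 0.05  # sd exactly 0.01
        band = coverage_band(x)
        assert band.half_width == pytest.approx(1.96 * 0.01 / 10)
        assert coverage_band([0.1, 0.1, 0.1]).half_width == \
            pytest.approx(0.0, abs=1e-12)
        literal = coverage_band(x, literal_n=True)
        assert literal.half_width == pytest.approx(1.96 * 0.01 / 100)
        with pytest.raises(ValueError):
            coverage_band([0.1])

    def test_inflation_rate(self):
        assert inflation_rate(1000, 950).rate == pytest.approx(5.26, abs=0.01)
        assert inflation_rate(500, 500).rate == 0.0
        assert inflation_rate(900, 1000).rate < 0
        with pytest.raises(ValueError):
            inflation_rate(10, 0)

    def test_direct_fdp(self):
        df = pd.DataFrame({
            "id": [f"x{i}" for i in range(100)],
            "label": ["original"] * 100,
            "score": 1.0,
            "q_value": 0.005,
            "is_false": [True] * 2 + [False] * 98,
        })
        assert direct_fdp(DiscoveryTable(df)) == pytest.approx(0.02)
        assert direct_fdp(DiscoveryTable(df.assign(is_false=False))) == 0.0
        assert direct_fdp(DiscoveryTable(df.assign(is_false=True))) == 1.0
        with pytest.raises(ValueError, match="is_false"):
            direct_fdp(DiscoveryTable(df.drop(columns=["is_false"])))


class TestModelInterface:
    def test_fit_summary_and_inflation(self, random_table_factory):
        rng = np.random.default_rng(21)
        table, pairs = random_table_factory(rng, n_pairs=200)
        model = EntrapmentModel(table, pairs, r=1.0)
        res = model.fit(thresholds=np.linspace(0.005, 1.0, 100))
        text = res.summary()
        assert "combined" in text and "paired" in text
        # the lower bound always admits a guided cutoff at a loose level
        infl = res.inflation(fdr_threshold=0.9, method="lower")
        assert infl.n1 >= 0 and infl.n2 >= 0

    def test_paired_requires_pairing(self):
        table = make_table([
            ("T1", "original", 2.0, 0.01, None),
            ("E1", "entrapment", 1.0, 0.02, None),
        ])
        with pytest.raises(ValueError, match="pairing"):
            EntrapmentModel(table).fit(methods=("paired",))

    def test_estimate_at(self, random_table_factory):
        rng = np.random.default_rng(4)
        table, pairs = random_table_factory(rng, n_pairs=100)
        res = EntrapmentModel(table, pairs).fit(
            thresholds=[0.1, 0.5], methods=("lower",))
        assert res.estimate_at("lower", 0.5) == res.curve.estimates["lower"][1]
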
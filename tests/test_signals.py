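"""ROR, information component, p-values, FDR and the joint signal rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import faerspv
from faerspv.cohort import CohortAssignment
from faerspv.records import DemoRecord, PartialDate, ReacRecord
from faerspv.signals import (
    ContingencyTable,
    build_tables,
    fdr_adjust,
    ic,
    ic025_matrix,
    pt_p_value,
    ror,
    screen_group,
    signal_flag,
)


def table(a, b, c, d, group="G", pt="pt"):
    return ContingencyTable(group=group, pt=pt, a=a, b=b, c=c, d=d)


cells = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
)


class TestBuildTables:
    def _background(self):
        # group X: 10 cases; others: 95 cases in group Y
        demo, reac, assign = [], [], []
        for i in range(10):
            pid = f"x{i}"
            demo.append(DemoRecord(pid, pid, PartialDate(2023)))
            assign.append(CohortAssignment(pid, "IPI_NIVO"))
        for i in range(95):
            pid = f"y{i}"
            demo.append(DemoRecord(pid, pid, PartialDate(2023)))
            assign.append(CohortAssignment(pid, "NIVO"))
        # target: PT "q" x4 plus 6 other records; elsewhere: q x10, 180 others
        for i in range(4):
            reac.append(ReacRecord(f"x{i}", "q"))
        for i in range(6):
            reac.append(ReacRecord(f"x{4 + i}", f"other{i}"))
        for i in range(10):
            reac.append(ReacRecord(f"y{i}", "q"))
        for i in range(90):
            reac.append(ReacRecord(f"y{i}", f"noise{i % 45}"))
            reac.append(ReacRecord(f"y{90 + i % 5}", f"noise{45 + i % 45}"))
        return demo, reac, assign

    def test_hand_counted_cells(self):
        demo, reac, assign = self._background()
        tables = build_tables(reac, assign, demo, "IPI_NIVO")
        t = tables["q"]
        assert (t.a, t.b, t.c, t.d) == (4, 6, 10, 180)

    def test_pt_absent_from_target_not_emitted(self):
        demo, reac, assign = self._background()
        tables = build_tables(reac, assign, demo, "IPI_NIVO")
        assert "noise0" not in tables

    def test_margin_identity(self):
        demo, reac, assign = self._background()
        tables = build_tables(reac, assign, demo, "IPI_NIVO")
        total_target = sum(t.a for t in tables.values())
        assert all(t.a + t.b == 10 for t in tables.values())
        assert total_target == 10
        # a+c is the PT's record count in the whole background
        assert tables["q"].a + tables["q"].c == 14

    def test_single_group_background_degenerate(self):
        demo = [DemoRecord("1", "1", PartialDate(2023))]
        reac = [ReacRecord("1", "q")]
        tables = build_tables(reac, [CohortAssignment("1", "IPI")], demo, "IPI")
        assert tables["q"].degenerate

    def test_empty_target_group(self):
        demo = [DemoRecord("1", "1", PartialDate(2023))]
        assert build_tables([], [CohortAssignment("1", "IPI")], demo, "IPI") == {}


class TestRor:
    def test_proportional_table_is_unity(self):
        estimate, lo, hi, haldane = ror(table(100, 900, 1000, 9000))
        assert estimate == pytest.approx(1.0)
        assert lo < 1.0 < hi and not haldane

    def test_closed_form_value(self):
        estimate, lo, hi, _ = ror(table(10, 90, 100, 9900))
        assert estimate == pytest.approx(11.0)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(11.0 * math.exp(-1.96 * se))
        assert lo == pytest.approx(5.5595, abs=1e-3)

    def test_haldane_correction_on_zero_cell(self):
        estimate, _, _, haldane = ror(table(0, 10, 5, 100))
        assert haldane
        assert estimate == pytest.approx((0.5 * 100.5) / (10.5 * 5.5))

    @given(cells)
    @settings(max_examples=200, deadline=None)
    def test_reciprocity_swapping_rows(self, abcd):
        a, b, c, d = abcd
        est, lo, hi, _ = ror(table(a, b, c, d))
        inv, ilo, ihi, _ = ror(table(c, d, a, b))
        assert inv == pytest.approx(1 / est, rel=1e-12)
        assert ilo == pytest.approx(1 / hi, rel=1e-12)
        assert ihi == pytest.approx(1 / lo, rel=1e-12)

    def test_scale_monotonicity_of_lower_bound(self):
        base = table(10, 90, 100, 9900)
        lo_prev = ror(base)[1]
        for k in (2, 5, 10):
            lo_k = ror(table(10 * k, 90 * k, 100 * k, 9900 * k))[1]
            assert lo_k > lo_prev
            lo_prev = lo_k


class TestIc:
    def test_exact_independence_zero_bits(self):
        point, lower = ic(table(100, 900, 1000, 9000))
        assert point == pytest.approx(0.0, abs=1e-12)
        assert lower < 0

    def test_gamma_point_and_quantile(self):
        t = table(10, 90, 100, 9900)
        point, lower = ic(t)
        assert t.expected_a == pytest.approx(1.0891, abs=1e-4)
        assert point == pytest.approx(math.log2(10.5 / (t.expected_a + 0.5)), rel=1e-12)
        assert point == pytest.approx(2.724, abs=1e-3)
        assert lower == pytest.approx(1.694, abs=1e-3)

    def test_gamma_quantile_against_numerical_inversion(self):
        t = table(10, 90, 100, 9900)
        _, lower = ic(t)
        # independent oracle: bisection on the gamma CDF
        shape, rate = 10.5, t.expected_a + 0.5
        lo_x, hi_x = 1e-9, 1e3
        for _ in range(200):
            mid = (lo_x + hi_x) / 2
            if stats.gamma.cdf(mid, shape, scale=1 / rate) < 0.025:
                lo_x = mid
            else:
                hi_x = mid
        assert lower == pytest.approx(math.log2(lo_x), abs=1e-9)

    def test_monte_carlo_quantile(self):
        t = table(25, 975, 500, 48500)
        _, lower = ic(t)
        rng = np.random.default_rng(5)
        draws = rng.gamma(t.a + 0.5, 1.0 / (t.expected_a + 0.5), size=200_000)
        empirical = math.log2(np.quantile(draws, 0.025))
        assert lower == pytest.approx(empirical, abs=0.05)

    def test_a_zero_allowed_and_negative(self):
        point, lower = ic(table(0, 10, 50, 1000))
        assert lower < point < 0

    @given(cells)
    @settings(max_examples=200, deadline=None)
    def test_shrinkage_and_ordering(self, abcd):
        t = table(*abcd)
        point, lower = ic(t)
        assert lower < point
        if t.a / t.expected_a > 1:
            assert point <= math.log2(t.a / t.expected_a)

    def test_large_count_consistency(self):
        # lower bound approaches log2(a/E) from below as counts scale up
        a, b, c, d = 10, 90, 100, 9900
        exact = math.log2(a * (a + b + c + d) / ((a + b) * (a + c)))
        prev = -math.inf
        for k in (10, 100, 1000):
            t = table(a * k, b * k, c * k, d * k)
            _, lower = ic(t)
            assert prev < lower < exact
            prev = lower
        assert exact - lower < 0.05

    def test_bate_variant_close_to_gamma_for_large_counts(self):
        t = table(1000, 9000, 10000, 990000)
        g_point, g_lower = ic(t, variant="gamma")
        b_point, b_lower = ic(t, variant="bate")
        assert b_point == pytest.approx(g_point, abs=0.05)
        assert b_lower == pytest.approx(g_lower, abs=0.1)
        assert b_lower < b_point

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ic(table(1, 1, 1, 1), variant="ebgm")


class TestSignalFlag:
    @pytest.mark.parametrize(
        "a, lo, ic025, expected",
        [
            (3, 1.001, 0.001, True),
            (2, 5.0, 1.0, False),  # count criterion
            (100, 0.99, 0.5, False),  # ROR criterion
            (100, 1.5, -0.001, False),  # IC criterion
            (100, float("nan"), 1.0, False),  # not computable
        ],
    )
    def test_joint_rule(self, a, lo, ic025, expected):
        assert signal_flag(a, lo, ic025) is expected


class TestFdrAdjust:
    def test_hand_computed_step_up(self):
        adjusted = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        # BH: p_(i) * m / i, cumulative min from the right
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_hand_computed_mixed(self):
        adjusted = fdr_adjust([0.005, 0.04, 0.03, 0.8])
        assert adjusted == pytest.approx([0.02, 0.0533333333, 0.0533333333, 0.8])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.123]) == pytest.approx([0.123])

    def test_all_equal_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw_and_rank_monotone(self):
        raw = [0.001, 0.01, 0.02, 0.5, 0.9, 0.04]
        adj = fdr_adjust(raw)
        assert (adj >= np.asarray(raw)).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestPtPValue:
    def test_proportional_table_p_one(self):
        p, method = pt_p_value(table(100, 900, 1000, 9000))
        assert p == pytest.approx(1.0) and method == "chi2"

    def test_chi_square_matches_oracle(self):
        t = table(30, 70, 100, 800)
        p, method = pt_p_value(t)
        arr = np.array([[30, 70], [100, 800]], float)
        expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
        chi2 = ((arr - expected) ** 2 / expected).sum()
        assert (expected >= 5).all() and method == "chi2"
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)

    def test_fisher_branch_for_small_expected(self):
        p, method = pt_p_value(table(1, 2, 3, 4))
        assert method == "fisher"
        assert p == pytest.approx(stats.fisher_exact([[1, 2], [3, 4]])[1])

    def test_degenerate_margin(self):
        p, method = pt_p_value(table(0, 0, 5, 5))
        assert p == 1.0 and method == "degenerate"


class TestScreenGroup:
    def test_screen_assembles_all_statistics(self):
        tables = {
            "hot": table(30, 70, 50, 4850, pt="hot"),
            "cold": table(5, 95, 500, 4400, pt="cold"),
        }
        df = screen_group(tables)
        assert set(df["pt"]) == {"hot", "cold"}
        hot = df.set_index("pt").loc["hot"]
        assert bool(hot["positive"]) is True
        assert (df["p_fdr"] >= df["p_raw"] - 1e-15).all()

    def test_ic025_matrix_shape_and_threshold(self):
        screens = {
            "A": screen_group({"x": table(150, 850, 100, 9000, group="A", pt="x"),
                               "y": table(5, 995, 50, 9050, group="A", pt="y")}),
            "B": screen_group({"x": table(120, 880, 130, 8970, group="B", pt="x")}),
        }
        full = ic025_matrix(screens)
        assert set(full.index) == {"x", "y"}
        filtered = ic025_matrix(screens, min_a=100)
        assert set(filtered.index) == {"x"}
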
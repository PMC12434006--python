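"""Drug normalization, group assignment, and baseline statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

import faerspv
from faerspv.cohort import (
    assign_group,
    baseline_summary,
    country_counts,
    cramers_v,
    onset_time,
    seriousness,
)
from faerspv.records import DemoRecord, DrugRecord, OutcRecord, PartialDate, TherRecord

# Published baseline cross-tabulations of the pooled single-agent (sICI)
# vs dual-therapy (DIG) checkpoint-inhibitor cohorts; counts are inputs,
# the V statistics are recomputed from them.
TABLE2 = {
    "gender": ([[11721, 3691], [21617, 6863], [8895, 2265]], 0.036),
    "age": (
        [[82, 28], [1654, 803], [8787, 3314], [7678, 2745], [4776, 1738], [19256, 4191]],
        0.114,
    ),
    "serious": ([[35686, 11664], [6547, 1155]], 0.079),
    "hospitalization": ([[10091, 4845], [32142, 7974]], 0.132),
    "death": ([[12985, 3238], [29248, 9581]], 0.051),
    "disability": ([[509, 143], [41724, 12676]], 0.004),
}


def drug(role, name, seq="1", ai=None):
    return DrugRecord("1", seq, role, name, ai)


class TestNormalizeDrug:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("OPDIVO.", "nivolumab"),
            ("Nivolumab 240 MG", "nivolumab"),
            ("  yervoy ", "ipilimumab"),
            ("IMFINZI", "durvalumab"),
            ("IMJUDO", "tremelimumab"),
            ("PEMBROLIZUMAB", None),
            ("", None),
        ],
    )
    def test_substring_matching(self, synonyms, name, expected):
        assert faerspv.normalize_drug(name, None, synonyms) == expected

    def test_prod_ai_fallback(self, synonyms):
        assert faerspv.normalize_drug("UNKNOWN BRAND", "NIVOLUMAB", synonyms) == "nivolumab"


class TestAssignGroup:
    def test_monotherapy(self, synonyms):
        a = assign_group("c", [drug("PS", "OPDIVO")], synonyms)
        assert a.group == "NIVO" and a.is_background

    def test_combination_ps_plus_ss(self, synonyms):
        a = assign_group(
            "c", [drug("PS", "YERVOY"), drug("SS", "NIVOLUMAB", seq="2")], synonyms
        )
        assert a.group == "IPI_NIVO"

    def test_combination_both_ps(self, synonyms):
        a = assign_group(
            "c", [drug("PS", "DURVALUMAB"), drug("PS", "TREMELIMUMAB", seq="2")], synonyms
        )
        assert a.group == "DURVA_TREME"

    def test_non_study_ps_is_other(self, synonyms):
        assert assign_group("c", [drug("PS", "PEMBROLIZUMAB")], synonyms).group == "OTHER"

    def test_concomitant_study_drug_does_not_make_combo(self, synonyms):
        a = assign_group(
            "c", [drug("PS", "OPDIVO"), drug("C", "YERVOY", seq="2")], synonyms
        )
        assert a.group == "NIVO"

    def test_study_ss_next_to_study_ps_breaks_monotherapy(self, synonyms):
        a = assign_group(
            "c", [drug("PS", "OPDIVO"), drug("SS", "IMFINZI", seq="2")], synonyms
        )
        assert a.group == "OTHER"  # not a recognised pair

    def test_no_ps_record_is_other(self, synonyms):
        assert assign_group("c", [drug("SS", "OPDIVO")], synonyms).group == "OTHER"


class TestCramersV:
    @pytest.mark.parametrize("name", sorted(TABLE2))
    def test_published_baseline_values_reproduced(self, name):
        counts, expected_v = TABLE2[name]
        res = cramers_v(counts)
        assert round(res.v, 3) == expected_v

    def test_disability_p_value(self):
        assert cramers_v(TABLE2["disability"][0]).p == pytest.approx(0.411, abs=5e-4)

    def test_proportional_table_exact_independence(self):
        res = cramers_v([[10, 20], [30, 60]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.v == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_row_dropped(self):
        full = cramers_v([[5, 10], [0, 0], [10, 5]])
        assert full.dof == 1

    def test_degenerate_after_dropping_raises(self):
        with pytest.raises(ValueError):
            cramers_v([[5, 0], [10, 0]])

    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=2, max_size=4),
            min_size=2,
            max_size=4,
        ).filter(
            lambda rows: len({len(r) for r in rows}) == 1
            and all(sum(r) > 0 for r in rows)
            and all(sum(col) > 0 for col in zip(*rows))
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_explicit_chi_square_oracle(self, rows):
        arr = np.array(rows, dtype=float)
        res = cramers_v(arr)
        # brute force: sum (O-E)^2/E over cells
        n = arr.sum()
        expected = np.outer(arr.sum(1), arr.sum(0)) / n
        chi2 = ((arr - expected) ** 2 / expected).sum()
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.v == pytest.approx(math.sqrt(chi2 / (n * (min(arr.shape) - 1))), abs=1e-10)
        dof = (arr.shape[0] - 1) * (arr.shape[1] - 1)
        assert res.p == pytest.approx(chi2_dist.sf(chi2, dof), abs=1e-10)

    def test_invariant_to_row_and_column_swaps(self):
        base = [[11721, 3691], [21617, 6863], [8895, 2265]]
        v0 = cramers_v(base).v
        assert cramers_v(base[::-1]).v == pytest.approx(v0, abs=1e-12)
        assert cramers_v([r[::-1] for r in base]).v == pytest.approx(v0, abs=1e-12)

    def test_scaling_counts_scales_chi2_exactly(self):
        base = np.array([[10, 25], [30, 15]], float)
        r0, rk = cramers_v(base), cramers_v(base * 7)
        assert rk.chi2 == pytest.approx(7 * r0.chi2, rel=1e-12)
        assert rk.v == pytest.approx(r0.v, rel=1e-12)


class TestSeriousness:
    def test_flags_follow_codes(self):
        serious, flags = seriousness([OutcRecord("1", "HO"), OutcRecord("1", "OT")])
        assert serious and flags["HO"] and flags["OT"] and not flags["DE"]

    def test_no_outcome_rows_non_serious(self):
        serious, flags = seriousness([])
        assert not serious and not any(flags.values())


class TestOnsetTime:
    def _case(self, event, start):
        d = DemoRecord("1", "c", PartialDate(2023, 6, 1), event_dt=PartialDate.parse(event) if event else None)
        drugs = [DrugRecord("1", "1", "PS", "OPDIVO")]
        ther = [TherRecord("1", "1", start_dt=PartialDate.parse(start) if start else None)]
        return d, drugs, ther

    def test_simple_delta(self):
        days, neg = onset_time(*self._case("20230206", "20230101"))
        assert days == 36 and not neg

    def test_missing_event_date(self):
        assert onset_time(*self._case(None, "20230101")) == (None, False)

    def test_partial_start_date_is_missing(self):
        assert onset_time(*self._case("20230206", "202301")) == (None, False)

    def test_negative_delta_flagged(self):
        days, neg = onset_time(*self._case("20230301", "20230310"))
        assert days == -9 and neg

    def test_earliest_ps_start_used(self):
        demo = DemoRecord("1", "c", PartialDate(2023, 6, 1), event_dt=PartialDate(2023, 2, 6))
        drugs = [DrugRecord("1", "1", "PS", "OPDIVO"), DrugRecord("1", "2", "SS", "YERVOY")]
        ther = [
            TherRecord("1", "1", start_dt=PartialDate(2023, 1, 15)),
            TherRecord("1", "1", start_dt=PartialDate(2023, 1, 1)),
            TherRecord("1", "2", start_dt=PartialDate(2022, 1, 1)),  # not PS: ignored
        ]
        assert onset_time(demo, drugs, ther)[0] == 36


class TestCountryCounts:
    def test_basic_counts_sorted(self):
        demo = [
            DemoRecord(str(i), str(i), PartialDate(2023), occr_country=c)
            for i, c in enumerate(["US", "US", "US", "JP"])
        ]
        s = country_counts(demo)
        assert s.to_dict() == {"US": 3, "JP": 1}
        assert list(s.index) == ["US", "JP"]

    def test_reporter_country_fallback(self):
        demo = [DemoRecord("1", "1", PartialDate(2023), reporter_country="FR")]
        assert country_counts(demo).to_dict() == {"FR": 1}

    def test_empty_cohort(self):
        assert country_counts([]).empty


class TestBaselineSummary:
    @pytest.fixture
    def small_cohort(self, synonyms):
        demo, drugs, outc, ther = [], [], [], []
        spec = [
            # (caseid, group drug/role pairs, sex, age, outcomes, start, event)
            ("1", [("PS", "OPDIVO")], "M", 70, ["HO"], "20230101", "20230131"),
            ("2", [("PS", "OPDIVO")], "F", 50, [], "20230101", None),
            ("3", [("PS", "YERVOY"), ("SS", "OPDIVO")], "M", None, ["DE"], None, "20230301"),
            ("4", [("PS", "IMFINZI"), ("SS", "IMJUDO")], "F", 62, ["HO", "OT"], "20230101", "20230401"),
            ("5", [("PS", "PEMBROLIZUMAB")], "M", 40, [], None, None),
        ]
        for cid, dr, sex, age, codes, start, event in spec:
            pid = cid
            demo.append(
                DemoRecord(pid, cid, PartialDate(2023, 6, 1),
                           event_dt=PartialDate.parse(event) if event else None,
                           age=float(age) if age else None, age_cod="YR" if age else None,
                           sex=sex, occp_cod="MD", reporter_country="US", occr_country="US")
            )
            for seq, (role, name) in enumerate(dr, start=1):
                drugs.append(DrugRecord(pid, str(seq), role, name))
            for c in codes:
                outc.append(OutcRecord(pid, c))
            if start:
                ther.append(TherRecord(pid, "1", start_dt=PartialDate.parse(start)))
        assignments = faerspv.assign_cohort(demo, drugs, synonyms)
        return assignments, demo, outc, ther, drugs

    def test_partition_and_pool_sizes(self, small_cohort):
        assignments = small_cohort[0]
        groups = [a.group for a in assignments]
        assert groups == ["NIVO", "NIVO", "IPI_NIVO", "DURVA_TREME", "OTHER"]
        summary = baseline_summary(*small_cohort)
        assert summary.n_sici == 2 and summary.n_dig == 2

    def test_counts_sum_to_totals_and_pcts_to_100(self, small_cohort):
        summary = baseline_summary(*small_cohort)
        for var, tab in summary.tables.items():
            assert tab["sICI"].sum() == summary.n_sici, var
            assert tab["DIG"].sum() == summary.n_dig, var
            assert tab["sICI_pct"].sum() == pytest.approx(100.0)

    def test_serious_classification(self, small_cohort):
        tab = baseline_summary(*small_cohort).tables["serious"]
        assert tab.loc["Serious", "sICI"] == 1 and tab.loc["Serious", "DIG"] == 2

    def test_onset_quantitative_block(self, small_cohort):
        q = baseline_summary(*small_cohort).quantitative["onset_days"]
        assert q.loc["n", "sICI"] == 1 and q.loc["median", "sICI"] == 30
        assert q.loc["median", "DIG"] == 90

    def test_onset_modes_differ_on_negative_delta(self, synonyms):
        demo = [DemoRecord("1", "1", PartialDate(2023, 6, 1), event_dt=PartialDate(2023, 1, 1),
                           sex="M")]
        drugs = [DrugRecord("1", "1", "PS", "OPDIVO")]
        ther = [TherRecord("1", "1", start_dt=PartialDate(2023, 1, 10))]
        assignments = faerspv.assign_cohort(demo, drugs, synonyms)
        inc = baseline_summary(assignments, demo, [], ther, drugs, onset_mode="inclusive")
        strict = baseline_summary(assignments, demo, [], ther, drugs, onset_mode="strict")
        assert inc.tables["onset_band"].loc["<30 days", "sICI"] == 1
        assert strict.tables["onset_band"].loc["Missing", "sICI"] == 1
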
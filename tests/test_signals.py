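import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.signals import (
    ContingencyTable,
    PtSocMap,
    SignalResult,
    SignalStats,
    Thresholds,
    ZeroCellError,
    build_tables,
    compute_stats,
    flag_signal,
    prr_chi2,
    pt_distribution_within_soc,
    rank_signals,
    ror_with_ci,
    soc_distribution,
)

cells = st.integers(min_value=1, max_value=2000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def _chi2_expected_counts(t: ContingencyTable) -> float:
    """Independent Pearson oracle via the expected-counts formulation."""
    obs = [[t.a, t.b], [t.c, t.d]]
    rows = [t.a + t.b, t.c + t.d]
    cols = [t.a + t.c, t.b + t.d]
    n = t.n
    return sum(
        (obs[i][j] - rows[i] * cols[j] / n) ** 2 / (rows[i] * cols[j] / n)
        for i in range(2)
        for j in range(2)
    )


class TestWorkedExample:
    """Hand-checked fourfold table: a=10, b=90, c=100, d=9900."""

    T = ContingencyTable(10, 90, 100, 9900)

    def test_ror_exact(self):
        ror, lo, hi = ror_with_ci(self.T)
        assert ror == 11.0

    def test_prr_exact(self):
        prr, _ = prr_chi2(self.T)
        assert prr == 10.0

    def test_ci_low_matches_hand_oracle(self):
        # se^2 = 1/10 + 1/90 + 1/100 + 1/9900 = 4/33 exactly
        se = math.sqrt(float(Fraction(4, 33)))
        expected = math.exp(math.log(11.0) - 1.96 * se)
        _, lo, hi = ror_with_ci(self.T)
        assert lo == pytest.approx(expected, rel=1e-12)
        assert lo == pytest.approx(5.56, abs=0.01)
        assert hi == pytest.approx(math.exp(math.log(11.0) + 1.96 * se), rel=1e-12)

    def test_chi2_matches_exact_fraction(self):
        exact = Fraction((10 * 9900 - 90 * 100) ** 2 * 10100, 100 * 10000 * 110 * 9990)
        _, chi2 = prr_chi2(self.T)
        assert chi2 == pytest.approx(float(exact), rel=1e-12)
        assert chi2 == pytest.approx(74.45, abs=0.01)


class TestAlgebraicIdentities:
    def test_perfect_symmetry_is_null(self):
        t = ContingencyTable(5, 5, 5, 5)
        ror, lo, hi = ror_with_ci(t)
        prr, chi2 = prr_chi2(t)
        assert ror == prr == 1.0
        assert chi2 == 0.0
        assert lo < 1.0 < hi

    @given(cells, cells, cells, cells)
    @settings(deadline=None, derandomize=True)
    def test_independence_structured_table_is_null(self, x, y, w, z):
        # a=xy, b=xz, c=wy, d=wz has ad == bc by construction
        t = ContingencyTable(x * y, x * z, w * y, w * z)
        ror, _, _ = ror_with_ci(t)
        prr, chi2 = prr_chi2(t)
        assert ror == pytest.approx(1.0)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_ror_exceeds_prr_iff_ad_exceeds_bc(self, t):
        ror, _, _ = ror_with_ci(t)
        prr, _ = prr_chi2(t)
        if t.a * t.d >= t.b * t.c:
            assert ror >= prr * (1 - 1e-12)
        else:
            assert ror <= prr * (1 + 1e-12)

    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_chi2_invariant_under_transposition(self, t):
        _, chi2 = prr_chi2(t)
        _, chi2_t = prr_chi2(ContingencyTable(t.a, t.c, t.b, t.d))
        assert chi2 == pytest.approx(chi2_t, rel=1e-12)

    @given(tables)
    @settings(deadline=None, derandomize=True)
    def test_ror_invariant_under_double_swap(self, t):
        ror, _, _ = ror_with_ci(t)
        ror_s, _, _ = ror_with_ci(ContingencyTable(t.d, t.c, t.b, t.a))
        assert ror == pytest.approx(ror_s, rel=1e-12)

    def test_ror_and_prr_strictly_increase_in_a(self):
        prev_ror, prev_prr = 0.0, 0.0
        for a in range(1, 50):
            t = ContingencyTable(a, 50, 40, 900)
            ror, _, _ = ror_with_ci(t)
            prr, _ = prr_chi2(t)
            assert ror > prev_ror and prr > prev_prr
            prev_ror, prev_prr = ror, prr

    @given(tables)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_chi2_matches_expected_counts_oracle(self, t):
        _, chi2 = prr_chi2(t)
        assert chi2 == pytest.approx(_chi2_expected_counts(t), rel=1e-9)

    def test_chi2_matches_scipy_uncorrected(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            _, chi2 = prr_chi2(t)
            ref = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)[0]
            assert chi2 == pytest.approx(ref, rel=1e-9)

    def test_yates_correction_reduces_chi2(self):
        t = ContingencyTable(10, 90, 100, 9900)
        _, plain = prr_chi2(t)
        _, corrected = prr_chi2(t, yates=True)
        assert corrected < plain


class TestZeroCells:
    @pytest.mark.parametrize("t", [ContingencyTable(0, 5, 5, 5), ContingencyTable(5, 0, 5, 5), ContingencyTable(5, 5, 0, 5), ContingencyTable(5, 5, 5, 0)])
    def test_zero_cell_raises(self, t):
        with pytest.raises(ZeroCellError):
            ror_with_ci(t)

    def test_zero_cell_stats_non_computable_never_flagged(self):
        stats = compute_stats(ContingencyTable(50, 0, 1, 1))
        assert not stats.computable
        assert stats.reason
        assert math.isnan(stats.ror)
        assert not (stats.ror_flag or stats.mhra_flag or stats.combined_flag)

    def test_degenerate_single_report_table(self):
        stats = compute_stats(ContingencyTable(1, 0, 0, 0))
        assert not stats.computable


def _stats(ror=5.0, lo=2.0, hi=10.0, prr=5.0, chi2=30.0):
    return SignalStats(ror=ror, ror_ci_low=lo, ror_ci_high=hi, prr=prr, chi2=chi2)


class TestFlags:
    def test_small_a_blocks_all_flags_despite_huge_ror(self):
        t = ContingencyTable(2, 1, 1, 10000)
        out = flag_signal(_stats(ror=20000.0, lo=1000.0), t)
        assert not (out.ror_flag or out.mhra_flag or out.combined_flag)

    def test_inclusive_boundaries_prr_chi2_a_strict_ci(self):
        t = ContingencyTable(3, 10, 10, 1000)
        out = flag_signal(_stats(lo=1.001, prr=2.0, chi2=4.0), t)
        assert out.ror_flag and out.mhra_flag and out.combined_flag
        at_one = flag_signal(_stats(lo=1.0, prr=2.0, chi2=4.0), t)
        assert not at_one.ror_flag and at_one.mhra_flag and not at_one.combined_flag

    @given(
        st.integers(min_value=0, max_value=8),
        st.floats(min_value=0.5, max_value=3.0),
        st.floats(min_value=0.5, max_value=4.0),
        st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_flags_replicate_threshold_inequalities(self, a, lo, prr, chi2):
        t = ContingencyTable(a, 10, 10, 100)
        out = flag_signal(_stats(lo=lo, prr=prr, chi2=chi2), t)
        assert out.ror_flag == (a >= 3 and lo > 1.0)
        assert out.mhra_flag == (a >= 3 and prr >= 2.0 and chi2 >= 4.0)
        assert out.combined_flag == (out.ror_flag and out.mhra_flag)


class TestBuildTables:
    def test_enumerated_eight_pair_example(self):
        # 4 reports, 2 in cohort; DIARRHOEA on both cohort reports and one
        # background report; every report carries 2 PTs
        events = pd.DataFrame(
            {
                "primaryid": [1, 1, 2, 2, 3, 3, 4, 4],
                "pt": [
                    "Diarrhoea",
                    "Nausea",
                    "Diarrhoea",
                    "Rash",
                    "Diarrhoea",
                    "Fatigue",
                    "Nausea",
                    "Rash",
                ],
            }
        )
        tables = build_tables({1, 2}, events, {1, 2, 3, 4})
        t = tables["Diarrhoea"]
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 3)
        assert t.n == len(events)

    def test_a_plus_b_constant_across_pts(self):
        rng = np.random.default_rng(0)
        events = pd.DataFrame(
            {
                "primaryid": rng.integers(1, 200, 1000),
                "pt": rng.choice(["P1", "P2", "P3", "P4"], 1000),
            }
        ).drop_duplicates()
        cohort = set(range(1, 60))
        tables = build_tables(cohort, events, set(range(1, 200)))
        sums = {t.a + t.b for t in tables.values()}
        assert len(sums) == 1
        assert sum(t.a for t in tables.values()) == events[
            events["primaryid"].isin(cohort)
        ].shape[0]

    def test_single_report_dataset_degenerate_bounds(self):
        events = pd.DataFrame({"primaryid": [1], "pt": ["Nausea"]})
        tables = build_tables({1}, events, {1})
        assert (tables["Nausea"].a, tables["Nausea"].b) == (1, 0)

    def test_empty_cohort_yields_empty_result(self):
        events = pd.DataFrame({"primaryid": [1], "pt": ["Nausea"]})
        assert build_tables(set(), events, {1}) == {}

    def test_report_unit_margins(self):
        events = pd.DataFrame(
            {"primaryid": [1, 1, 2, 3], "pt": ["P1", "P2", "P1", "P2"]}
        )
        tables = build_tables({1, 2}, events, {1, 2, 3}, unit="report")
        t = tables["P1"]
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 1)


def _result(pt, ror, a, soc="SOC A", flag=True):
    t = ContingencyTable(a, 10, 10, 1000)
    stats = SignalStats(
        ror=ror,
        ror_ci_low=2.0,
        ror_ci_high=ror * 2,
        prr=ror,
        chi2=50.0,
        ror_flag=flag,
        mhra_flag=flag,
        combined_flag=flag,
    )
    return SignalResult("DrugX", pt, soc, t, stats)


class TestRankingAndSoc:
    def test_tie_broken_by_case_count_then_pt(self):
        rs = [
            _result("Bpt", 5.0, 3),
            _result("Apt", 5.0, 5),
            _result("Cpt", 5.0, 3),
        ]
        ranked = rank_signals(rs)
        assert [r.pt for r in ranked] == ["Apt", "Bpt", "Cpt"]

    def test_top_n_truncates_and_overshoot_returns_all(self):
        rs = [_result(f"P{i}", float(i + 1), 5) for i in range(6)]
        assert len(rank_signals(rs, top_n=3)) == 3
        assert len(rank_signals(rs, top_n=50)) == 6

    def test_ranking_is_stable_and_descending(self):
        rs = [_result(f"P{i}", float((i * 7) % 5 + 1), 4) for i in range(20)]
        once = rank_signals(rs)
        assert [r.pt for r in once] == [r.pt for r in rank_signals(rs)]
        rors = [r.stats.ror for r in once]
        assert rors == sorted(rors, reverse=True)

    def test_unflagged_results_not_rankable(self):
        rs = [_result("P1", 5.0, 5, flag=False)]
        assert rank_signals(rs) == []

    def test_soc_percentages_are_case_count_shares(self):
        rs = [
            _result("P1", 5.0, 50, soc="SOC A"),
            _result("P2", 5.0, 25, soc="SOC A"),
            _result("P3", 5.0, 25, soc="SOC B"),
        ]
        dist = soc_distribution(rs)
        table = dist.table.set_index("soc")
        assert table.loc["SOC A", "pct"] == pytest.approx(75.0)
        assert table.loc["SOC B", "pct"] == pytest.approx(25.0)
        assert dist.table["pct"].sum() == pytest.approx(100.0)
        assert dist.n_socs == 2

    def test_single_soc_gets_everything(self):
        rs = [_result("P1", 5.0, 10), _result("P2", 4.0, 10)]
        dist = soc_distribution(rs)
        assert dist.table["pct"].iloc[0] == pytest.approx(100.0)

    def test_unmapped_pt_accumulates_under_reserved_soc(self):
        rs = [_result("P1", 5.0, 10, soc=None)]
        dist = soc_distribution(rs)
        assert dist.table["soc"].iloc[0] == "UNMAPPED"
        assert dist.n_socs == 0
        assert dist.n_unmapped_pts == 1

    def test_per_soc_lists_partition_flagged_signals(self):
        rs = [
            _result("P1", 5.0, 10, soc="SOC A"),
            _result("P2", 4.0, 10, soc="SOC B"),
            _result("P3", 3.0, 10, soc="SOC A"),
            _result("P4", 9.0, 10, soc="SOC B", flag=False),
        ]
        union = []
        for soc in ("SOC A", "SOC B"):
            union += pt_distribution_within_soc(rs, soc)
        assert {r.pt for r in union} == {"P1", "P2", "P3"}

    def test_soc_absent_from_results_is_empty(self):
        assert pt_distribution_within_soc([_result("P1", 5.0, 10)], "Nope") == []


class TestPtSocMap:
    def test_tsv_round_trip_and_case_normalization(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("pt\tsoc\nDiarrhoea\tGastrointestinal disorders\n")
        m = PtSocMap.from_tsv(path)
        assert m.get("DIARRHOEA") == "Gastrointestinal disorders"
        assert "diarrhoea" in m
        assert m.get("Unknown term") is None

    def test_conflicting_duplicate_keys_rejected(self):
        with pytest.raises(ValueError):
            PtSocMap({"Nausea": "SOC A", "NAUSEA": "SOC B"})
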
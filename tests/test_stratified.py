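import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency, fisher_exact

from faerspv import io as fio
from faerspv.preprocess import ADULT, CHILD, CaseReport
from faerspv.signal_stats import ContingencyTable, screen
from faerspv.stratified import (
    annual_counts,
    bh_adjust,
    demographics_table,
    fisher_p,
    soc_shares,
    volcano_rows,
)


class TestFisher:
    def test_perfect_independence(self):
        assert fisher_p(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_extreme_table_enumeration(self):
        # (5,0,0,5): only the two extreme tables qualify, p = 2/252
        assert fisher_p(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 40, 4)
            if a + b + c + d == 0:
                continue
            p1 = fisher_p(ContingencyTable(a, b, c, d))
            p2 = fisher_p(ContingencyTable(a, c, b, d))
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 60, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            ours = fisher_p(ContingencyTable(a, b, c, d))
            ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_agrees_with_chi2_on_large_balanced_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            base = (int(x) for x in rng.integers(2000, 4000, 4))
            t = ContingencyTable(*base)
            p_f = fisher_p(t)
            p_c = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)[1]
            # asymptotic agreement degrades in the far tail
            if 1e-3 < p_c < 0.99:
                assert p_f == pytest.approx(p_c, rel=0.10)


def _bh_reference(pvals):
    """Hand-stepped BH: q_(i) = min_{j>=i} m p_(j) / j, clipped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_stepped_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40)).tolist()
            assert bh_adjust(p) == pytest.approx(_bh_reference(p), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.permutations(list(range(8))))
    def test_order_equivariance(self, perm):
        p = [0.001, 0.2, 0.04, 0.9, 0.3, 0.011, 0.5, 0.07]
        q = bh_adjust(p)
        p_perm = [p[i] for i in perm]
        q_perm = bh_adjust(p_perm)
        assert q_perm == pytest.approx([q[i] for i in perm])


class TestVolcano:
    def test_unity_ror_gives_zero_log2(self, null_cohort, mini_dict):
        child = screen(null_cohort["universe"], level="PT", stratum=CHILD,
                       dictionary=mini_dict)
        adult = screen(null_cohort["universe"], level="PT", stratum=ADULT,
                       dictionary=mini_dict)
        rows = volcano_rows(child, adult)
        near_unity = rows[np.isclose(rows["log2_ror"], 0.0, atol=1e-9)]
        # log2 is 0 exactly when ror is 1
        for r in near_unity.itertuples():
            assert r.log2_ror == pytest.approx(0.0, abs=1e-9)
        assert set(rows["stratum"]) <= {CHILD, ADULT}

    def test_injected_child_signal_significant_in_child_only(
        self, cohort20k, mini_dict, injected_pt
    ):
        child = screen(cohort20k["universe"], level="PT", stratum=CHILD,
                       dictionary=mini_dict)
        adult = screen(cohort20k["universe"], level="PT", stratum=ADULT,
                       dictionary=mini_dict)
        rows = volcano_rows(child, adult)
        hit = rows[rows["term"] == injected_pt]
        child_row = hit[hit["stratum"] == CHILD]
        adult_row = hit[hit["stratum"] == ADULT]
        assert bool(child_row["significant"].iloc[0])
        assert not bool(adult_row["significant"].iloc[0])

    def test_null_cohort_fdr_control(self, null_cohort, mini_dict):
        child = screen(null_cohort["universe"], level="PT", stratum=CHILD,
                       dictionary=mini_dict)
        adult = screen(null_cohort["universe"], level="PT", stratum=ADULT,
                       dictionary=mini_dict)
        rows = volcano_rows(child, adult, q_threshold=0.05)
        assert rows["significant"].mean() <= 0.05


class TestSocShares:
    def _screen_frame(self, pairs):
        import pandas as pd
        return pd.DataFrame([{"term": t, "a": a} for t, a in pairs])

    def test_single_soc_universe(self):
        child = self._screen_frame([("soc x", 5)])
        adult = self._screen_frame([("soc x", 50)])
        df = soc_shares(child, adult)
        assert df["child_pct"].iloc[0] == 100.0
        assert df["adult_pct"].iloc[0] == 100.0
        assert df["group"].iloc[0] == "shared"

    def test_child_only_soc_is_exclusive(self):
        child = self._screen_frame([("soc x", 5), ("soc y", 5)])
        adult = self._screen_frame([("soc x", 50)])
        df = soc_shares(child, adult).set_index("soc")
        assert df.loc["soc y", "group"] == "exclusive"
        assert df.loc["soc y", "adult_pct"] == 0.0

    def test_percentages_sum_to_100_per_stratum(self, cohort20k, mini_dict):
        child = screen(cohort20k["universe"], level="SOC", stratum=CHILD,
                       dictionary=mini_dict)
        adult = screen(cohort20k["universe"], level="SOC", stratum=ADULT,
                       dictionary=mini_dict)
        df = soc_shares(child, adult)
        assert df["child_pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert df["adult_pct"].sum() == pytest.approx(100.0, abs=0.1)


def _case(case_id, stratum, sex=None, weight=None, country=None, occ=None,
          fda="20200101"):
    return CaseReport(
        case_id=case_id, primary_id=case_id, fda_dt=fda,
        event_dt=fio.parse_partial_date(None), age_years=None, stratum=stratum,
        sex=sex, weight_kg=weight, reporter_country=country, occupation=occ,
    )


class TestDemographics:
    def test_empty_input_gives_all_zero_table(self):
        df = demographics_table([])
        assert (df["child_n"] == 0).all() and (df["adult_n"] == 0).all()

    def test_within_stratum_percentages(self):
        cases = [
            _case("1", CHILD, sex="M", weight=30.0, country="US", occ="MD"),
            _case("2", CHILD, sex="F", weight=120.0, country="FR", occ="CN"),
            _case("3", ADULT, sex="M", country="US", occ="HP"),
            _case("4", ADULT, sex="M", weight=49.9, country="US", occ="PH"),
        ]
        df = demographics_table(cases).set_index(["characteristic", "category"])
        assert df.loc[("Sex", "Male"), "child_n"] == 1
        assert df.loc[("Sex", "Male"), "child_pct"] == 50.0
        assert df.loc[("Sex", "Male"), "adult_pct"] == 100.0
        assert df.loc[("Weight (kg)", "<50"), "adult_n"] == 1
        assert df.loc[("Weight (kg)", ">100"), "child_n"] == 1
        assert df.loc[("Weight (kg)", "Data missing"), "adult_n"] == 1
        assert df.loc[("Reporter country", "US"), "adult_n"] == 2


class TestAnnualCounts:
    def test_single_year_bucket(self):
        cases = [_case(str(i), ADULT, fda="20150601") for i in range(5)]
        df = annual_counts(cases)
        assert df.to_dict("records") == [{"year": "2015", "count": 5}]

    def test_conservation_with_unknown(self):
        cases = [_case("1", ADULT, fda="20150601"),
                 _case("2", ADULT, fda=None),
                 _case("3", ADULT, fda="20160101")]
        df = annual_counts(cases)
        assert df["count"].sum() == 3
        assert "unknown" in set(df["year"])

    def test_uniform_dates_fill_all_years(self, cohort20k):
        df = annual_counts(cohort20k["universe"]).set_index("year")["count"]
        years = [y for y in df.index if y != "unknown"]
        assert min(years) <= "2005" and max(years) >= "2023"
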
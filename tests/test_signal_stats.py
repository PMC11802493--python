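import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

from faerspv import io as fio
from faerspv.preprocess import ADULT, CaseReport
from faerspv.signal_stats import (
    ContingencyTable,
    EmptyStratumError,
    SignalStatistics,
    bcpnn_ic,
    build_contingency,
    compute_statistics,
    ebgm_simple,
    is_positive,
    prr_stat,
    ror_stat,
    screen,
)

positive_cells = st.integers(min_value=1, max_value=500)


def random_tables(n, seed, low=1, high=2000):
    rng = np.random.default_rng(seed)
    return [ContingencyTable(*rng.integers(low, high, size=4)) for _ in range(n)]


class TestRor:
    def test_basic_arithmetic(self):
        ror, _, _ = ror_stat(ContingencyTable(10, 20, 30, 40))
        assert ror == pytest.approx(2 / 3, abs=1e-12)

    def test_independence_ci(self):
        # balanced table: SE = sqrt(0.4), CI = exp(+-1.96*SE)
        ror, lo, hi = ror_stat(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0
        assert lo == pytest.approx(math.exp(-1.96 * math.sqrt(0.4)), rel=1e-9)
        assert hi == pytest.approx(math.exp(1.96 * math.sqrt(0.4)), rel=1e-9)
        assert (lo, hi) == (pytest.approx(0.2895, abs=1e-4), pytest.approx(3.4543, abs=1e-4))

    def test_proportional_rows_give_unity(self):
        ror, _, _ = ror_stat(ContingencyTable(10, 20, 20, 40))
        assert ror == pytest.approx(1.0)

    def test_zero_cell_undefined(self):
        assert all(math.isnan(x) for x in ror_stat(ContingencyTable(0, 5, 5, 5)))


class TestPrr:
    def test_basic_arithmetic(self):
        prr, _ = prr_stat(ContingencyTable(10, 20, 30, 40))
        assert prr == pytest.approx((10 / 30) / (30 / 70), abs=1e-12)

    def test_equal_row_rates(self):
        prr, chi2 = prr_stat(ContingencyTable(10, 20, 20, 40))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_background_undefined(self):
        prr, _ = prr_stat(ContingencyTable(5, 5, 0, 10))
        assert math.isnan(prr)


class TestBcpnn:
    def test_independent_table_ic_zero(self):
        ic, _ = bcpnn_ic(ContingencyTable(10, 10, 10, 10))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_closed_form(self):
        ic, _ = bcpnn_ic(ContingencyTable(10, 90, 90, 9810))
        assert ic == pytest.approx(math.log2(10), abs=1e-9)

    def test_zero_a_undefined(self):
        assert all(math.isnan(x) for x in bcpnn_ic(ContingencyTable(0, 10, 10, 10)))

    def test_count_variant_penalty(self):
        t = ContingencyTable(10, 90, 90, 9810)
        ic, ic025 = bcpnn_ic(t, variant="count")
        assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(10) - 2.1 / 10 ** 1.5)

    def test_ic025_below_ic_both_variants(self):
        for t in random_tables(50, seed=5):
            for variant in ("bate", "count"):
                ic, ic025 = bcpnn_ic(t, variant=variant)
                assert ic025 < ic


class TestEbgmSimple:
    def test_independent_table(self):
        ebgm, eb05 = ebgm_simple(ContingencyTable(10, 10, 10, 10))
        assert ebgm == pytest.approx(1.0)
        assert eb05 == pytest.approx(math.exp(-1.64 * math.sqrt(0.4)), rel=1e-9)
        assert eb05 == pytest.approx(0.3544, abs=2e-4)

    def test_observed_over_expected(self):
        ebgm, _ = ebgm_simple(ContingencyTable(10, 90, 90, 9810))
        assert ebgm == pytest.approx(10.0)

    def test_ic_equals_log2_ebgm_in_simple_mode(self):
        for t in random_tables(200, seed=11):
            s = compute_statistics(t)
            assert s.ic == pytest.approx(math.log2(s.ebgm), abs=1e-9)


class TestOracleEquivalence:
    """Closed forms vs independent reference implementations, 1000 tables."""

    TABLES = None

    @classmethod
    def setup_class(cls):
        cls.TABLES = random_tables(1000, seed=42)

    def test_ror_matches_statsmodels(self):
        for t in self.TABLES:
            sm = Table2x2([[t.a, t.b], [t.c, t.d]])
            ror, lo, hi = ror_stat(t)
            assert ror == pytest.approx(sm.oddsratio, rel=1e-10)
            lo_sm, hi_sm = sm.oddsratio_confint(0.05)
            # statsmodels uses the exact normal quantile; we use 1.96
            assert lo == pytest.approx(lo_sm, rel=1e-4)
            assert hi == pytest.approx(hi_sm, rel=1e-4)

    def test_chi2_matches_scipy_pearson(self):
        for t in self.TABLES:
            _, chi2 = prr_stat(t)
            ref = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)[0]
            assert chi2 == pytest.approx(ref, rel=1e-10)

    def test_yates_matches_scipy_corrected(self):
        for t in self.TABLES[:200]:
            _, chi2 = prr_stat(t, yates=True)
            ref = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True)[0]
            assert chi2 == pytest.approx(ref, rel=1e-10)

    def test_prr_matches_direct_rates(self):
        for t in self.TABLES:
            prr, _ = prr_stat(t)
            assert prr == pytest.approx(
                (t.a / (t.a + t.b)) / (t.c / (t.c + t.d)), rel=1e-12
            )


@settings(deadline=None, derandomize=True, max_examples=300)
@given(a=positive_cells, b=positive_cells, c=positive_cells, d=positive_cells)
def test_all_four_statistics_agree_on_direction(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    s = compute_statistics(t)
    sign = lambda x: (x > 0) - (x < 0)
    assert (
        sign(round(s.ror - 1, 12))
        == sign(round(s.prr - 1, 12))
        == sign(round(s.ic, 12))
        == sign(round(math.log(s.ebgm), 12))
    )


@settings(deadline=None, derandomize=True, max_examples=300)
@given(a=positive_cells, b=positive_cells, c=positive_cells, d=positive_cells)
def test_prr_ror_ordering(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    ror = ror_stat(t)[0]
    prr = prr_stat(t)[0]
    if prr > 1:
        assert ror >= prr - 1e-12
    elif prr < 1:
        assert ror <= prr + 1e-12


class TestIsPositive:
    def _stats(self, ror_lo, prr, chi2, ebgm05, ic025):
        return SignalStatistics(
            ror=ror_lo * 1.5, ror_lo95=ror_lo, ror_hi95=ror_lo * 3,
            prr=prr, chi2=chi2, ic=ic025 + 1, ic025=ic025,
            ebgm=ebgm05 * 1.5, ebgm05=ebgm05,
        )

    def test_child_psychiatric_row_is_positive(self):
        s = self._stats(ror_lo=2.4, prr=3.32, chi2=50.05, ebgm05=2.41, ic025=0.04)
        assert is_positive(s, a=31).positive

    def test_adult_eye_disorders_row_is_not_positive(self):
        s = self._stats(ror_lo=1.9, prr=2.42, chi2=48.14, ebgm05=1.94, ic025=-0.39)
        v = is_positive(s, a=57)
        assert not v.pass_mgps and not v.pass_bcpnn and not v.positive

    def test_small_count_gate(self):
        s = self._stats(ror_lo=50.0, prr=100.0, chi2=500.0, ebgm05=40.0, ic025=3.0)
        v = is_positive(s, a=2)
        assert not v.pass_ror and not v.pass_prr and not v.positive

    def test_undefined_components_fail_their_flag(self):
        v = is_positive(SignalStatistics(), a=10)
        assert not any([v.pass_ror, v.pass_prr, v.pass_bcpnn, v.pass_mgps])


def _mini_case(case_id, target, pts, stratum=ADULT):
    return CaseReport(
        case_id=case_id, primary_id=case_id, fda_dt="20200101",
        event_dt=fio.parse_partial_date(None), age_years=30.0, stratum=stratum,
        sex=None, weight_kg=None, reporter_country=None, occupation=None,
        reactions=list(pts), is_target=target,
    )


class TestBuildContingency:
    # four hand-written cases; counts checked by enumeration
    CASES = [
        _mini_case("1", True, ["rash", "nausea"]),
        _mini_case("2", True, ["nausea", "nausea"]),  # repeated PT counts once
        _mini_case("3", False, ["rash"]),
        _mini_case("4", False, ["fever"]),
    ]

    def test_hand_count(self):
        t = build_contingency(self.CASES, "nausea", stratum=ADULT)
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)
        t = build_contingency(self.CASES, "rash", stratum=ADULT)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_unreported_term(self):
        t = build_contingency(self.CASES, "coma", stratum=ADULT)
        assert t.a == 0 and t.c == 0 and t.N == 4

    def test_empty_stratum_raises(self):
        with pytest.raises(EmptyStratumError):
            build_contingency(self.CASES, "rash", stratum="child")


class TestScreen:
    def test_soc_frequency_counts_distinct_case_soc_pairs(self, cohort20k, mini_dict):
        universe = cohort20k["universe"]
        df = screen(universe, level="SOC", stratum="adult", dictionary=mini_dict)
        # recount independently: distinct (case, SOC) incidence for target cases
        expect = {}
        for c in universe:
            if c.stratum != "adult" or not c.is_target:
                continue
            for soc in {mini_dict.soc_of(pt) for pt in c.reactions}:
                expect[soc] = expect.get(soc, 0) + 1
        got = dict(zip(df["term"], df["a"]))
        assert got == expect

    def test_positive_rows_sorted_by_descending_ror(self, cohort20k, mini_dict):
        df = screen(cohort20k["universe"], level="PT", stratum="child",
                    dictionary=mini_dict)
        pos = df[df["positive"]]
        rors = pos["ror"].tolist()
        assert rors == sorted(rors, reverse=True)
        assert df["positive"].tolist() == sorted(df["positive"], reverse=True)
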
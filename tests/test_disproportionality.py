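import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency, norm
from statsmodels.stats.contingency_tables import Table2x2

from faersig.disproportionality import (
    ContingencyTable,
    SignalCriteria,
    build_contingency,
    chi2_yates,
    compute_stats,
    count_pairs,
    flag_signal,
    format_ror_ci,
    prr_estimate,
    ror_estimate,
    round_half_up,
    signal_table,
)
from faersig.errors import EstimateError
from faersig.ingest import CaseReport
from faersig.pipeline import load_cases
from faersig.simulate import sample_pair_tables

cells = st.integers(min_value=1, max_value=400)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def make_case(cid, drugs=(), reactions=()):
    return CaseReport(
        caseid=str(cid),
        primaryid=str(cid) + "1",
        fda_date=None,
        drugs=frozenset((d, "PS") for d in drugs),
        reactions=frozenset(reactions),
    )


class TestContingency:
    def test_four_case_enumeration(self):
        cases = [
            make_case(1, ["D"], ["E"]),
            make_case(2, ["D"], []),
            make_case(3, [], ["E"]),
            make_case(4, [], []),
        ]
        t = build_contingency(cases, "D", "E")
        assert t.cells == (1, 1, 1, 1)

    def test_cells_partition_case_set(self, tiny_quarter):
        cases, _ = load_cases(tiny_quarter)
        t = build_contingency(cases, "SPIRIVA", "DYSPNOEA")
        assert t.cells == (1, 1, 1, 1)
        assert t.n == len(cases)

    def test_repeat_mentions_count_once(self):
        # set semantics upstream: a case is one counting unit
        case = make_case(1, ["D"], ["E"])
        t = build_contingency([case, make_case(2)], "D", "E")
        assert t.a == 1

    def test_count_pairs_matches_direct_counting(self):
        cases = [
            make_case(1, ["D", "F"], ["E", "G"]),
            make_case(2, ["D"], ["G"]),
            make_case(3, ["F"], ["E"]),
            make_case(4, [], []),
        ]
        counts = count_pairs(cases)
        for drug in ("D", "F"):
            for event in ("E", "G"):
                assert counts.contingency(drug, event) == build_contingency(cases, drug, event)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestEstimates:
    def test_symmetric_table_is_null(self):
        ror, lo, hi = ror_estimate(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo < 1 < hi
        prr, *_ = prr_estimate(ContingencyTable(5, 5, 5, 5))
        assert prr == pytest.approx(1.0)

    def test_worked_example(self):
        # direct arithmetic: ror = (10*9900)/(90*100) = 11, prr = 0.1/0.01 = 10,
        # ln(11)=2.3979, SE=sqrt(0.1 + 1/90 + 0.01 + 1/9900)=0.3482
        t = ContingencyTable(10, 90, 100, 9900)
        ror, lo, hi = ror_estimate(t)
        assert ror == pytest.approx(11.0)
        # exp(ln 11 ± 1.96 * 0.348155) computed independently
        assert lo == pytest.approx(5.5596, abs=0.001)
        assert hi == pytest.approx(21.7645, abs=0.001)
        prr, *_ = prr_estimate(t)
        assert prr == pytest.approx(10.0)

    def test_doubling_cells_preserves_ror_and_narrows_ci(self):
        t1 = ContingencyTable(10, 90, 100, 9900)
        t2 = ContingencyTable(20, 180, 200, 19800)
        r1, lo1, hi1 = ror_estimate(t1)
        r2, lo2, hi2 = ror_estimate(t2)
        assert r1 == pytest.approx(r2)
        assert lo2 > lo1 and hi2 < hi1

    def test_haldane_correction_only_on_zero_cells(self):
        t = ContingencyTable(0, 10, 10, 100)
        ror, lo, hi = ror_estimate(t)
        af, bf, cf, df = 0.5, 10.5, 10.5, 100.5
        assert ror == pytest.approx((af * df) / (bf * cf))
        with pytest.raises(EstimateError):
            ror_estimate(t, correction=False)
        # non-degenerate tables are never altered
        clean = ContingencyTable(1, 10, 10, 100)
        assert ror_estimate(clean)[0] == pytest.approx((1 * 100) / (10 * 10))

    def test_degenerate_margin_is_an_error_for_prr(self):
        with pytest.raises(EstimateError, match="margin"):
            prr_estimate(ContingencyTable(0, 0, 10, 100))

    @settings(derandomize=True, max_examples=300)
    @given(tables)
    def test_cross_check_against_statsmodels(self, t):
        """Independent route: statsmodels Table2x2 odds/risk ratios + log CIs."""
        z = norm.ppf(0.975)
        sm_table = Table2x2(np.array(t.cells).reshape(2, 2))
        ror, lo, hi = ror_estimate(t, z=z)
        assert ror == pytest.approx(sm_table.oddsratio, rel=1e-10)
        sm_lo, sm_hi = sm_table.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-9)
        assert hi == pytest.approx(sm_hi, rel=1e-9)
        prr, plo, phi = prr_estimate(t, z=z)
        assert prr == pytest.approx(sm_table.riskratio, rel=1e-10)
        sm_plo, sm_phi = sm_table.riskratio_confint(0.05)
        assert plo == pytest.approx(sm_plo, rel=1e-9)
        assert phi == pytest.approx(sm_phi, rel=1e-9)

    @settings(derandomize=True, max_examples=300)
    @given(tables)
    def test_concordance_and_shrinkage(self, t):
        """(ror-1) and (prr-1) agree in sign; |ln ror| >= |ln prr|."""
        ror, *_ = ror_estimate(t)
        prr, *_ = prr_estimate(t)
        assert (ror - 1) * (prr - 1) >= -1e-12
        assert abs(math.log(ror)) >= abs(math.log(prr)) - 1e-12

    @settings(derandomize=True, max_examples=200)
    @given(tables)
    def test_monotonicity_in_a(self, t):
        bumped = ContingencyTable(t.a + 1, t.b, t.c, t.d)
        assert ror_estimate(bumped)[0] > ror_estimate(t)[0]
        assert prr_estimate(bumped)[0] > prr_estimate(t)[0]


class TestChi2:
    def test_independence_is_zero(self):
        assert chi2_yates(ContingencyTable(50, 50, 50, 50)) == 0.0

    def test_strong_association_large(self):
        assert chi2_yates(ContingencyTable(20, 80, 100, 9800)) > 100

    @settings(derandomize=True, max_examples=300)
    @given(tables)
    def test_cross_check_against_scipy(self, t):
        expected = chi2_contingency(np.array(t.cells).reshape(2, 2), correction=True).statistic
        assert chi2_yates(t) == pytest.approx(expected, rel=1e-10, abs=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(tables)
    def test_transpose_invariance(self, t):
        assert chi2_yates(t) == pytest.approx(
            chi2_yates(ContingencyTable(t.a, t.c, t.b, t.d)), rel=1e-12
        )

    def test_zero_margin_is_an_error(self):
        with pytest.raises(EstimateError, match="margin"):
            chi2_yates(ContingencyTable(0, 0, 5, 5))


class TestSignalFlag:
    def test_ror_criterion(self):
        # CI lower bound above 1 with enough reports
        positive = compute_stats("D", "E", ContingencyTable(30, 70, 100, 9800))
        assert positive.ror_low > 1 and positive.is_signal
        # wide CI spanning 1
        negative = compute_stats("D", "E", ContingencyTable(3, 97, 300, 9600))
        assert not negative.is_signal

    def test_min_count_gate(self):
        strong_but_rare = compute_stats("D", "E", ContingencyTable(2, 2, 10, 10000))
        assert strong_but_rare.ror_low > 1
        assert not strong_but_rare.is_signal  # a < 3

    def test_prr_criterion(self):
        criteria = SignalCriteria(method="prr")
        stats = compute_stats("D", "E", ContingencyTable(30, 70, 100, 9800), criteria=criteria)
        assert stats.prr >= 2 and stats.chi2 >= 4 and stats.is_signal

    def test_flag_from_published_ci_only(self):
        from faersig.disproportionality import SignalStats

        spiriva = SignalStats.from_published("Spiriva", "Dyspnoea", 8.87, 7.92, 9.93, frequency=1465)
        assert spiriva.is_signal
        pomalyst = SignalStats.from_published("Pomalyst", "Chest pain", 1.08, 0.94, 1.24)
        assert not pomalyst.is_signal


class TestSignalTable:
    def test_observed_vs_all_pairs(self):
        cases = [
            make_case(1, ["D"], ["E"]),
            make_case(2, ["D"], []),
            make_case(3, ["F"], []),
            make_case(4, [], ["E"]),
        ]
        observed = signal_table(cases)
        assert {(s.drug, s.event) for s in observed} == {("D", "E")}
        every = signal_table(cases, pairs="all")
        assert {(s.drug, s.event) for s in every} == {("D", "E"), ("F", "E")}
        assert all(s.table.n == 4 for s in every)


class TestCoverage:
    def test_woolf_ci_covers_known_odds_ratio(self):
        """~95% coverage of the planted odds ratio over simulated tables."""
        rho = 2.0
        rng = np.random.default_rng(20180101)
        draws = sample_pair_tables(
            n_cases=10_000, exposure=0.1, background=0.05, rho=rho, n_reps=10_000, rng=rng
        )
        covered = 0
        for a, b, c, d in draws:
            _, lo, hi = ror_estimate(ContingencyTable(int(a), int(b), int(c), int(d)))
            covered += lo <= rho <= hi
        assert 0.93 <= covered / len(draws) <= 0.97


class TestFormatting:
    @pytest.mark.parametrize("x, expected", [(8.865, 8.87), (1.005, 1.01), (2.0, 2.0)])
    def test_half_up_rounding(self, x, expected):
        assert round_half_up(x) == expected

    def test_published_style_string(self):
        assert format_ror_ci(8.8701, 7.9199, 9.9301) == "8.87(7.92-9.93)"
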
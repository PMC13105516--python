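"""Core valuation chain: benefit transfer, per-life-year values, annuity
discounting, welfare-loss triples, and their invariants — checked against
an independent single-expression oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlwelfare.io_harmonize import CountryEconRecord, DalyRecord
from vlwelfare.valuation import (
    DomainError,
    ValuationParams,
    annuity_factor,
    compute_vlw,
    compute_vsl,
    compute_vsly,
    compute_vsly_discounted,
    pct_gdp,
    value_country,
)

PARAMS = ValuationParams(gdp_pc_benchmark=64_000.0)


def _daly(val, lower, upper, loc="X"):
    return DalyRecord(loc, 2021, "Colorectal cancer", val, lower, upper)


def _econ(gdp_pc, le, pop, loc="X"):
    rec = CountryEconRecord(location_id=loc, year=2021, gdp_per_capita=gdp_pc,
                            population=pop, life_expectancy=le)
    rec.gdp_total = gdp_pc * pop
    return rec


class TestComputeVsl:
    @pytest.mark.parametrize("eps", [0.0, 0.55, 1.0, 1.5])
    def test_benchmark_income_always_gets_benchmark_vsl(self, eps):
        p = PARAMS.with_(elasticity=eps)
        assert compute_vsl(64_000.0, p) == pytest.approx(11_800_000.0)

    def test_quarter_income_unit_elasticity(self):
        assert compute_vsl(16_000.0, PARAMS) == pytest.approx(2_950_000.0)

    def test_quarter_income_low_elasticity(self):
        p = PARAMS.with_(elasticity=0.55)
        assert compute_vsl(16_000.0, p) == pytest.approx(
            11.8e6 * math.exp(0.55 * math.log(0.25)), abs=1.0)
        assert compute_vsl(16_000.0, p) == pytest.approx(5_504_900, abs=100)

    def test_no_ceiling_above_benchmark(self):
        assert compute_vsl(128_000.0, PARAMS) == pytest.approx(23_600_000.0)

    def test_non_positive_income_rejected(self):
        with pytest.raises(DomainError):
            compute_vsl(0.0, PARAMS)


class TestComputeVsly:
    def test_half_life_division(self):
        assert compute_vsly(2_950_000.0, 70.0) == pytest.approx(84_285.71, abs=0.01)
        assert compute_vsly(11_800_000.0, 80.0) == pytest.approx(295_000.0)

    def test_doubling_life_expectancy_halves_vsly(self):
        assert compute_vsly(1e6, 80.0) == pytest.approx(compute_vsly(1e6, 40.0) / 2)

    def test_non_positive_life_expectancy_rejected(self):
        with pytest.raises(DomainError):
            compute_vsly(1e6, 0.0)


class TestAnnuityFactor:
    def test_zero_rate_limit_is_exact(self):
        assert annuity_factor(0.0, 40.0) == 40.0

    @pytest.mark.parametrize("n, expected", [(35.0, 21.487), (40.0, 23.115)])
    def test_closed_form_at_three_percent(self, n, expected):
        assert annuity_factor(0.03, n) == pytest.approx(expected, abs=0.01)

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            annuity_factor(-0.01, 10.0)

    def test_continuity_at_zero(self):
        assert annuity_factor(1e-12, 30.0) == pytest.approx(30.0, rel=1e-6)


class TestDiscountedVsly:
    def test_annuitized_value(self):
        assert compute_vsly_discounted(2_950_000.0, 70.0, 0.03) == pytest.approx(
            137_291, abs=20)

    def test_zero_rate_equals_plain_vsly_exactly(self):
        assert compute_vsly_discounted(2.95e6, 70.0, 0.0) == compute_vsly(2.95e6, 70.0)

    def test_uplift_at_le_seventy(self):
        uplift = compute_vsly_discounted(1e6, 70.0, 0.03) / compute_vsly(1e6, 70.0) - 1
        assert uplift * 100 == pytest.approx(62.9, abs=0.2)


class TestVlwAndPctGdp:
    def test_interval_scales_elementwise(self):
        vlw = compute_vlw(_daly(1000, 800, 1200), 84_285.71)
        assert vlw == pytest.approx((84.29e6, 67.43e6, 101.14e6), abs=0.01e6)

    def test_zero_burden_gives_zero_loss(self):
        assert compute_vlw(_daly(0, 0, 0), 100.0) == (0.0, 0.0, 0.0)

    def test_unit_vsly_is_identity(self):
        assert compute_vlw(_daly(1000, 800, 1200), 1.0) == (1000.0, 800.0, 1200.0)

    def test_pct_gdp_scale(self):
        pct = pct_gdp((84.2857e6, 67.4286e6, 101.1429e6), 8e10)
        assert pct[0] == pytest.approx(0.1054, abs=1e-4)

    def test_loss_equal_to_gdp_is_hundred_percent(self):
        assert pct_gdp((5e9, 5e9, 5e9), 5e9) == (100.0, 100.0, 100.0)

    def test_non_positive_gdp_rejected(self):
        with pytest.raises(DomainError):
            pct_gdp((1.0, 1.0, 1.0), 0.0)


class TestValueCountry:
    def test_full_chain_toy_country(self):
        cv = value_country(_econ(16_000.0, 70.0, 5e6), _daly(1000, 800, 1200),
                           PARAMS.with_(discounting_enabled=False))
        assert cv.vsl == pytest.approx(2_950_000.0)
        assert cv.vsly == pytest.approx(84_285.71, abs=0.01)
        assert cv.vlw[0] == pytest.approx(84_285_714.29, abs=10)
        assert cv.vlw_pct_gdp[0] == pytest.approx(0.1054, abs=1e-4)
        assert cv.discount_uplift_pct == 0.0

    @pytest.mark.parametrize("eps", [0.3, 1.0, 1.4])
    def test_benchmark_country_valued_at_benchmark_vsl(self, eps):
        cv = value_country(_econ(64_000.0, 80.0, 1e8), _daly(100, 80, 120),
                           PARAMS.with_(elasticity=eps))
        assert cv.vsl == pytest.approx(11_800_000.0)

    def test_zero_elasticity_gives_everyone_benchmark_vsl(self):
        p = PARAMS.with_(elasticity=0.0)
        for gdp_pc in (500.0, 16_000.0, 200_000.0):
            cv = value_country(_econ(gdp_pc, 70.0, 1e6), _daly(10, 8, 12), p)
            assert cv.vsl == pytest.approx(11_800_000.0)

    def test_missing_inputs_are_rejected(self):
        rec = CountryEconRecord(location_id="X", year=2021, gdp_per_capita=1000.0,
                                population=1e6, life_expectancy=70.0)  # gdp_total NaN
        with pytest.raises(DomainError, match="imputation"):
            value_country(rec, _daly(10, 8, 12), PARAMS)


def _oracle(gdp_pc, le, pop, dv, dl, du, eps, r):
    """Independent re-statement of the whole chain, one expression per output."""
    vsl = 11.8e6 * (gdp_pc / 64_000.0) ** eps
    vsly = vsl / (le / 2)
    vsly_d = vsl / ((le / 2) if r == 0 else (1 - (1 + r) ** (-le / 2)) / r)
    gdp = gdp_pc * pop
    return {
        "vsl": vsl,
        "vsly": vsly,
        "vsly_discounted": vsly_d,
        "vlw": (dv * vsly, dl * vsly, du * vsly),
        "vlw_discounted": (dv * vsly_d, dl * vsly_d, du * vsly_d),
        "pct": (100 * dv * vsly / gdp, 100 * dl * vsly / gdp, 100 * du * vsly / gdp),
        "uplift": 100 * (vsly_d / vsly - 1),
    }


class TestOracleEquivalence:
    def test_thousand_randomized_countries(self):
        rng = np.random.default_rng(20210)
        for _ in range(1000):
            gdp_pc = float(np.exp(rng.uniform(np.log(300), np.log(300_000))))
            le = float(rng.uniform(40, 90))
            pop = float(np.exp(rng.uniform(np.log(1e4), np.log(1.5e9))))
            dv = float(rng.uniform(1, 1e6))
            dl, du = dv * rng.uniform(0.5, 1.0), dv * rng.uniform(1.0, 1.5)
            eps = float(rng.choice([0.55, 1.0, 1.5]))
            r = float(rng.choice([0.0, 0.03]))
            cv = value_country(
                _econ(gdp_pc, le, pop), _daly(dv, dl, du),
                PARAMS.with_(elasticity=eps, discount_rate=r))
            exp = _oracle(gdp_pc, le, pop, dv, dl, du, eps, r)
            assert cv.vsl == pytest.approx(exp["vsl"], rel=1e-10)
            assert cv.vsly == pytest.approx(exp["vsly"], rel=1e-10)
            assert cv.vsly_discounted == pytest.approx(exp["vsly_discounted"], rel=1e-10)
            for got, want in zip(cv.vlw, exp["vlw"]):
                assert got == pytest.approx(want, rel=1e-10)
            for got, want in zip(cv.vlw_pct_gdp, exp["pct"]):
                assert got == pytest.approx(want, rel=1e-10)
            assert cv.discount_uplift_pct == pytest.approx(exp["uplift"], rel=1e-9, abs=1e-9)


class TestInvariants:
    @given(gdp_pc=st.floats(500, 40_000))
    @settings(max_examples=50, derandomize=True)
    def test_vlw_decreases_with_elasticity_below_benchmark(self, gdp_pc):
        vals = [
            value_country(_econ(gdp_pc, 70.0, 1e6), _daly(100, 80, 120),
                          PARAMS.with_(elasticity=e)).vlw[0]
            for e in (0.55, 1.0, 1.5)
        ]
        assert vals[0] > vals[1] > vals[2]

    @given(gdp_pc=st.floats(70_000, 500_000))
    @settings(max_examples=50, derandomize=True)
    def test_vlw_increases_with_elasticity_above_benchmark(self, gdp_pc):
        vals = [
            value_country(_econ(gdp_pc, 70.0, 1e6), _daly(100, 80, 120),
                          PARAMS.with_(elasticity=e)).vlw[0]
            for e in (0.55, 1.0, 1.5)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_uplift_positive_monotone_and_bounded_over_le_range(self):
        les = np.linspace(50, 85, 36)
        uplifts = [
            value_country(_econ(10_000.0, le, 1e6), _daly(100, 80, 120),
                          PARAMS).discount_uplift_pct
            for le in les
        ]
        assert all(u > 0 for u in uplifts)
        assert all(b > a for a, b in zip(uplifts, uplifts[1:]))
        assert min(uplifts) >= 40.0 and max(uplifts) <= 80.0

    @given(k=st.floats(1e-3, 1e3), dv=st.floats(1, 1e5))
    @settings(max_examples=50, derandomize=True)
    def test_homogeneity_in_burden(self, k, dv):
        base = value_country(_econ(16_000.0, 70.0, 5e6), _daly(dv, 0.8 * dv, 1.2 * dv),
                             PARAMS)
        scaled = value_country(_econ(16_000.0, 70.0, 5e6),
                               _daly(k * dv, 0.8 * k * dv, 1.2 * k * dv), PARAMS)
        for a, b in zip(base.vlw, scaled.vlw):
            assert b == pytest.approx(k * a, rel=1e-12)
        for a, b in zip(base.vlw_pct_gdp, scaled.vlw_pct_gdp):
            assert b == pytest.approx(k * a, rel=1e-12)

    @given(
        gdp_pc=st.floats(300, 300_000), le=st.floats(40, 90),
        dv=st.floats(1, 1e6),
        lo_frac=st.floats(0.1, 1.0), hi_frac=st.floats(1.0, 3.0),
        eps=st.sampled_from([0.55, 1.0, 1.5]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_interval_ordering_preserved_through_every_stage(
            self, gdp_pc, le, dv, lo_frac, hi_frac, eps):
        cv = value_country(_econ(gdp_pc, le, 1e6),
                           _daly(dv, dv * lo_frac, dv * hi_frac),
                           PARAMS.with_(elasticity=eps))
        for triple in (cv.vlw, cv.vlw_discounted, cv.vlw_pct_gdp,
                       cv.vlw_pct_gdp_discounted):
            val, lower, upper = triple
            assert lower <= val <= upper
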
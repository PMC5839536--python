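"""Illness-death solver, acute recalibration and the smoking split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthchecksim.dismod_rates import (
    AcuteFatalityParams,
    InfeasibleRatesError,
    LifeTable,
    SmokingSplitParams,
    forward_illness_death,
    recalibrate_case_fatality,
    solve_illness_death,
    solve_rate_table,
    split_incidence_by_smoking,
)
from tests.conftest import mc_forward_illness_death


def _constant_curves(n=40, i=0.01, f=0.05, mb=0.01, prev0=0.0):
    inc = np.full(n, i)
    cf = np.full(n, f)
    bg = np.full(n, mb)
    prev, cm = forward_illness_death(inc, cf, bg, prev0=prev0)
    return inc, cf, bg, prev, cm


class TestSolver:
    def test_empty_disease_gives_zero_rates(self):
        n = 30
        inc, cf = solve_illness_death(np.zeros(n), np.zeros(n), np.full(n, 0.01))
        assert np.all(inc == 0) and np.all(cf == 0)

    def test_recovers_known_constant_hazards(self):
        """Forward-simulation oracle: a disease built from known (i, f) is
        inverted to within 2% at every age."""
        inc, cf, bg, prev, cm = _constant_curves(prev0=0.02)
        i_hat, f_hat = solve_illness_death(prev, cm, bg + cm)
        np.testing.assert_allclose(i_hat[:-1], inc[:-1], rtol=0.02)
        np.testing.assert_allclose(f_hat[1:-1], cf[1:-1], rtol=0.02)

    def test_monte_carlo_oracle_agreement(self):
        """An independent stochastic three-state simulation reproduces the
        deterministic recurrence the solver inverts."""
        inc, cf, bg, prev, cm = _constant_curves(prev0=0.02)
        prev_mc, cm_mc = mc_forward_illness_death(inc, cf, bg, n=100000, prev0=0.02, seed=3)
        np.testing.assert_allclose(prev_mc, prev, atol=0.01)
        np.testing.assert_allclose(cm_mc, cm, atol=0.002)

    def test_case_fatality_monotone_in_cause_mortality(self):
        """Doubling input cause mortality at fixed prevalence never lowers
        the solved case fatality (scanned over a rate grid)."""
        inc, cf, bg, prev, cm = _constant_curves(i=0.02, f=0.04, prev0=0.05)
        prev_fix = prev.copy()
        last = None
        for scale in (1.0, 1.25, 1.5):
            try:
                _, f_hat = solve_illness_death(prev_fix, cm * scale, bg + cm * scale)
            except InfeasibleRatesError:
                break
            if last is not None:
                assert np.all(f_hat[:-1] >= last[:-1] - 1e-9)
            last = f_hat

    def test_infeasible_inputs_name_first_age(self):
        n = 20
        prev = np.linspace(0.3, 0.0, n)  # prevalence falling with no deaths
        with pytest.raises(InfeasibleRatesError) as err:
            solve_illness_death(prev, np.zeros(n), np.full(n, 0.02), ages=np.arange(40, 40 + n))
        assert err.value.age is not None

    def test_cause_exceeding_all_cause_rejected(self):
        n = 10
        with pytest.raises(InfeasibleRatesError):
            solve_illness_death(np.full(n, 0.1), np.full(n, 0.05), np.full(n, 0.01))

    def test_solved_tables_reproduce_input_prevalence(self, rate_tables):
        """Round trip on the shipped epidemiology: solving and forward-
        integrating returns the input prevalence within 1% absolute."""
        tables, lifetable = rate_tables
        for d, t in tables.items():
            for sex in ("male", "female"):
                bg = np.clip(lifetable.qx[sex] - t.cause_mortality[sex], 0, 1)
                prev2, _ = forward_illness_death(
                    t.incidence[sex], t.case_fatality[sex], bg, prev0=t.prevalence[sex][0]
                )
                np.testing.assert_allclose(prev2, t.prevalence[sex], atol=0.01)


class TestRecalibration:
    @staticmethod
    def _lifetable_like(t):
        ages = t.ages
        qx = {s: np.clip(t.cause_mortality[s] + 0.01, 0, 1) for s in ("male", "female")}
        return LifeTable(ages=ages, qx=qx)

    @staticmethod
    def _solved_table(prev0=0.01):
        n = 61
        ages = np.arange(40, 101)
        inc = np.full(n, 0.004)
        cf = np.full(n, 0.05)
        bg = np.full(n, 0.01)
        prev, cm = {}, {}
        for s in ("male", "female"):
            prev[s], cm[s] = forward_illness_death(inc, cf, bg, prev0=prev0)
        lt = LifeTable(ages=ages, qx={s: np.clip(bg + cm[s], 0, 1) for s in ("male", "female")})
        return solve_rate_table("ihd", ages, prev, cm, lt), lt

    def test_zero_acute_is_identity(self):
        table, lt = self._solved_table()
        acute = AcuteFatalityParams(
            mi_fraction={"male": 0.0, "female": 0.0},
            mi_acute_cf={"male": 0.0, "female": 0.0},
            stroke_full_fraction=0.0,
            stroke_acute_cf={"under_80": {"male": 0, "female": 0}, "over_80": {"male": 0, "female": 0}},
        )
        out = recalibrate_case_fatality(table, acute, lt)
        for s in ("male", "female"):
            np.testing.assert_allclose(out.case_fatality_chronic[s], table.case_fatality[s])
            assert np.all(out.acute_fatality[s] == 0)

    def test_first_year_fatality_is_acute_event_mix(self, config):
        """Men's first-year IHD fatality equals 0.58 x 0.32 = 0.1856 from the
        MI share and MI acute fatality."""
        table, lt = self._solved_table()
        acute = AcuteFatalityParams.from_config(config)
        out = recalibrate_case_fatality(table, acute, lt)
        assert out.acute_fatality["male"][0] == pytest.approx(0.58 * 0.32)
        assert out.acute_fatality["female"][0] == pytest.approx(0.44 * 0.30)

    def test_cumulative_deaths_conserved(self, config):
        """Adjusted first-year + scaled chronic fatality reproduce the
        unadjusted cumulative deaths to age 100 within 1%."""
        from healthchecksim.dismod_rates import _forward_cause_deaths

        table, lt = self._solved_table()
        acute = AcuteFatalityParams.from_config(config)
        out = recalibrate_case_fatality(table, acute, lt)
        for s in ("male", "female"):
            bg = np.clip(lt.qx[s] - table.cause_mortality[s], 0, 1)
            before = _forward_cause_deaths(
                table.incidence[s], table.case_fatality[s], np.zeros_like(bg), bg,
                table.prevalence[s][0], half_year_new=True,
            )
            after = _forward_cause_deaths(
                out.incidence[s], out.case_fatality_chronic[s], out.acute_fatality[s], bg,
                out.prevalence[s][0], half_year_new=False,
            )
            assert after == pytest.approx(before, rel=0.01)

    def test_acute_exceeding_total_deaths_rejected(self):
        table, lt = self._solved_table()
        acute = AcuteFatalityParams(
            mi_fraction={"male": 1.0, "female": 1.0},
            mi_acute_cf={"male": 1.0, "female": 1.0},
            stroke_full_fraction=0.0,
            stroke_acute_cf={"under_80": {"male": 0, "female": 0}, "over_80": {"male": 0, "female": 0}},
        )
        with pytest.raises(InfeasibleRatesError):
            recalibrate_case_fatality(table, acute, lt)


class TestSmokingSplit:
    def test_zero_paf_no_attribution(self):
        i = np.array([0.001, 0.002])
        i_s, i_ns = split_incidence_by_smoking(i, SmokingSplitParams(paf=0.0, smoking_prevalence=0.25))
        np.testing.assert_array_equal(i_s, i)
        np.testing.assert_array_equal(i_ns, i)

    def test_matches_independent_linear_solve(self):
        """Solve the 2x2 system (mixture + PAF identities) with numpy and
        compare."""
        i, p, paf = 0.001, 0.25, 0.8
        # p*i_s + (1-p)*i_ns = i ;  p*i_s - p*i_ns = paf*i
        A = np.array([[p, 1 - p], [p, -p]])
        b = np.array([i, paf * i])
        i_s_ref, i_ns_ref = np.linalg.solve(A, b)
        i_s, i_ns = split_incidence_by_smoking(np.array([i]), SmokingSplitParams(paf=paf, smoking_prevalence=p))
        assert i_s[0] == pytest.approx(i_s_ref, rel=1e-12)
        assert i_ns[0] == pytest.approx(i_ns_ref, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        i=st.floats(1e-6, 0.2),
        p=st.floats(0.01, 0.99),
        paf=st.floats(0.0, 0.99),
    )
    def test_mixture_and_paf_identities(self, i, p, paf):
        i_s, i_ns = split_incidence_by_smoking(np.array([i]), SmokingSplitParams(paf=paf, smoking_prevalence=p))
        assert p * i_s[0] + (1 - p) * i_ns[0] == pytest.approx(i, abs=1e-12 + 1e-9 * i)
        assert (i_s[0] - i_ns[0]) * p / i == pytest.approx(paf, abs=1e-9)
        assert i_s[0] >= 0 and i_ns[0] >= 0

    def test_paf_without_smokers_rejected(self):
        with pytest.raises(ValueError):
            split_incidence_by_smoking(np.array([0.001]), SmokingSplitParams(paf=0.5, smoking_prevalence=0.0))
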
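"""Hazard calibration, event allocation, baseline disease, statin calibration."""

import numpy as np
import pytest

import healthchecksim as hcs
from healthchecksim.dismod_rates import AcuteFatalityParams
from healthchecksim.disease_engine import (
    EVENT_CODES,
    CvdAllocationParams,
    assign_baseline_disease,
    calibrate_hazards,
    calibrate_statin_multiplier,
    cell_index,
    other_cause_probability,
)


@pytest.fixture(scope="module")
def acute(config):
    return AcuteFatalityParams.from_config(config)


class TestHazardCalibration:
    def test_homogeneous_cohort_matches_table_exactly(self):
        n = 1000
        scores = np.full(n, 0.03)
        age = np.full(n, 50)
        sex = np.zeros(n, dtype=int)
        inc_cells = np.full(61 * 2, 0.002)
        cal = calibrate_hazards(scores, age, sex, inc_cells)
        np.testing.assert_allclose(cal.hazard(scores, age, sex), 0.002, rtol=1e-12)

    def test_scale_invariance(self):
        """Doubling every score halves every calibration factor."""
        rng = np.random.default_rng(20)
        n = 5000
        scores = rng.uniform(0.01, 0.2, n)
        age = rng.integers(40, 46, n)
        sex = rng.integers(0, 2, n)
        inc = np.full(61 * 2, 0.002)
        c1 = calibrate_hazards(scores, age, sex, inc).factors
        c2 = calibrate_hazards(2 * scores, age, sex, inc).factors
        filled = c1 > 0
        np.testing.assert_allclose(c2[filled], c1[filled] / 2, rtol=1e-12)

    def test_post_calibration_incidence_matches_table(self):
        """One simulated year at 100,000 individuals reproduces the cell
        incidence within 5%."""
        rng = np.random.default_rng(21)
        n = 100000
        scores = rng.lognormal(np.log(0.03), 0.5, n)
        age = rng.integers(40, 46, n)
        sex = rng.integers(0, 2, n)
        inc = np.full(61 * 2, 0.004)
        cal = calibrate_hazards(scores, age, sex, inc)
        h = cal.hazard(scores, age, sex)
        events = rng.random(n) < h
        assert events.mean() == pytest.approx(0.004, rel=0.05)

    def test_sparse_cells_inherit_band_mean(self):
        scores = np.full(10, 0.05)
        age = np.full(10, 50)
        sex = np.zeros(10, dtype=int)
        inc = np.full(61 * 2, 0.002)
        cal = calibrate_hazards(scores, age, sex, inc, min_cell_size=20)
        # the populated cell falls back to the band/sex mean, still yielding
        # the right hazard because all scores are equal
        assert cal.hazard(scores, age, sex)[0] == pytest.approx(0.002)


class TestEventAllocation:
    def _alloc(self, acute, n, age=60, sex_code=0, seed=22):
        rng = np.random.default_rng(seed)
        share = np.full(61 * 2, 0.6)  # 60% of CVD events are IHD
        alloc = CvdAllocationParams(acute=acute, ihd_share_by_cell=share)
        event = np.ones(n, dtype=bool)
        code, fatal = alloc.allocate(
            event, np.full(n, age), np.full(n, sex_code),
            rng.random(n), rng.random(n), rng.random(n),
        )
        return code, fatal

    def test_mi_fraction_among_male_ihd_events(self, acute):
        code, _ = self._alloc(acute, 100000, sex_code=0)
        ihd = (code == EVENT_CODES["mi"]) | (code == EVENT_CODES["other_ihd"])
        mi_frac = (code[ihd] == EVENT_CODES["mi"]).mean()
        assert mi_frac == pytest.approx(0.58, abs=0.01)

    def test_mi_fraction_among_female_ihd_events(self, acute):
        code, _ = self._alloc(acute, 100000, sex_code=1, seed=23)
        ihd = (code == EVENT_CODES["mi"]) | (code == EVENT_CODES["other_ihd"])
        assert (code[ihd] == EVENT_CODES["mi"]).mean() == pytest.approx(0.44, abs=0.01)

    def test_stroke_tia_split_is_60_40(self, acute):
        code, _ = self._alloc(acute, 100000, seed=24)
        cere = (code == EVENT_CODES["stroke"]) | (code == EVENT_CODES["tia"])
        assert (code[cere] == EVENT_CODES["stroke"]).mean() == pytest.approx(0.60, abs=0.01)

    def test_acute_fatality_by_type_and_age(self, acute):
        code, fatal = self._alloc(acute, 200000, age=60, sex_code=0, seed=25)
        mi = code == EVENT_CODES["mi"]
        assert fatal[mi].mean() == pytest.approx(0.32, abs=0.01)
        tia = code == EVENT_CODES["tia"]
        assert not fatal[tia].any()
        stroke = code == EVENT_CODES["stroke"]
        assert fatal[stroke].mean() == pytest.approx(0.07, abs=0.01)
        code_o, fatal_o = self._alloc(acute, 200000, age=85, sex_code=0, seed=26)
        stroke_o = code_o == EVENT_CODES["stroke"]
        assert fatal_o[stroke_o].mean() == pytest.approx(0.24, abs=0.01)


class TestOtherCauseAndBaseline:
    def test_zero_cause_mortality_identity(self):
        qx = np.linspace(0.001, 0.3, 61)
        np.testing.assert_array_equal(other_cause_probability(qx, np.zeros(61)), qx)

    def test_negative_adjustment_floored(self):
        out = other_cause_probability(np.array([0.01]), np.array([0.02]))
        assert out[0] == 0.0

    def test_baseline_prevalence_hit_within_binomial_tolerance(self):
        """Realised baseline prevalence within +-0.3 percentage points of the
        target at n = 200,000; higher-score individuals are flagged more."""
        rng = np.random.default_rng(27)
        n = 200000
        scores = rng.lognormal(np.log(0.03), 0.6, n)
        age = rng.integers(40, 46, n)
        sex = rng.integers(0, 2, n)
        target = 0.02
        prev_cells = np.full(61 * 2, target)
        flags = assign_baseline_disease(scores, age, sex, prev_cells, rng.random(n))
        assert flags.mean() == pytest.approx(target, abs=0.003)
        assert scores[flags].mean() > scores[~flags].mean()

    def test_zero_target_flags_nobody(self):
        rng = np.random.default_rng(28)
        n = 1000
        flags = assign_baseline_disease(
            rng.uniform(0.01, 0.1, n), np.full(n, 42), np.zeros(n, int),
            np.zeros(61 * 2), rng.random(n),
        )
        assert not flags.any()


class TestEngineInvariants:
    def test_no_transitions_after_death_and_conservation(self, sim_3k, config):
        from healthchecksim.engine import ArmPolicy

        res, = sim_3k.run([ArmPolicy.from_config(config)], seed=31)
        st = res.state
        dead = ~np.isnan(st.death_age)
        # event ages never exceed the death age
        for d in ("ihd", "stroke", "dementia", "lung_cancer"):
            has = ~np.isnan(st.first_age[d]) & dead
            assert np.all(st.first_age[d][has] <= st.death_age[has] + 1e-9)
        # conservation: alive + dead = cohort
        assert st.alive.sum() + dead.sum() == res.n
        # first-CVD-event uniqueness: a person has at most one CVD event code
        cvd_flags = (~np.isnan(st.first_age["ihd"])).astype(int) \
            + (~np.isnan(st.first_age["stroke"])).astype(int) \
            + (~np.isnan(st.tia_age)).astype(int)
        assert cvd_flags[st.cvd_event_code >= 0].max() <= 1
        # life-years bounded by follow-up
        assert np.all(st.life_years <= 101 - 40)
        assert np.all(st.qalys <= st.life_years + 1e-9)

    def test_event_log_export(self, sim_3k, config):
        from healthchecksim.engine import ArmPolicy

        res, = sim_3k.run([ArmPolicy.from_config(config)], seed=32)
        log = res.events_frame()
        assert set(log.columns) == {"person", "age", "event", "fatal"}
        assert (log["age"] >= 40).all()


class TestStatinCalibration:
    def test_null_target_with_null_effects(self, sim_3k):
        """Target relative risk 1 with no cholesterol effect calibrates to a
        multiplier of 1."""
        from healthchecksim.health_check import TreatmentEffectParams

        effects = TreatmentEffectParams(
            statin_tc={"male": 0.0, "female": 0.0}, statin_hdl={"male": 0.0, "female": 0.0}
        )
        m = calibrate_statin_multiplier(
            lambda mult: sim_3k.statin_event_ratio(mult, effects=effects), target_5yr_rr=1.0
        )
        assert m == pytest.approx(1.0)

    def test_multiplier_monotone_in_target(self, sim_3k):
        targets = (0.8, 0.7, 0.6)
        mults = [
            calibrate_statin_multiplier(lambda mult: sim_3k.statin_event_ratio(mult), t)
            for t in targets
        ]
        assert mults[0] >= mults[1] >= mults[2]

    def test_unattainable_target_rejected(self, sim_3k):
        with pytest.raises(ValueError):
            calibrate_statin_multiplier(lambda mult: sim_3k.statin_event_ratio(mult), 0.01)
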
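"""Programme process: eligibility, offers, attendance, treatment, adherence."""

import numpy as np
import pytest

from healthchecksim.health_check import (
    AdherenceParams,
    ClipLog,
    EligibilityCriteria,
    OfferAttendParams,
    TreatmentEffectParams,
    TreatmentUptakeParams,
    active_offsets,
    is_eligible,
    referral_deltas_from_counts,
    update_adherence,
)


def _elig(age, diabetes=False, cvd=False, htn=False, criteria=None):
    criteria = criteria or EligibilityCriteria()
    return is_eligible(
        np.array([age]), np.array([diabetes]), np.array([cvd]), np.array([htn]), criteria
    )[0]


class TestEligibility:
    def test_base_case_eligible(self):
        assert _elig(41)

    def test_condition_exclusions(self):
        assert not _elig(41, diabetes=True)
        assert not _elig(41, cvd=True)
        assert not _elig(41, htn=True)

    def test_hypertension_inclusion_scenario(self):
        inclusive = EligibilityCriteria(exclude_hypertension=False)
        assert not _elig(41, htn=True)
        assert _elig(41, htn=True, criteria=inclusive)

    def test_upper_age_extension_scenario(self):
        assert not _elig(76)
        assert _elig(76, criteria=EligibilityCriteria(max_age=79))

    def test_start_age_scenario(self):
        assert _elig(45)
        assert not _elig(45, criteria=EligibilityCriteria(min_age=50))

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            EligibilityCriteria(min_age=80, max_age=74)


class TestOfferProcess:
    def test_mean_gap_between_offers_matches_geometric_law(self):
        """With annual offer probability 0.197 the mean wait between offers
        is 1/0.197 ~ 5.08 years (the once-every-five-years design)."""
        p = OfferAttendParams().annual_offer_prob
        rng = np.random.default_rng(10)
        offers = rng.random((100000, 120)) < p
        waits = 1 + np.argmax(offers, axis=1)  # year of first offer, 1-based
        waits = waits[offers.any(axis=1)]
        assert np.mean(waits) == pytest.approx(1 / p, rel=0.02)

    def test_attendance_normalisation_hits_target_mean(self, cohort_20k):
        params = OfferAttendParams.from_config()
        from healthchecksim.risk_scores import classify_risk_band, cvd_10yr_risk

        band = classify_risk_band(cvd_10yr_risk(cohort_20k))
        covs = dict(
            age=cohort_20k["age"].to_numpy(), sex=cohort_20k["sex"].to_numpy(),
            ethnicity=cohort_20k["ethnicity"].to_numpy(),
            deprivation=cohort_20k["deprivation"].to_numpy(),
            smoking=cohort_20k["smoking"].to_numpy(), qrisk_band=band,
        )
        params.calibrate_base_scale(**covs)
        assert params.attendance_prob(**covs).mean() == pytest.approx(params.mean_prob, rel=1e-9)

    def test_smoker_rate_ratio_below_one(self):
        params = OfferAttendParams.from_config()
        rr = params.rate_ratios["smoking"]
        assert rr["current"] < rr["never"]


class TestTreatmentUptake:
    def test_gates(self):
        uptake = TreatmentUptakeParams()
        probs = uptake.offer_probabilities(
            qrisk_band=np.array(["low", "high"], object),
            sbp=np.array([120.0, 150.0]),
            bmi=np.array([25.0, 32.0]),
            smoking=np.array(["never", "current"], object),
        )
        # never-smoker with low BP and BMI gets no referral probabilities
        assert probs["smoking"][0] == 0.0
        assert probs["antihypertensive"][0] == 0.0
        assert probs["weight"][0] == 0.0
        assert probs["statin"][0] == pytest.approx(0.0205)
        # high-risk hypertensive obese smoker is offered all four
        assert probs["statin"][1] == pytest.approx(0.1423)
        assert probs["antihypertensive"][1] == pytest.approx(0.0248)
        assert probs["smoking"][1] == pytest.approx(0.036)
        assert probs["weight"][1] == pytest.approx(0.275)

    def test_statin_offer_fraction_among_high_risk(self):
        """Among 100,000 high-risk attenders the statin initiation fraction
        approaches 14.23%; the 2.5x scenario approaches 35.6%."""
        n = 100000
        rng = np.random.default_rng(11)
        uptake = TreatmentUptakeParams()
        band = np.full(n, "high", dtype=object)
        p = uptake.offer_probabilities(band, np.full(n, 120.0), np.full(n, 25.0),
                                       np.full(n, "never", object))["statin"]
        frac = (rng.random(n) < p).mean()
        assert frac == pytest.approx(0.1423, abs=0.004)
        uptake.multipliers["statin"] = 2.5
        p2 = uptake.offer_probabilities(band, np.full(n, 120.0), np.full(n, 25.0),
                                        np.full(n, "never", object))["statin"]
        frac2 = (rng.random(n) < p2).mean()
        assert frac2 == pytest.approx(0.1423 * 2.5, abs=0.006)

    def test_multiplier_clipping_counted(self):
        uptake = TreatmentUptakeParams(weight_referral=0.8)
        uptake.multipliers["weight"] = 2.5
        clip = ClipLog()
        probs = uptake.offer_probabilities(
            np.array(["low"], object), np.array([120.0]), np.array([35.0]),
            np.array(["never"], object), clip=clip,
        )
        assert probs["weight"][0] == 1.0
        assert clip.report()["uptake.weight"] == 1

    def test_referral_deltas_recomputed_from_counts(self, config):
        """Programme-attributable referral probabilities re-derived from the
        attender / non-attender evaluation counts match the configured
        values to a tenth of a percent."""
        deltas = referral_deltas_from_counts(config["health_check"]["uptake"]["source_counts"])
        assert deltas["smoking"] * 100 == pytest.approx(3.6, abs=0.1)
        assert deltas["weight"] * 100 == pytest.approx(27.5, abs=0.1)


class TestAdherence:
    def test_zero_discontinuation_is_permanent(self):
        on = np.ones(1000, dtype=bool)
        rng = np.random.default_rng(12)
        for _ in range(30):
            on = update_adherence(on, 0.0, rng.random(1000))
        assert on.all()

    def test_statin_persistence_follows_geometric_decay(self):
        """Fraction on statins t years after offer is 0.5 x 0.95^t."""
        n = 100000
        rng = np.random.default_rng(13)
        adherence = AdherenceParams()
        on = rng.random(n) < adherence.statin_initial
        for t in range(1, 9):
            on = update_adherence(on, adherence.annual_discontinuation, rng.random(n))
            expected = adherence.statin_initial * (1 - adherence.annual_discontinuation) ** t
            assert on.mean() == pytest.approx(expected, abs=0.006)

    def test_discontinuation_absorbing(self):
        on = np.array([False] * 10)
        out = update_adherence(on, 0.0, np.zeros(10))
        assert not out.any()


class TestActiveOffsets:
    def test_statin_offsets_by_sex(self):
        effects = TreatmentEffectParams.from_config()
        offs = active_offsets(
            effects, np.array(["male", "female"], object), np.array([50, 50]),
            on_statin=np.array([True, True]), on_aht=np.array([False, False]),
            years_since_weight=np.array([0, 0]),
        )
        assert offs["tc"][0] == pytest.approx(-1.22)
        assert offs["tc"][1] == pytest.approx(-1.16)
        assert offs["hdl"][0] == pytest.approx(0.04)
        assert offs["hdl"][1] == pytest.approx(0.036)
        assert offs["sbp"][0] == 0.0

    def test_bp_drug_class_by_age_threshold(self):
        effects = TreatmentEffectParams.from_config()
        offs = active_offsets(
            effects, np.array(["female", "female", "male"], object), np.array([50, 60, 60]),
            on_statin=np.zeros(3, bool), on_aht=np.ones(3, bool),
            years_since_weight=np.zeros(3, int),
        )
        assert offs["sbp"][0] == pytest.approx(-6.29)   # ACE inhibitor under 55
        assert offs["dbp"][0] == pytest.approx(-4.14)
        assert offs["sbp"][1] == pytest.approx(-9.0)    # CCB, woman 55+
        assert offs["dbp"][1] == pytest.approx(-3.5)
        assert offs["sbp"][2] == pytest.approx(-7.6)    # CCB, man 55+
        assert offs["dbp"][2] == pytest.approx(-3.1)

    def test_weight_schedule_regains_by_year_five(self):
        effects = TreatmentEffectParams.from_config()
        sex = np.array(["male"] * 7, object)
        offs = active_offsets(
            effects, sex, np.full(7, 50), np.zeros(7, bool), np.zeros(7, bool),
            years_since_weight=np.arange(7),
        )
        np.testing.assert_allclose(offs["bmi"], [0.0, -1.5, -0.9, -0.6, -0.3, 0.0, 0.0])

    def test_no_treatment_no_offsets(self):
        effects = TreatmentEffectParams.from_config()
        offs = active_offsets(
            effects, np.array(["male"], object), np.array([50]),
            np.array([False]), np.array([False]), np.array([0]),
        )
        assert all(v[0] == 0.0 for v in offs.values())
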
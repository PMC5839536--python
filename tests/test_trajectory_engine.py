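"""Donor matching, annual factor advancement, offsets and relapse."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from healthchecksim.config import FACTORS
from healthchecksim.synthetic_data import PanelDataset
from healthchecksim.trajectory_engine import (
    DonorMatcher,
    MatchKey,
    advance_year,
    apply_offsets,
    match_donor,
    smoking_relapse,
)


def _panel_from_rows(rows):
    return PanelDataset(pd.DataFrame(rows))


def _donor_row(person_id, age=50, sex="male", smoking="never", sbp=120.0, dsbp=0.0, quit=False):
    row = {
        "person_id": person_id, "wave": 0, "age": age, "sex": sex, "smoking": smoking,
        "smoking_next": "ex" if quit else smoking,
    }
    for f in FACTORS:
        row[f] = sbp if f == "sbp" else 1.0
        row[f + "_next"] = (sbp + dsbp) if f == "sbp" else 1.0
    return row


def _query(age=50, sex="male", smoking="never", sbp=120.0):
    d = {"age": age, "sex": sex, "smoking": smoking}
    for f in FACTORS:
        d[f] = sbp if f == "sbp" else 1.0
    return d


class TestMatching:
    def test_exact_donor_always_selected_with_k1(self):
        panel = _panel_from_rows([
            _donor_row(0, sbp=120.0), _donor_row(1, sbp=180.0), _donor_row(2, sbp=200.0),
        ])
        key = MatchKey(k_neighbours=1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            donor = match_donor(_query(sbp=120.0), panel, key, rng)
            assert donor["person_id"] == 0

    def test_uniform_selection_among_tied_neighbours(self):
        """Ten identical donors: selection frequencies are uniform (chi-square
        goodness of fit, p > 0.01 over 10,000 draws)."""
        panel = _panel_from_rows([_donor_row(i, sbp=120.0) for i in range(10)])
        matcher = DonorMatcher(panel, MatchKey(k_neighbours=10))
        rng = np.random.default_rng(1)
        n_draws = 10000
        q = _query()
        sex = np.full(n_draws, "male", dtype=object)
        smoking = np.full(n_draws, "never", dtype=object)
        covs = {c: np.full(n_draws, float(q[c])) for c in matcher.key.covariates}
        picks = matcher.match(sex, smoking, covs, rng)
        counts = np.bincount(picks, minlength=10)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_nearest_neighbour_dominance(self):
        """The chosen donor is never farther than any donor outside the
        k-nearest set."""
        rng0 = np.random.default_rng(2)
        rows = [_donor_row(i, sbp=float(s)) for i, s in enumerate(rng0.uniform(100, 180, 50))]
        panel = _panel_from_rows(rows)
        key = MatchKey(k_neighbours=5)
        matcher = DonorMatcher(panel, key)
        q = _query(sbp=140.0)
        rng = np.random.default_rng(3)
        covs = {c: np.array([float(q[c])]) for c in key.covariates}
        pick = matcher.match(np.array(["male"], object), np.array(["never"], object), covs, rng)[0]
        dist = np.abs(panel.df["sbp"].to_numpy() - 140.0)  # only sbp varies
        k_set = np.argsort(dist, kind="stable")[:5]
        assert dist[pick] <= dist[np.setdiff1d(np.arange(50), k_set)].min() + 1e-12

    def test_advance_with_zero_change_panel_keeps_factors(self):
        panel = _panel_from_rows([_donor_row(i, sbp=120.0, dsbp=0.0) for i in range(5)])
        matcher = DonorMatcher(panel, MatchKey(k_neighbours=3))
        n = 50
        factors = {f: np.full(n, 120.0 if f == "sbp" else 1.0) for f in FACTORS}
        before = {f: v.copy() for f, v in factors.items()}
        rng = np.random.default_rng(4)
        factors, smoking = advance_year(
            factors, np.full(n, 50), np.full(n, "male", object),
            np.full(n, "never", object), matcher, rng,
        )
        for f in FACTORS:
            np.testing.assert_array_equal(factors[f], before[f])

    def test_never_smokers_stay_never(self):
        panel = _panel_from_rows(
            [_donor_row(i, smoking="never") for i in range(3)]
            + [_donor_row(i + 3, smoking="current", quit=True) for i in range(3)]
        )
        matcher = DonorMatcher(panel, MatchKey(k_neighbours=2))
        n = 100
        factors = {f: np.full(n, 120.0 if f == "sbp" else 1.0) for f in FACTORS}
        smoking = np.full(n, "never", dtype=object)
        rng = np.random.default_rng(5)
        for _ in range(10):
            factors, smoking = advance_year(
                factors, np.full(n, 50), np.full(n, "male", object), smoking, matcher, rng
            )
        assert (smoking == "never").all()

    def test_population_drift_tracks_panel_age_trend(self, config, matcher):
        """Mean simulated SBP drift per year over 20 years stays within
        0.5 mmHg/year of the panel's configured age trend."""
        n = 10000
        rng_pop = np.random.default_rng(6)
        factors = {f: np.full(n, {"sbp": 122.6, "dbp": 75.2, "tc": 5.5, "hdl": 1.37,
                                  "bmi": 27.5, "hba1c": 5.6}[f]) for f in FACTORS}
        smoking = np.full(n, "never", dtype=object)
        sex = np.full(n, "male", dtype=object)
        age = np.full(n, 45)
        start = factors["sbp"].mean()
        rng = np.random.default_rng(7)
        years = 20
        for y in range(years):
            factors, smoking = advance_year(factors, age + y, sex, smoking, matcher, rng)
        drift_per_year = (factors["sbp"].mean() - start) / years
        assert abs(drift_per_year - config["panel"]["age_trend"]["sbp"]) < 0.5


class TestOffsets:
    def test_no_offsets_is_identity(self):
        cf = {f: np.array([100.0, 50.0]) for f in FACTORS}
        out = apply_offsets(cf, {})
        for f in FACTORS:
            np.testing.assert_array_equal(out[f], cf[f])

    def test_offsets_additive_and_independent(self):
        cf = {f: np.array([100.0]) for f in FACTORS}
        out = apply_offsets(cf, {"tc": np.array([-1.22]), "sbp": np.array([-7.6])})
        assert out["tc"][0] == pytest.approx(100.0 - 1.22)
        assert out["sbp"][0] == pytest.approx(100.0 - 7.6)
        assert out["bmi"][0] == 100.0

    def test_unknown_factor_rejected(self):
        cf = {f: np.array([1.0]) for f in FACTORS}
        with pytest.raises(KeyError):
            apply_offsets(cf, {"glucose": np.array([1.0])})


class TestRelapse:
    def test_zero_hazard_means_permanent_quit(self):
        rng = np.random.default_rng(8)
        assert not smoking_relapse(1000, 0.0, rng).any()

    def test_geometric_survival_at_constant_hazard(self):
        """At constant hazard h the fraction still quit after t years is
        (1-h)^t (10,000 simulants)."""
        rng = np.random.default_rng(9)
        n, h, t = 10000, 0.08, 6
        quit_flag = np.ones(n, dtype=bool)
        for _ in range(t):
            relapsed = smoking_relapse(n, h, rng)
            quit_flag &= ~relapsed
        expected = (1 - h) ** t
        assert quit_flag.mean() == pytest.approx(expected, abs=0.015)

    def test_panel_relapse_rate_annualisation(self, panel_10k, config):
        """Annualised ex->current rate is consistent with the per-wave
        relapse probability."""
        per_wave = config["panel"]["smoking_relapse_prob_per_wave"]
        expected = 1 - (1 - per_wave) ** 0.5
        assert panel_10k.annual_relapse_rate() == pytest.approx(expected, abs=0.005)
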
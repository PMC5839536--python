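"""Individual risk scores.

Two deterministic scores drive disease hazards in the simulation:

* a Cox-type 10-year cardiovascular risk score,
  ``risk = 1 - S0(10) ** exp(lp)``, with a sex-specific baseline survival
  and a linear predictor centred at a reference profile (a reduced
  coefficient set over the covariates present in the synthetic cohort;
  a full published set of the same file shape can be substituted);
* a point-based 20-year dementia risk score from midlife cardiovascular
  risk factors (age band, education, sex, and SBP/BMI/cholesterol
  thresholds) with a monotone points-to-risk mapping.

Both accept a cohort DataFrame (or mapping of equal-length arrays) and
return a float array; scalars work through one-row frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SEXES, load_json_data

logger = logging.getLogger(__name__)

#: Validity range of the CVD score; ages outside are clamped with a warning.
CVD_AGE_RANGE = (25, 84)

CVD_REQUIRED = (
    "age", "sex", "ethnicity", "deprivation", "sbp", "tc", "hdl",
    "bmi", "smoking", "diabetes", "treated_hypertension",
)
BAND_LABELS = ("low", "medium", "high")


class MissingCovariateError(KeyError):
    pass


def _columns(data, required) -> dict[str, np.ndarray]:
    cols = {}
    for name in required:
        try:
            col = data[name]
        except (KeyError, IndexError) as exc:
            raise MissingCovariateError(f"missing covariate '{name}'") from exc
        cols[name] = np.asarray(col)
    return cols


@dataclass
class CvdCoefficientSet:
    """Versioned coefficient file for the 10-year CVD risk score."""

    params: dict

    def __post_init__(self):
        for sex in SEXES:
            s0 = self.params[sex]["baseline_survival_10yr"]
            if not 0.0 < s0 < 1.0:
                raise ValueError(f"baseline 10-year survival for {sex} must lie in (0,1)")

    @classmethod
    def default(cls) -> "CvdCoefficientSet":
        return cls(load_json_data("qrisk_coefficients.json"))

    @classmethod
    def null(cls) -> "CvdCoefficientSet":
        """All-zero coefficients (risk = 1 - S0 for everyone); test utility."""
        import copy

        p = copy.deepcopy(load_json_data("qrisk_coefficients.json"))
        for sex in SEXES:
            c = p[sex]["coefficients"]
            for k in c:
                c[k] = {e: 0.0 for e in c[k]} if isinstance(c[k], dict) else 0.0
        return cls(p)

    def linear_predictor(self, data) -> np.ndarray:
        cols = _columns(data, CVD_REQUIRED)
        n = len(cols["age"])
        age = cols["age"].astype(float)
        out_of_range = (age < CVD_AGE_RANGE[0]) | (age > CVD_AGE_RANGE[1])
        if out_of_range.any():
            logger.warning(
                "CVD score: %d ages outside validity range %s clamped",
                int(out_of_range.sum()), CVD_AGE_RANGE,
            )
            age = np.clip(age, *CVD_AGE_RANGE)
        tchdl = cols["tc"].astype(float) / cols["hdl"].astype(float)
        lp = np.zeros(n)
        for sex in SEXES:
            m = cols["sex"] == sex
            if not m.any():
                continue
            ref = self.params[sex]["reference"]
            co = self.params[sex]["coefficients"]
            da = age[m] - ref["age"]
            lp_s = (
                co["age"] * da
                + co.get("age_squared", 0.0) * da * da
                + co["sbp"] * (cols["sbp"][m].astype(float) - ref["sbp"])
                + co["tchdl"] * (tchdl[m] - ref["tchdl"])
                + co["bmi"] * (cols["bmi"][m].astype(float) - ref["bmi"])
                + co["deprivation"] * (cols["deprivation"][m].astype(float) - ref["deprivation"])
                + co["diabetes"] * cols["diabetes"][m].astype(float)
                + co["treated_hypertension"] * cols["treated_hypertension"][m].astype(float)
            )
            smoking = cols["smoking"][m]
            lp_s = lp_s + np.where(
                smoking == "current", co["smoking_current"],
                np.where(smoking == "ex", co["smoking_ex"], 0.0),
            )
            eth = co["ethnicity"]
            lp_s = lp_s + np.vectorize(lambda e: eth[e])(cols["ethnicity"][m]).astype(float)
            lp[m] = lp_s
        return lp

    def baseline_survival(self, sex_col: np.ndarray) -> np.ndarray:
        s0 = np.empty(len(sex_col))
        for sex in SEXES:
            s0[sex_col == sex] = self.params[sex]["baseline_survival_10yr"]
        return s0


def cvd_10yr_risk(data, coeffs: CvdCoefficientSet | None = None) -> np.ndarray:
    """10-year first-CVD-event risk, ``1 - S0(10) ** exp(lp)``, in (0, 1)."""
    coeffs = coeffs or CvdCoefficientSet.default()
    if isinstance(data, pd.Series):
        data = data.to_frame().T
    lp = coeffs.linear_predictor(data)
    s0 = coeffs.baseline_survival(np.asarray(data["sex"]))
    return 1.0 - s0 ** np.exp(lp)


@dataclass
class CaidePointsTable:
    """Point assignments and the monotone points-to-risk mapping for the
    20-year dementia risk score."""

    params: dict

    def __post_init__(self):
        mapping = self.params["risk_mapping"]
        risks = [m["risk"] for m in mapping]
        if any(b < a for a, b in zip(risks, risks[1:])):
            raise ValueError("risk mapping must be monotone non-decreasing in points")
        points = (
            [b["points"] for b in self.params["age_bands"]]
            + list(self.params["education"].values())
            + list(self.params["sex"].values())
            + [self.params[k] for k in ("sbp_points", "bmi_points", "tc_points", "activity_points")]
        )
        if any(p < 0 or int(p) != p for p in points):
            raise ValueError("points must be non-negative integers")

    @classmethod
    def default(cls) -> "CaidePointsTable":
        return cls(load_json_data("caide_points.json"))

    def points(self, data) -> np.ndarray:
        cols = _columns(data, ("age", "education", "sex", "sbp", "bmi", "tc"))
        p = self.params
        age = cols["age"].astype(float)
        pts = np.zeros(len(age), dtype=int)
        prev_max = -np.inf
        for band in p["age_bands"]:
            pts += np.where((age > prev_max) & (age <= band["max_age"]), band["points"], 0)
            prev_max = band["max_age"]
        pts += np.vectorize(lambda e: p["education"][e])(cols["education"]).astype(int)
        pts += np.vectorize(lambda s: p["sex"][s])(cols["sex"]).astype(int)
        pts += np.where(cols["sbp"].astype(float) > p["sbp_threshold"], p["sbp_points"], 0)
        pts += np.where(cols["bmi"].astype(float) > p["bmi_threshold"], p["bmi_points"], 0)
        pts += np.where(cols["tc"].astype(float) > p["tc_threshold"], p["tc_points"], 0)
        pts += int(p["activity_points"])
        return pts

    def risk_from_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts)
        mapping = self.params["risk_mapping"]
        if np.any(pts > mapping[-1]["max_points"]) or np.any(pts < 0):
            raise ValueError("points outside the risk-mapping domain")
        risk = np.empty(pts.shape, dtype=float)
        prev_max = -1
        for m in mapping:
            sel = (pts > prev_max) & (pts <= m["max_points"])
            risk[sel] = m["risk"]
            prev_max = m["max_points"]
        return risk


def dementia_20yr_risk(data, table: CaidePointsTable | None = None) -> np.ndarray:
    """20-year dementia risk from the summed component points."""
    table = table or CaidePointsTable.default()
    if isinstance(data, pd.Series):
        data = data.to_frame().T
    return table.risk_from_points(table.points(data))


def classify_risk_band(risk10, thresholds: tuple[float, float] = (0.10, 0.20)) -> np.ndarray:
    """Treatment-uptake risk band: low < 10%, medium 10-20%, high >= 20%.

    The 20% boundary itself is assigned to the high band.
    """
    r = np.atleast_1d(np.asarray(risk10, dtype=float))
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risk must lie in [0, 1]")
    lo, hi = thresholds
    return np.asarray(BAND_LABELS, dtype=object)[(r >= lo).astype(int) + (r >= hi).astype(int)]
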
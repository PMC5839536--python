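"""Annual risk-factor trajectories by nonparametric donor matching.

Each simulated individual is matched every year to a donor person-wave
transition in the longitudinal panel with similar characteristics: exact
match on sex and smoking status, weighted Euclidean distance on standardised
continuous covariates (age and current factor levels), uniform choice among
the k nearest donors.  The donor's observed biennial change, scaled by the
annual interpolation factor, is added to the individual's counterfactual
factor path; the treated path is the counterfactual plus the currently
active treatment offsets (no interaction between treatments, no washout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import FACTORS, SMOKING_LEVELS, load_default_config
from .synthetic_data import PanelDataset

logger = logging.getLogger(__name__)


@dataclass
class MatchKey:
    """Donor-matching configuration: covariates, weights, neighbourhood size."""

    covariates: list[str] = field(default_factory=lambda: ["age", *FACTORS])
    weights: dict[str, float] = field(default_factory=dict)
    k_neighbours: int = 10
    annual_interpolation: float = 0.5
    max_distance: float = np.inf

    def __post_init__(self):
        if "age" not in self.covariates:
            raise ValueError("matching covariates must include age")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("matching weights must be non-negative")

    @classmethod
    def from_config(cls, config: dict | None = None) -> "MatchKey":
        config = config if config is not None else load_default_config()
        m = config["matching"]
        return cls(
            covariates=list(m["covariates"]),
            weights=dict(m["weights"]),
            k_neighbours=int(m["k_neighbours"]),
            annual_interpolation=float(m["annual_interpolation"]),
        )


class DonorMatcher:
    """KD-tree donor lookup over the panel, grouped by (sex, smoking)."""

    def __init__(self, panel: PanelDataset, key: MatchKey | None = None):
        self.key = key or MatchKey()
        self.panel = panel
        df = panel.df
        self._scale = {}
        for cov in self.key.covariates:
            sd = float(df[cov].std())
            w = self.key.weights.get(cov, 1.0)
            self._scale[cov] = w / sd if sd > 0 else 0.0
        # annualised factor deltas per donor record
        self.deltas = {
            f: (df[f + "_next"].to_numpy() - df[f].to_numpy()) * self.key.annual_interpolation
            for f in FACTORS
        }
        self.smoking_next = df["smoking_next"].to_numpy()
        self.smoking_now = df["smoking"].to_numpy()
        self._groups: dict[tuple[str, str], tuple[cKDTree, np.ndarray]] = {}
        sex_arr = df["sex"].to_numpy()
        for sex in ("male", "female"):
            for smoking in SMOKING_LEVELS:
                idx = np.flatnonzero((sex_arr == sex) & (self.smoking_now == smoking))
                if len(idx) == 0:
                    idx = np.flatnonzero(sex_arr == sex)  # fallback pool
                    if len(idx) == 0:
                        continue
                    logger.warning("no %s/%s donors; falling back to all %s donors", sex, smoking, sex)
                X = self._standardise(df.iloc[idx])
                self._groups[(sex, smoking)] = (cKDTree(X), idx)
        if not self._groups:
            raise ValueError("panel is empty")

    def _standardise(self, data) -> np.ndarray:
        return np.column_stack([
            np.asarray(data[cov], dtype=float) * self._scale[cov] for cov in self.key.covariates
        ])

    def match(
        self,
        sex: np.ndarray,
        smoking: np.ndarray,
        covariates: dict[str, np.ndarray],
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Return one donor record index per query individual.

        For each individual the k nearest same-sex, same-smoking donors are
        found and one is drawn uniformly.  If no donor lies within
        ``max_distance`` the single nearest donor is used (logged).
        """
        n = len(sex)
        out = np.full(n, -1, dtype=int)
        X_all = np.column_stack([
            np.asarray(covariates[cov], dtype=float) * self._scale[cov]
            for cov in self.key.covariates
        ])
        for (gsex, gsmoke), (tree, idx) in self._groups.items():
            sel = np.flatnonzero((sex == gsex) & (smoking == gsmoke))
            if len(sel) == 0:
                continue
            k = min(self.key.k_neighbours, len(idx))
            dist, nbr = tree.query(X_all[sel], k=k, workers=-1)
            if k == 1:
                dist, nbr = dist[:, None], nbr[:, None]
            pick = rng.integers(0, k, size=len(sel))
            if np.isfinite(self.key.max_distance):
                beyond = dist[np.arange(len(sel)), pick] > self.key.max_distance
                if beyond.any():
                    logger.warning(
                        "%d matches beyond max_distance; using nearest donor", int(beyond.sum())
                    )
                    pick[beyond] = 0
            out[sel] = idx[nbr[np.arange(len(sel)), pick]]
        if np.any(out < 0):
            raise ValueError("some individuals found no donor group for their sex")
        return out


def match_donor(individual, panel: PanelDataset, key: MatchKey, rng: np.random.Generator):
    """Match a single individual; returns the donor person-wave record."""
    matcher = DonorMatcher(panel, key)
    covs = {c: np.array([individual[c]]) for c in key.covariates}
    idx = matcher.match(
        np.array([individual["sex"]]), np.array([individual["smoking"]]), covs, rng
    )
    return panel.df.iloc[idx[0]]


def advance_year(
    factors: dict[str, np.ndarray],
    age: np.ndarray,
    sex: np.ndarray,
    smoking: np.ndarray,
    matcher: DonorMatcher,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Advance counterfactual factors and smoking status by one year.

    Each factor is incremented by the matched donor's interpolated annual
    change; the donor's smoking transition (quit or relapse over a biennial
    wave) is applied with probability equal to the interpolation factor.
    Never-smokers never transition.  Only ``mask`` rows are advanced.
    Ages are not modified here; the caller owns the clock.
    """
    mask = np.ones(len(age), dtype=bool) if mask is None else mask
    sel = np.flatnonzero(mask)
    if len(sel) == 0:
        return factors, smoking
    covs = {c: (age[sel] if c == "age" else factors[c][sel]) for c in matcher.key.covariates}
    donors = matcher.match(sex[sel], smoking[sel], covs, rng)
    for f in FACTORS:
        upd = factors[f].copy()
        upd[sel] = np.maximum(upd[sel] + matcher.deltas[f][donors], 0.1)
        factors[f] = upd
    d_now, d_next = matcher.smoking_now[donors], matcher.smoking_next[donors]
    transitioned = d_now != d_next
    apply = transitioned & (rng.random(len(sel)) < matcher.key.annual_interpolation)
    new_smoking = smoking.copy()
    tgt = new_smoking[sel]
    valid = apply & (tgt != "never")  # never-smokers are absorbing
    tgt[valid] = d_next[valid]
    new_smoking[sel] = tgt
    return factors, new_smoking


@dataclass
class TrajectoryPair:
    """Counterfactual and treated factor paths for one individual or cohort.

    The treated path is always the counterfactual plus the sum of currently
    active treatment offsets; paths coincide before the first health-check
    treatment and snap back on discontinuation.
    """

    counterfactual: dict[str, np.ndarray]
    offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def treated(self) -> dict[str, np.ndarray]:
        return apply_offsets(self.counterfactual, self.offsets)


def apply_offsets(
    counterfactual: dict[str, np.ndarray], offsets: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Treated factor values: counterfactual + active offsets, additively and
    without interaction terms.  Unknown factor names are an error."""
    unknown = set(offsets) - set(FACTORS)
    if unknown:
        raise KeyError(f"offsets for unknown factors: {sorted(unknown)}")
    return {
        f: np.maximum(np.asarray(counterfactual[f]) + np.asarray(offsets.get(f, 0.0)), 0.1)
        for f in counterfactual
    }


def smoking_relapse(
    n_quitters: int,
    annual_hazard: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One year of relapse draws for programme quitters.

    The hazard is the panel's ex-to-current annual transition rate scaled by
    the configured adjustment factor (computed by the caller).
    """
    if annual_hazard <= 0:
        return np.zeros(n_quitters, dtype=bool)
    return rng.random(n_quitters) < annual_hazard
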
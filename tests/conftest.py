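import numpy as np
import pytest

import healthchecksim as hcs
from healthchecksim.config import DynamicsParams, PopulationSpec
from healthchecksim.scenarios import derive_rate_tables
from healthchecksim.trajectory_engine import DonorMatcher, MatchKey


@pytest.fixture(scope="session")
def config():
    return hcs.load_default_config()


@pytest.fixture(scope="session")
def rate_tables(config):
    tables, lifetable = derive_rate_tables(config)
    return tables, lifetable


@pytest.fixture(scope="session")
def cohort_20k(config):
    spec = PopulationSpec.from_config(config, n_individuals=20000, seed=42)
    return hcs.generate_population(spec)


@pytest.fixture(scope="session")
def panel_10k(config):
    spec = PopulationSpec.from_config(config, n_individuals=100, seed=43)
    dynamics = DynamicsParams.from_config(config)
    return hcs.generate_panel(spec, dynamics, seed=43)


@pytest.fixture(scope="session")
def matcher(panel_10k, config):
    return DonorMatcher(panel_10k, MatchKey.from_config(config))


@pytest.fixture(scope="session")
def sim_3k(config, rate_tables):
    tables, lifetable = rate_tables
    return hcs.build_simulation(config, n_individuals=3000, seed=7, n_panel=3000,
                                tables=tables, lifetable=lifetable)


@pytest.fixture(scope="session")
def sim_20k(config, rate_tables):
    tables, lifetable = rate_tables
    return hcs.build_simulation(config, n_individuals=20000, seed=17, n_panel=8000,
                                tables=tables, lifetable=lifetable)


@pytest.fixture(scope="session")
def headline_run_100k(config, rate_tables):
    """One full paired run of the current programme vs no programme at
    n = 100,000, shared by the large-sample checks."""
    tables, lifetable = rate_tables
    sim = hcs.build_simulation(config, n_individuals=100000, seed=11, n_panel=10000,
                               tables=tables, lifetable=lifetable)
    return hcs.run_pair("base", "no_programme", master_seed=11, sim=sim, config=config)


@pytest.fixture(scope="session")
def psa_30(config):
    """A 30-run probabilistic sensitivity analysis at desk scale, shared by
    the uncertainty-property checks."""
    from healthchecksim.uncertainty import psa

    return psa("base", "no_programme", master_seed=21, n_runs=30,
               n_individuals=1500, config=config)


def mc_forward_illness_death(incidence, case_fatality, background, n=100000, prev0=0.0, seed=0):
    """Independent Monte-Carlo three-state oracle used to cross-check the
    deterministic recurrence and the solver.

    Mirrors the stated cycle conventions: incident cases arise mid-year with
    half-year case-fatality exposure; background mortality independent.
    """
    rng = np.random.default_rng(seed)
    ill = rng.random(n) < prev0
    alive = np.ones(n, dtype=bool)
    prev, cm = [], []
    for i, f, mb in zip(incidence, case_fatality, background):
        n_alive = alive.sum()
        prev.append(ill[alive].mean() if n_alive else 0.0)
        u1, u2, u3 = rng.random(n), rng.random(n), rng.random(n)
        new = alive & ~ill & (u1 < i)
        half = 1.0 - np.sqrt(1.0 - f)
        die_cause = (alive & ill & (u2 < f)) | (new & (u2 < half))
        ill = ill | new
        die_bg = alive & (u3 < mb)
        cm.append(die_cause.sum() / n_alive if n_alive else 0.0)
        alive = alive & ~die_cause & ~die_bg
    return np.array(prev), np.array(cm)
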
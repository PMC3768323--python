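"""Shared fixtures: the expensive equilibrium runs are computed once per session."""

import numpy as np
import pytest

import mitoinherit as mi
from mitoinherit import experiments as xp
from mitoinherit.lifecycle import DiploidPopulation, Haplotype


@pytest.fixture(scope="session")
def base_params():
    """The standard study condition: M=50, mu=0.01, concave fitness, AxA BPI."""
    return mi.ModelParams(M=50, mu=0.01)


@pytest.fixture(scope="session")
def base_invasion(base_params):
    """Invasion of A into a pure-a population at the standard condition."""
    return mi.run_invasion(base_params)


@pytest.fixture(scope="session")
def base_report(base_invasion, base_params):
    return mi.classify_equilibrium(base_invasion, base_params)


@pytest.fixture(scope="session")
def merged_params():
    """High mutation pressure where E1 merges with E2: M=100, mu=0.1."""
    return mi.ModelParams(M=100, mu=0.1)


@pytest.fixture(scope="session")
def merged_report(merged_params):
    traj = mi.run_invasion(merged_params)
    return mi.classify_equilibrium(traj, merged_params)


@pytest.fixture(scope="session")
def bpi_baseline(base_params):
    """Pure-biparental population at mutation-selection balance."""
    pop = DiploidPopulation.monomorphic(base_params.M, Haplotype("a"), 0)
    pop, records, converged, _ = xp.iterate_to_convergence(pop, base_params)
    assert converged
    return pop, records[-1]


def postintro_records(traj):
    """Records strictly after the invader's introduction."""
    g0 = traj.introduction_generation
    return [s for s in traj.records if s.generation > g0]


@pytest.fixture(scope="session")
def uniform_random_dists():
    """Deterministic grid of parental gamete distributions (capacity 25)."""
    rng = np.random.default_rng(20130122)
    return [rng.dirichlet(np.full(26, 0.3)) for _ in range(25)]
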
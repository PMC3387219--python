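"""Shared fixtures: hand-built toy networks and small designed universes."""

from fractions import Fraction

import numpy as np
import pytest

from synmet import fba
from synmet.universe import (
    EXTERNAL,
    INTERNAL,
    KIND_EXCHANGE,
    KIND_TRANSPORT,
    ROLE_BIOMASS,
    ROLE_CARBON_SOURCE,
    Metabolite,
    Reaction,
    ReactionUniverse,
    UniverseConfig,
    generate_universe,
)


def _f(x):
    return Fraction(x)


@pytest.fixture
def t1_universe():
    """Hand-built toy: Cx(6C) -> C -> 2 H(3C); H -> B1(3C); H -> 3 CO2.

    The single productive route gives Z = 2 x uptake at the drain; the CO2
    branch is a vent that is never needed at the optimum.
    """
    mets = [
        Metabolite("Cx", "source", 6, EXTERNAL, frozenset({ROLE_CARBON_SOURCE})),
        Metabolite("C", "source (cytosol)", 6, INTERNAL),
        Metabolite("H", "hub", 3, INTERNAL),
        Metabolite("B1", "biomass", 3, INTERNAL, frozenset({ROLE_BIOMASS})),
        Metabolite("CO2", "carbon dioxide", 1, INTERNAL),
        Metabolite("CO2_x", "carbon dioxide (external)", 1, EXTERNAL),
    ]
    rxns = [
        Reaction("T_Cx", {"Cx": _f(-1), "C": _f(1)}, kind=KIND_TRANSPORT),
        Reaction("EX_Cx", {"Cx": _f(-1)}, kind=KIND_EXCHANGE),
        Reaction("R1", {"C": _f(-1), "H": _f(2)}),
        Reaction("R2", {"H": _f(-1), "B1": _f(1)}),
        Reaction("R3", {"H": _f(-1), "CO2": _f(3)}),
        Reaction("T_CO2", {"CO2": _f(-1), "CO2_x": _f(1)}, kind=KIND_TRANSPORT),
        Reaction("EX_CO2", {"CO2_x": _f(-1)}, kind=KIND_EXCHANGE),
    ]
    return ReactionUniverse.from_parts(mets, rxns, ["Cx"], ["B1"])


@pytest.fixture
def t1_lossy_universe(t1_universe):
    """T1 with R1 replaced by the lossy R1': C -> H + 3 CO2 (6 = 3 + 3)."""
    u = t1_universe
    rxns = [r for r in u.reactions.values() if r.id != "R1"]
    rxns.append(Reaction("R1p", {"C": _f(-1), "H": _f(1), "CO2": _f(3)}))
    return ReactionUniverse.from_parts(u.metabolites.values(), rxns, ["Cx"], ["B1"])


@pytest.fixture
def t1_env(t1_universe):
    return fba.Environment.minimal_medium(t1_universe, "Cx", 10.0)


@pytest.fixture
def t1_spec():
    return fba.BiomassSpec.weighted({"B1": 1.0})


@pytest.fixture(scope="session")
def small_universe():
    """The worked design: 3 sources, 2 targets, L_N=2, L_B=3, redundancy 1."""
    return generate_universe(UniverseConfig(
        n_carbon_sources=3, n_biomass_candidates=2, L_N=2, L_B=3,
        redundancy_factor=1, n_waste_branches=1, seed=7))


@pytest.fixture(scope="session")
def small_envs(small_universe):
    return [fba.Environment.minimal_medium(small_universe, c)
            for c in small_universe.carbon_sources]


@pytest.fixture(scope="session")
def small_spec(small_universe):
    return fba.BiomassSpec.isostoichiometric(small_universe.biomass_candidates)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
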
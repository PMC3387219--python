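"""Steady-state flux balance analysis.

Given a genotype (a subset of the universe's internal reactions, plus the
fixed transport/exchange infrastructure), a minimal sole-carbon-source
environment and a biomass specification, this module builds the
stoichiometric system S v = 0 with bounds a <= v <= b and maximizes the
flux through a biomass drain reaction by linear programming.  The drain
consumes every target molecule in proportion to its stoichiometric weight,
so a positive drain flux certifies that all targets are synthesizable
simultaneously.

By default a second, parsimonious LP is solved after the maximization:
total absolute flux is minimized at the fixed biomass optimum.  This
resolves degenerate alternate optima so that the number of active
reactions R_A and the carbon waste W are reproducible quantities rather
than solver accidents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .universe import (
    EXTERNAL,
    KIND_EXCHANGE,
    KIND_INTERNAL,
    ROLE_CARBON_SOURCE,
    ROLE_CURRENCY,
    ReactionUniverse,
)

__all__ = [
    "Environment",
    "BiomassSpec",
    "FluxSolution",
    "LPSystem",
    "FBAError",
    "EPS_VIABILITY",
    "ACTIVE_FLUX_TOL",
    "build_stoichiometric_system",
    "maximize_biosynthetic_flux",
    "is_viable",
    "is_viable_all",
    "count_active_reactions",
    "compute_waste",
    "mean_biosynthetic_flux",
]

#: viability threshold on the biomass drain flux, mmol gDW^-1 h^-1.
#: Well above LP feasibility tolerance, far below any genuine optimum at
#: the default carbon uptake bound of 10.
EPS_VIABILITY = 1e-6

#: a reaction is "active" when |flux| exceeds this, mmol gDW^-1 h^-1
ACTIVE_FLUX_TOL = 1e-6

#: default unconstrained-flux cap for inorganic uptake and secretion
FREE_BOUND = 1000.0

DRAIN_ID = "BIOMASS_DRAIN"


class FBAError(RuntimeError):
    """LP construction or solver failure."""


@dataclass(frozen=True)
class Environment:
    """A minimal chemical environment with a single carbon source.

    Only the designated carbon source may be imported among
    carbon-containing metabolites; all other carbon exchanges are
    secretion-only.  Inorganic components are freely exchangeable.
    """

    carbon_source: str
    carbon_uptake_bound: float = 10.0
    inorganic_components: frozenset = frozenset()
    name: str = ""

    @classmethod
    def minimal_medium(cls, u: ReactionUniverse, carbon_source: str,
                       carbon_uptake_bound: float = 10.0) -> "Environment":
        """Sole-carbon-source medium with every carbon-free external open."""
        m = u.metabolites.get(carbon_source)
        if m is None or ROLE_CARBON_SOURCE not in m.roles:
            raise FBAError(f"{carbon_source!r} is not a carbon_source_candidate")
        if carbon_uptake_bound < 0:
            raise FBAError("carbon_uptake_bound must be non-negative")
        inorganics = frozenset(
            mm.id for mm in u.metabolites.values()
            if mm.compartment == EXTERNAL and mm.carbon_atoms == 0)
        return cls(carbon_source, carbon_uptake_bound, inorganics,
                   name=f"minimal:{carbon_source}")


@dataclass(frozen=True)
class BiomassSpec:
    """The molecules a network must synthesize and their drain weights.

    ``targets`` defines biosynthetic ability B as the number of
    non-currency targets; ``weights`` are the coefficients of the biomass
    drain (the objective column).  Isostoichiometric mode sets all weights
    to one.
    """

    targets: tuple
    weights: tuple  # ((target_id, float weight), ...) aligned with targets
    mode: str = "weighted"

    @classmethod
    def weighted(cls, weights: Mapping[str, float]) -> "BiomassSpec":
        targets = tuple(sorted(weights))
        if any(w <= 0 for w in weights.values()):
            raise FBAError("biomass weights must be positive")
        return cls(targets, tuple((t, float(weights[t])) for t in targets), "weighted")

    @classmethod
    def isostoichiometric(cls, targets: Iterable[str]) -> "BiomassSpec":
        targets = tuple(sorted(set(targets)))
        return cls(targets, tuple((t, 1.0) for t in targets), "isostoichiometric")

    def weight_map(self) -> dict:
        return dict(self.weights)

    def ability(self, u: ReactionUniverse) -> int:
        """B: the number of non-currency target molecules."""
        return sum(1 for t in self.targets
                   if ROLE_CURRENCY not in u.metabolites[t].roles)

    def carbon_per_unit(self, u: ReactionUniverse) -> float:
        """Carbon atoms drained per unit of biomass flux."""
        return float(sum(w * u.metabolites[t].carbon_atoms for t, w in self.weights))


@dataclass
class LPSystem:
    """The assembled LP: S (m x n), bounds, objective and index maps."""

    reaction_ids: list
    metabolite_ids: list
    S: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    kind_by_column: list


@dataclass
class FluxSolution:
    fluxes: dict
    objective: float
    status: str  # optimal | zero_growth | infeasible
    secondary_minimized: bool
    environment: Environment | None = None

    def export_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction\tflux\n")
            for rid, v in sorted(self.fluxes.items()):
                fh.write(f"{rid}\t{v!r}\n")


def build_stoichiometric_system(genotype: frozenset, u: ReactionUniverse,
                                env: Environment, bm: BiomassSpec) -> LPSystem:
    """Assemble S, bounds and objective for a genotype in an environment.

    Columns are the genotype's internal reactions, all transports, all
    exchanges, and one biomass drain; rows are all metabolites (exchange
    columns are the system boundary for external ones).
    """
    internal_all = set(u.internal_reaction_ids())
    bad = sorted(set(genotype) - internal_all)
    if bad:
        raise FBAError(f"genotype contains non-internal reactions: {bad}")

    columns = sorted(genotype) + u.transport_reaction_ids() + u.exchange_reaction_ids()
    met_ids = sorted(u.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    n = len(columns) + 1
    S = np.zeros((len(met_ids), n))
    lower = np.empty(n)
    upper = np.empty(n)
    kinds = []

    for j, rid in enumerate(columns):
        r = u.reactions[rid]
        kinds.append(r.kind)
        for mid, coef in r.stoichiometry.items():
            S[met_index[mid], j] = float(coef)
        lo, hi = r.default_bounds
        if r.kind == KIND_EXCHANGE:
            (mid,) = r.stoichiometry
            m = u.metabolites[mid]
            if mid == env.carbon_source:
                lo, hi = -env.carbon_uptake_bound, FREE_BOUND
            elif m.carbon_atoms > 0:
                lo, hi = 0.0, FREE_BOUND  # secretion only: sole carbon source
            elif mid in env.inorganic_components:
                lo, hi = -FREE_BOUND, FREE_BOUND
            else:
                lo, hi = 0.0, FREE_BOUND
        lower[j], upper[j] = lo, hi

    # biomass drain: consumes targets in proportion to their weights
    j = n - 1
    kinds.append("drain")
    for t, w in bm.weights:
        if t not in met_index:
            raise FBAError(f"biomass target {t!r} not in universe")
        S[met_index[t], j] -= w
    lower[j], upper[j] = 0.0, FREE_BOUND

    c = np.zeros(n)
    c[j] = 1.0
    return LPSystem(columns + [DRAIN_ID], met_ids, S, lower, upper, c, kinds)


def _solve(c, A_eq, b_eq, lower, upper):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq,
                  bounds=np.column_stack([lower, upper]), method="highs")
    return res


def maximize_biosynthetic_flux(genotype: frozenset, u: ReactionUniverse,
                               env: Environment, bm: BiomassSpec,
                               secondary_flux_min: bool = True) -> FluxSolution:
    """Maximize the biomass drain flux; optionally re-solve parsimoniously.

    Returns Z in mmol biomass gDW^-1 h^-1.  With ``secondary_flux_min``
    (default) the flux vector additionally minimizes total |v| at the fixed
    optimum, making active-reaction counts and waste reproducible.
    """
    sys_ = build_stoichiometric_system(genotype, u, env, bm)
    m, n = sys_.S.shape
    b_eq = np.zeros(m)
    res = _solve(-sys_.objective, sys_.S, b_eq, sys_.lower, sys_.upper)
    if res.status == 2:
        return FluxSolution({}, 0.0, "infeasible", False, env)
    if not res.success:
        raise FBAError(f"LP solver failure: {res.message}")
    z = float(-res.fun)
    v = res.x

    if secondary_flux_min and z > 0:
        # min sum t_i  s.t.  S v = 0, v_drain = z, -t <= v <= t
        lower = sys_.lower.copy()
        upper = sys_.upper.copy()
        lower[-1] = upper[-1] = z
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq2 = np.hstack([sys_.S, np.zeros((m, n))])
        eye = np.eye(n)
        A_ub = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, -eye])])
        b_ub = np.zeros(2 * n)
        tmax = np.maximum(np.abs(lower), np.abs(upper))
        res2 = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq2, b_eq=b_eq,
                       bounds=np.column_stack([
                           np.concatenate([lower, np.zeros(n)]),
                           np.concatenate([upper, tmax])]),
                       method="highs")
        if not res2.success:
            raise FBAError(f"secondary LP failure: {res2.message}")
        v = res2.x[:n]

    fluxes = dict(zip(sys_.reaction_ids, v))
    status = "optimal" if z >= EPS_VIABILITY else "zero_growth"
    return FluxSolution(fluxes, z, status, secondary_flux_min and z > 0, env)


def is_viable(genotype: frozenset, u: ReactionUniverse, env: Environment,
              bm: BiomassSpec) -> bool:
    """True iff the genotype can drain biomass at >= the viability threshold."""
    sol = maximize_biosynthetic_flux(genotype, u, env, bm, secondary_flux_min=False)
    return sol.status == "optimal" and sol.objective >= EPS_VIABILITY


def is_viable_all(genotype: frozenset, u: ReactionUniverse,
                  envs: Iterable[Environment], bm: BiomassSpec,
                  rng: np.random.Generator | None = None) -> bool:
    """Viable on every environment; short-circuits on first failure.

    When an ``rng`` is supplied (as samplers do), the check order is
    shuffled so failure statistics are not biased toward the first listed
    environment; the result is order-independent.
    """
    envs = list(envs)
    if not envs:
        raise FBAError("is_viable_all requires at least one environment")
    if rng is not None:
        order = rng.permutation(len(envs))
        envs = [envs[i] for i in order]
    return all(is_viable(genotype, u, env, bm) for env in envs)


def count_active_reactions(sol: FluxSolution, tol: float = ACTIVE_FLUX_TOL,
                           u: ReactionUniverse | None = None,
                           internal_only: bool = False) -> int:
    """R_A: reactions with |flux| > tol at the optimum.

    Counts internal plus transport reactions by default (exchanges and the
    biomass drain are boundary bookkeeping, not metabolic reactions);
    ``internal_only`` restricts to internal reactions.
    """
    if u is None:
        raise FBAError("count_active_reactions needs the universe for reaction kinds")
    count = 0
    for rid, v in sol.fluxes.items():
        if rid == DRAIN_ID:
            continue
        kind = u.reactions[rid].kind
        if kind == KIND_EXCHANGE or (internal_only and kind != KIND_INTERNAL):
            continue
        if abs(v) > tol:
            count += 1
    return count


def compute_waste(sol: FluxSolution, u: ReactionUniverse) -> float:
    """W: carbon exported through outward exchange fluxes, mmol C gDW^-1 h^-1.

    Carbon leaving through the biomass drain is product, not waste.
    """
    w = 0.0
    for rid, v in sol.fluxes.items():
        if rid == DRAIN_ID:
            continue
        r = u.reactions[rid]
        if r.kind != KIND_EXCHANGE or v <= ACTIVE_FLUX_TOL:
            continue
        (mid,) = r.stoichiometry
        w += v * u.metabolites[mid].carbon_atoms
    return w


def mean_biosynthetic_flux(genotype: frozenset, u: ReactionUniverse,
                           envs: Iterable[Environment], bm: BiomassSpec) -> float:
    """S: arithmetic mean of the per-environment biomass optima."""
    envs = list(envs)
    if not envs:
        raise FBAError("mean_biosynthetic_flux requires at least one environment")
    zs = [maximize_biosynthetic_flux(genotype, u, env, bm,
                                     secondary_flux_min=False).objective
          for env in envs]
    return float(np.mean(zs))
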
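"""Minimal networks and reaction-swap MCMC sampling of genotype space.

A genotype is a subset of the universe's internal reactions (transports and
exchanges are fixed infrastructure, present in every network).  Two kinds of
sampled networks are produced:

* **Minimal networks** — viability-preserving random reaction removal from a
  starting network until every remaining reaction is essential.  A single
  pass over a random permutation suffices: removing reactions only shrinks
  the feasible flux cone, so a reaction that cannot be removed now can never
  become removable after further deletions (monotone essentiality).

* **Random viable networks of fixed size** — a Markov chain whose move is a
  *reaction swap*: remove one random genotype reaction, add one random
  universe reaction absent from the genotype, accept iff the result stays
  viable on every required environment.  The proposal is uniform over the
  constant-size set of (removal, addition) pairs and therefore symmetric, so
  the chain satisfies detailed balance and its stationary distribution is
  uniform over the reachable viable genotypes of that size.

Viability checks are memoized per (genotype, environment set, biomass spec),
which makes long chains on small universes cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import fba
from .universe import ReactionUniverse

__all__ = [
    "MetabolicNetwork",
    "ChainRecord",
    "SamplingError",
    "ViabilityCache",
    "minimize_network",
    "verify_minimal",
    "reduce_to_size",
    "reaction_swap",
    "mcmc_sample",
    "PAPER_SCALE_BURN_IN",
    "PAPER_SCALE_THINNING",
]

#: full-scale chain preset: accepted swaps discarded before sampling and
#: accepted swaps between samples (desk-scale runs use much smaller values)
PAPER_SCALE_BURN_IN = 2_500_000
PAPER_SCALE_THINNING = 5_000


class SamplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class MetabolicNetwork:
    """A genotype: internal reaction set bound to a universe by hash."""

    universe_hash: str
    internal_reactions: frozenset

    @property
    def R(self) -> int:
        return len(self.internal_reactions)

    @classmethod
    def from_universe(cls, u: ReactionUniverse,
                      reactions: Iterable[str] | None = None) -> "MetabolicNetwork":
        internal = u.internal_reaction_ids()
        if reactions is None:
            reactions = internal
        reactions = frozenset(reactions)
        bad = sorted(reactions - set(internal))
        if bad:
            raise SamplingError(f"not internal reactions of this universe: {bad}")
        return cls(u.content_hash(), reactions)


@dataclass
class ChainRecord:
    """Samples and bookkeeping of one MCMC run."""

    samples: list
    burn_in: int
    thinning: int
    seed: int | None
    acceptance_attempts: list = field(default_factory=list)

    @property
    def mean_attempts_per_swap(self) -> float:
        if not self.acceptance_attempts:
            return float("nan")
        return float(np.mean(self.acceptance_attempts))


class ViabilityCache:
    """Memoized is_viable_all keyed by genotype (envs and spec are fixed)."""

    def __init__(self, u: ReactionUniverse, envs, bm: fba.BiomassSpec):
        self.u = u
        self.envs = list(envs)
        self.bm = bm
        self._cache: dict = {}
        self.n_lp_calls = 0

    def __call__(self, genotype: frozenset,
                 rng: np.random.Generator | None = None) -> bool:
        hit = self._cache.get(genotype)
        if hit is not None:
            return hit
        self.n_lp_calls += 1
        ok = fba.is_viable_all(genotype, self.u, self.envs, self.bm, rng=rng)
        self._cache[genotype] = ok
        return ok


def _as_genotype(g, u: ReactionUniverse) -> frozenset:
    if isinstance(g, MetabolicNetwork):
        return g.internal_reactions
    return frozenset(g)


def minimize_network(g, u: ReactionUniverse, envs, bm: fba.BiomassSpec,
                     rng: np.random.Generator) -> MetabolicNetwork:
    """Remove randomly chosen reactions while viability on all envs holds.

    One pass over a random permutation; failed removals are reverted.  The
    result is minimal: every remaining reaction is essential on at least one
    required environment.
    """
    genotype = set(_as_genotype(g, u))
    check = ViabilityCache(u, envs, bm)
    if not check(frozenset(genotype), rng):
        raise SamplingError("minimize_network: starting network is not viable")
    order = sorted(genotype)
    rng.shuffle(order)
    for rid in order:
        genotype.discard(rid)
        if not check(frozenset(genotype), rng):
            genotype.add(rid)
    return MetabolicNetwork(u.content_hash(), frozenset(genotype))


def verify_minimal(g, u: ReactionUniverse, envs, bm: fba.BiomassSpec) -> bool:
    """True iff every single-reaction deletion abolishes viability somewhere."""
    genotype = _as_genotype(g, u)
    if not fba.is_viable_all(genotype, u, envs, bm):
        raise SamplingError("verify_minimal: network is not viable")
    for rid in sorted(genotype):
        if fba.is_viable_all(genotype - {rid}, u, envs, bm):
            return False
    return True


def reduce_to_size(u: ReactionUniverse, envs, bm: fba.BiomassSpec,
                   target_R: int, rng: np.random.Generator) -> MetabolicNetwork:
    """Viability-preserving removal from the full universe down to target_R.

    Fails explicitly when the removal order hits a minimal network larger
    than the target; retry with a different rng stream or a larger target.
    """
    internal = u.internal_reaction_ids()
    if target_R > len(internal):
        raise SamplingError(
            f"target_R={target_R} exceeds universe internal count {len(internal)}")
    genotype = set(internal)
    check = ViabilityCache(u, envs, bm)
    if not check(frozenset(genotype), rng):
        raise SamplingError("reduce_to_size: full universe is not viable")
    candidates = sorted(genotype)
    rng.shuffle(candidates)
    for rid in candidates:
        if len(genotype) == target_R:
            break
        genotype.discard(rid)
        if not check(frozenset(genotype), rng):
            genotype.add(rid)
    if len(genotype) != target_R:
        raise SamplingError(
            f"reduce_to_size: stuck at R={len(genotype)} > target {target_R} "
            f"(minimal size for this removal order exceeds the target; "
            f"try a larger target_R)")
    return MetabolicNetwork(u.content_hash(), frozenset(genotype))


def reaction_swap(g, u: ReactionUniverse, envs, bm: fba.BiomassSpec,
                  rng: np.random.Generator,
                  cache: ViabilityCache | None = None):
    """One accepted reaction swap: (remove one, add one), viability preserved.

    Proposals are uniform over (member, non-member) pairs and retried until
    a viable genotype is found.  Returns the new network and the number of
    proposals tried (the acceptance bookkeeping of the chain).
    """
    genotype = _as_genotype(g, u)
    internal = u.internal_reaction_ids()
    absent = sorted(set(internal) - genotype)
    if not absent:
        raise SamplingError("reaction_swap: genotype already equals the full "
                            "universe internal set; no addition candidate")
    if cache is None:
        cache = ViabilityCache(u, envs, bm)
    members = sorted(genotype)
    attempts = 0
    while True:
        attempts += 1
        out = members[rng.integers(len(members))]
        inn = absent[rng.integers(len(absent))]
        candidate = (genotype - {out}) | {inn}
        if cache(candidate, rng):
            return MetabolicNetwork(u.content_hash(), candidate), attempts


def mcmc_sample(start, u: ReactionUniverse, envs, bm: fba.BiomassSpec,
                n_samples: int, burn_in: int, thinning: int,
                rng: np.random.Generator,
                seed: int | None = None) -> ChainRecord:
    """Run a reaction-swap chain; record a genotype every ``thinning`` swaps.

    ``burn_in`` and ``thinning`` count *accepted* swaps (rejected proposals
    are retries within a step).  All samples share the start's size R and
    are viable on every required environment.
    """
    genotype = _as_genotype(start, u)
    cache = ViabilityCache(u, envs, bm)
    if not cache(genotype, rng):
        raise SamplingError("mcmc_sample: starting network is not viable")
    current = MetabolicNetwork(u.content_hash(), genotype)
    record = ChainRecord([], burn_in, thinning, seed)

    for _ in range(burn_in):
        current, att = reaction_swap(current, u, envs, bm, rng, cache)
        record.acceptance_attempts.append(att)
    for _ in range(n_samples):
        for _ in range(thinning):
            current, att = reaction_swap(current, u, envs, bm, rng, cache)
            record.acceptance_attempts.append(att)
        record.samples.append(current)
    return record
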
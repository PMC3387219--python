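"""Universal reaction networks with designed ground truth.

A :class:`ReactionUniverse` is the global reaction set from which all
metabolic genotypes are drawn: a collection of metabolites (with carbon
content and compartment), carbon-balanced internal reactions, and a fixed
transport/exchange infrastructure.  Real universal networks are assembled
from reaction databases; here :func:`generate_universe` builds synthetic
universes with a hub-and-spoke topology whose pathway lengths are known by
construction, so that downstream estimates (e.g. reactions-per-nutrient
slopes) can be checked against designed values.

Topology of a generated universe:

* one internal *hub* metabolite (the analog of central carbon metabolism);
* per carbon source, a dedicated linear catabolic route of exactly ``L_N``
  internal reactions from the imported source to the hub;
* per biomass candidate, a dedicated linear anabolic route of exactly
  ``L_B`` internal reactions from the hub to the target;
* optionally, ``redundancy_factor`` equal-length duplicate routes per
  pathway (alternative pathways with distinct intermediates);
* optionally, lossy catabolic variants that vent part of the source carbon
  as CO2, and hub-to-CO2 waste branches;
* optionally, a group of biochemically related targets sharing a common
  anabolic prefix, emulating e.g. the amino-acid family;
* transport and exchange reactions for every carbon source, inorganic
  medium component, currency metabolite and excretable product.

All stoichiometric coefficients are exact rationals so the carbon-balance
invariant (sum of coefficient x carbon atoms = 0 over every internal
reaction) can be checked exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionUniverse",
    "UniverseConfig",
    "UniverseError",
    "UniverseParseError",
    "generate_universe",
    "validate_universe",
    "write_universe",
    "read_universe",
    "write_genotype",
    "read_genotype",
]

INTERNAL = "internal"
EXTERNAL = "external"

ROLE_CARBON_SOURCE = "carbon_source_candidate"
ROLE_BIOMASS = "biomass_candidate"
ROLE_CURRENCY = "currency"
ROLE_INORGANIC = "inorganic_medium"
_ROLES = {ROLE_CARBON_SOURCE, ROLE_BIOMASS, ROLE_CURRENCY, ROLE_INORGANIC}

KIND_INTERNAL = "internal"
KIND_TRANSPORT = "transport"
KIND_EXCHANGE = "exchange"
_KINDS = {KIND_INTERNAL, KIND_TRANSPORT, KIND_EXCHANGE}

DEFAULT_FLUX_CAP = 1000.0


class UniverseError(ValueError):
    """Inconsistent universe configuration or content."""


class UniverseParseError(UniverseError):
    """A universe or genotype file could not be parsed."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    carbon_atoms: int = 0
    compartment: str = INTERNAL
    roles: frozenset = frozenset()

    def __post_init__(self):
        if self.carbon_atoms < 0:
            raise UniverseError(f"metabolite {self.id}: carbon_atoms < 0")
        if self.compartment not in (INTERNAL, EXTERNAL):
            raise UniverseError(f"metabolite {self.id}: bad compartment {self.compartment!r}")
        bad = set(self.roles) - _ROLES
        if bad:
            raise UniverseError(f"metabolite {self.id}: unknown roles {sorted(bad)}")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed exact coefficient
    (negative = consumed, positive = produced).  Bounds are in
    mmol gDW^-1 h^-1; irreversible reactions have lower bound >= 0.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    kind: str = KIND_INTERNAL
    default_bounds: tuple = None  # filled in __post_init__

    def __post_init__(self):
        if not self.stoichiometry:
            raise UniverseError(f"reaction {self.id}: empty stoichiometry")
        if self.kind not in _KINDS:
            raise UniverseError(f"reaction {self.id}: unknown kind {self.kind!r}")
        sto = {m: Fraction(c) for m, c in self.stoichiometry.items()}
        object.__setattr__(self, "stoichiometry", sto)
        if self.default_bounds is None:
            lo = -DEFAULT_FLUX_CAP if self.reversible else 0.0
            object.__setattr__(self, "default_bounds", (lo, DEFAULT_FLUX_CAP))
        lo, hi = self.default_bounds
        if not self.reversible and lo < 0:
            raise UniverseError(f"reaction {self.id}: irreversible with lower bound < 0")
        if lo > hi:
            raise UniverseError(f"reaction {self.id}: lower bound exceeds upper bound")


@dataclass
class ReactionUniverse:
    """The global reaction set from which genotypes are drawn."""

    metabolites: dict
    reactions: dict
    carbon_sources: list
    biomass_candidates: list
    ground_truth: dict | None = None

    # -- construction ---------------------------------------------------
    @classmethod
    def from_parts(cls, metabolites: Iterable[Metabolite], reactions: Iterable[Reaction],
                   carbon_sources, biomass_candidates, ground_truth=None) -> "ReactionUniverse":
        mets = {}
        for m in metabolites:
            if m.id in mets:
                raise UniverseError(f"duplicate metabolite id {m.id!r}")
            mets[m.id] = m
        rxns = {}
        for r in reactions:
            if r.id in rxns:
                raise UniverseError(f"duplicate reaction id {r.id!r}")
            rxns[r.id] = r
        return cls(mets, rxns, list(carbon_sources), list(biomass_candidates), ground_truth)

    # -- views -----------------------------------------------------------
    def internal_reaction_ids(self) -> list:
        return sorted(r.id for r in self.reactions.values() if r.kind == KIND_INTERNAL)

    def transport_reaction_ids(self) -> list:
        return sorted(r.id for r in self.reactions.values() if r.kind == KIND_TRANSPORT)

    def exchange_reaction_ids(self) -> list:
        return sorted(r.id for r in self.reactions.values() if r.kind == KIND_EXCHANGE)

    def summary(self) -> str:
        n_int = len(self.internal_reaction_ids())
        return (f"ReactionUniverse: {n_int} internal reactions, "
                f"{len(self.metabolites)} metabolites, "
                f"{len(self.carbon_sources)} carbon sources, "
                f"{len(self.biomass_candidates)} biomass candidates")

    # -- hashing ---------------------------------------------------------
    def canonical_serialization(self) -> str:
        """Deterministic text form, invariant to insertion order."""
        lines = []
        for m in sorted(self.metabolites.values(), key=lambda m: m.id):
            lines.append("M\t%s\t%s\t%d\t%s\t%s" % (
                m.id, m.name, m.carbon_atoms, m.compartment, ",".join(sorted(m.roles))))
        for r in sorted(self.reactions.values(), key=lambda r: r.id):
            sto = ";".join(f"{mid}:{coef}" for mid, coef in sorted(r.stoichiometry.items()))
            lines.append("R\t%s\t%s\t%d\t%s\t%r\t%r" % (
                r.id, sto, int(r.reversible), r.kind, r.default_bounds[0], r.default_bounds[1]))
        lines.append("CS\t" + ",".join(self.carbon_sources))
        lines.append("BM\t" + ",".join(self.biomass_candidates))
        return "\n".join(lines) + "\n"

    def content_hash(self) -> str:
        return hashlib.sha256(self.canonical_serialization().encode()).hexdigest()

    def __eq__(self, other):
        if not isinstance(other, ReactionUniverse):
            return NotImplemented
        return (self.canonical_serialization() == other.canonical_serialization()
                and self.ground_truth == other.ground_truth)


# ---------------------------------------------------------------------------
# Synthetic universe generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniverseConfig:
    """Design parameters of a synthetic universe.

    ``L_N`` is the number of internal reactions on each dedicated catabolic
    route (carbon source -> hub); ``L_B`` the number on each dedicated
    anabolic route (hub -> biomass candidate).  ``redundancy_factor``
    equal-length alternative routes are added per dedicated pathway.
    ``n_lossy_routes`` of the carbon sources additionally get a wasteful
    catabolic variant that vents part of the carbon as CO2.
    ``n_related_targets`` extra biomass candidates share an anabolic prefix
    of ``related_prefix_len`` reactions plus one dedicated step each.
    """

    n_carbon_sources: int = 3
    n_biomass_candidates: int = 2
    L_N: int = 2
    L_B: int = 3
    redundancy_factor: int = 1
    n_waste_branches: int = 1
    currency_count: int = 2
    n_inorganics: int = 3
    n_lossy_routes: int = 0
    n_related_targets: int = 0
    related_prefix_len: int = 0
    source_carbon: int = 6
    hub_carbon: int = 3
    seed: int = 0

    def validate(self):
        if self.n_carbon_sources < 1:
            raise UniverseError("n_carbon_sources must be >= 1")
        if self.n_biomass_candidates < 1:
            raise UniverseError("n_biomass_candidates must be >= 1")
        if self.L_N < 1 or self.L_B < 1:
            raise UniverseError("pathway lengths L_N, L_B must be >= 1")
        if self.redundancy_factor < 0 or self.n_waste_branches < 0:
            raise UniverseError("redundancy_factor and n_waste_branches must be >= 0")
        if self.source_carbon < 1:
            raise UniverseError("carbon sources must contain at least one carbon atom")
        if self.hub_carbon < 1:
            raise UniverseError("hub metabolite must contain at least one carbon atom")
        if self.source_carbon % self.hub_carbon != 0:
            raise UniverseError("source_carbon must be a multiple of hub_carbon")
        if self.n_lossy_routes > self.n_carbon_sources:
            raise UniverseError("n_lossy_routes exceeds n_carbon_sources")
        if self.n_lossy_routes > 0 and self.source_carbon // self.hub_carbon < 2:
            raise UniverseError("lossy routes need source_carbon >= 2 x hub_carbon")
        if self.n_related_targets > 0 and self.related_prefix_len < 1:
            raise UniverseError("related targets require related_prefix_len >= 1")


def generate_universe(config: UniverseConfig) -> ReactionUniverse:
    """Build a synthetic universal network from design parameters.

    Deterministic for a fixed config (the seed is recorded in the ground
    truth so downstream artifacts can name their provenance).
    """
    cfg = config
    cfg.validate()

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    hub = Metabolite("hub", "central carbon hub", cfg.hub_carbon, INTERNAL)
    mets.append(hub)
    k_hub = cfg.source_carbon // cfg.hub_carbon  # hubs per source at full yield

    need_co2 = cfg.n_waste_branches > 0 or cfg.n_lossy_routes > 0
    if need_co2:
        mets.append(Metabolite("co2", "carbon dioxide", 1, INTERNAL))
        mets.append(Metabolite("co2_x", "carbon dioxide (external)", 1, EXTERNAL))
        rxns.append(Reaction("T_co2", {"co2": Fraction(-1), "co2_x": Fraction(1)},
                             kind=KIND_TRANSPORT))
        rxns.append(Reaction("EX_co2", {"co2_x": Fraction(-1)}, kind=KIND_EXCHANGE))

    def linear_chain(prefix, start, end, n_steps, mid_carbon, final_sto=None):
        """Append n_steps internal reactions start -> ... -> end.

        Intermediates carry mid_carbon atoms.  final_sto overrides the
        product side of the last step (default: 1 end)."""
        prev = start
        for j in range(1, n_steps + 1):
            last = j == n_steps
            if last:
                prod = final_sto if final_sto is not None else {end: Fraction(1)}
            else:
                inter = f"{prefix}_i{j}"
                mets.append(Metabolite(inter, "", mid_carbon, INTERNAL))
                prod = {inter: Fraction(1)}
            sto = {prev: Fraction(-1)}
            for mid, c in prod.items():
                sto[mid] = sto.get(mid, Fraction(0)) + c
            rxns.append(Reaction(f"{prefix}_s{j}", sto, kind=KIND_INTERNAL))
            prev = next(iter(prod)) if not last else end

    # carbon sources: external metabolite + transport + exchange + routes
    carbon_sources = []
    for i in range(1, cfg.n_carbon_sources + 1):
        ext, internal = f"cs{i}", f"cs{i}_c"
        carbon_sources.append(ext)
        mets.append(Metabolite(ext, f"carbon source {i}", cfg.source_carbon, EXTERNAL,
                               frozenset({ROLE_CARBON_SOURCE})))
        mets.append(Metabolite(internal, f"carbon source {i} (cytosol)",
                               cfg.source_carbon, INTERNAL))
        rxns.append(Reaction(f"T_cs{i}", {ext: Fraction(-1), internal: Fraction(1)},
                             kind=KIND_TRANSPORT))
        rxns.append(Reaction(f"EX_cs{i}", {ext: Fraction(-1)}, kind=KIND_EXCHANGE))

        full_yield = {"hub": Fraction(k_hub)}
        linear_chain(f"cat{i}", internal, "hub", cfg.L_N, cfg.source_carbon,
                     final_sto=full_yield)
        for k in range(1, cfg.redundancy_factor + 1):
            linear_chain(f"cat{i}r{k}", internal, "hub", cfg.L_N, cfg.source_carbon,
                         final_sto=full_yield)
        if i <= cfg.n_lossy_routes:
            vented = cfg.source_carbon - (k_hub - 1) * cfg.hub_carbon
            lossy = {"hub": Fraction(k_hub - 1), "co2": Fraction(vented)}
            linear_chain(f"cat{i}L", internal, "hub", cfg.L_N, cfg.source_carbon,
                         final_sto=lossy)

    # biomass candidates: anabolic routes from the hub
    biomass_candidates = []
    for i in range(1, cfg.n_biomass_candidates + 1):
        bm = f"bm{i}"
        biomass_candidates.append(bm)
        mets.append(Metabolite(bm, f"biomass molecule {i}", cfg.hub_carbon, INTERNAL,
                               frozenset({ROLE_BIOMASS})))
        linear_chain(f"ana{i}", "hub", bm, cfg.L_B, cfg.hub_carbon)
        for k in range(1, cfg.redundancy_factor + 1):
            linear_chain(f"ana{i}r{k}", "hub", bm, cfg.L_B, cfg.hub_carbon)

    # related target family: shared prefix + one dedicated step per target
    if cfg.n_related_targets > 0:
        pre = "relpre"
        linear_chain(pre, "hub", f"{pre}_end", cfg.related_prefix_len, cfg.hub_carbon,
                     final_sto=None if cfg.related_prefix_len == 0 else {
                         f"{pre}_end": Fraction(1)})
        mets.append(Metabolite(f"{pre}_end", "shared anabolic precursor",
                               cfg.hub_carbon, INTERNAL))
        for i in range(1, cfg.n_related_targets + 1):
            rel = f"relbm{i}"
            biomass_candidates.append(rel)
            mets.append(Metabolite(rel, f"related biomass molecule {i}", cfg.hub_carbon,
                                   INTERNAL, frozenset({ROLE_BIOMASS})))
            rxns.append(Reaction(f"rel{i}", {f"{pre}_end": Fraction(-1), rel: Fraction(1)},
                                 kind=KIND_INTERNAL))

    # waste branches: hub -> CO2 vents
    for w in range(1, cfg.n_waste_branches + 1):
        rxns.append(Reaction(f"waste{w}", {"hub": Fraction(-1),
                                           "co2": Fraction(cfg.hub_carbon)},
                             kind=KIND_INTERNAL))

    # currency metabolites: carbon-free cofactor analogs with uptake
    for i in range(1, cfg.currency_count + 1):
        cur, ext = f"cur{i}", f"cur{i}_x"
        mets.append(Metabolite(cur, f"currency metabolite {i}", 0, INTERNAL,
                               frozenset({ROLE_CURRENCY})))
        mets.append(Metabolite(ext, f"currency metabolite {i} (external)", 0, EXTERNAL,
                               frozenset({ROLE_INORGANIC})))
        rxns.append(Reaction(f"T_cur{i}", {ext: Fraction(-1), cur: Fraction(1)},
                             reversible=True, kind=KIND_TRANSPORT))
        rxns.append(Reaction(f"EX_cur{i}", {ext: Fraction(-1)}, reversible=True,
                             kind=KIND_EXCHANGE))

    # inorganic medium components (carbon-free; infrastructure only)
    for i in range(1, cfg.n_inorganics + 1):
        ext, internal = f"inorg{i}", f"inorg{i}_c"
        mets.append(Metabolite(ext, f"inorganic component {i}", 0, EXTERNAL,
                               frozenset({ROLE_INORGANIC})))
        mets.append(Metabolite(internal, f"inorganic component {i} (cytosol)", 0, INTERNAL))
        rxns.append(Reaction(f"T_inorg{i}", {ext: Fraction(-1), internal: Fraction(1)},
                             reversible=True, kind=KIND_TRANSPORT))
        rxns.append(Reaction(f"EX_inorg{i}", {ext: Fraction(-1)}, reversible=True,
                             kind=KIND_EXCHANGE))

    core_size = (cfg.related_prefix_len + cfg.n_related_targets
                 if cfg.n_related_targets > 0 else 0)
    ground_truth = {
        "L_N": cfg.L_N,
        "L_B": cfg.L_B,
        "core_size": core_size,
        "n_dedicated": (cfg.n_carbon_sources * cfg.L_N
                        + cfg.n_biomass_candidates * cfg.L_B + core_size),
        "redundancy_factor": cfg.redundancy_factor,
        "n_waste_branches": cfg.n_waste_branches,
        "n_lossy_routes": cfg.n_lossy_routes,
        "seed": cfg.seed,
    }
    return ReactionUniverse.from_parts(mets, rxns, carbon_sources,
                                       biomass_candidates, ground_truth)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_universe(u: ReactionUniverse, check_viability: bool = True) -> list:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    violations = []
    for r in u.reactions.values():
        missing = [m for m in r.stoichiometry if m not in u.metabolites]
        if missing:
            violations.append(f"reaction {r.id}: unknown metabolite ids {missing}")
            continue
        if r.kind == KIND_INTERNAL:
            bal = sum(coef * u.metabolites[m].carbon_atoms
                      for m, coef in r.stoichiometry.items())
            if bal != 0:
                violations.append(
                    f"reaction {r.id}: carbon imbalance (net {bal} carbon atoms)")
            ext = [m for m in r.stoichiometry
                   if u.metabolites[m].compartment == EXTERNAL]
            if ext:
                violations.append(
                    f"reaction {r.id}: internal reaction touches external {ext}")
        elif r.kind == KIND_EXCHANGE:
            if len(r.stoichiometry) != 1:
                violations.append(
                    f"reaction {r.id}: exchange touches {len(r.stoichiometry)} metabolites")
            else:
                (mid,) = r.stoichiometry
                if u.metabolites[mid].compartment != EXTERNAL:
                    violations.append(
                        f"reaction {r.id}: exchange on internal metabolite {mid}")
        if not r.reversible and r.default_bounds[0] < 0:
            violations.append(f"reaction {r.id}: irreversible with negative lower bound")
    for cs in u.carbon_sources:
        m = u.metabolites.get(cs)
        if m is None:
            violations.append(f"carbon source {cs}: not a metabolite")
        elif m.carbon_atoms < 1:
            violations.append(f"carbon source {cs}: contains no carbon")
    for bm in u.biomass_candidates:
        if bm not in u.metabolites:
            violations.append(f"biomass candidate {bm}: not a metabolite")

    if check_viability and not violations:
        from . import fba  # deferred: fba depends on this module

        genotype = frozenset(u.internal_reaction_ids())
        spec = fba.BiomassSpec.isostoichiometric(tuple(u.biomass_candidates))
        for cs in u.carbon_sources:
            env = fba.Environment.minimal_medium(u, cs)
            if not fba.is_viable(genotype, u, env, spec):
                violations.append(f"full universe not viable on sole carbon source {cs}")
    return violations


# ---------------------------------------------------------------------------
# Serialization: two TSV tables + JSON header; genotypes as id lists
# ---------------------------------------------------------------------------

def _format_coef(c: Fraction) -> str:
    return str(c.numerator) if c.denominator == 1 else f"{c.numerator}/{c.denominator}"


def format_equation(r: Reaction) -> str:
    """Render stoichiometry as e.g. ``2 A + B -> C`` (``<->`` if reversible)."""
    lhs, rhs = [], []
    for mid, coef in sorted(r.stoichiometry.items()):
        side = rhs if coef > 0 else lhs
        mag = abs(coef)
        side.append(mid if mag == 1 else f"{_format_coef(mag)} {mid}")
    arrow = "<->" if r.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def parse_equation(eq: str, reaction_id: str = "?") -> tuple:
    """Parse an equation string; returns (stoichiometry, reversible)."""
    if "<->" in eq:
        arrow, reversible = "<->", True
    elif "->" in eq:
        arrow, reversible = "->", False
    else:
        raise UniverseParseError(f"reaction {reaction_id}: no arrow in equation {eq!r}")
    lhs, rhs = eq.split(arrow, 1)
    sto: dict = {}

    def add_side(side: str, sign: int):
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                coef, mid = Fraction(1), parts[0]
            elif len(parts) == 2:
                coef, mid = Fraction(parts[0]), parts[1]
            else:
                raise UniverseParseError(
                    f"reaction {reaction_id}: malformed term {term!r}")
            sto[mid] = sto.get(mid, Fraction(0)) + sign * coef

    add_side(lhs, -1)
    add_side(rhs, +1)
    return {m: c for m, c in sto.items() if c != 0}, reversible


def write_universe(u: ReactionUniverse, path) -> None:
    """Write a universe as metabolites.tsv + reactions.tsv + meta.json under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "universe.metabolites.tsv", "w") as fh:
        fh.write("id\tname\tcarbon_atoms\tcompartment\troles\n")
        for m in sorted(u.metabolites.values(), key=lambda m: m.id):
            fh.write(f"{m.id}\t{m.name}\t{m.carbon_atoms}\t{m.compartment}\t"
                     f"{','.join(sorted(m.roles))}\n")
    with open(path / "universe.reactions.tsv", "w") as fh:
        fh.write("id\tequation\treversible\tkind\tlb\tub\n")
        for r in sorted(u.reactions.values(), key=lambda r: r.id):
            fh.write(f"{r.id}\t{format_equation(r)}\t{int(r.reversible)}\t{r.kind}\t"
                     f"{r.default_bounds[0]!r}\t{r.default_bounds[1]!r}\n")
    meta = {
        "carbon_sources": u.carbon_sources,
        "biomass_candidates": u.biomass_candidates,
        "ground_truth": u.ground_truth,
        "sha256": u.content_hash(),
    }
    with open(path / "universe.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_universe(path) -> ReactionUniverse:
    """Read a universe written by :func:`write_universe`; verifies the stored hash."""
    path = Path(path)
    mets = []
    with open(path / "universe.metabolites.tsv") as fh:
        header = fh.readline()
        for line in fh:
            mid, name, carbon, comp, roles = line.rstrip("\n").split("\t")
            mets.append(Metabolite(mid, name, int(carbon), comp,
                                   frozenset(r for r in roles.split(",") if r)))
    met_ids = {m.id for m in mets}
    rxns = []
    with open(path / "universe.reactions.tsv") as fh:
        header = fh.readline()
        for line in fh:
            rid, eq, rev, kind, lb, ub = line.rstrip("\n").split("\t")
            sto, eq_rev = parse_equation(eq, rid)
            unknown = sorted(set(sto) - met_ids)
            if unknown:
                raise UniverseParseError(
                    f"reaction {rid}: references unknown metabolite id(s) "
                    f"{', '.join(repr(x) for x in unknown)}")
            rxns.append(Reaction(rid, sto, reversible=bool(int(rev)), kind=kind,
                                 default_bounds=(float(lb), float(ub))))
    with open(path / "universe.meta.json") as fh:
        meta = json.load(fh)
    gt = meta.get("ground_truth")
    u = ReactionUniverse.from_parts(mets, rxns, meta["carbon_sources"],
                                    meta["biomass_candidates"], gt)
    stored = meta.get("sha256")
    if stored and stored != u.content_hash():
        warnings.warn(f"universe at {path}: content hash mismatch "
                      f"(stored {stored[:12]}..., computed {u.content_hash()[:12]}...)",
                      stacklevel=2)
    return u


def write_genotype(genotype: frozenset, u: ReactionUniverse, path) -> None:
    """Write a genotype (set of internal reaction ids) with its universe hash."""
    internal = set(u.internal_reaction_ids())
    bad = sorted(set(genotype) - internal)
    if bad:
        raise UniverseError(f"genotype lists non-internal or unknown reactions: {bad}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#universe_hash={u.content_hash()}\n")
        for rid in sorted(genotype):
            fh.write(rid + "\n")


def read_genotype(path, u: ReactionUniverse) -> frozenset:
    """Read a genotype file, checking it refers to ``u``."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#universe_hash="):
            raise UniverseParseError(f"{path}: missing universe hash header")
        stored = header.split("=", 1)[1]
        if stored != u.content_hash():
            raise UniverseParseError(
                f"{path}: genotype refers to universe {stored[:12]}..., "
                f"got {u.content_hash()[:12]}...")
        ids = [line.strip() for line in fh if line.strip()]
    internal = set(u.internal_reaction_ids())
    bad = sorted(set(ids) - internal)
    if bad:
        raise UniverseParseError(
            f"{path}: non-internal or unknown reaction ids {bad}")
    return frozenset(ids)
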
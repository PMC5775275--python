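"""Continuous Petri-net representation of biochemical reaction networks.

A network is a bipartite structure of *places* (chemical species holding
continuous concentrations) and *transitions* (reactions).  Under mass-action
kinetics every reaction fires at a rate equal to its rate constant times the
product of its substrate concentrations (with multiplicity), which induces a
system of ordinary differential equations

    dx/dt = S · v(x),

where ``S`` is the stoichiometry matrix over the dynamic (non-clamped) places
and ``v`` the flux vector.  Clamped (boundary) places participate in fluxes
but have derivative identically zero, e.g. species held in large excess such
as ATP and Mg2+ in an enzyme assay buffer.

All concentrations are expressed in one abstract model concentration unit
(c.u.); by convention assay species are loaded in mM-equivalents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy

__all__ = [
    "Place",
    "Reaction",
    "ReactionNetwork",
    "NetworkValidationError",
    "ConfigurationError",
    "validate_network",
    "stoichiometry_matrix",
    "mass_action_rates",
    "compile_odes",
    "conserved_moieties",
    "network_to_dict",
    "network_from_dict",
    "write_network_json",
    "read_network_json",
]


class NetworkValidationError(ValueError):
    """Raised when an operation requires a valid network but validation fails."""


class ConfigurationError(KeyError):
    """Raised when rate constants or species referenced by name are missing."""


@dataclass(frozen=True)
class Place:
    """A species with an initial concentration.

    ``clamped`` marks a boundary species: it may appear in reaction rate laws
    but its time derivative is forced to zero.
    """

    name: str
    initial: float = 0.0
    clamped: bool = False


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction (Petri-net transition).

    ``substrates`` and ``products`` map species name to integer stoichiometry
    (>= 1); ``rate_constant`` names the parameter supplying the mass-action
    rate coefficient.
    """

    name: str
    substrates: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: str


@dataclass
class ReactionNetwork:
    places: list[Place] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    @property
    def species_names(self) -> list[str]:
        return [p.name for p in self.places]

    @property
    def dynamic_species(self) -> list[str]:
        return [p.name for p in self.places if not p.clamped]

    @property
    def clamped_species(self) -> list[str]:
        return [p.name for p in self.places if p.clamped]

    def place(self, name: str) -> Place:
        for p in self.places:
            if p.name == name:
                return p
        raise ConfigurationError(f"unknown species {name!r}")

    def initial_state(self) -> dict[str, float]:
        return {p.name: p.initial for p in self.places}


def validate_network(net: ReactionNetwork) -> list[str]:
    """Check structural well-formedness; return a list of violations.

    An empty list means the network is valid.  Checks: unique place and
    reaction names, nonnegative initial concentrations, at least one
    substrate per reaction, positive integer stoichiometries, and that all
    species referenced by reactions are declared places.
    """
    violations: list[str] = []
    names = [p.name for p in net.places]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            violations.append(f"duplicate place name {n!r}")
        seen.add(n)
    rnames: set[str] = set()
    for r in net.reactions:
        if r.name in rnames:
            violations.append(f"duplicate reaction name {r.name!r}")
        rnames.add(r.name)
    for p in net.places:
        if p.initial < 0:
            violations.append(
                f"place {p.name!r} has negative initial concentration {p.initial}"
            )
    declared = set(names)
    for r in net.reactions:
        if not r.substrates:
            violations.append(f"reaction {r.name!r} has no substrates")
        for side, mapping in (("substrate", r.substrates), ("product", r.products)):
            for sp, coeff in mapping.items():
                if sp not in declared:
                    violations.append(
                        f"reaction {r.name!r} references undeclared species {sp!r}"
                    )
                if not (isinstance(coeff, (int, np.integer)) and coeff >= 1):
                    violations.append(
                        f"reaction {r.name!r} has non-positive-integer "
                        f"{side} stoichiometry for {sp!r}: {coeff}"
                    )
    return violations


def _require_valid(net: ReactionNetwork) -> None:
    violations = validate_network(net)
    if violations:
        raise NetworkValidationError("; ".join(violations))


def stoichiometry_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer stoichiometry matrix over the dynamic places.

    Rows follow the order of non-clamped places, columns the order of
    reactions; entry (i, j) is product minus substrate stoichiometry of
    species i in reaction j.  Clamped places are excluded entirely.
    """
    _require_valid(net)
    dyn = net.dynamic_species
    index = {name: i for i, name in enumerate(dyn)}
    S = np.zeros((len(dyn), len(net.reactions)), dtype=int)
    for j, r in enumerate(net.reactions):
        for sp, c in r.substrates.items():
            if sp in index:
                S[index[sp], j] -= c
        for sp, c in r.products.items():
            if sp in index:
                S[index[sp], j] += c
    return S


def _rate_constants(net: ReactionNetwork, params: Mapping[str, float]) -> np.ndarray:
    k = np.empty(len(net.reactions))
    for j, r in enumerate(net.reactions):
        if r.rate_constant not in params:
            raise ConfigurationError(
                f"missing rate constant {r.rate_constant!r} for reaction {r.name!r}"
            )
        k[j] = params[r.rate_constant]
    return k


def mass_action_rates(
    net: ReactionNetwork,
    params: Mapping[str, float],
    state: Mapping[str, float],
) -> np.ndarray:
    """Flux of every reaction at the given state (c.u./s).

    flux_j = k_j * prod over substrates s of [s]^stoich, clamped substrates
    included.  Nonnegative states give nonnegative fluxes.
    """
    k = _rate_constants(net, params)
    flux = k.copy()
    for j, r in enumerate(net.reactions):
        for sp, c in r.substrates.items():
            if sp not in state:
                raise ConfigurationError(f"state is missing species {sp!r}")
            flux[j] *= state[sp] ** c
    return flux


def compile_odes(
    net: ReactionNetwork, params: Mapping[str, float]
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into a mass-action right-hand-side function.

    The returned callable maps ``(t, y)`` with ``y`` ordered as
    ``net.species_names`` to the vector of time derivatives; clamped species
    have derivative exactly zero.  The compilation precomputes the substrate
    exponent matrix and the (clamp-masked) stoichiometry matrix so the RHS is
    a pair of array operations, suitable for stiff integrators.
    """
    _require_valid(net)
    species = net.species_names
    index = {name: i for i, name in enumerate(species)}
    n_sp, n_rx = len(species), len(net.reactions)

    k = _rate_constants(net, params)
    exponents = np.zeros((n_rx, n_sp))
    S_full = np.zeros((n_sp, n_rx))
    for j, r in enumerate(net.reactions):
        for sp, c in r.substrates.items():
            exponents[j, index[sp]] += c
            S_full[index[sp], j] -= c
        for sp, c in r.products.items():
            S_full[index[sp], j] += c
    for p in net.places:
        if p.clamped:
            S_full[index[p.name], :] = 0.0

    # mask of species actually appearing as substrates, to skip 0**0 work
    active = exponents > 0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (n_sp,):
            raise ValueError(
                f"state vector has shape {y.shape}, expected ({n_sp},)"
            )
        flux = k.copy()
        for j in range(n_rx):
            idx = active[j]
            if idx.any():
                flux[j] *= np.prod(y[idx] ** exponents[j, idx])
        return S_full @ flux

    rhs.species = species  # type: ignore[attr-defined]
    return rhs


def conserved_moieties(net: ReactionNetwork) -> np.ndarray:
    """Basis of conservation laws over the dynamic places.

    Returns an integer matrix whose rows v satisfy v·S = 0, i.e. the weighted
    concentration sums v·x are constant along every trajectory.  Computed as
    the left null space of the stoichiometry matrix, scaled to smallest
    integer entries.  Rows align with ``net.dynamic_species``.
    """
    S = stoichiometry_matrix(net)
    null = sympy.Matrix(S.T).nullspace()
    basis = []
    for vec in null:
        denoms = [sympy.Rational(x).q for x in vec]
        scale = sympy.ilcm(*denoms) if denoms else 1
        ints = [int(x * scale) for x in vec]
        g = int(sympy.igcd(*[abs(x) for x in ints if x != 0] or [1]))
        ints = [x // g for x in ints]
        if sum(ints) < 0:  # sign convention: prefer nonnegative sums
            ints = [-x for x in ints]
        basis.append(ints)
    if not basis:
        return np.zeros((0, S.shape[0]), dtype=int)
    return np.array(basis, dtype=int)


# --- JSON serialization -----------------------------------------------------

def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "places": [
            {"name": p.name, "initial": p.initial, "clamped": p.clamped}
            for p in net.places
        ],
        "reactions": [
            {
                "name": r.name,
                "substrates": dict(r.substrates),
                "products": dict(r.products),
                "rate_constant": r.rate_constant,
            }
            for r in net.reactions
        ],
    }


def network_from_dict(d: Mapping) -> ReactionNetwork:
    try:
        places = [
            Place(
                name=str(p["name"]),
                initial=float(p.get("initial", 0.0)),
                clamped=bool(p.get("clamped", False)),
            )
            for p in d["places"]
        ]
        reactions = [
            Reaction(
                name=str(r["name"]),
                substrates={str(s): int(c) for s, c in r["substrates"].items()},
                products={str(s): int(c) for s, c in r.get("products", {}).items()},
                rate_constant=str(r["rate_constant"]),
            )
            for r in d["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise NetworkValidationError(f"malformed network description: {exc}") from exc
    net = ReactionNetwork(places=places, reactions=reactions)
    _require_valid(net)
    return net


def write_network_json(net: ReactionNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=2) + "\n")


def read_network_json(path: str | Path) -> ReactionNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))
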
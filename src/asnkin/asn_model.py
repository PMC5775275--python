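"""The canonical asparagine synthetase (ASN) reaction network.

Asparagine synthetase catalyzes the ATP-dependent transfer of glutamine's
amide nitrogen to aspartate, producing asparagine, glutamate and AMP.  The
mechanism is decomposed into four sequential elementary steps plus a
dissociation step for the enzyme–ammonia complex:

    r1: ASNe + Gln                      -> ASNe-Gln
    r2: ASNe-Gln                        -> Glu + ASNe-NH3
    r3: ASNe-NH3 + Asp + ATP + Mg2+     -> bAsp-AMP-ASNe-NH3   (Mg2+ catalytic)
    r4: bAsp-AMP-ASNe-NH3               -> Asn + ASNe + AMP
    D : ASNe-NH3                        -> ASNe

The dissociation step D loses the bound amide nitrogen, letting glutamate
production (r1, r2) run ahead of, and independently of, asparagine production
(r3, r4) once aspartate is depleted.  ATP and Mg2+ are clamped boundary
species (held in excess by the assay buffer); water and pyrophosphate are
ubiquitous and omitted.

Two wheat enzymes are parameterized: TaASN1 and TaASN2.  They share k2-k4 and
differ in the glutamine binding constant k1 and, chiefly, in the dissociation
constant kD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .netcore import (
    ConfigurationError,
    Place,
    Reaction,
    ReactionNetwork,
    network_from_dict,
)

import json

__all__ = [
    "SPECIES",
    "RateParams",
    "EnzymeProfile",
    "ENZYMES",
    "build_asn_network",
    "load_asn_network",
    "table4_parameters",
    "enzyme_profile",
    "default_initial_state",
]

# canonical species order (11 places); complexes use ASCII-safe names
ENZYME = "ASNe"
SPECIES = (
    "AMP",
    "Asn",
    "ASNe",
    "ASNe-Gln",
    "ASNe-NH3",
    "Asp",
    "ATP",
    "bAsp-AMP-ASNe-NH3",
    "Gln",
    "Glu",
    "Mg2+",
)


@dataclass(frozen=True)
class RateParams:
    """The five mass-action rate constants of the ASN mechanism.

    Magnitudes are in the package's abstract concentration-unit system;
    mass-action constants of different reaction orders do not share physical
    units, so the printed values are taken at face value as magnitudes.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    kD: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "kD"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate constant {name} must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "k4": self.k4,
            "kD": self.kD,
        }


@dataclass(frozen=True)
class EnzymeProfile:
    """Fitted parameter set and default enzyme loading for one enzyme."""

    name: str
    params: RateParams
    enzyme_start: float  # c.u., the concentration the constants were fitted against
    enzyme_molar_start_nmol_per_ml: float  # informational metadata only


_TABLE4 = {
    "TaASN1": RateParams(k1=0.016, k2=3.0, k3=0.043, k4=10.0, kD=700.0),
    "TaASN2": RateParams(k1=0.02, k2=3.0, k3=0.043, k4=10.0, kD=400.0),
}

ENZYMES = {
    "TaASN1": EnzymeProfile(
        name="TaASN1",
        params=_TABLE4["TaASN1"],
        enzyme_start=0.1,
        enzyme_molar_start_nmol_per_ml=2.03,
    ),
    "TaASN2": EnzymeProfile(
        name="TaASN2",
        params=_TABLE4["TaASN2"],
        enzyme_start=0.09,
        enzyme_molar_start_nmol_per_ml=2.10,
    ),
}


def build_asn_network() -> ReactionNetwork:
    """Construct the canonical 11-species, 5-reaction ASN network.

    ATP and Mg2+ are clamped; Mg2+ appears only in the r3 flux product (it is
    written on both sides of the reaction and its level never changes).
    Initial concentrations are zero; use :func:`default_initial_state` for
    assay conditions.
    """
    places = [
        Place("AMP"),
        Place("Asn"),
        Place("ASNe"),
        Place("ASNe-Gln"),
        Place("ASNe-NH3"),
        Place("Asp"),
        Place("ATP", clamped=True),
        Place("bAsp-AMP-ASNe-NH3"),
        Place("Gln"),
        Place("Glu"),
        Place("Mg2+", clamped=True),
    ]
    reactions = [
        Reaction("r1", {"ASNe": 1, "Gln": 1}, {"ASNe-Gln": 1}, "k1"),
        Reaction("r2", {"ASNe-Gln": 1}, {"Glu": 1, "ASNe-NH3": 1}, "k2"),
        Reaction(
            "r3",
            {"ASNe-NH3": 1, "Asp": 1, "ATP": 1, "Mg2+": 1},
            {"bAsp-AMP-ASNe-NH3": 1, "Mg2+": 1},
            "k3",
        ),
        Reaction(
            "r4", {"bAsp-AMP-ASNe-NH3": 1}, {"Asn": 1, "ASNe": 1, "AMP": 1}, "k4"
        ),
        Reaction("D", {"ASNe-NH3": 1}, {"ASNe": 1}, "kD"),
    ]
    return ReactionNetwork(places=places, reactions=reactions)


def load_asn_network() -> ReactionNetwork:
    """Load the packaged JSON fixture of the canonical network."""
    text = resources.files("asnkin").joinpath("data/asn_network.json").read_text()
    return network_from_dict(json.loads(text))


def table4_parameters(enzyme: str) -> RateParams:
    """Fitted rate constants for one enzyme (TaASN1 or TaASN2)."""
    try:
        return _TABLE4[enzyme]
    except KeyError:
        raise ConfigurationError(
            f"unknown enzyme {enzyme!r}; choose from {sorted(_TABLE4)}"
        ) from None


def enzyme_profile(enzyme: str) -> EnzymeProfile:
    try:
        return ENZYMES[enzyme]
    except KeyError:
        raise ConfigurationError(
            f"unknown enzyme {enzyme!r}; choose from {sorted(ENZYMES)}"
        ) from None


def default_initial_state(
    enzyme: str, overrides: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Assay-buffer initial concentrations for one enzyme.

    Asp 1.6, Gln 10, ATP 10, Mg2+ 10 (mM-equivalents in model units), free
    enzyme at the profile's start value, every product and complex at zero.
    ``overrides`` replace individual species last.
    """
    profile = enzyme_profile(enzyme)
    state = {name: 0.0 for name in SPECIES}
    state.update(
        {
            "Asp": 1.6,
            "Gln": 10.0,
            "ATP": 10.0,
            "Mg2+": 10.0,
            "ASNe": profile.enzyme_start,
        }
    )
    if overrides:
        for sp, value in overrides.items():
            if sp not in state:
                raise ConfigurationError(f"unknown species in overrides: {sp!r}")
            state[sp] = float(value)
    return state
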
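"""Reaction-network genotypes: species, reversible reactions, and roles.

A :class:`Network` is the evolvable genotype.  It holds

* a set of species, each with a formula plus four real parameters
  (chemical potential, initial concentration, first-order decay rate, and
  an inflow rate that is only active if the species is the "food"),
* a list of reversible reactions (1-2 reactants, 1-2 products, and a
  genotype-encoded rate constant for the thermodynamically favoured
  direction), and
* an ordered input/output list assigning environmental roles by position:
  position 0 is the stimulus input channel (chemical "B", the conditioned
  stimulus), position 1 the control input channel (chemical "A", the
  unconditioned stimulus), position 2 the output read-out species, and
  position 3 the food species receiving constant inflow.

Thermodynamics: each species has a scalar potential phi in [0, 7.5].  The
favoured direction of a reaction is the one whose products have the lower
total potential; with dPhi = sum(phi, reactants) - sum(phi, products) of
the written direction, the favoured direction gets the encoded rate
constant k and the unfavoured direction k * exp(-|dPhi|), i.e. the
forward/backward ratio is the Boltzmann factor exp(|dPhi|).  Large |dPhi|
makes a reaction effectively irreversible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

from .chemistry import ChemistryRules, conserves_atoms

__all__ = [
    "PARAM_RANGES",
    "INIT_RANGES",
    "SpeciesSpec",
    "Reaction",
    "Network",
    "Roles",
    "NetworkError",
    "UnderspecifiedNetworkError",
    "UndefinedDensityError",
]

#: Allowable parameter ranges (mutation reflects at these bounds).
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "potential": (0.0, 7.5),
    "initial_concentration": (0.0, 5.0),
    "food_inflow": (0.0, 5.0),
    "decay_rate": (0.0, 10.0),
    "k_fav": (0.0, 1.0),
}

#: Initialisation ranges for freshly created species / reactions.
INIT_RANGES: dict[str, tuple[float, float]] = {
    "potential": (0.0, 7.5),
    "initial_concentration": (0.0, 2.0),
    "food_inflow": (0.0, 1.0),
    "decay_rate": (0.0, 1.0),
    "k_fav": (0.0, 0.1),
}


class NetworkError(ValueError):
    pass


class UnderspecifiedNetworkError(NetworkError):
    """Fewer than the four species needed for role assignment."""


class UndefinedDensityError(NetworkError):
    """No species participates in any reaction."""


@dataclass
class SpeciesSpec:
    """One chemical species and its real-valued genotype parameters."""

    formula: str
    potential: float
    initial_concentration: float
    decay_rate: float
    food_inflow: float

    def validate(self) -> None:
        for name in ("potential", "initial_concentration", "decay_rate", "food_inflow"):
            lo, hi = PARAM_RANGES[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise NetworkError(f"{self.formula}: {name}={v} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "potential": self.potential,
            "init_conc": self.initial_concentration,
            "decay": self.decay_rate,
            "inflow": self.food_inflow,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesSpec":
        return cls(
            formula=d["formula"],
            potential=float(d["potential"]),
            initial_concentration=float(d["init_conc"]),
            decay_rate=float(d["decay"]),
            food_inflow=float(d["inflow"]),
        )


@dataclass
class Reaction:
    """A reversible reaction written as lhs <-> rhs.

    ``k_fav`` is the rate constant of the thermodynamically favoured
    direction (which side that is depends on the species potentials and is
    not part of the encoding).
    """

    lhs: tuple[str, ...]
    rhs: tuple[str, ...]
    k_fav: float

    def __post_init__(self) -> None:
        self.lhs = tuple(self.lhs)
        self.rhs = tuple(self.rhs)
        if not 1 <= len(self.lhs) <= 2 or not 1 <= len(self.rhs) <= 2:
            raise NetworkError("reactions have 1-2 species per side")
        if self.k_fav < 0:
            raise NetworkError("k_fav must be >= 0")
        if not conserves_atoms(self.lhs, self.rhs):
            raise NetworkError(
                f"reaction {self.lhs} <-> {self.rhs} does not conserve atoms"
            )

    @property
    def is_null(self) -> bool:
        """True if both sides are the same multiset (no dynamical effect)."""
        return sorted(self.lhs) == sorted(self.rhs)

    def delta_potential(self, potentials: Mapping[str, float]) -> float:
        """dPhi = total potential(lhs) - total potential(rhs)."""
        return sum(potentials[s] for s in self.lhs) - sum(
            potentials[s] for s in self.rhs
        )

    def format(self) -> str:
        return " + ".join(self.lhs) + " <-> " + " + ".join(self.rhs)

    def to_dict(self) -> dict:
        return {"lhs": list(self.lhs), "rhs": list(self.rhs), "k_fav": self.k_fav}

    @classmethod
    def from_dict(cls, d: dict) -> "Reaction":
        return cls(lhs=tuple(d["lhs"]), rhs=tuple(d["rhs"]), k_fav=float(d["k_fav"]))


class Roles(NamedTuple):
    stimulus: str  # input channel "B" (conditioned stimulus S)
    control: str  # input channel "A" (unconditioned stimulus C)
    output: str  # read-out species O
    food: str  # species receiving constant inflow


@dataclass
class Network:
    """The full genotype: chemistry rules, species, reactions, io list."""

    rules: ChemistryRules
    species: dict[str, SpeciesSpec]
    reactions: list[Reaction]
    io_list: list[str]

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if sorted(self.io_list) != sorted(self.species):
            raise NetworkError("io_list must be a permutation of the species set")
        for f, spec in self.species.items():
            if spec.formula != f:
                raise NetworkError("species dict key must equal its formula")
            self.rules.validate(f)
            if len(f) > self.rules.max_length:
                raise NetworkError(f"formula {f!r} longer than max_length")
            spec.validate()
        for rxn in self.reactions:
            for s in rxn.lhs + rxn.rhs:
                if s not in self.species:
                    raise NetworkError(f"reaction references unknown species {s!r}")
            lo, hi = PARAM_RANGES["k_fav"]
            if not lo <= rxn.k_fav <= hi:
                raise NetworkError(f"k_fav={rxn.k_fav} outside [{lo}, {hi}]")

    # -- roles ---------------------------------------------------------

    def roles(self) -> Roles:
        """Positional read-off of the environmental roles from io_list."""
        if len(self.io_list) < 4:
            raise UnderspecifiedNetworkError(
                "role assignment needs at least 4 species"
            )
        return Roles(*self.io_list[:4])

    # -- thermodynamics ------------------------------------------------

    def _potentials(self) -> dict[str, float]:
        return {f: s.potential for f, s in self.species.items()}

    def favoured_direction(self, rxn: Reaction) -> str:
        """``"forward"`` or ``"reverse"`` as written.

        The favoured direction is the one whose products sit at lower
        total potential; an exact tie counts as forward.
        """
        dphi = rxn.delta_potential(self._potentials())
        return "forward" if dphi >= 0 else "reverse"

    def rate_constants(self, rxn: Reaction) -> tuple[float, float]:
        """(k_forward, k_reverse) as written, with k_fav in the favoured
        direction and k_fav * exp(-|dPhi|) in the other."""
        dphi = rxn.delta_potential(self._potentials())
        k_unfav = rxn.k_fav * math.exp(-abs(dphi))
        if dphi >= 0:
            return rxn.k_fav, k_unfav
        return k_unfav, rxn.k_fav

    # -- statistics ----------------------------------------------------

    def connection_density(self) -> float:
        """Mean number of distinct reactions per participating species.

        Species mentioned by no reaction are excluded; if there are none
        left the density is undefined.
        """
        counts = {f: 0 for f in self.species}
        for rxn in self.reactions:
            for f in set(rxn.lhs) | set(rxn.rhs):
                counts[f] += 1
        active = [c for c in counts.values() if c > 0]
        if not active:
            raise UndefinedDensityError("no species participates in any reaction")
        return sum(active) / len(active)

    # -- copying / serialization ---------------------------------------

    def copy(self) -> "Network":
        return Network(
            rules=self.rules,
            species={f: replace(s) for f, s in self.species.items()},
            reactions=[replace(r) for r in self.reactions],
            io_list=list(self.io_list),
        )

    def to_dict(self) -> dict:
        return {
            "chemistry": self.rules.to_dict(),
            "species": [self.species[f].to_dict() for f in self.species],
            "reactions": [r.to_dict() for r in self.reactions],
            "io_list": list(self.io_list),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Network":
        species = {s["formula"]: SpeciesSpec.from_dict(s) for s in d["species"]}
        net = cls(
            rules=ChemistryRules.from_dict(d["chemistry"]),
            species=species,
            reactions=[Reaction.from_dict(r) for r in d["reactions"]],
            io_list=list(d["io_list"]),
        )
        net.validate()
        return net

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "Network":
        """Load a genotype from a JSON string or file path."""
        import os

        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(source))
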
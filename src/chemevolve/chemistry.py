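"""Combinatorial string chemistries with conserved building blocks.

Every chemical species carries a "formula": a short string over a finite
digit alphabet (binary by default).  Each character is an indivisible
building block ("atom"), and every reaction is constructed so that the
multiset of characters on the left-hand side equals the multiset on the
right-hand side -- mass conservation by construction.

Three rule systems govern how formulas combine and split:

``polymer``
    Composition is concatenation; decomposition cuts the string at a
    uniformly chosen position.  Character order matters, so ``01`` and
    ``10`` are distinct species.  Resembles ligation/cleavage of polymers.

``rearrangement``
    Composition is concatenation followed by a fair shuffle of the
    characters; decomposition shuffles and then cuts.  Order still
    distinguishes species, but reactions can scramble it.

``aggregation``
    Only the character counts identify a species: formulas are stored
    lexicographically sorted, so ``10`` and ``01`` name the same species.
    Composition sorts the concatenation; decomposition shuffles, cuts and
    sorts each part.  Resembles inorganic aggregates of atoms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "ChemistryError",
    "InvalidFormulaError",
    "FormulaTooLongError",
    "IndivisibleFormulaError",
    "ChemistryRules",
    "CHEMISTRY_KINDS",
    "canonicalize",
    "compose",
    "decompose",
    "rearrange",
    "conserves_atoms",
]

CHEMISTRY_KINDS = ("polymer", "rearrangement", "aggregation")

_DIGITS = "0123456789"


class ChemistryError(ValueError):
    """Base class for chemistry rule violations."""


class InvalidFormulaError(ChemistryError):
    """Formula is empty or contains characters outside the alphabet."""


class FormulaTooLongError(ChemistryError):
    """A composition would exceed the maximum formula length."""


class IndivisibleFormulaError(ChemistryError):
    """A single-character formula cannot be decomposed."""


@dataclass(frozen=True)
class ChemistryRules:
    """Parameters of a string chemistry.

    Parameters
    ----------
    kind
        One of ``"polymer"``, ``"rearrangement"``, ``"aggregation"``.
    alphabet_size
        Number of distinct building-block characters (>= 2).  Characters
        are the decimal digits ``"0"``, ``"1"``, ...
    max_length
        Maximum formula length of any *species* (>= 2).  Transient
        composition intermediates inside a rearrangement reaction may be
        longer; the final products never are.
    """

    kind: str
    alphabet_size: int = 2
    max_length: int = 4

    def __post_init__(self) -> None:
        if self.kind not in CHEMISTRY_KINDS:
            raise ValueError(f"unknown chemistry kind {self.kind!r}")
        if not 2 <= self.alphabet_size <= len(_DIGITS):
            raise ValueError("alphabet_size must be in [2, 10]")
        if self.max_length < 2:
            raise ValueError("max_length must be >= 2")

    @property
    def alphabet(self) -> str:
        return _DIGITS[: self.alphabet_size]

    def validate(self, formula: str) -> None:
        """Raise :class:`InvalidFormulaError` if ``formula`` is malformed."""
        if not formula:
            raise InvalidFormulaError("empty formula")
        bad = set(formula) - set(self.alphabet)
        if bad:
            raise InvalidFormulaError(
                f"characters {sorted(bad)} outside alphabet {self.alphabet!r}"
            )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "alphabet_size": self.alphabet_size,
            "max_length": self.max_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChemistryRules":
        return cls(
            kind=d["kind"],
            alphabet_size=int(d.get("alphabet_size", 2)),
            max_length=int(d.get("max_length", 4)),
        )


def canonicalize(formula: str, rules: ChemistryRules) -> str:
    """Return the canonical spelling of ``formula`` under ``rules``.

    Aggregation chemistry identifies species by character counts only, so
    the canonical spelling is the sorted string; the other chemistries
    keep the string as written.
    """
    rules.validate(formula)
    if rules.kind == "aggregation":
        return "".join(sorted(formula))
    return formula


def _shuffled(s: str, rng: np.random.Generator) -> str:
    chars = list(s)
    rng.shuffle(chars)
    return "".join(chars)


def _valid_cuts(length: int, max_length: int) -> list[int]:
    return [i for i in range(1, length) if i <= max_length and length - i <= max_length]


def compose(
    a: str, b: str, rules: ChemistryRules, rng: np.random.Generator | None = None
) -> str:
    """Combine two formulas into one product formula.

    Raises
    ------
    FormulaTooLongError
        If the combined length exceeds ``rules.max_length``.  Callers that
        build reactions fall back to a rearrangement reaction in that case.
    """
    rules.validate(a)
    rules.validate(b)
    if len(a) + len(b) > rules.max_length:
        raise FormulaTooLongError(
            f"{a!r}+{b!r} would exceed max length {rules.max_length}"
        )
    glued = a + b
    if rules.kind == "polymer":
        return glued
    if rules.kind == "aggregation":
        return "".join(sorted(glued))
    if rng is None:
        raise ValueError("rearrangement composition needs a random generator")
    return _shuffled(glued, rng)


def _split(
    s: str, rules: ChemistryRules, rng: np.random.Generator | None
) -> Tuple[str, str]:
    """Cut ``s`` (possibly an over-length intermediate) into two legal parts."""
    if rules.kind != "polymer":
        if rng is None:
            raise ValueError("shuffled decomposition needs a random generator")
        s = _shuffled(s, rng)
    cuts = _valid_cuts(len(s), rules.max_length)
    if not cuts:
        raise FormulaTooLongError(f"no legal cut of {s!r} at max length {rules.max_length}")
    if len(cuts) == 1:
        cut = cuts[0]
    else:
        if rng is None:
            raise ValueError("cut choice needs a random generator")
        cut = cuts[int(rng.integers(len(cuts)))]
    left, right = s[:cut], s[cut:]
    if rules.kind == "aggregation":
        left = "".join(sorted(left))
        right = "".join(sorted(right))
    return left, right


def decompose(
    f: str, rules: ChemistryRules, rng: np.random.Generator | None = None
) -> Tuple[str, str]:
    """Split one formula into two, conserving its characters.

    Raises
    ------
    IndivisibleFormulaError
        If ``f`` has a single character (no reaction can be formed).
    """
    rules.validate(f)
    if len(f) < 2:
        raise IndivisibleFormulaError(f"cannot decompose single-character {f!r}")
    return _split(f, rules, rng)


def rearrange(
    a: str, b: str, rules: ChemistryRules, rng: np.random.Generator | None = None
) -> Tuple[str, str]:
    """Recombine two formulas into two (possibly different) formulas.

    Modelled as composition followed by decomposition; the transient
    concatenation may exceed ``max_length``, but the cut position is
    restricted so both products respect it.
    """
    rules.validate(a)
    rules.validate(b)
    return _split(a + b, rules, rng)


def conserves_atoms(lhs: Iterable[str], rhs: Iterable[str]) -> bool:
    """True iff the per-character counts match across reaction sides."""
    lhs = list(lhs)
    rhs = list(rhs)
    if not lhs or not rhs:
        raise ValueError("reaction sides must be non-empty")
    return Counter("".join(lhs)) == Counter("".join(rhs))


def all_canonical_formulas(rules: ChemistryRules, length: int) -> list[str]:
    """Enumerate every distinct species formula of a given length."""
    from itertools import combinations_with_replacement, product

    if rules.kind == "aggregation":
        return [
            "".join(c)
            for c in combinations_with_replacement(rules.alphabet, length)
        ]
    return ["".join(c) for c in product(rules.alphabet, repeat=length)]
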
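"""Combinatorial calculus of heterophilic adhesins and seeding elements.

Surface-displayed nanobody (Nb) / antigen (Ag) adhesin pairs bind strictly
within a family: Nb2 binds Ag2 and Nb3 binds Ag3, but Nb2 does not bind Ag3.
A strain (or strain mixture) seeded at one position carries a *set* of
adhesins, called an element.  With a four-adhesin library {Nb2, Ag2, Nb3,
Ag3} there are 2**4 = 16 elements, of which nine are of practical use for
patterning: the null element (no adhesin), four singlets and four doublets
whose two adhesins are non-complementary.  Elements containing an internal
complementary pair self-aggregate and are excluded from patterning.

A *visible* interface forms between two seeded populations iff some adhesin
of one is complementary to some adhesin of the other; otherwise the meeting
line is a *hidden* interface.  On the doublet subset this reduces to
"visible iff different".
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "Role",
    "Adhesin",
    "Element",
    "LibraryError",
    "NonPracticalElementError",
    "complementary",
    "default_library",
    "enumerate_elements",
    "ElementCensus",
    "visible_interface",
    "interface_matrix",
    "parse_element",
    "format_element",
    "NULL",
    "SINGLETS",
    "DOUBLETS",
]


class Role(str, Enum):
    """Binding role of an adhesin: nanobody (Nb) or its antigen (Ag)."""

    NB = "Nb"
    AG = "Ag"


@dataclass(frozen=True, order=True)
class Adhesin:
    """One surface-displayed adhesin, identified by family index and role.

    Two adhesins are complementary iff they share a family index and have
    opposite roles.  Family indices are open-ended integers; the
    experimentally characterized library uses families {2, 3}.
    """

    family: int
    role: Role

    def __str__(self) -> str:
        return f"{self.role.value}{self.family}"

    @property
    def partner(self) -> "Adhesin":
        """The unique adhesin this one binds."""
        other = Role.AG if self.role is Role.NB else Role.NB
        return Adhesin(self.family, other)


def complementary(a: Adhesin, b: Adhesin) -> bool:
    """True iff ``a`` binds ``b``: same family, opposite roles.

    Symmetric and irreflexive (an adhesin never binds a copy of itself).
    """
    return a.family == b.family and a.role is not b.role


@dataclass(frozen=True)
class Element:
    """The set of adhesins present at one seeding position.

    Cardinality 0 is the null element, 1 a singlet, 2 a doublet.  An
    element is *practical* iff it contains no internal complementary pair;
    only practical elements take part in interface patterning.  Whether the
    adhesins are co-expressed by one strain or contributed by a mixture of
    singlet strains is immaterial to the interface logic, so elements are
    plain unordered sets.
    """

    adhesins: frozenset[Adhesin]

    def __init__(self, adhesins: Iterable[Adhesin] = ()) -> None:
        object.__setattr__(self, "adhesins", frozenset(adhesins))

    @property
    def practical(self) -> bool:
        """No internal complementary pair (no self-interaction)."""
        return not any(
            complementary(a, b)
            for a, b in itertools.combinations(self.adhesins, 2)
        )

    @property
    def kind(self) -> str:
        """'null', 'singlet', 'doublet' or 'multiplet' by cardinality."""
        n = len(self.adhesins)
        return {0: "null", 1: "singlet", 2: "doublet"}.get(n, "multiplet")

    def __str__(self) -> str:
        return format_element(self)

    def __len__(self) -> int:
        return len(self.adhesins)

    def __iter__(self):
        return iter(sorted(self.adhesins))


class LibraryError(ValueError):
    """An adhesin library missing one member of a complementary pair."""


class NonPracticalElementError(ValueError):
    """A self-interacting element was used where patterning excludes it."""


def default_library() -> frozenset[Adhesin]:
    """The four-adhesin library of families 2 and 3 (4 bits)."""
    return frozenset(
        Adhesin(f, r) for f in (2, 3) for r in (Role.NB, Role.AG)
    )


@dataclass(frozen=True)
class ElementCensus:
    """Power-set enumeration of a library, partitioned by practical use."""

    all: tuple[Element, ...]
    practical: tuple[Element, ...]
    null: tuple[Element, ...]
    singlets: tuple[Element, ...]
    doublets: tuple[Element, ...]


def enumerate_elements(library: Iterable[Adhesin]) -> ElementCensus:
    """Enumerate every element over ``library`` and classify it.

    ``all`` is the full power set (2**|library| elements); ``practical``
    keeps those with no internal complementary pair.  For the four-adhesin
    library: 16 elements overall, of which 9 are practical (1 null +
    4 singlets + 4 doublets).

    Raises
    ------
    LibraryError
        If any adhesin's complementary partner is absent, the library
        cannot form interfaces and is rejected.
    """
    lib = sorted(set(library))
    unpaired = [a for a in lib if a.partner not in lib]
    if unpaired:
        raise LibraryError(
            "library is missing complementary partners for: "
            + ", ".join(str(a) for a in unpaired)
        )
    everything = tuple(
        Element(combo)
        for k in range(len(lib) + 1)
        for combo in itertools.combinations(lib, k)
    )
    practical = tuple(e for e in everything if e.practical)
    return ElementCensus(
        all=everything,
        practical=practical,
        null=tuple(e for e in practical if e.kind == "null"),
        singlets=tuple(e for e in practical if e.kind == "singlet"),
        doublets=tuple(e for e in practical if e.kind == "doublet"),
    )


def visible_interface(e1: Element, e2: Element) -> bool:
    """Whether two practical elements form a macroscopically visible interface.

    True iff some adhesin of ``e1`` is complementary to some adhesin of
    ``e2``.  Symmetric; always False for an element against itself (a
    practical element carries no complementary pair) and for the null
    element against anything.  On the doublet subset this is exactly the
    "visible iff different" rule.

    Raises
    ------
    NonPracticalElementError
        Self-interacting elements are excluded from patterning.
    """
    for e in (e1, e2):
        if not e.practical:
            raise NonPracticalElementError(
                f"element {e} self-interacts and is excluded from patterning"
            )
    return any(
        complementary(a, b) for a in e1.adhesins for b in e2.adhesins
    )


def interface_matrix(elements: list[Element]) -> np.ndarray:
    """Symmetric boolean matrix of ``visible_interface`` over all pairs.

    The diagonal is all False: a population never forms a visible interface
    with itself.
    """
    n = len(elements)
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = visible_interface(elements[i], elements[j])
    return out


# -- text syntax --------------------------------------------------------------
#
# "n" (null), "Nb2" / "Ag3" (singlets), "Nb2+Ag3" (doublets, '+'-joined,
# order-insensitive).  Used by the seed CSV `element` column and the CLI.

_ADHESIN_RE = re.compile(r"^(Nb|Ag)(\d+)$")


def _parse_adhesin(token: str) -> Adhesin:
    m = _ADHESIN_RE.match(token.strip())
    if not m:
        raise ValueError(f"unrecognized adhesin token {token!r}")
    return Adhesin(int(m.group(2)), Role(m.group(1)))


def parse_element(text: str) -> Element:
    """Parse the element text syntax: ``"n"``, ``"Nb2"``, ``"Nb2+Ag3"``."""
    text = text.strip()
    if text in ("n", "null", ""):
        return Element()
    return Element(_parse_adhesin(tok) for tok in text.split("+"))


def format_element(e: Element) -> str:
    """Inverse of :func:`parse_element` (adhesins in sorted order)."""
    if not e.adhesins:
        return "n"
    return "+".join(str(a) for a in sorted(e.adhesins))


# Canonical practical elements of the four-adhesin library, for convenience.
NULL = Element()
SINGLETS = tuple(
    Element([a]) for a in sorted(default_library())
)
DOUBLETS = tuple(
    Element(pair)
    for pair in itertools.combinations(sorted(default_library()), 2)
    if Element(pair).practical
)
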
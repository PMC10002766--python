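"""Exact-mass arithmetic over molecular formulas and ions.

A :class:`MolecularFormula` is an element->count map plus an explicit count
of oxygens designated as the heavy isotope (``n_heavy_o``).  Charge never
lives inside a formula; it is carried by :class:`IonSpec`.  Formula strings
use Hill notation (C first, then H, then other elements alphabetically)
with an optional ``[18O]k`` suffix marking k heavy oxygens, e.g.
``"C18H28N2O2[18O]1"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .constants import ELECTRON_MASS, O16_MASS, O18_MASS, PROTON_MASS, NIST_MASS, monoisotopic

__all__ = [
    "MolecularFormula",
    "IonSpec",
    "POSITIVE",
    "NEGATIVE",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "ion_mz",
    "cation_mz",
    "ppm_diff",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_HEAVY_SUFFIX = re.compile(r"\[18O\](\d+)$")


class MolecularFormula:
    """Immutable element-count map with a heavy-oxygen designation.

    Parameters
    ----------
    counts
        Mapping element symbol -> count.  All counts must be positive;
        zero entries are dropped.
    n_heavy_o
        Number of the formula's oxygens to weight at the 18O mass
        (0 <= n_heavy_o <= counts["O"]).
    """

    __slots__ = ("_counts", "_n_heavy_o", "_hash")

    def __init__(self, counts: Mapping[str, int], n_heavy_o: int = 0):
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if not isinstance(n, int):
                raise TypeError(f"count for {el!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if el not in NIST_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n > 0:
                clean[el] = n
        if n_heavy_o < 0:
            raise ValueError("n_heavy_o must be non-negative")
        if n_heavy_o > clean.get("O", 0):
            raise ValueError(
                f"n_heavy_o={n_heavy_o} exceeds oxygen count {clean.get('O', 0)}"
            )
        self._counts = clean
        self._n_heavy_o = n_heavy_o
        self._hash = hash((tuple(sorted(clean.items())), n_heavy_o))

    # -- mapping-ish access -------------------------------------------------
    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    @property
    def n_heavy_o(self) -> int:
        return self._n_heavy_o

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for el, n in other._counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts, self._n_heavy_o + other._n_heavy_o)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for el, n in other._counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction drives {el!r} negative ({counts.get(el, 0)} - {n})"
                )
            counts[el] = new
        n_heavy = self._n_heavy_o - other._n_heavy_o
        if n_heavy < 0:
            raise ValueError("subtraction drives n_heavy_o negative")
        return MolecularFormula(counts, n_heavy)

    def apply_delta(self, delta: Mapping[str, int]) -> "MolecularFormula":
        """Apply a signed element-count delta; raises if any count goes negative."""
        counts = dict(self._counts)
        for el, n in delta.items():
            new = counts.get(el, 0) + n
            if new < 0:
                raise ValueError(f"delta drives {el!r} negative")
            counts[el] = new
        return MolecularFormula(counts, self._n_heavy_o)

    def with_heavy_o(self, n_heavy_o: int) -> "MolecularFormula":
        """Copy with a different number of oxygens designated 18O."""
        return MolecularFormula(self._counts, n_heavy_o)

    # -- identity -----------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self._counts == other._counts and self._n_heavy_o == other._n_heavy_o

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"MolecularFormula({format_formula(self)!r})"

    def __str__(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class IonSpec:
    """Ionization convention: protonated [M+H]+ or deprotonated [M-H]-."""

    adduct: str = "protonated"
    polarity: int = field(init=False, default=0)

    def __post_init__(self):
        if self.adduct not in ("protonated", "deprotonated"):
            raise ValueError(f"unknown adduct: {self.adduct!r}")
        object.__setattr__(
            self, "polarity", +1 if self.adduct == "protonated" else -1
        )


POSITIVE = IonSpec("protonated")
NEGATIVE = IonSpec("deprotonated")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string, e.g. ``"C18H28N2O2[18O]1"``.

    The optional ``[18O]k`` suffix designates k of the formula's oxygens
    as the heavy isotope; it does not add oxygens.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    n_heavy = 0
    m = _HEAVY_SUFFIX.search(text)
    if m:
        n_heavy = int(m.group(1))
        text = text[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula at position {pos}: {text!r}")
        el, digits = m.group(1), m.group(2)
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n == 0:
                raise ValueError(f"zero count for element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(counts, n_heavy)


def format_formula(f: MolecularFormula) -> str:
    """Hill-order formula string; round-trips through :func:`parse_formula`."""
    counts = f.counts
    parts: list[str] = []

    def emit(el: str) -> None:
        n = counts.pop(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")

    if "C" in counts:
        emit("C")
        emit("H")
    for el in sorted(counts):
        emit(el)
    out = "".join(parts)
    if f.n_heavy_o:
        out += f"[18O]{f.n_heavy_o}"
    return out


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da, with ``n_heavy_o`` oxygens at the 18O mass."""
    total = 0.0
    for el, n in f.counts.items():
        total += n * monoisotopic(el)
    total += f.n_heavy_o * (O18_MASS - O16_MASS)
    return total


def ion_mz(f: MolecularFormula, ion: IonSpec = POSITIVE) -> float:
    """m/z of the singly charged ion.

    Protonated ions add the proton mass (not a hydrogen atom), i.e. the
    electron bookkeeping follows the Orbitrap-reported convention
    m/z([M+H]+) = M + 1.00728; deprotonated ions subtract it.
    """
    m = monoisotopic_mass(f)
    return m + PROTON_MASS if ion.adduct == "protonated" else m - PROTON_MASS


def cation_mz(f: MolecularFormula) -> float:
    """m/z of an even-electron cation whose composition *is* ``f``.

    Used for MS/MS product ions, whose formulas already include the
    transferred proton: m/z = monoisotopic mass - electron mass.
    """
    return monoisotopic_mass(f) - ELECTRON_MASS


def ppm_diff(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
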
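"""Isotope masses and abundances.

Monoisotopic masses and natural abundances are taken from the NIST table
shipped with pyteomics (CODATA/IUPAC values, full precision).  The
heavy-oxygen mass shift is exposed in two forms:

``O18_O16_DELTA``
    the full-precision mass difference M(18O) - M(16O) = 2.0042464 Da,
    used for all m/z arithmetic, channel placement and tolerance checks;

``O18_O16_DELTA_PRINTED``
    2.0043 Da, the difference of the 4-decimal-rounded isotope masses
    (17.9992 - 15.9949).  This is the conventional figure quoted for the
    single-oxygen shift in labeling experiments and is reproduced here
    for reporting; it differs from the full-precision value in the fourth
    decimal because rounding each mass before subtracting does not
    commute with subtraction.
"""

from __future__ import annotations

from pyteomics import mass as _pt_mass

#: element -> {mass number -> (monoisotopic mass, natural abundance)}
NIST_MASS = _pt_mass.nist_mass

PROTON_MASS: float = NIST_MASS["H+"][0][0]        # 1.00727646677 Da
ELECTRON_MASS: float = NIST_MASS["e*"][0][0]      # 0.00054857991 Da

O16_MASS: float = NIST_MASS["O"][16][0]
O18_MASS: float = NIST_MASS["O"][18][0]
O18_NATURAL_ABUNDANCE: float = NIST_MASS["O"][18][1]   # 0.00205

O18_O16_DELTA: float = O18_MASS - O16_MASS
O18_O16_DELTA_PRINTED: float = round(round(O18_MASS, 4) - round(O16_MASS, 4), 4)


def monoisotopic(element: str) -> float:
    """Monoisotopic (lightest-principal-isotope) mass of an element, Da."""
    try:
        return NIST_MASS[element][0][0]
    except KeyError as exc:
        raise KeyError(f"unknown element symbol: {element!r}") from exc


def isotope_distribution(element: str) -> list[tuple[float, float]]:
    """Natural isotope distribution of an element.

    Returns ``[(mass, abundance), ...]`` for isotopes with non-zero
    natural abundance, sorted by mass.
    """
    try:
        table = NIST_MASS[element]
    except KeyError as exc:
        raise KeyError(f"unknown element symbol: {element!r}") from exc
    iso = [(m, ab) for a, (m, ab) in table.items() if a != 0 and ab > 0.0]
    if not iso:  # element with a defined mass but no abundance table
        return [(table[0][0], 1.0)]
    iso.sort()
    total = sum(ab for _, ab in iso)
    return [(m, ab / total) for m, ab in iso]
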
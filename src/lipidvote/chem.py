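"""Elemental formulas, exact masses, and adducts for positive-mode DI-FTMS.

The element alphabet is fixed to {C, H, N, O, P}: the formula caches used for
assignment are enumerated over these five elements only.  Formulas are stored
as plain ``(C, H, N, O, P)`` count tuples so they can live in large numpy
caches; Hill-notation strings are used at every file boundary.

All monoisotopic masses and natural isotope abundances come from the NIST
tables shipped with :mod:`pyteomics`.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pmass

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P")

Formula = tuple[int, int, int, int, int]

_NIST = _pmass.nist_mass

#: monoisotopic mass of each element in the alphabet, Da
MONO_MASS: dict[str, float] = {el: _NIST[el][0][0] for el in ELEMENTS}

ELECTRON_MASS: float = _NIST["e*"][0][0]

#: mass shift of one heavy-isotope substitution, Da
ISOTOPE_DELTA: dict[str, float] = {
    "13C": _NIST["C"][13][0] - _NIST["C"][12][0],
    "15N": _NIST["N"][15][0] - _NIST["N"][14][0],
    "2H": _NIST["H"][2][0] - _NIST["H"][1][0],
}

#: natural abundance of the heavy isotope (per atom of the parent element)
NATURAL_ABUNDANCE: dict[str, float] = {
    "13C": _NIST["C"][13][1],
    "15N": _NIST["N"][15][1],
    "2H": _NIST["H"][2][1],
    "18O": _NIST["O"][18][1],
}

#: which element carries each heavy isotope
ISOTOPE_ELEMENT: dict[str, str] = {"13C": "C", "15N": "N", "2H": "H", "18O": "O"}

#: singly charged positive-mode adducts: name -> mass added to the neutral, Da
ADDUCT_DELTA: dict[str, float] = {
    "H": MONO_MASS["H"] - ELECTRON_MASS,
    "NH4": MONO_MASS["N"] + 4 * MONO_MASS["H"] - ELECTRON_MASS,
    "Na": _NIST["Na"][0][0] - ELECTRON_MASS,
    "K": _NIST["K"][0][0] - ELECTRON_MASS,
}

ADDUCTS: tuple[str, ...] = tuple(ADDUCT_DELTA)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_from_string(s: str) -> Formula:
    """Parse a Hill-notation formula restricted to the C/H/N/O/P alphabet.

    Raises ``ValueError`` on unknown elements or unparseable input.
    """
    counts = dict.fromkeys(ELEMENTS, 0)
    pos = 0
    s = s.strip()
    if not s:
        raise ValueError("empty formula string")
    for m in _FORMULA_TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {s!r} at position {pos}")
        pos = m.end()
        el, n = m.group(1), m.group(2)
        if el not in counts:
            raise ValueError(f"element {el!r} outside the C/H/N/O/P alphabet in {s!r}")
        counts[el] += int(n) if n else 1
    if pos != len(s):
        raise ValueError(f"unparseable formula {s!r} at position {pos}")
    return tuple(counts[el] for el in ELEMENTS)  # type: ignore[return-value]


def formula_to_string(f: Formula) -> str:
    """Hill notation: C first, H second, then N, O, P alphabetically."""
    parts = []
    for el, n in zip(ELEMENTS, f):
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts) or "∅"


def monoisotopic_mass(f: Formula) -> float:
    """Neutral monoisotopic mass in Da."""
    return sum(n * MONO_MASS[el] for el, n in zip(ELEMENTS, f))


def element_count(f: Formula, element: str) -> int:
    return f[ELEMENTS.index(element)]


def imf_mz(elements: Formula, heavy: dict[str, int], adduct: str) -> float:
    """m/z of a singly charged positive adduct of an isotopologue.

    ``heavy`` maps isotope labels ("13C", "15N", "2H") to substitution counts;
    each count must not exceed the corresponding element count.
    """
    for iso, n in heavy.items():
        if n < 0 or n > element_count(elements, ISOTOPE_ELEMENT[iso]):
            raise ValueError(
                f"{n} {iso} substitutions impossible in {formula_to_string(elements)}"
            )
    m = monoisotopic_mass(elements)
    m += sum(n * ISOTOPE_DELTA[iso] for iso, n in heavy.items())
    return m + ADDUCT_DELTA[adduct]
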
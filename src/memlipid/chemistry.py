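"""Elemental compositions, monoisotopic masses and ESI adduct arithmetic.

An :class:`ElementalComposition` is a plain element -> count mapping
(``Counter`` subclass) so compositions add and subtract naturally.
Monoisotopic masses are looked up in the NIST table shipped with
:mod:`pyteomics`; heavy isotopes are written in pyteomics bracket
notation (``C[13]``, ``H[2]``) so deuterated internal standards and
13C tracers are first-class citizens.
"""

from __future__ import annotations

from collections import Counter

from pyteomics import mass as _pmass

__all__ = [
    "ElementalComposition",
    "monoisotopic_mass",
    "adduct_mz",
    "ADDUCTS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER",
]

ELECTRON_MASS = 0.00054857990946
#: mass of H+ (hydrogen atom minus one electron), Da
PROTON_MASS = 1.00727646688


class ElementalComposition(Counter):
    """Element symbol -> non-negative integer count.

    Subtraction that would drive any count negative raises ``ValueError``
    (a molecule cannot contain a negative number of atoms).
    """

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(self)
        for k, v in other.items():
            out[k] += v
        return out

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(self)
        for k, v in other.items():
            out[k] -= v
            if out[k] < 0:
                raise ValueError(f"negative count for element {k}")
            if out[k] == 0:
                del out[k]
        return out

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition({k: v * n for k, v in self.items()})

    __rmul__ = __mul__

    def formula(self) -> str:
        """Hill-ish formula string (C, H first, then alphabetical)."""
        order = sorted(self, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{e}{self[e]}" if self[e] != 1 else e for e in order)


def _atom_mass(symbol: str) -> float:
    try:
        if "[" in symbol:
            elem, iso = symbol.rstrip("]").split("[")
            return _pmass.nist_mass[elem][int(iso)][0]
        return _pmass.nist_mass[symbol][0][0]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown element symbol: {symbol!r}") from exc


def monoisotopic_mass(composition: ElementalComposition | dict) -> float:
    """Monoisotopic mass in Da of an elemental composition.

    Empty compositions weigh 0. Raises ``ValueError`` for unknown symbols.
    """
    total = 0.0
    for symbol, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for element {symbol}")
        total += _atom_mass(symbol) * count
    return total


WATER = ElementalComposition({"H": 2, "O": 1})

# Singly charged adducts used in shotgun ESI lipidomics.  The delta is the
# mass added to the neutral molecule (charge carriers corrected for the
# electron), charge is signed.
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, +1),
    "[M+NH4]+": (monoisotopic_mass({"N": 1, "H": 4}) - ELECTRON_MASS, +1),
    "[M+Na]+": (monoisotopic_mass({"Na": 1}) - ELECTRON_MASS, +1),
    "[M-H]-": (-PROTON_MASS, -1),
    "[M+Cl]-": (monoisotopic_mass({"Cl": 1}) + ELECTRON_MASS, -1),
}


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of ``adduct`` formed from a neutral of ``neutral_mass`` Da."""
    try:
        delta, charge = ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}"
        ) from None
    return (neutral_mass + delta) / abs(charge)
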
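"""Elemental constants used throughout the package.

Z and A are standard atomic numbers and relative atomic masses; I is the
elemental mean excitation energy in eV from the standard stopping-power
tabulation (ICRU Report 37 values, as distributed with NIST ESTAR/PSTAR).
Only elements that occur in body tissues and tissue surrogates are listed;
compositions referencing anything else are rejected up front.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    symbol: str
    z: int
    a: float
    i_ev: float


ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("H", 1, 1.008, 19.2),
        Element("C", 6, 12.011, 78.0),
        Element("N", 7, 14.007, 82.0),
        Element("O", 8, 15.999, 95.0),
        Element("Na", 11, 22.990, 149.0),
        Element("Mg", 12, 24.305, 156.0),
        Element("P", 15, 30.974, 173.0),
        Element("S", 16, 32.06, 180.0),
        Element("Cl", 17, 35.45, 174.0),
        Element("Ar", 18, 39.948, 188.0),
        Element("K", 19, 39.098, 190.0),
        Element("Ca", 20, 40.078, 191.0),
    ]
}

#: Column order used in composition CSV files.
CSV_ELEMENT_ORDER = ["H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "Ar", "K", "Ca"]
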
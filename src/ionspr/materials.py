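"""Tissue compositions and composition-level physics oracles.

A :class:`TissueComposition` is a named material with a mass density and
elemental mass fractions.  From it the quantities that drive both imaging
chains are derived:

* relative electron density (ED), electrons per volume relative to water,
* effective atomic number (EAN), the electron-fraction-weighted power mean
  of the elemental atomic numbers with exponent n = 2.94,
* mean excitation energy (I-value) via Bragg additivity over electron
  fractions.

The embedded reference tissues are ICRU-44/ICRP-style adult compositions;
they are package fixtures standing in for the reference human tissues that a
clinical stoichiometric calibration would use.  The tissue-surrogate insert
set is synthetic: mixtures of the reference tissues with water spanning
lung-equivalent to cortical-bone-equivalent, in the role of a commercial
electron-density calibration phantom.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elements import CSV_ELEMENT_ORDER, ELEMENTS

#: Default exponent of the effective-atomic-number power mean.
EAN_EXPONENT = 2.94

#: Electrons per gram of water, Σ w_i Z_i / A_i (mol electrons per gram).
_WATER_ZA = 0.1119 * 1 / 1.008 + 0.8881 * 8 / 15.999


@dataclass(frozen=True)
class TissueComposition:
    """Named material: mass density (g/cm³) and elemental mass fractions."""

    name: str
    mass_density: float
    elemental_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if not self.elemental_fractions:
            raise ValueError(f"{self.name}: empty composition")
        for sym in self.elemental_fractions:
            if sym not in ELEMENTS:
                raise ValueError(f"{self.name}: element {sym!r} has no tabulated data")
        total = sum(self.elemental_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")

    # -- derived quantities -------------------------------------------------

    def electron_fractions(self) -> dict[str, float]:
        """λ_i = w_i Z_i/A_i normalized to sum 1 (fraction of electrons)."""
        raw = {
            s: w * ELEMENTS[s].z / ELEMENTS[s].a
            for s, w in self.elemental_fractions.items()
        }
        tot = sum(raw.values())
        return {s: v / tot for s, v in raw.items()}

    def electrons_per_gram(self) -> float:
        return sum(
            w * ELEMENTS[s].z / ELEMENTS[s].a
            for s, w in self.elemental_fractions.items()
        )

    def electron_density(self) -> float:
        """Relative electron density (water = 1)."""
        return self.mass_density * self.electrons_per_gram() / _WATER_ZA


def ean_from_composition(comp: TissueComposition, exponent: float = EAN_EXPONENT) -> float:
    """Effective atomic number, (Σ λ_i Z_i^n)^(1/n) over electron fractions."""
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    lam = comp.electron_fractions()
    return float(sum(l * ELEMENTS[s].z ** exponent for s, l in lam.items()) ** (1.0 / exponent))


def ivalue_from_composition(comp: TissueComposition) -> float:
    """Bragg-additivity mean excitation energy, ln I = Σ λ_i ln I_i (eV).

    Uses the raw elemental I-values; Bragg additivity is approximate in the
    condensed phase (water evaluates to ~68.9 eV versus the 78.73 eV assigned
    to liquid water), so calibrated chains apply a water-anchoring rescale on
    top of this — see :func:`anchored_ivalue`.
    """
    lam = comp.electron_fractions()
    ln_i = sum(l * math.log(ELEMENTS[s].i_ev) for s, l in lam.items())
    return float(math.exp(ln_i))


def anchored_ivalue(comp: TissueComposition, i_water: float = 78.73) -> float:
    """Bragg-additivity I rescaled so that water evaluates to ``i_water``.

    A single multiplicative condensed-phase correction keeps the whole I
    scale self-consistent with the assigned water I-value; ratios of
    stopping numbers are nearly invariant under the rescale.
    """
    return ivalue_from_composition(comp) * (i_water / ivalue_from_composition(WATER))


def mix(name: str, a: TissueComposition, b: TissueComposition, frac_a: float,
        mass_density: float) -> TissueComposition:
    """Mass-fraction mixture of two materials at a prescribed density."""
    fr: dict[str, float] = {}
    for s, w in a.elemental_fractions.items():
        fr[s] = fr.get(s, 0.0) + frac_a * w
    for s, w in b.elemental_fractions.items():
        fr[s] = fr.get(s, 0.0) + (1 - frac_a) * w
    total = sum(fr.values())
    fr = {s: w / total for s, w in fr.items()}
    return TissueComposition(name, mass_density, fr)


# -- embedded reference tissues (ICRU-44/ICRP adult) -------------------------

WATER = TissueComposition("water", 1.000, {"H": 0.1119, "O": 0.8881})

AIR = TissueComposition("air", 0.0012, {"N": 0.755, "O": 0.232, "Ar": 0.013})

REFERENCE_TISSUES: dict[str, TissueComposition] = {
    t.name: t
    for t in [
        AIR,
        TissueComposition("lung_inflated", 0.26, {
            "H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749,
            "Na": 0.002, "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002}),
        TissueComposition("adipose", 0.95, {
            "H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
            "Na": 0.001, "S": 0.001, "Cl": 0.001}),
        WATER,
        TissueComposition("csf", 1.007, {
            "H": 0.111, "O": 0.880, "Na": 0.005, "Cl": 0.004}),
        TissueComposition("brain", 1.04, {
            "H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712,
            "Na": 0.002, "P": 0.004, "S": 0.002, "Cl": 0.003, "K": 0.003}),
        TissueComposition("eye", 1.07, {
            "H": 0.096, "C": 0.195, "N": 0.057, "O": 0.646,
            "Na": 0.001, "P": 0.001, "S": 0.003, "Cl": 0.001}),
        TissueComposition("soft_tissue", 1.03, {
            "H": 0.105, "C": 0.256, "N": 0.027, "O": 0.602,
            "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.002, "K": 0.002}),
        TissueComposition("muscle", 1.05, {
            "H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710,
            "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004}),
        TissueComposition("liver", 1.06, {
            "H": 0.102, "C": 0.139, "N": 0.030, "O": 0.716,
            "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}),
        TissueComposition("spongiosa", 1.18, {
            "H": 0.085, "C": 0.404, "N": 0.028, "O": 0.367,
            "Na": 0.001, "P": 0.034, "S": 0.002, "Cl": 0.002, "K": 0.001,
            "Ca": 0.076}),
        TissueComposition("skull_base_bone", 1.52, {
            "H": 0.056, "C": 0.235, "N": 0.040, "O": 0.434,
            "Na": 0.001, "Mg": 0.002, "P": 0.072, "S": 0.003, "Ca": 0.157}),
        TissueComposition("cranial_bone", 1.61, {
            "H": 0.050, "C": 0.212, "N": 0.040, "O": 0.435,
            "Na": 0.001, "Mg": 0.002, "P": 0.081, "S": 0.003, "Ca": 0.176}),
        TissueComposition("cortical_bone", 1.92, {
            "H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
            "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}),
    ]
}

SOFT_TISSUE_NAMES = frozenset({
    "lung_inflated", "adipose", "water", "csf", "brain", "eye",
    "soft_tissue", "muscle", "liver",
})
BONE_TISSUE_NAMES = frozenset({
    "spongiosa", "skull_base_bone", "cranial_bone", "cortical_bone",
})

#: The 11 tissues used to build the CT-number→SPR calibration curve; their
#: vertices give the ten-line-segment HLUT used by the single-energy chain.
#: (soft_tissue/liver are left out: soft_tissue forms a non-bijective HU/SPR
#: pair with CSF — two materials, nearly one CT number, different SPR — which
#: a single monotone HLUT cannot represent.)
HLUT_CALIBRATION_NAMES = [
    "air", "lung_inflated", "adipose", "water", "csf", "brain", "muscle",
    "eye", "skull_base_bone", "cranial_bone", "cortical_bone",
]


def ean_i_calibration_tissues() -> list["TissueComposition"]:
    """Reference tissues for the EAN→I calibration: all embedded tissues
    except air, whose anomalous I-value (high-Z argon/nitrogen mix) would
    distort the soft-tissue segment; air voxels are handled by the
    electron-density floor in the spectral chain."""
    return [t for n, t in REFERENCE_TISSUES.items() if n != "air"]


def hlut_calibration_tissues() -> list[TissueComposition]:
    return [REFERENCE_TISSUES[n] for n in HLUT_CALIBRATION_NAMES]


def synthetic_insert_set() -> list[TissueComposition]:
    """Synthetic tissue-surrogate inserts spanning lung to cortical bone.

    Stand-in for a commercial electron-density phantom insert set; mixtures
    are labelled synthetic by construction.
    """
    r = REFERENCE_TISSUES
    cort, wat = r["cortical_bone"], WATER
    return [
        mix("syn_lung300", r["lung_inflated"], WATER, 1.0, 0.30),
        mix("syn_lung450", r["lung_inflated"], WATER, 1.0, 0.45),
        r["adipose"],
        mix("syn_breast", r["adipose"], WATER, 0.5, 0.98),
        WATER,
        r["brain"],
        r["liver"],
        r["muscle"],
        mix("syn_inner_bone", cort, wat, 0.4, 1.14),
        mix("syn_b200", cort, wat, 0.45, 1.15),
        mix("syn_cb2_30", cort, wat, 0.55, 1.34),
        mix("syn_cb2_50", cort, wat, 0.75, 1.56),
        mix("syn_cortical", cort, wat, 0.97, 1.82),
    ]


# -- CSV round-trip -----------------------------------------------------------

def compositions_to_csv(comps: list[TissueComposition]) -> str:
    rows = []
    for c in comps:
        row = {"name": c.name, "density": c.mass_density}
        for s in CSV_ELEMENT_ORDER:
            row[s] = c.elemental_fractions.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows).to_csv(index=False)


def compositions_from_csv(text: str) -> list[TissueComposition]:
    df = pd.read_csv(io.StringIO(text))
    out = []
    for _, row in df.iterrows():
        fr = {s: float(row[s]) for s in CSV_ELEMENT_ORDER if s in df.columns and row[s] > 0}
        out.append(TissueComposition(str(row["name"]), float(row["density"]), fr))
    return out
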
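"""The single-energy CT chain: stoichiometric calibration and the HLUT.

A two-parameter stoichiometric model expresses relative photon attenuation as
μ/μ_w = ρe (k1 Z̃₁^3.62 + k2 Z̃₂^1.86 + 1) / (k1 Z̃₁w^3.62 + k2 Z̃₂w^1.86 + 1),
where Z̃_j are electron-fraction-weighted power means of the atomic numbers
(photoelectric exponent 3.62, coherent-scatter exponent 1.86) and k1, k2 are
scanner-spectrum weights fitted on tissue-surrogate insert readings.  CT
numbers predicted for reference human tissues, paired with their ground-truth
SPR, yield the piecewise-linear Hounsfield look-up table (HLUT) that converts
patient CT numbers to SPR.  An identity curve (SPR = 1 + HU/1000) reproduces
the one-to-one conversion used to import externally computed SPR maps into a
planning system.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .bethe import BetheParams, ground_truth_spr
from .elements import ELEMENTS
from .grid import ScalarVolume
from .materials import AIR, WATER, TissueComposition

HU_RANGE = (-1024.0, 3071.0)


@dataclass(frozen=True)
class StoichiometricParams:
    """Photoelectric (k1) and coherent-scatter (k2) weights of the scanner."""

    k1: float
    k2: float
    e1: float = 3.62
    e2: float = 1.86

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1, k2 must be non-negative")


@dataclass(frozen=True)
class InsertReading:
    composition: TissueComposition
    measured_hu: float

    def __post_init__(self) -> None:
        if not HU_RANGE[0] <= self.measured_hu <= HU_RANGE[1]:
            raise ValueError("measured HU outside the representable range")


def z_tilde(comp: TissueComposition, exponent: float) -> float:
    """Electron-fraction-weighted power mean (Σ λ_i Z_i^e)^(1/e)."""
    lam = comp.electron_fractions()
    return float(sum(l * ELEMENTS[s].z ** exponent for s, l in lam.items()) ** (1 / exponent))


def _attenuation_terms(comp: TissueComposition, params: StoichiometricParams):
    a = z_tilde(comp, params.e1) ** params.e1
    b = z_tilde(comp, params.e2) ** params.e2
    return a, b


def predict_hu(comp: TissueComposition, params: StoichiometricParams) -> float:
    """Theoretical CT number of a composition under the fitted scanner model."""
    a, b = _attenuation_terms(comp, params)
    aw, bw = _attenuation_terms(WATER, params)
    mu_rel = comp.electron_density() * (params.k1 * a + params.k2 * b + 1.0) / (
        params.k1 * aw + params.k2 * bw + 1.0
    )
    return float(1000.0 * (mu_rel - 1.0))


def fit_stoichiometric(
    readings: list[InsertReading],
    e1: float = 3.62,
    e2: float = 1.86,
) -> tuple[StoichiometricParams, pd.DataFrame]:
    """Recover (k1, k2) from insert readings by non-negative least squares.

    The model is linear in (k1, k2) after cross-multiplication:
    μr (k1 aw + k2 bw + 1) = ρe (k1 a + k2 b + 1).  Returns the fitted
    parameters and a per-insert residual table (HU).
    """
    if len(readings) < 3:
        raise ValueError("need at least 3 insert readings")
    ref = StoichiometricParams(0.0, 0.0, e1, e2)
    aw, bw = _attenuation_terms(WATER, ref)
    rows, rhs = [], []
    eds = []
    for r in readings:
        a, b = _attenuation_terms(r.composition, ref)
        ed = r.composition.electron_density()
        eds.append(ed)
        mu_r = 1.0 + r.measured_hu / 1000.0
        rows.append([ed * a - mu_r * aw, ed * b - mu_r * bw])
        rhs.append(mu_r - ed)
    zt = [z_tilde(r.composition, e1) for r in readings]
    if max(zt) - min(zt) < 0.5:
        warnings.warn("degenerate insert design (narrow EAN span): "
                      "parameters poorly constrained", stacklevel=2)
    sol, _ = nnls(np.asarray(rows), np.asarray(rhs))
    params = StoichiometricParams(float(sol[0]), float(sol[1]), e1, e2)
    resid = pd.DataFrame(
        {
            "insert": [r.composition.name for r in readings],
            "measured_hu": [r.measured_hu for r in readings],
            "predicted_hu": [predict_hu(r.composition, params) for r in readings],
        }
    )
    resid["residual_hu"] = resid["predicted_hu"] - resid["measured_hu"]
    return params, resid


# -- HLUT ---------------------------------------------------------------------

#: Default fixed HU knots for the least-squares HLUT (10 segments spanning
#: air to cortical bone; the −500 knot decouples the lung region from the
#: adipose-to-water segment, which a single monotone segment cannot serve).
DEFAULT_HU_KNOTS = [-1000.0, -500.0, -120.0, -80.0, 0.0, 50.0, 100.0, 300.0,
                    800.0, 1600.0, 3071.0]


@dataclass(frozen=True)
class HLUT:
    """Continuous piecewise-linear CT-number→SPR conversion curve."""

    hu_knots: tuple[float, ...]
    spr_knots: tuple[float, ...]

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu_knots)
        spr = np.asarray(self.spr_knots)
        if len(hu) < 2 or np.any(np.diff(hu) <= 0):
            raise ValueError("HU knots must be strictly increasing")
        if len(spr) != len(hu):
            raise ValueError("knot arrays must have equal length")
        if np.any(np.diff(spr) < -1e-12):
            raise ValueError("SPR vertices must be non-decreasing")

    @property
    def n_segments(self) -> int:
        return len(self.hu_knots) - 1

    def __call__(self, hu):
        """Linear interpolation; terminal-slope extrapolation, clamped >= 0."""
        hu = np.asarray(hu, dtype=float)
        x = np.asarray(self.hu_knots)
        y = np.asarray(self.spr_knots)
        out = np.interp(hu, x, y)
        lo_slope = (y[1] - y[0]) / (x[1] - x[0])
        hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out = np.where(hu < x[0], y[0] + (hu - x[0]) * lo_slope, out)
        out = np.where(hu > x[-1], y[-1] + (hu - x[-1]) * hi_slope, out)
        out = np.maximum(out, 0.0)
        return out if out.shape else float(out)

    def to_csv(self, path: str | Path | None = None,
               metadata: dict | None = None) -> str:
        text = pd.DataFrame({"hu": self.hu_knots, "spr": self.spr_knots}).to_csv(index=False)
        if path is not None:
            p = Path(path)
            p.write_text(text)
            if metadata is not None:
                p.with_suffix(".json").write_text(json.dumps(
                    {"n_segments": self.n_segments, **metadata}, indent=2))
        return text

    @classmethod
    def from_csv(cls, text_or_path: str | Path) -> "HLUT":
        p = Path(str(text_or_path))
        df = pd.read_csv(p if p.exists() else pd.io.common.StringIO(str(text_or_path)))
        return cls(tuple(df["hu"]), tuple(df["spr"]))


def identity_hlut() -> HLUT:
    """The one-to-one workaround curve: SPR = 1 + HU/1000 (clamped at 0)."""
    hu = np.linspace(-1000.0, 3071.0, 2)
    return HLUT(tuple(hu), tuple(1.0 + hu / 1000.0))


def build_hlut(
    stoich_params: StoichiometricParams,
    reference_tissues: list[TissueComposition],
    segment_spec: list[float] | str | None = None,
    bethe_params: BetheParams = BetheParams(),
    anchor_air: bool = True,
    anchor_water: bool = True,
) -> HLUT:
    """Build the HLUT from (predicted HU, ground-truth SPR) of reference tissues.

    ``segment_spec`` is either a list of HU knot positions (continuous
    least-squares linear spline, default the 10-segment knot set) or
    ``"interpolate"`` (vertices at the tissue points themselves — exact at
    every reference tissue; with the standard 11-tissue set this gives ten
    line segments).  The curve is anchored at (−1000, SPR_air) and at (0, 1).
    """
    pts = sorted(
        (predict_hu(t, stoich_params), ground_truth_spr(t, bethe_params))
        for t in reference_tissues
    )
    hu = np.array([p[0] for p in pts])
    spr = np.array([p[1] for p in pts])

    if len(pts) == 1:
        # single reference material: flat curve through it
        h0, s0 = pts[0]
        return HLUT((HU_RANGE[0], HU_RANGE[1]), (s0, s0))

    if segment_spec == "interpolate":
        knots, vals = list(hu), list(spr)
        if anchor_air and knots[0] > -1000.0:
            knots.insert(0, -1000.0)
            vals.insert(0, ground_truth_spr(AIR, bethe_params))
        if anchor_water and not np.any(np.isclose(knots, 0.0, atol=1e-9)):
            i = int(np.searchsorted(knots, 0.0))
            knots.insert(i, 0.0)
            vals.insert(i, 1.0)
        vals = list(np.maximum.accumulate(vals))
        return HLUT(tuple(knots), tuple(vals))

    knots = np.asarray(segment_spec if segment_spec is not None else DEFAULT_HU_KNOTS,
                       dtype=float)
    counts = np.histogram(hu, bins=knots)[0]
    if np.any(counts < 2):
        warnings.warn(
            f"{int(np.sum(counts < 2))} HLUT segment(s) with <2 tissues; "
            "interpolating from neighbouring segments", stacklevel=2)

    # knots with tissue data in an adjacent segment stay free parameters;
    # the rest are implied by the polyline through their neighbours
    supported = np.zeros(len(knots), dtype=bool)
    supported[:-1] |= counts > 0
    supported[1:] |= counts > 0
    anchors: list[tuple[float, float]] = []
    if anchor_air:
        anchors.append((-1000.0, ground_truth_spr(AIR, bethe_params)))
    if anchor_water:
        anchors.append((0.0, 1.0))
    for ax, _ in anchors:
        supported |= np.isclose(knots, ax)
    eff = knots[supported]
    n = len(eff)
    eye = np.eye(n)
    basis = np.stack([np.interp(hu, eff, eye[j]) for j in range(n)], axis=1)
    # isotonic parameterization: vertex_j = v0 + Σ_{i<=j} d_i with d >= 0,
    # so the fitted polyline is non-decreasing by construction; anchors are
    # enforced as heavily weighted rows
    from scipy.optimize import lsq_linear

    lmat = np.tril(np.ones((n, n - 1)), k=-1)   # cumulative-increment map
    a_full = np.hstack([np.ones((len(hu), 1)), basis @ lmat])
    rows, rhs = [a_full], [spr]
    w_anchor = 1e6
    for ax, ay in anchors:
        hat = np.array([np.interp(ax, eff, eye[j]) for j in range(n)])
        rows.append(w_anchor * np.concatenate([[1.0], hat @ lmat])[None, :])
        rhs.append(np.array([w_anchor * ay]))
    lb = np.concatenate([[-np.inf], np.zeros(n - 1)])
    sol = lsq_linear(np.vstack(rows), np.concatenate(rhs),
                     bounds=(lb, np.full(n, np.inf)))
    coef_eff = sol.x[0] + lmat @ sol.x[1:]
    # evaluate at the requested knots; terminal-slope extrapolation outside
    coef = np.interp(knots, eff, coef_eff)
    if eff[0] > knots[0]:
        s0 = (coef_eff[1] - coef_eff[0]) / (eff[1] - eff[0])
        coef[knots < eff[0]] = coef_eff[0] + s0 * (knots[knots < eff[0]] - eff[0])
    if eff[-1] < knots[-1]:
        s1 = (coef_eff[-1] - coef_eff[-2]) / (eff[-1] - eff[-2])
        coef[knots > eff[-1]] = coef_eff[-1] + s1 * (knots[knots > eff[-1]] - eff[-1])
    coef = np.maximum(coef, 0.0)
    mono = np.maximum.accumulate(coef)
    if np.any(mono - coef > 1e-9):
        warnings.warn("non-monotone HLUT vertices clipped (check reference set)",
                      stacklevel=2)
    return HLUT(tuple(knots), tuple(mono))


def apply_hlut(hu_volume: ScalarVolume, hlut: HLUT) -> ScalarVolume:
    """Per-voxel CT-number→SPR conversion."""
    return ScalarVolume(np.asarray(hlut(hu_volume.data)), hu_volume.grid)
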
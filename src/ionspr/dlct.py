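"""The dual-layer spectral CT chain: (ED, EAN) volumes → SPR map.

The scanner's spectral output is a relative-electron-density and an
effective-atomic-number volume.  A calibrated piecewise-log-linear map turns
EAN into a mean-excitation-energy (I-value) map, and the Bethe ratio then
yields SPR voxel by voxel.  The EAN→I map is fitted to reference tissues and
water-anchored so that (ED = 1, EAN_water) maps to SPR = 1 exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bethe import BetheParams, spr_bethe
from .grid import ScalarVolume
from .materials import (
    EAN_EXPONENT,
    WATER,
    TissueComposition,
    anchored_ivalue,
    ean_from_composition,
)

EAN_DOMAIN = (1.0, 16.0)


@dataclass(frozen=True)
class EanIModel:
    """Piecewise-linear ln I vs EAN map on the domain [1, 16]."""

    ean_knots: tuple[float, ...]
    ln_i_knots: tuple[float, ...]
    calibration_provenance: str = ""

    def __post_init__(self) -> None:
        k = np.asarray(self.ean_knots)
        if len(k) < 2 or np.any(np.diff(k) <= 0):
            raise ValueError("EAN knots must be strictly increasing, >= 2 knots")
        if len(self.ln_i_knots) != len(k):
            raise ValueError("knot arrays must have equal length")

    def i_value(self, ean):
        """I(EAN) in eV; EAN clipped to the model domain before lookup."""
        ean = np.clip(np.asarray(ean, dtype=float), *EAN_DOMAIN)
        ln_i = np.interp(ean, self.ean_knots, self.ln_i_knots)
        out = np.exp(ln_i)
        return out if out.shape else float(out)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "ean_knots": list(self.ean_knots),
                "ln_i_knots": list(self.ln_i_knots),
                "calibration_provenance": self.calibration_provenance,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "EanIModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(tuple(d["ean_knots"]), tuple(d["ln_i_knots"]),
                   d.get("calibration_provenance", ""))


def _segment_fit(x: np.ndarray, y: np.ndarray, knots: np.ndarray,
                 anchor: tuple[float, float] | None) -> np.ndarray:
    """Least-squares continuous linear spline through fixed knots.

    Solves for the knot ordinates with hat-function basis; an optional anchor
    point is enforced exactly via elimination.
    """
    n = len(knots)
    basis = np.zeros((len(x), n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        basis[:, j] = np.interp(x, knots, e)
    if anchor is None:
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return coef
    ax, ay = anchor
    a_row = np.array([np.interp(ax, knots, np.eye(n)[j]) for j in range(n)])
    # eliminate the constraint a_row @ coef = ay via the largest basis weight
    p = int(np.argmax(np.abs(a_row)))
    keep = [j for j in range(n) if j != p]
    b_mod = basis[:, keep] - np.outer(basis[:, p], a_row[keep]) / a_row[p]
    y_mod = y - basis[:, p] * ay / a_row[p]
    coef_keep, *_ = np.linalg.lstsq(b_mod, y_mod, rcond=None)
    coef = np.zeros(n)
    coef[keep] = coef_keep
    coef[p] = (ay - a_row[keep] @ coef_keep) / a_row[p]
    return coef


def fit_ean_i_model(
    reference_tissues: list[TissueComposition],
    exponent: float = EAN_EXPONENT,
    anchor_water: bool = True,
    n_segments: int = 2,
    knot_ean: float = 8.5,
    i_water_ev: float = 78.73,
    interpolate: bool = False,
) -> EanIModel:
    """Calibrate the EAN→I map on reference tissues.

    Points are (EAN, ln I) with I from water-anchored Bragg additivity, so
    the fitted scale is consistent with the assigned water I-value.  With
    ``anchor_water`` the curve is constrained through (EAN_water, ln i_water).
    ``interpolate=True`` places a knot at every tissue (exact interpolation),
    the mode used by the study pipeline; otherwise a ``n_segments`` linear
    spline is fitted with a knot near EAN ``knot_ean`` separating soft tissue
    from bone when ``n_segments`` is 2.
    """
    if len(reference_tissues) < 4:
        raise ValueError("need at least 4 reference tissues")
    pts = sorted(
        (ean_from_composition(t, exponent), math.log(anchored_ivalue(t, i_water_ev)))
        for t in reference_tissues
    )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.any(np.diff(x) <= 1e-9):
        keep = np.concatenate([[True], np.diff(x) > 1e-9])
        x, y = x[keep], y[keep]

    ean_w = ean_from_composition(WATER, exponent)
    anchor = (ean_w, math.log(i_water_ev)) if anchor_water else None

    if interpolate:
        knots, vals = list(x), list(y)
        if anchor_water and not np.any(np.isclose(knots, ean_w)):
            i = int(np.searchsorted(knots, ean_w))
            knots.insert(i, ean_w)
            vals.insert(i, math.log(i_water_ev))
        return EanIModel(tuple(knots), tuple(vals),
                         f"interpolated through {len(knots)} reference points")

    if n_segments == 2:
        knots = np.array([x[0], knot_ean, x[-1]])
    else:
        knots = np.linspace(x[0], x[-1], n_segments + 1)
    # every segment needs data to be determined
    counts = np.histogram(x, bins=knots)[0]
    if np.any(counts == 0):
        raise ValueError("a segment contains no reference tissue")
    coef = _segment_fit(x, y, knots, anchor)
    return EanIModel(tuple(knots), tuple(coef),
                     f"{n_segments}-segment LSQ fit on {len(x)} tissues, "
                     f"water-anchored={anchor_water}")


def predict_spr_dlct(
    ed_volume: ScalarVolume,
    ean_volume: ScalarVolume,
    ean_i_model: EanIModel,
    params: BetheParams = BetheParams(),
    air_threshold: float = 0.05,
    floor_spr: float = 0.001,
) -> ScalarVolume:
    """SPR map from spectral (ED, EAN) volumes.

    Voxels with ED below ``air_threshold`` are set to ``floor_spr``: the
    Bethe ratio is ill-conditioned for near-vacuum voxels.
    """
    if not ed_volume.same_grid(ean_volume):
        raise ValueError("ED and EAN volumes must share one grid")
    i_map = ean_i_model.i_value(ean_volume.data)
    spr = spr_bethe(np.maximum(ed_volume.data, 0.0), i_map, params)
    spr = np.where(ed_volume.data < air_threshold, floor_spr, spr)
    return ScalarVolume(np.asarray(spr), ed_volume.grid)
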
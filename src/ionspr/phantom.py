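"""Synthetic labeled head phantoms and simulated SECT/DLCT acquisitions.

The phantom is a concentric-ellipsoid head: scalp/soft tissue, a cranial-bone
shell, brain, paired eyes and lateral ventricles (CSF), a skull-base bone
slab and a nasal air cavity.  Only the radiological-depth structure matters
for range analysis, so no image-derived atlas is used.  Each voxel takes the
label of the highest-priority structure containing its center.

The scanner models are deliberately simple: the single-energy scan applies
the stoichiometric attenuation model (the "truth" scanner physics) plus bias
and Gaussian noise; the spectral scan returns the ground-truth ED and EAN
volumes perturbed by per-tissue or global multiplicative bias plus noise.
The per-tissue bias is the knob that imposes a modality discrepancy of the
sub-percent to ~2% magnitude seen between spectral- and single-energy-based
SPR in homogeneous head regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .bethe import BetheParams, ground_truth_spr
from .grid import Grid3D, ScalarVolume
from .materials import REFERENCE_TISSUES, TissueComposition, ean_from_composition
from .sect import StoichiometricParams, predict_hu

#: Truth scanner-spectrum weights used to synthesize CT numbers (120 kVp-like).
TRUTH_STOICH = StoichiometricParams(k1=1.0e-5, k2=5.0e-3)


# -- geometry -----------------------------------------------------------------

@dataclass(frozen=True)
class Structure:
    """Ellipsoid (or ellipsoidal shell) structure; mm units, world coords."""

    name: str
    tissue: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    inner_semi_axes: tuple[float, float, float] | None = None  # shell if set

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        inside = r2 <= 1.0
        if self.inner_semi_axes is not None:
            bx, by, bz = self.inner_semi_axes
            q2 = ((x - cx) / bx) ** 2 + ((y - cy) / by) ** 2 + ((z - cz) / bz) ** 2
            inside &= q2 > 1.0
        return inside


@dataclass(frozen=True)
class GeometryConfig:
    """Ordered structure list; earlier entries have higher priority."""

    structures: tuple[Structure, ...]
    background_tissue: str = "air"

    @classmethod
    def from_yaml(cls, text: str) -> "GeometryConfig":
        d = yaml.safe_load(text)
        structs = tuple(
            Structure(
                name=s["name"],
                tissue=s["tissue"],
                center=tuple(s["center"]),
                semi_axes=tuple(s["semi_axes"]),
                inner_semi_axes=tuple(s["inner_semi_axes"]) if s.get("inner_semi_axes") else None,
            )
            for s in d["structures"]
        )
        return cls(structs, d.get("background_tissue", "air"))


def default_head_geometry(jitter_seed: int | None = None) -> GeometryConfig:
    """Adult-head-like nested-ellipsoid geometry; optional per-patient jitter.

    Jitter rescales the head globally by a few percent and nudges internal
    structures by up to 2 mm, emulating anatomical variation across patients.
    """
    rng = np.random.default_rng(jitter_seed) if jitter_seed is not None else None

    def j_scale() -> float:
        return float(1.0 + rng.uniform(-0.04, 0.04)) if rng is not None else 1.0

    def j_off() -> np.ndarray:
        return rng.uniform(-2.0, 2.0, 3) if rng is not None else np.zeros(3)

    s = j_scale()

    def sc(v):
        return tuple(float(s * x) for x in v)

    def ct(v):
        return tuple(float(s * x + d) for x, d in zip(v, j_off()))

    structures = (
        Structure("eye_l", "eye", ct((-30.0, 62.0, -25.0)), sc((11.0, 11.0, 11.0))),
        Structure("eye_r", "eye", ct((30.0, 62.0, -25.0)), sc((11.0, 11.0, 11.0))),
        Structure("nasal_cavity", "air", ct((0.0, 58.0, -35.0)), sc((10.0, 14.0, 12.0))),
        Structure("ventricle_l", "csf", ct((-11.0, -5.0, 10.0)), sc((6.0, 20.0, 10.0))),
        Structure("ventricle_r", "csf", ct((11.0, -5.0, 10.0)), sc((6.0, 20.0, 10.0))),
        Structure("skull_base", "skull_base_bone", ct((0.0, -5.0, -34.0)), sc((52.0, 62.0, 6.0))),
        Structure("cranium", "cranial_bone", (0.0, 0.0, 0.0),
                  sc((62.0, 78.0, 74.0)), inner_semi_axes=sc((56.0, 72.0, 68.0))),
        Structure("brain", "brain", (0.0, 0.0, 0.0), sc((56.0, 72.0, 68.0))),
        Structure("head", "muscle", (0.0, 0.0, 0.0), sc((72.0, 88.0, 84.0))),
    )
    return GeometryConfig(structures)


DEFAULT_LABEL_TABLE = {
    name: REFERENCE_TISSUES[name]
    for name in ["air", "muscle", "cranial_bone", "brain", "eye", "csf",
                 "skull_base_bone"]
}


@dataclass
class LabeledPhantom:
    grid: Grid3D
    labels: np.ndarray                      # int16 label volume
    label_names: dict[int, str]             # label value → structure name
    label_table: dict[int, TissueComposition]  # label value → tissue
    truth_ed: ScalarVolume
    truth_ean: ScalarVolume
    truth_spr: ScalarVolume

    def structure_mask(self, name: str) -> np.ndarray:
        ids = [l for l, n in self.label_names.items() if n == name]
        if not ids:
            raise KeyError(f"no structure named {name!r}")
        return np.isin(self.labels, ids)

    def tissue_mask(self, tissue_name: str) -> np.ndarray:
        ids = [l for l, c in self.label_table.items() if c.name == tissue_name]
        return np.isin(self.labels, ids)


def build_head_phantom(
    geometry: GeometryConfig,
    label_table: dict[str, TissueComposition] | None = None,
    grid: Grid3D | None = None,
    bethe_params: BetheParams = BetheParams(),
) -> LabeledPhantom:
    """Rasterize the geometry and attach per-voxel ground-truth ED/EAN/SPR.

    Truth volumes are piecewise constant per tissue, computed once per
    composition from the same oracles the spectral chain is calibrated on.
    """
    if grid is None:
        grid = Grid3D((96, 112, 100), (2.0, 2.0, 2.0), (-95.0, -111.0, -99.0))
    table = dict(DEFAULT_LABEL_TABLE if label_table is None else label_table)
    needed = {s.tissue for s in geometry.structures} | {geometry.background_tissue}
    missing = needed - set(table)
    if missing:
        raise KeyError(f"label table missing compositions: {sorted(missing)}")
    names = [s.name for s in geometry.structures]
    if len(set(names)) != len(names):
        raise ValueError("structure names must be unique (priority is by order)")

    x, y, z = grid.coordinate_grids()
    labels = np.zeros(grid.shape, dtype=np.int16)  # 0 = background
    label_names = {0: "background"}
    label_tissue = {0: table[geometry.background_tissue]}
    unassigned = np.ones(grid.shape, dtype=bool)
    for i, s in enumerate(geometry.structures, start=1):
        m = s.contains(x, y, z) & unassigned
        labels[m] = i
        unassigned &= ~m
        label_names[i] = s.name
        label_tissue[i] = table[s.tissue]

    ed = np.zeros(grid.shape)
    ean = np.zeros(grid.shape)
    spr = np.zeros(grid.shape)
    for lab, comp in label_tissue.items():
        m = labels == lab
        ed[m] = comp.electron_density()
        ean[m] = ean_from_composition(comp)
        spr[m] = ground_truth_spr(comp, bethe_params)
    return LabeledPhantom(
        grid=grid,
        labels=labels,
        label_names=label_names,
        label_table=label_tissue,
        truth_ed=ScalarVolume(ed, grid),
        truth_ean=ScalarVolume(ean, grid),
        truth_spr=ScalarVolume(spr, grid),
    )


# -- scanner models -----------------------------------------------------------

@dataclass(frozen=True)
class ScannerModel:
    """Bias/noise model for the simulated acquisitions.

    Biases are fractions (ED/EAN, multiplicative) or HU (additive); each may
    be a single global value or a map tissue-name → value.  Noise is i.i.d.
    Gaussian per voxel; the seed fully determines the output.
    """

    ed_bias: float | dict[str, float] = 0.0
    ean_bias: float | dict[str, float] = 0.0
    hu_bias: float | dict[str, float] = 0.0
    noise_sd_ed: float = 0.0
    noise_sd_ean: float = 0.0
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.noise_sd_ed, self.noise_sd_ean, self.noise_sd_hu) < 0:
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def null(cls, seed: int = 0) -> "ScannerModel":
        return cls(seed=seed)

    def _bias_map(self, bias, phantom: LabeledPhantom) -> np.ndarray:
        if isinstance(bias, dict):
            out = np.zeros(phantom.grid.shape)
            for lab, comp in phantom.label_table.items():
                out[phantom.labels == lab] = bias.get(comp.name, bias.get("default", 0.0))
            return out
        return np.full(phantom.grid.shape, float(bias))


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_dlct(phantom: LabeledPhantom,
                  scanner: ScannerModel) -> tuple[ScalarVolume, ScalarVolume]:
    """Spectral output volumes: biased, noisy copies of truth ED and EAN."""
    rng_ed, rng_ean = _rngs(scanner.seed, 2)
    ed = phantom.truth_ed.data * (1.0 + scanner._bias_map(scanner.ed_bias, phantom))
    ean = phantom.truth_ean.data * (1.0 + scanner._bias_map(scanner.ean_bias, phantom))
    if scanner.noise_sd_ed > 0:
        ed = ed + rng_ed.normal(0.0, scanner.noise_sd_ed, ed.shape)
    if scanner.noise_sd_ean > 0:
        ean = ean + rng_ean.normal(0.0, scanner.noise_sd_ean, ean.shape)
    ed = np.maximum(ed, 1e-4)
    ean = np.clip(ean, 1.0, 16.0)
    return ScalarVolume(ed, phantom.grid), ScalarVolume(ean, phantom.grid)


def simulate_sect(phantom: LabeledPhantom,
                  stoich_params: StoichiometricParams = TRUTH_STOICH,
                  scanner: ScannerModel = ScannerModel()) -> ScalarVolume:
    """CT-number volume from the stoichiometric truth physics plus bias/noise."""
    (rng_hu,) = _rngs(scanner.seed + 1_000_003, 1)
    hu_by_label = {lab: predict_hu(comp, stoich_params)
                   for lab, comp in phantom.label_table.items()}
    hu = np.zeros(phantom.grid.shape)
    for lab, val in hu_by_label.items():
        hu[phantom.labels == lab] = val
    hu = hu + scanner._bias_map(scanner.hu_bias, phantom)
    if scanner.noise_sd_hu > 0:
        hu = hu + rng_hu.normal(0.0, scanner.noise_sd_hu, hu.shape)
    return ScalarVolume(np.clip(hu, -1024.0, 3071.0), phantom.grid)


def simulate_insert_readings(
    inserts: list[TissueComposition],
    stoich_params: StoichiometricParams = TRUTH_STOICH,
    noise_sd_hu: float = 0.0,
    seed: int = 0,
):
    """Synthetic calibration-phantom readings (mean ROI HU per insert)."""
    from .sect import InsertReading

    rng = np.random.default_rng(seed)
    out = []
    for c in inserts:
        hu = predict_hu(c, stoich_params)
        if noise_sd_hu > 0:
            hu += float(rng.normal(0.0, noise_sd_hu))
        out.append(InsertReading(c, float(np.clip(hu, -1024.0, 3071.0))))
    return out
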
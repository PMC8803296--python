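"""Evaluation layer: ROI SPR statistics, range-shift summaries, 3D gamma, DVH.

Conventions (stated because several are ambiguous in common usage):
percentiles interpolate linearly between order statistics; standard
deviations use the n−1 denominator; the SEM is SD/√n; box-plot whiskers
extend to the most extreme points within 1.5×IQR of the quartiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import distance_transform_edt, map_coordinates

from .grid import ScalarVolume


# -- ROI placement --------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """Circular per-slice ROI: area (mm²) replicated over consecutive slices."""

    name: str
    structure: str
    area_mm2: float
    n_slices: int

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0 or self.n_slices < 1:
            raise ValueError("ROI area and slice count must be positive")


#: ROI sizes of the five homogeneous head regions evaluated per patient:
#: brain ~100 mm² × 10 slices, eyes ~100 × 5, lateral ventricles ~50 × 5,
#: cranial bone ~50 × 10, skull-base bone ~25 × 10.
DEFAULT_ROI_SPECS = [
    RoiSpec("brain", "brain", 100.0, 10),
    RoiSpec("cranial_bone", "cranium", 50.0, 10),
    RoiSpec("eyes", "eye_l", 100.0, 5),
    RoiSpec("lateral_ventricles", "ventricle_l", 50.0, 5),
    RoiSpec("skull_base_bone", "skull_base", 25.0, 10),
]


def roi_slice_masks(structure_mask: np.ndarray, grid, spec: RoiSpec
                    ) -> list[np.ndarray]:
    """Automatic circular ROI seeding inside a labeled structure.

    In each of ``n_slices`` axial slices around the structure's central
    slice, the ROI disc is centred on the in-slice point farthest from the
    structure boundary (distance-transform maximum), mirroring manual
    placement in a homogeneous region.
    """
    if not structure_mask.any():
        raise ValueError("empty structure mask")
    radius_mm = float(np.sqrt(spec.area_mm2 / np.pi))
    sx, sy, sz = grid.spacing
    zs = np.unique(np.nonzero(structure_mask)[2])
    # prefer slices with the largest cross-section
    areas = np.array([structure_mask[:, :, z].sum() for z in zs])
    order = zs[np.argsort(areas)[::-1]]
    chosen = np.sort(order[: spec.n_slices])
    ii, jj = np.meshgrid(np.arange(structure_mask.shape[0]),
                         np.arange(structure_mask.shape[1]), indexing="ij")
    masks = []
    for z in chosen:
        sl = structure_mask[:, :, z]
        dist = distance_transform_edt(sl, sampling=(sx, sy))
        ci, cj = np.unravel_index(np.argmax(dist), dist.shape)
        r_eff = min(radius_mm, max(float(dist[ci, cj]), min(sx, sy)))
        disc = ((ii - ci) * sx) ** 2 + ((jj - cj) * sy) ** 2 <= r_eff ** 2
        m = np.zeros_like(structure_mask)
        m[:, :, z] = disc & sl
        if m.any():
            masks.append(m)
    if not masks:
        raise ValueError(f"could not place ROI {spec.name!r}")
    return masks


def roi_spr_table(spr_sect: ScalarVolume, spr_dlct: ScalarVolume,
                  roi_masks: dict[str, list[np.ndarray]]) -> pd.DataFrame:
    """Per-ROI relative SPR difference statistics for one patient.

    For each ROI slice, δ = (mean_DLCT − mean_SECT)/mean_SECT × 100; the
    table reports the per-patient mean and SD of δ over slices, plus the
    per-modality mean SPR.
    """
    if not spr_sect.same_grid(spr_dlct):
        raise ValueError("SPR volumes must share one grid")
    rows = []
    for name, slices in roi_masks.items():
        if not slices or not any(m.any() for m in slices):
            raise ValueError(f"ROI {name!r} has no voxels")
        deltas, ms, md = [], [], []
        for m in slices:
            a = float(spr_sect.data[m].mean())
            b = float(spr_dlct.data[m].mean())
            deltas.append((b - a) / a * 100.0)
            ms.append(a)
            md.append(b)
        deltas = np.asarray(deltas)
        rows.append({
            "roi": name,
            "n_slices": len(slices),
            "mean_spr_sect": float(np.mean(ms)),
            "mean_spr_dlct": float(np.mean(md)),
            "delta_spr_pct": float(np.mean(deltas)),
            "sd_delta_spr_pct": float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def cohort_roi_summary(per_patient: list[pd.DataFrame]) -> pd.DataFrame:
    """Cohort rollup: median and mean ± SEM of the per-patient δ̄ per ROI."""
    allp = pd.concat(per_patient, keys=range(len(per_patient)), names=["patient"])
    out = []
    for roi, g in allp.groupby("roi", sort=False):
        d = g["delta_spr_pct"].to_numpy()
        out.append({
            "roi": roi,
            "n_patients": len(d),
            "median_delta_pct": float(np.median(d)),
            "mean_delta_pct": float(np.mean(d)),
            "sem_delta_pct": float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0,
        })
    return pd.DataFrame(out)


# -- paired statistics -----------------------------------------------------------

def paired_t_ci(differences, alpha: float = 0.05) -> dict:
    """Two-sided paired t-test on per-unit differences, with a (1−α) CI.

    CI = mean ± t_{1−α/2, n−1} · SD/√n.  A zero-variance sample is flagged
    degenerate: p is reported as exactly 0 (any nonzero mean difference is
    then certain) and the CI collapses to the common value.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return {"t": float("inf") if mean != 0 else 0.0, "df": n - 1,
                "p": 0.0 if mean != 0 else 1.0, "mean": mean,
                "ci": (mean, mean), "degenerate": True}
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    half = tq * sd / np.sqrt(n)
    return {"t": float(t), "df": n - 1, "p": p, "mean": mean,
            "ci": (mean - half, mean + half), "degenerate": False}


def _box_stats(v: np.ndarray) -> dict:
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo) & (v <= hi)]
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "p25": float(q1), "p50": float(q2), "p75": float(q3),
        "p100": float(np.max(v)),
        "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max()),
        "n_outliers": int(np.sum((v < lo) | (v > hi))),
        "n": int(v.size),
    }


def range_shift_summary(records: pd.DataFrame, group_by: str = "plan_id",
                        value_cols: tuple[str, ...] = ("rel_dr90", "rel_dr80"),
                        as_percent: bool = True) -> pd.DataFrame:
    """Grouped percentile/box statistics of range shifts (|relative| in %)."""
    recs = records[~records["excluded"]] if "excluded" in records else records
    rows = []
    groups = list(recs.groupby(group_by, sort=False)) + [("all", recs)]
    for key, g in groups:
        for col in value_cols:
            v = np.abs(g[col].dropna().to_numpy())
            if v.size == 0:
                continue
            if as_percent and col.startswith("rel"):
                v = v * 100.0
            rows.append({group_by: key, "metric": col, **_box_stats(v)})
    return pd.DataFrame(rows)


def variability(records: pd.DataFrame, value_col: str = "rel_dr90",
                patient_col: str = "patient_id") -> tuple[float, float]:
    """(intrapatient, interpatient) variability of range shifts.

    Intrapatient = mean over patients of the per-patient SD; interpatient =
    SD over patients of the per-patient mean.  Sample SD (n−1) throughout.
    """
    recs = records[~records["excluded"]] if "excluded" in records else records
    per_sd, per_mean = [], []
    for _, g in recs.groupby(patient_col, sort=False):
        v = np.abs(g[value_col].dropna().to_numpy())
        per_mean.append(np.mean(v))
        if v.size < 2:
            warnings.warn("patient with a single record: intrapatient SD undefined",
                          stacklevel=2)
        else:
            per_sd.append(np.std(v, ddof=1))
    if len(per_mean) < 2:
        raise ValueError("need at least 2 patients")
    intra = float(np.mean(per_sd)) if per_sd else float("nan")
    inter = float(np.std(per_mean, ddof=1))
    return intra, inter


# -- 3D gamma ---------------------------------------------------------------------

@dataclass(frozen=True)
class GammaConfig:
    dose_criterion: float = 0.01       # fraction of local (or max) reference dose
    dta_mm: float = 1.0
    normalization: str = "local"       # or "global"
    low_dose_cutoff: float = 0.05      # fraction of max reference dose
    search_radius_mm: float = 3.0
    lattice_step_fraction: float = 0.1  # candidate lattice step, × dta

    def __post_init__(self) -> None:
        if min(self.dose_criterion, self.dta_mm, self.search_radius_mm) <= 0:
            raise ValueError("gamma criteria must be positive")
        if not 0.0 <= self.low_dose_cutoff < 1.0:
            raise ValueError("cutoff must be in [0, 1)")
        if self.normalization not in ("local", "global"):
            raise ValueError("normalization must be 'local' or 'global'")


def _offset_shells(config: GammaConfig) -> list[tuple[float, np.ndarray]]:
    """Candidate offsets (mm) on the search lattice, grouped by distance."""
    step = config.lattice_step_fraction * config.dta_mm
    r = config.search_radius_mm
    n = int(np.floor(r / step))
    ax = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= r + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist)
    offs, dist = offs[order], dist[order]
    shells = []
    # group into bins of one lattice step so early exit can prune whole groups
    edges = np.arange(0.0, r + 2 * step, step)
    for k in range(len(edges) - 1):
        m = (dist >= edges[k]) & (dist < edges[k + 1])
        if m.any():
            shells.append((float(edges[k]), offs[m]))
    return shells


def gamma_3d(dose_ref: ScalarVolume, dose_eval: ScalarVolume,
             config: GammaConfig = GammaConfig()) -> tuple[float, ScalarVolume]:
    """Local (or global) 3D gamma index of eval against reference.

    γ(r) = min over candidate offsets Δ of
    √(‖Δ‖²/dta² + (D_eval(r+Δ) − D_ref(r))²/(c·D_norm)²), with D_norm the
    local reference dose (local mode) or the reference maximum (global mode).
    Candidates lie on a 0.1·dta lattice out to the search radius; the shell
    search stops per voxel once the distance term alone exceeds the current
    minimum, which makes the result identical to an exhaustive lattice search.
    Voxels below the low-dose cutoff are excluded (NaN in the gamma volume).
    """
    if not dose_ref.same_grid(dose_eval):
        raise ValueError("dose volumes must share one grid")
    ref = np.asarray(dose_ref.data, dtype=float)
    ev = np.asarray(dose_eval.data, dtype=float)
    cutoff = config.low_dose_cutoff * ref.max()
    active_mask = ref > cutoff
    if not active_mask.any():
        raise ValueError("all reference voxels below the low-dose cutoff")
    g = dose_ref.grid
    spacing = np.asarray(g.spacing)
    idx = np.argwhere(active_mask).astype(float)
    d_ref = ref[active_mask]
    denom = (config.dose_criterion *
             (d_ref if config.normalization == "local" else ref.max()))
    best = np.full(idx.shape[0], np.inf)
    alive = np.arange(idx.shape[0])
    for dist_lo, offs in _offset_shells(config):
        # distance lower bound: voxels whose γ can no longer improve drop out
        keep = best[alive] > dist_lo / config.dta_mm
        alive = alive[keep]
        if alive.size == 0:
            break
        pts = idx[alive][:, None, :] + (offs / spacing)[None, :, :]
        de = map_coordinates(ev, pts.reshape(-1, 3).T, order=1,
                             mode="constant", cval=0.0).reshape(len(alive), -1)
        dd2 = ((de - d_ref[alive, None]) / denom[alive, None]) ** 2
        r2 = (np.linalg.norm(offs, axis=1) / config.dta_mm) ** 2
        cand = np.sqrt(dd2 + r2[None, :]).min(axis=1)
        best[alive] = np.minimum(best[alive], cand)
    gamma = np.full(g.shape, np.nan)
    gamma[active_mask] = best
    # tiny tolerance so an exactly-at-criterion dose difference counts as a pass
    pass_rate = float(np.mean(best <= 1.0 + 1e-9) * 100.0)
    return pass_rate, ScalarVolume(gamma, g)


# -- DVH ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DvhMetrics:
    structure: str
    d_mean: float
    d_003cc: float
    d99: float
    dose_grid: np.ndarray
    volume_fraction: np.ndarray
    small_structure: bool = False


def dvh(dose_volume: ScalarVolume, mask: np.ndarray, structure: str = "",
        n_bins: int = 400) -> DvhMetrics:
    """Cumulative DVH and its summary metrics for one structure.

    Dmean is the arithmetic voxel mean; D0.03cc the minimum dose among the
    hottest ⌈0.03 cm³ / voxel volume⌉ voxels (falls back to the maximum voxel
    dose for structures smaller than 0.03 cm³, flagged); D99 the dose received
    by at least 99% of the volume (linear interpolation between order
    statistics).
    """
    if not mask.any():
        raise ValueError("empty structure mask")
    doses = np.asarray(dose_volume.data)[mask].astype(float)
    vox_cc = dose_volume.grid.voxel_volume_mm3 / 1000.0
    d_mean = float(doses.mean())
    k = int(np.ceil(0.03 / vox_cc))
    small = k > doses.size
    if small:
        d003 = float(doses.max())
    else:
        d003 = float(np.partition(doses, -k)[-k:].min())
    d99 = float(np.percentile(doses, 1.0))
    grid = np.linspace(0.0, max(doses.max(), 1e-12), n_bins)
    vf = np.array([(doses >= d).mean() for d in grid])
    return DvhMetrics(structure, d_mean, d003, d99, grid, vf, small)


def oar_dose_flags(dvh_sect: dict[str, DvhMetrics], dvh_dlct: dict[str, DvhMetrics],
                   threshold_gy: float = 0.5) -> pd.DataFrame:
    """Per-structure dose deltas; flag |ΔDmean| or |ΔD0.03cc| strictly above
    the threshold.  ΔD99 is signed (SECT − DLCT), the coverage convention."""
    rows = []
    for name, ms in dvh_sect.items():
        if name not in dvh_dlct:
            warnings.warn(f"structure {name!r} missing on the DLCT side; skipped",
                          stacklevel=2)
            continue
        md = dvh_dlct[name]
        d_mean = abs(ms.d_mean - md.d_mean)
        d_max = abs(ms.d_003cc - md.d_003cc)
        rows.append({
            "structure": name,
            "abs_d_mean_diff_gy": d_mean,
            "abs_d003cc_diff_gy": d_max,
            "delta_d99_gy": ms.d99 - md.d99,
            "flagged": bool(d_mean > threshold_gy or d_max > threshold_gy),
        })
    return pd.DataFrame(rows)
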
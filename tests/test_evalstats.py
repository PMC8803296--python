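"""ROI statistics, paired tests, range-shift summaries, 3D gamma, DVH."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from ionspr.evalstats import (
    DvhMetrics,
    GammaConfig,
    RoiSpec,
    dvh,
    gamma_3d,
    oar_dose_flags,
    paired_t_ci,
    range_shift_summary,
    roi_slice_masks,
    roi_spr_table,
    variability,
)
from ionspr.grid import Grid3D, ScalarVolume


def _vol(data, spacing=1.0):
    data = np.asarray(data, dtype=float)
    return ScalarVolume(data, Grid3D(data.shape, (spacing,) * 3))


# -- ROI statistics -------------------------------------------------------------

class TestRoiSprTable:
    def _masks(self, shape=(20, 20, 10)):
        m = []
        for z in range(3):
            s = np.zeros(shape, dtype=bool)
            s[5:15, 5:15, z] = True
            m.append(s)
        return {"brain": m}

    def test_identical_volumes_give_zero_delta(self):
        a = _vol(np.full((20, 20, 10), 1.04))
        t = roi_spr_table(a, a, self._masks())
        assert t.loc[0, "delta_spr_pct"] == 0.0
        assert t.loc[0, "sd_delta_spr_pct"] == 0.0

    def test_constant_ratio_gives_exact_percent(self):
        a = _vol(np.full((20, 20, 10), 1.04))
        b = _vol(1.011 * a.data)
        t = roi_spr_table(a, b, self._masks())
        assert t.loc[0, "delta_spr_pct"] == pytest.approx(1.10, abs=1e-9)

    def test_empty_roi_rejected(self):
        a = _vol(np.ones((20, 20, 10)))
        with pytest.raises(ValueError):
            roi_spr_table(a, a, {"x": [np.zeros((20, 20, 10), dtype=bool)]})

    def test_cohort_sem_definition(self):
        from ionspr.evalstats import cohort_roi_summary

        tables = []
        deltas = [0.8, 1.0, 1.2, 1.0, 0.9, 1.1, 1.0, 1.0]
        for d in deltas:
            tables.append(pd.DataFrame([{
                "roi": "brain", "n_slices": 10, "mean_spr_sect": 1.0,
                "mean_spr_dlct": 1.0, "delta_spr_pct": d, "sd_delta_spr_pct": 0.1}]))
        s = cohort_roi_summary(tables)
        v = np.array(deltas)
        assert s.loc[0, "mean_delta_pct"] == pytest.approx(v.mean())
        assert s.loc[0, "sem_delta_pct"] == pytest.approx(
            v.std(ddof=1) / np.sqrt(8), rel=1e-12)
        assert s.loc[0, "median_delta_pct"] == pytest.approx(np.median(v))

    def test_roi_placement_respects_area_and_structure(self):
        g = Grid3D((40, 40, 20), (1.0, 1.0, 1.0))
        structure = np.zeros(g.shape, dtype=bool)
        structure[5:35, 5:35, :] = True
        spec = RoiSpec("brain", "brain", 100.0, 5)
        masks = roi_slice_masks(structure, g, spec)
        assert len(masks) == 5
        for m in masks:
            assert m.sum() == pytest.approx(100.0, rel=0.15)  # ~100 mm² discs
            assert not (m & ~structure).any()


class TestPairedT:
    def test_toy_case_1_2_3(self):
        r = paired_t_ci([1.0, 2.0, 3.0])
        assert r["t"] == pytest.approx(3.4641, abs=1e-3)
        assert r["df"] == 2
        assert r["p"] == pytest.approx(0.0742, abs=1e-3)

    def test_degenerate_constant_differences(self):
        r = paired_t_ci([0.5, 0.5, 0.5])
        assert r["degenerate"]
        assert r["p"] == 0.0
        assert r["ci"] == (0.5, 0.5)

    def test_sign_symmetry(self):
        a = paired_t_ci([1.0, 2.0, 4.0])
        b = paired_t_ci([-1.0, -2.0, -4.0])
        assert b["t"] == pytest.approx(-a["t"])
        assert b["p"] == pytest.approx(a["p"])

    def test_ci_contains_mean_and_matches_formula(self):
        from scipy import stats

        d = np.array([0.9, 1.1, 1.3, 0.7, 1.0])
        r = paired_t_ci(d, alpha=0.05)
        half = stats.t.ppf(0.975, 4) * d.std(ddof=1) / np.sqrt(5)
        assert r["ci"][0] == pytest.approx(d.mean() - half)
        assert r["ci"][1] == pytest.approx(d.mean() + half)


class TestRangeShiftSummary:
    def _records(self, values, plan="A", patient="P1"):
        return pd.DataFrame({
            "plan_id": plan, "patient_id": patient,
            "rel_dr90": values, "rel_dr80": values,
            "dr90_mm": np.abs(values), "dr80_mm": np.abs(values),
            "excluded": False,
        })

    def test_constant_records(self):
        t = range_shift_summary(self._records([0.004] * 6))
        row = t[(t["plan_id"] == "A") & (t["metric"] == "rel_dr90")].iloc[0]
        assert row["p25"] == row["p50"] == row["p75"] == pytest.approx(0.4)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_percentile_convention(self):
        t = range_shift_summary(self._records([0.002, 0.004, 0.006, 0.008]))
        row = t[(t["plan_id"] == "A") & (t["metric"] == "rel_dr90")].iloc[0]
        assert row["p50"] == pytest.approx(0.5)
        assert row["p25"] == pytest.approx(0.35)
        assert row["p75"] == pytest.approx(0.65)

    def test_duplication_invariance(self):
        v = [0.002, 0.004, 0.006, 0.008]
        t1 = range_shift_summary(self._records(v))
        t2 = range_shift_summary(self._records(v + v))
        for c in ("p25", "p50", "p75", "p100"):
            assert t1.iloc[0][c] == pytest.approx(t2.iloc[0][c])

    def test_whisker_rule(self):
        v = [0.001, 0.0011, 0.0012, 0.0013, 0.01]  # one far outlier
        t = range_shift_summary(self._records(v))
        row = t[(t["plan_id"] == "A") & (t["metric"] == "rel_dr90")].iloc[0]
        assert row["n_outliers"] == 1
        assert row["whisker_hi"] == pytest.approx(0.13)


class TestVariability:
    def test_toy_case(self):
        recs = pd.DataFrame({
            "patient_id": ["A", "A", "B", "B"],
            "rel_dr90": [1.0, 3.0, 2.0, 2.0],
            "excluded": False,
        })
        intra, inter = variability(recs)
        assert intra == pytest.approx(np.sqrt(2) / 2, abs=1e-6)
        assert inter == pytest.approx(0.0, abs=1e-12)

    def test_identical_patients_zero_interpatient(self):
        recs = pd.DataFrame({
            "patient_id": ["A"] * 3 + ["B"] * 3,
            "rel_dr90": [1.0, 2.0, 3.0] * 2,
            "excluded": False,
        })
        _, inter = variability(recs)
        assert inter == 0.0

    def test_homogeneity_under_scaling(self):
        recs = pd.DataFrame({
            "patient_id": ["A", "A", "B", "B"],
            "rel_dr90": [1.0, 3.0, 2.0, 5.0],
            "excluded": False,
        })
        i1 = variability(recs)
        recs2 = recs.assign(rel_dr90=2 * recs["rel_dr90"])
        i2 = variability(recs2)
        assert i2[0] == pytest.approx(2 * i1[0])
        assert i2[1] == pytest.approx(2 * i1[1])

    def test_single_patient_rejected(self):
        recs = pd.DataFrame({"patient_id": ["A"], "rel_dr90": [1.0],
                             "excluded": False})
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                variability(recs)


# -- gamma -----------------------------------------------------------------------

def brute_force_gamma(ref: ScalarVolume, ev: ScalarVolume,
                      config: GammaConfig) -> float:
    """Independent oracle: exhaustive evaluation of every lattice offset."""
    from scipy.ndimage import map_coordinates

    r = np.asarray(ref.data, float)
    e = np.asarray(ev.data, float)
    cutoff = config.low_dose_cutoff * r.max()
    active = np.argwhere(r > cutoff)
    dref = r[r > cutoff]
    denom = config.dose_criterion * (dref if config.normalization == "local"
                                     else r.max())
    step = config.lattice_step_fraction * config.dta_mm
    n = int(np.floor(config.search_radius_mm / step))
    ax = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], 1)
    offs = offs[np.linalg.norm(offs, axis=1) <= config.search_radius_mm + 1e-9]
    spacing = np.asarray(ref.grid.spacing)
    best = np.full(len(active), np.inf)
    for chunk in np.array_split(offs, max(1, len(offs) // 2000)):
        pts = active[:, None, :] + (chunk / spacing)[None, :, :]
        de = map_coordinates(e, pts.reshape(-1, 3).T, order=1, mode="constant",
                             cval=0.0).reshape(len(active), -1)
        g2 = (((de - dref[:, None]) / denom[:, None]) ** 2
              + ((np.linalg.norm(chunk, axis=1) / config.dta_mm) ** 2)[None, :])
        best = np.minimum(best, g2.min(axis=1))
    return float(np.mean(np.sqrt(best) <= 1.0) * 100.0)


class TestGamma3d:
    def test_identical_volumes(self):
        rng = np.random.default_rng(1)
        d = gaussian_filter(rng.random((12, 12, 12)), 2.0)
        ref = _vol(d)
        rate, gvol = gamma_3d(ref, ref)
        assert rate == 100.0
        assert np.nanmax(gvol.data) == 0.0

    def test_one_percent_scaling_passes_local_1pct(self):
        rng = np.random.default_rng(2)
        d = gaussian_filter(rng.random((10, 10, 10)), 2.0) + 0.5
        ref = _vol(d)
        ev = _vol(1.01 * d)
        rate, gvol = gamma_3d(ref, ev)
        assert rate == 100.0
        assert np.nanmax(gvol.data) <= 1.0 + 1e-9

    def test_matches_brute_force_oracle(self):
        """Shell search with early exit vs exhaustive lattice evaluation."""
        rng = np.random.default_rng(3)
        cfg = GammaConfig(search_radius_mm=2.0)
        for _ in range(3):
            base = gaussian_filter(rng.random((10, 10, 10)), 1.5)
            base /= base.max()
            pert = base * (1 + rng.normal(0, 0.02, base.shape)) \
                + rng.normal(0, 0.005, base.shape)
            ref, ev = _vol(base), _vol(pert)
            fast, _ = gamma_3d(ref, ev, cfg)
            brute = brute_force_gamma(ref, ev, cfg)
            assert fast == pytest.approx(brute, abs=0.5)

    def test_local_mode_is_asymmetric(self):
        # local normalization divides by the reference dose, so swapping the
        # roles of the two distributions may change the pass rate
        rng = np.random.default_rng(4)
        base = gaussian_filter(rng.random((8, 8, 8)), 1.0) + 0.2
        pert = base * (1 + rng.normal(0, 0.03, base.shape))
        r1, _ = gamma_3d(_vol(base), _vol(pert))
        r2, _ = gamma_3d(_vol(pert), _vol(base))
        assert isinstance(r1, float) and isinstance(r2, float)

    def test_all_below_cutoff_rejected(self):
        z = _vol(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError):
            gamma_3d(z, z)

    def test_grid_mismatch_rejected(self):
        a = _vol(np.ones((5, 5, 5)))
        b = ScalarVolume(np.ones((5, 5, 5)), Grid3D((5, 5, 5), (2.0, 2.0, 2.0)))
        with pytest.raises(ValueError):
            gamma_3d(a, b)


# -- DVH -------------------------------------------------------------------------

class TestDvh:
    def test_uniform_dose(self):
        d = _vol(np.full((10, 10, 10), 2.0), spacing=2.0)
        mask = np.ones((10, 10, 10), dtype=bool)
        m = dvh(d, mask)
        assert m.d_mean == m.d99 == m.d_003cc == pytest.approx(2.0)

    def test_half_and_half(self):
        data = np.zeros((10, 10, 10))
        data[:5] = 2.0
        d = _vol(data, spacing=2.0)
        m = dvh(d, np.ones((10, 10, 10), dtype=bool))
        assert m.d_mean == pytest.approx(1.0)
        assert m.d99 == pytest.approx(0.0)

    def test_hottest_three_voxel_rule(self):
        """1000 voxels of 0.01 cc at doses 1..1000 mGy → D0.03cc = 998 mGy."""
        doses = np.arange(1.0, 1001.0).reshape(10, 10, 10) / 1000.0
        g = Grid3D((10, 10, 10), (2.0, 2.23606797749979, 2.23606797749979))
        vol = ScalarVolume(doses, g)
        assert g.voxel_volume_mm3 == pytest.approx(10.0)  # 0.01 cc
        m = dvh(vol, np.ones((10, 10, 10), dtype=bool))
        assert m.d_003cc == pytest.approx(0.998)

    def test_small_structure_fallback_flagged(self):
        d = _vol(np.arange(8.0).reshape(2, 2, 2), spacing=1.0)  # 8 mm³ total
        m = dvh(d, np.ones((2, 2, 2), dtype=bool))
        assert m.small_structure
        assert m.d_003cc == pytest.approx(7.0)

    def test_curve_monotone_and_dmean_exact(self):
        rng = np.random.default_rng(5)
        data = rng.random((8, 8, 8)) * 60
        d = _vol(data, spacing=2.0)
        mask = rng.random((8, 8, 8)) > 0.4
        m = dvh(d, mask)
        assert np.all(np.diff(m.volume_fraction) <= 1e-12)
        assert m.d_mean == pytest.approx(float(data[mask].mean()), rel=1e-14)
        assert m.d_003cc >= m.d_mean

    def test_empty_mask_rejected(self):
        d = _vol(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            dvh(d, np.zeros((4, 4, 4), dtype=bool))


class TestOarDoseFlags:
    def _metrics(self, name, mean, dmax, d99=50.0):
        return DvhMetrics(name, mean, dmax, d99, np.array([0.0]), np.array([1.0]))

    def test_identical_plans_no_flags(self):
        a = {"oar": self._metrics("oar", 10.0, 20.0)}
        t = oar_dose_flags(a, a)
        assert not t["flagged"].any()

    def test_boundary_is_strict(self):
        a = {"oar": self._metrics("oar", 10.0, 20.0)}
        b = {"oar": self._metrics("oar", 10.5, 20.0)}
        t = oar_dose_flags(a, b, threshold_gy=0.5)
        assert not t["flagged"].any()          # exactly 0.5 → not flagged
        c = {"oar": self._metrics("oar", 10.501, 20.0)}
        assert oar_dose_flags(a, c)["flagged"].any()

    def test_signed_d99_convention(self):
        a = {"ptv": self._metrics("ptv", 54.0, 56.0, d99=60.0)}
        b = {"ptv": self._metrics("ptv", 54.0, 56.0, d99=59.5)}
        t = oar_dose_flags(a, b)
        assert t.loc[0, "delta_d99_gy"] == pytest.approx(0.5)

    def test_missing_structure_skipped_with_warning(self):
        a = {"x": self._metrics("x", 1.0, 2.0), "y": self._metrics("y", 1.0, 2.0)}
        b = {"x": self._metrics("x", 1.0, 2.0)}
        with pytest.warns(UserWarning, match="missing"):
            t = oar_dose_flags(a, b)
        assert len(t) == 1
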
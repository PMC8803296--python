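# ionspr

Stopping-power-ratio (SPR) prediction from dual-layer spectral CT versus
single-energy CT, and the downstream ion-beam range and dose evaluation, on
synthetic head phantoms.

## The problem

Proton, helium and carbon-ion treatment planning needs the stopping-power
ratio relative to water in every voxel of the planning CT: the SPR map
determines where each beam stops. Two prediction routes exist clinically:

* **Single-energy CT (SECT)**: a scanner-specific Hounsfield look-up table
  (HLUT) maps CT numbers to SPR. The HLUT comes from a two-parameter
  stoichiometric calibration — relative attenuation is modelled as
  μ/μ_w = ρe·(k₁·Z̃₁^3.62 + k₂·Z̃₂^1.86 + 1)/(water term), the weights
  (k₁, k₂) are fitted on tissue-surrogate insert readings, theoretical CT
  numbers are predicted for reference human tissues, and the (HU, SPR)
  scatter is joined into a monotone piecewise-linear curve.
* **Dual-layer spectral CT (DLCT)**: the scanner itself reconstructs relative
  electron density ρe and effective atomic number Z_eff. SPR follows directly
  from the Bethe formula (no higher-order corrections) at a fixed effective
  energy of 100 MeV,

      SPR = ρe · L(I) / L(I_w),   L(I) = ln(2 m_e c² β² / (I(1−β²))) − β²,

  with I_w = 78.73 eV and a calibrated piecewise-log-linear map from Z_eff
  (electron-fraction-weighted power mean with exponent 2.94) to the mean
  excitation energy I.

The two routes disagree at the sub-percent to ~2% level in homogeneous head
tissues, and a 1% SPR difference shifts an ion range by 1 mm per 10 cm of
depth. This package reproduces the whole comparison chain on synthetic
anthropomorphic head phantoms with known ground truth: phantom → simulated
SECT and spectral scans → both SPR chains → water-equivalent-path-length ray
tracing with analytic spread-out Bragg peaks → R90/R80 range shifts
(ΔR = |R_SECT − R_DLCT|, relative shifts divided by the spectral-CT range) →
3D gamma analysis (1%/1 mm local, 5% cutoff), DVH metrics (Dmean, D0.03cc,
D99) and per-plan/per-patient summary tables.

Audience: medical-physics researchers studying CT-calibration-driven range
uncertainty who need a fully synthetic, ground-truth-controlled testbed.

## Worked example

```python
from ionspr import (StudyConfig, run_study)

result = run_study(StudyConfig(seed=1))
print(result.table1_roi_spr[["roi", "mean_delta_pct", "sem_delta_pct"]])
print(f"mean |dR90| = {result.summary['mean_abs_dr90_mm']:.2f} mm over "
      f"{result.summary['n_profiles']} profiles")
print(f"gamma pass rate = {result.summary['gamma_mean_pass_pct']:.1f} %")
```

prints (seed 1):

```
                  roi  mean_delta_pct  sem_delta_pct
0               brain        1.079764       0.045495
1        cranial_bone        1.110378       0.081962
2                eyes        1.338729       0.045102
3  lateral_ventricles        0.263827       0.042401
4     skull_base_bone        1.100645       0.083462
mean |dR90| = 0.83 mm over 270 profiles
gamma pass rate = 98.3 %
```

Reading: the default spectral scanner model imposes per-tissue electron-
density biases of +0.5…+1.2% (the magnitude observed clinically between the
two modalities in head tissue), so the ROI analysis over 8 synthetic patients
reads back SPR differences of that size; on 270 line-dose profiles over
6 patients × 4 plan archetypes the imposed ~1% discrepancy becomes a mean
distal range shift of 0.83 mm, while the dose distributions still agree at
98.3% under a 1%/1 mm local gamma criterion.

A zero-discrepancy scanner (`ScannerModel.null()`) is the built-in control:
both chains then reproduce the phantom ground truth exactly and every range
shift is zero.

## Command line

```bash
ionspr phantom make --seed 3 --out phantom/        # labeled head + scans (NIfTI)
ionspr spr dlct --ed ed.nii.gz --ean ean.nii.gz --out spr.nii.gz
ionspr hlut fit --inserts inserts.csv --segments 10 --out hlut.csv
ionspr spr sect --ct ct.nii.gz --hlut hlut.csv --out spr.nii.gz
ionspr study run --seed 1 --out results/           # full synthetic study
```

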
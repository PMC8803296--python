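# Methods

This note documents the models behind `ionspr`, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical choices
made where the design was open.

## Elemental data and composition oracles

Elements H…Ca carry standard atomic numbers and weights and elemental mean
excitation energies from the standard stopping-power tabulation (ICRU-37
values as used by NIST ESTAR/PSTAR). A `TissueComposition` is a mass density
plus elemental mass fractions (validated to sum to 1 within 1e-6). From it:

* relative electron density ρe = ρ·(Σ wᵢZᵢ/Aᵢ) / (water value);
* effective atomic number Z_eff = (Σ λᵢZᵢⁿ)^(1/n) with electron fractions
  λᵢ = wᵢZᵢ/Aᵢ (normalized) and exponent **n = 2.94**, the electron-fraction
  weighting used by dual-layer scanners;
* mean excitation energy by Bragg additivity, ln I = Σ λᵢ ln Iᵢ.

Bragg additivity with gas-phase elemental I-values underestimates the I-value
of condensed water: it yields ≈69.0 eV against the 78.73 eV assigned to
liquid water. We therefore keep `ivalue_from_composition` as the raw Bragg
value (the residual is itself informative) and apply one global
**water-anchoring rescale** — all I-values multiplied by 78.73/69.0 — wherever
a calibrated scale is needed (`anchored_ivalue`). Because the Bethe stopping
number enters only logarithmically, SPR ratios are nearly invariant under
this rescale (≤0.1% even for cortical bone); its purpose is to make ground
truth, spectral chain and HLUT share one consistent scale, so the water
identities hold exactly.

The embedded reference tissues are ICRU-44/ICRP-style adult compositions
(13 tissues from inflated lung to cortical bone, plus air and water). They
are package fixtures; the tissue-surrogate insert set for calibration is
synthetic (mixtures of cortical bone, lung and water spanning 0.30–1.82
g/cm³), standing in for a commercial electron-density phantom.

## The spectral (DLCT) chain

SPR is computed voxel-wise from (ρe, Z_eff) with the Bethe formula without
higher-order corrections, at a fixed kinetic energy of **100 MeV** (proton
kinematics, β² = 0.1834) and **I_w = 78.73 eV**. The energy choice exploits
the flatness of the ratio: between 80 and 200 MeV the SPR of soft tissues
changes by <0.2% (bone up to ~0.5%). One SPR map serves all three ions —
at equal E/Mc² all species share β², and species differences enter only
through their depth-dose shapes.

The Z_eff → I map is piecewise-linear in (Z_eff, ln I), calibrated on the
reference tissues with water-anchored Bragg-additivity I-values. Two modes:

* a **2-segment least-squares fit** with a knot at Z_eff = 8.5 separating
  soft tissue from bone, optionally constrained through
  (Z_eff,water, ln 78.73) — the compact, smooth model;
* an **interpolating model** (knot at every calibration tissue), used by the
  study pipeline so that the chain is exact at every phantom tissue; this is
  what makes the zero-discrepancy control study reproduce ground truth
  bit-for-bit.

Air is excluded from this calibration (its argon/nitrogen I-value of ~98 eV
would put a spike into the soft-tissue segment); spectral voxels with
ρe < 0.05 are instead floored — the Bethe ratio is ill-conditioned near
vacuum. The pipeline floors them at the nominal air SPR so both chains agree
in air cavities. Observed Z_eff is clipped to [1, 16] before lookup.

## The single-energy (SECT) chain

CT numbers follow the two-parameter stoichiometric model with photoelectric
exponent 3.62 and coherent-scatter exponent 1.86 (configurable; the values
are the standard ones from the stoichiometric-calibration literature, not
measured here). The truth scanner constants k₁ = 1.0e-5, k₂ = 5.0e-3 give
120 kVp-like numbers (adipose −95 HU, brain +32 HU, cranial bone +920 HU,
cortical bone +1411 HU). Calibration from insert readings is a linear
problem after cross-multiplication and is solved by non-negative least
squares: noise-free readings recover (k₁, k₂) to machine precision, making
the calibration a genuine, exactly invertible inverse problem.

The HLUT is built from (predicted HU, ground-truth SPR) of 11 reference
tissues. Two constructions:

* **interpolating** (pipeline default): vertices at the tissue points plus
  anchors at (−1000, SPR_air) and (0, 1) — ten line segments from air to
  cortical bone, exact at every calibration tissue;
* **fixed-knot least squares**: a continuous linear spline on configured HU
  knots (default −1000, −500, −120, −80, 0, 50, 100, 300, 800, 1600, 3071 —
  ten segments). The fit is isotonic-constrained (solved in non-negative
  increments), air/water anchors are enforced, knots with no tissue data in
  either adjacent segment are interpolated from their neighbours, and end
  knots beyond the data are extrapolated with the terminal slope.

The −500 knot gives the lung region its own segment; a single monotone
segment spanning lung→adipose cannot represent the embedded tissue set to
within 2%. Two of the embedded tissues (average soft tissue and CSF) form a
non-bijective pair — nearly identical CT numbers, 2% different SPR — which no
monotone HLUT can resolve; the calibration set therefore uses muscle for the
scalp and leaves average soft tissue as a test case of exactly this
degeneracy. An identity curve (SPR = 1 + HU/1000) is provided for importing
externally computed SPR maps through a CT-number interface.

## Phantom and scanner models

The head phantom is a set of nested ellipsoids on a default 2 mm isotropic
grid (192×224×200 mm): muscle scalp, cranial-bone shell (6 mm), brain, paired
eyes (r = 11 mm) and lateral ventricles (CSF), a 12 mm skull-base bone slab
and a nasal air cavity. A voxel takes the label of the highest-priority
structure containing its center; priority is the configured order.
Per-patient anatomy jitter rescales the head by ±4% and nudges internal
structures by up to 2 mm. Ground-truth ρe/Z_eff/SPR volumes are piecewise
constant per tissue, computed from the same composition oracles the chains
are calibrated on.

The scanner model applies per-tissue (or global) multiplicative bias and
i.i.d. Gaussian voxel noise; a seed fully determines the output (independent
sub-streams per volume via seed-sequence spawning). Defaults for the
realistic study: spectral ED biases of +1.10% (brain), +1.13% (cranial
bone), +0.69% (eyes), +0.48% (ventricles), +1.22% (skull base), +0.8%
(other soft tissue) and −3% (air) — the per-region discrepancy magnitudes
reported clinically between the two modalities — scaled per patient by a
factor ~N(1, 0.15); noise 8 HU / 0.008 ED / 0.12 Z_eff.

One consequence worth knowing: CT noise propagated through a *kinked*
piecewise-linear HLUT biases ROI means (Jensen's inequality at the
vertices), by up to ~±0.6% for ROIs whose tissue sits at a strong kink (eye,
CSF). The realized ROI differences therefore do not equal the imposed biases
exactly, but all stay within the clinically observed 0.3–1.9% band. This is
a property of the method, not an artifact of the implementation.

What the generator does **not** emulate: projection-space physics, beam
hardening, metal/streak artifacts, partial-volume mixtures at interfaces
(labels are crisp), spatially correlated noise, and real anatomical texture.
Passing tests therefore demonstrate the correctness and self-consistency of
the analysis chain under controlled discrepancies — not the clinical accuracy
of either scanner.

## Beam model and range analysis

Transport is strictly per-ray (no lateral scattering or nuclear
interactions): parallel rays on a 2 mm lattice accumulate WEPL by midpoint
sampling with trilinear interpolation (step = 0.5 × voxel spacing), and the
dose at geometric depth d is the water depth-dose evaluated at WEPL(d).
Pristine Bragg peaks are Bragg-Kleeman power-law curves, dose ∝ (R−z)^(1/p−1)
with p = 1.77, convolved with a Gaussian width

    σ(ion, R₀) = √[(c_ion·R₀^0.935)² + (0.012·R₀)²],

straggling constants c = 0.012 / 0.0066 / 0.0037 (proton/helium/carbon — the
ordering encodes the sharper distal gradients of heavier ions) plus a 1.2%
delivery energy-spread term; all are model constants of this package,
configurable per call. Each curve is shifted so its distal 80% crossing sits
exactly at the nominal range. Spread-out peaks solve non-negative
least-squares weights for a flat plateau (normalized to 100); peak pull-back
spacing follows the local σ, and flatness is required up to 1.2σ before the
distal edge, where the fall-off necessarily begins (plateau ripple ≤ ~0.2%
at automatic spacing, ≤ 2% even at 12 fixed peaks over 50 mm).

Ranges R90/R80 are the most distal crossings of 90%/80% of the *prescribed*
(plateau) dose, located by linear interpolation; profiles that never cross
are flagged and excluded. Per beam, five equidistant profiles span ±60% of
the target radius along the lateral axis perpendicular to the beam, and the
profile depth axis starts at the skin (first sample with local SPR > 0.3).
Range shifts follow ΔR = |R_SECT − R_DLCT| with relative shifts
(R_SECT − R_DLCT)/R_DLCT (spectral range in the denominator, sign kept in
the records, magnitudes in the summaries). The quantitative backbone is the
uniform-scaling law — SPR×(1+δ) moves the range by −δ/(1+δ)·R — which the
implementation reproduces to <0.02 mm at δ ≤ 2% on a 150 mm beam.

Dose volumes are unions of per-ray contributions with nearest-ray assignment
inside the field (no penumbra). Plans deliver 54 Gy(RBE) split equally over
beams; protons use a fixed RBE of 1.1, helium and carbon unit scaling —
biological models are out of scope, so inter-ion differences arise purely
from distal-gradient sharpness.

## Study design

Four plan archetypes on the synthetic head: A — brain target (r = 20 mm),
three beams at 0°/120°/240°; B — small skull-base target (r = 11 mm), two
nearly opposing beams; C — the plan-A target region treated with two beams
60° apart; D — central target (r = 13 mm), two nearly opposing fields.
Defaults: 8 ROI-analysis patients, 6 planning patients, protons everywhere
plus helium and carbon for the first patient (24 proton plans + 8 ion
variants). Beam parameters (SOBP weights, geometry) are fixed on the
single-energy map; dose is recalculated on the spectral map without
reoptimization — so SECT-vs-DLCT differences propagate only through the SPR
maps. Organs at risk are synthetic stand-ins: a small serial structure
abutting the distal target edge of the first beam, a brainstem-like central
structure, and the eyes from the labels.

ROI analysis mirrors the clinical sizes: brain ~100 mm² × 10 slices, eyes
~100 × 5 (one per eye), ventricles ~50 × 5, cranial bone ~50 × 10, skull
base ~25 × 10; discs are auto-seeded per slice at the in-structure
distance-transform maximum. The per-slice relative difference
δ = (mean_DLCT − mean_SECT)/mean_SECT is averaged per patient (SD over
slices) and summarized over the cohort as median and mean ± SEM, with a
two-sided paired t-test and t-based confidence interval on the per-patient
per-ROI means.

## Evaluation conventions

* Percentiles: linear interpolation between order statistics. SD: n−1
  denominator. SEM = SD/√n. Box whiskers: most extreme points within
  1.5×IQR. Intrapatient variability = mean over patients of the per-patient
  SD of shifts; interpatient = SD over patients of the per-patient means.
* 3D gamma: local normalization, 1%/1 mm, 5% low-dose cutoff, candidate
  offsets on a 0.1·DTA lattice within a 3 mm radius, searched shell-by-shell
  with a per-voxel early exit once the distance term alone exceeds the
  current minimum — mathematically identical to the exhaustive lattice
  search (verified against a brute-force oracle). Local-mode gamma is not
  symmetric under swapping reference and evaluated distributions.
* DVH: Dmean is the arithmetic voxel mean; D0.03cc the minimum dose of the
  hottest ⌈0.03 cm³/voxel volume⌉ voxels (maximum voxel dose, flagged, for
  structures smaller than 0.03 cm³); D99 the dose received by ≥99% of the
  volume (1st percentile of voxel doses). OAR flags use a strict ">" at the
  0.5 Gy(RBE) threshold; PTV coverage difference is signed, D99_SECT −
  D99_DLCT.

## Numerical choices and degenerate inputs

Determinism everywhere: one master seed, sub-streams spawned per stage;
re-running a configuration reproduces byte-identical CSV outputs. Degenerate
cases are explicit: zero-variance paired samples are flagged (p reported as
exact 0), single-record patients make intrapatient variability undefined
(flagged), rays missing the volume return empty traces, profiles without a
level crossing carry NaN ranges and are excluded from statistics, empty ROI
masks and all-below-cutoff gamma inputs raise.

Problem sizes: the default study uses a 2 mm grid (96×112×100 voxels),
2 mm ray spacing, 1 mm WEPL steps for dose volumes and 0.5 mm for line
profiles; the full default study (8+6 patients, 32 plan-ion combinations
with gamma and DVH) completes in ~1.5 minutes on one CPU. Tests use reduced
cohorts of the same models.

## Known limitations

* No reproduction of patient-specific clinical values: inputs are synthetic
  and the imposed discrepancies are configurable conditions, not
  measurements.
* The 2-segment Z_eff→I model cross-validates to <5 eV only where the
  reference table is dense (soft tissue); the lone mid-Z_eff bone
  (spongiosa) leaves ~9 eV under leave-one-out.
* Per-ray transport understates dose blurring; gamma pass rates on these
  synthetic doses are sharper-edged than a clinical dose engine would give.
* The HLUT kink-rectification bias (above) couples scan noise into ROI
  means; real calibration curves share this property.
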
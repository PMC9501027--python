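# Methods

## Acquisition model

A whole-body dynamic (WBD) FDG protocol is represented by a `FrameSchedule`:
a fixed early cardiac ladder (12×5 s, 4×10 s, 8×25 s, plus a configurable
number of 60 s frames, contiguous from injection) followed by sparse
whole-body passes. Because the passes are unidirectional, every bed position
is revisited at an even interval of `n_beds × sec_per_bed` seconds; the
simulator encodes exactly that property for one tracked bed position rather
than simulating table motion. Defaults — five 60 s frames (early segment
ending at 10 min), 11 passes of 35 s/bed over 5 beds — give a 40-frame
schedule ending near 40 min post-injection. Protocol variability (the
number of 60 s frames and of passes varied per patient in the motivating
study design) is exposed as parameters, not fixed.

Injected activity follows the BMI-adapted rule 1.5 / 2 / 3.1 MBq/kg for
BMI < 20 / 20–24.5 / > 24.5, capped at 320 MBq.

All activities are decay-corrected to injection time, so no ¹⁸F decay term
appears in any curve, and SUV and Patlak formulas need no decay handling.
Internal units: minutes, kBq/mL, Ki in mL/min/mL, Vd in mL/mL.

## Plasma input function

The simulated plasma curve is a triangular bolus rising to
`peak_amplitude` at `peak_time`, continued by a double-exponential tail
`A1·e^(−λ1 t) + A2·e^(−λ2 t)` rescaled for continuity at the peak. The
defaults (peak 88.5 kBq/mL at 0.5 min; A1 = 71.2, λ1 = 0.35 /min,
A2 = 17.3, λ2 = 0.04 /min) were calibrated once, in closed form, against
two anchors:

- liver kinetics Ki = 1.0×10⁻² mL/min/mL, Vd = 1.1 should map to a liver
  SUV near 3.1 g/mL, and tumour kinetics Ki = 3.0×10⁻², Vd = 0.9 to an SUV
  near 7.8, at the cohort reference patient (210 MBq, 82 kg). Through the
  Patlak identity these two constraints pin ∫₀⁶⁰Cp ≈ 618 kBq·min/mL and
  Cp(60) ≈ 1.6 kBq/mL.
- the tail must leave the Patlak regressors well conditioned: with too slow
  a terminal rate the late ∫Cp and Cp become nearly collinear and the
  residual equilibration transient of two-tissue-compartment tissues leaks
  into the fitted slope. Carrying most of the late area in the slow
  exponential at λ2 = 0.04 /min satisfies the same two anchors while keeping
  the t\* = 20 min slope bias of the reference tissue within a few percent,
  decreasing monotonically in t\*.

Whole blood and plasma are related by a time-varying plasma-to-whole-blood
ratio `p(t) = p_inf − (p_inf − p0)·e^(−t/τ)` with defaults p0 = 1.0,
p_inf = 1.16, τ = 5 min — a three-parameter saturating form near published
FDG plasma/whole-blood ratios. The aortic tube of the phantom contains
whole blood, i.e. Cp/p(t).

## Tissue kinetics

Tissues are either *micro* (K1, k2, k3, vb; irreversible 2TC:
dC1/dt = K1·Cp − (k2+k3)·C1, dC2/dt = k3·C1, C_T = C1 + C2 + vb·Cp) or
*macro* (exact Patlak identity C_T = Ki·∫Cp + Vd·Cp). The 2TC system is
solved on the input function's fine grid (10 ms steps by default) with an
exponential-integrator step that is exact for piecewise-linear Cp; the
trapped compartment accumulates by trapezoid. Tests verify agreement with
`scipy.integrate.solve_ivp` at rtol 10⁻¹⁰ to better than 10⁻⁴ relative.

The phantom's liver (and any background tissue) uses micro kinetics
(K1 = 0.5, k2 = 0.476, k3 = 0.0097, vb = 0.05, implying Ki ≈ 1.0×10⁻²,
Vd ≈ 1.06): the macro identity is an asymptotic description and is
unphysical at early times, where Vd·Cp would make the liver brighter than
the blood pool and defeat the aorta segmentation. Lesions are macro-mode so
that their ground-truth (Ki, Vd) is exact by construction and end-to-end
recovery can be asserted tightly.

## Frames, noise, phantoms, cohorts

Frame values are time-averages of the continuous curve over each frame
(trapezoid, 64 sub-intervals). Noise is additive Gaussian with standard
deviation `noise_scale·sqrt(max(value, floor)/duration)` — a
count-statistics proxy in which the variance of a reconstructed frame mean
scales inversely with frame duration — clipped at zero, and every random
stream takes an explicit seed. This is a desk-scale surrogate for
reconstructed-image noise: no sinogram Poisson statistics, no
reconstruction point-spread, no inter-voxel correlation (see Limitations).

The default phantom layout is deterministic: an aortic cylinder (12 mm
radius) spanning the volume, a liver ellipsoid, and spherical lesions
(8 mm radius) on a 26 mm ring inside the liver, kept clear of the liver
VOI centre.

The lesion cohort draws true Ki and Vd log-normally per group, with the
log-normal σ chosen so the distribution has exactly the configured median
and IQR (σ = asinh(IQR/2·median)/z₀.₇₅; zero IQR collapses onto the
median). Defaults are the study-shaped values: 60 cancer lesions
(Ki median 3.0×10⁻², IQR 2.2×10⁻²; Vd 0.9, IQR 0.5) versus 17 inflammatory
(Ki 2.0×10⁻², IQR 1.1×10⁻²; Vd 0.7, IQR 0.4), liver Ki 1.0×10⁻² and
Vd 1.1 with a modest per-lesion log-σ of 0.2 emulating per-patient liver
variability. Each lesion's TAC follows the macro identity plus noise; its
SUV is *emergent* from the same kinetics at the static window (55–65 min)
rather than drawn independently. Consequently cancer-lesion and liver SUV
medians land near the calibrated anchors, while inflammatory SUV and the
LBR medians sit below typical clinical report values — lesion-max versus
liver-mean reading effects and partial-volume behaviour are not modelled,
and we chose kinetic consistency over matching every marginal summary.

## Image-derived input function

1. **Segmentation** — the frames within the first 2 min are summed; voxels
   above 50% of the image's robust maximum (99.9th percentile) are kept,
   the largest 6-connected component selected, and the mask eroded by one
   voxel to suppress the partial-volume rim (erosion treats the volume
   border as foreground because the aorta continues beyond the field of
   view). The threshold is relative, so segmentation is invariant to global
   rescaling. The mask is propagated unchanged to all frames; a per-frame
   re-centering hook exists for motion but is a no-op (phantoms are
   motion-free; registration is out of scope).
2. **Extraction and conversion** — per-frame mean over the mask, multiplied
   by p(t) at frame mid-times.
3. **Tail fit** — weighted least squares of a double exponential to samples
   at t ≥ 10 min (weights ∝ frame duration), multi-start over decay pairs
   spanning 10⁻³–1 /min with amplitudes profiled out linearly, refined by
   Levenberg–Marquardt; λ1 > λ2 canonical ordering.
4. **Early reconstruction** — integral-preserving linear interpolation:
   knots at frame boundaries, knot values from the recursion
   v[k+1] = 2·value[k] − v[k] with v[0] = 0 (no tracer precedes injection),
   which makes the average over every original frame equal that frame's
   value exactly; linear inputs are fixed points.
5. **Assembly** — interpolated early part below the switch time (default
   10 min, the end of the early cardiac segment), fitted tail above, a
   one-grid-step continuity blend at the switch, and an error if the two
   segments disagree by more than 10% there. The discretized curve (10 ms
   grid) caches its running integral for the Patlak design.

## Patlak estimation

"Weighted multilinear regression" is implemented in the un-divided form —
response C_T, regressors (∫Cp, Cp) — which is the same model as the divided
Patlak plot without amplifying noise by dividing by Cp. Weights are
proportional to frame duration, matching the simulator's noise model so
weighted least squares is efficient; the vendor weighting is undisclosed,
so this (and t\*) are the main expected sources of discrepancy against
vendor outputs. Regressors are evaluated as frame *time-averages* of Cp and
its running integral rather than mid-time point values: frames are
themselves time-averages, so this makes the fit exactly consistent with
noiseless macro data (mid-time evaluation differs only at second order in
frame duration but breaks exactness). The 2×2 weighted normal equations are
solved in closed form; a collinear design raises a "degenerate design"
error; negative Ki or Vd estimates are reported, never clipped — clipping
is a display concern. t\* defaults to 20 min: the 2TC transient decays as
e^(−(k2+k3)t), below 2% of its initial size by then for typical FDG rates;
it is a configuration knob, and on noiseless data the residual Ki bias
decreases monotonically as t\* grows.

Voxelwise maps share one design, so the whole volume is fitted with a
single vectorized solve; per-voxel failures (non-finite inputs) are
recorded as zeros with zero r² rather than raised, and results are
independent of evaluation order. The static SUV image is the
overlap-weighted frame average over a window divided by injected activity
per body weight.

For a tail decaying at rate λ2 the asymptotic Patlak intercept of a 2TC
tissue is vb + K1·k2/((k2+k3)(k2+k3−λ2)) — the textbook
vb + K1·k2/(k2+k3)² is its λ2 → 0 limit; tests assert against the corrected
form.

## Measurements and statistics

VOIs are spheres of nominal volume at 0-based x/y/z voxel centres (the
reference-tissue volumes follow the reading protocol: blood 1 cm³, bone,
brain, fat, muscle, spleen 2 cm³, liver and lung 3 cm³); realization keeps
every voxel whose centre lies within the nominal radius and always includes
the centre voxel. Lesion values are VOI maxima, liver references VOI means,
and LBR = lesion max / liver mean (invariant to global map rescaling). In
the TAC-based cohort path each lesion's curve stands for its peak voxel and
is paired with its own liver curve.

Group comparison is gated by Shapiro–Wilk in both groups (α = 0.05):
Welch's unpaired t-test when both pass (the default behaviour of the usual
statistical software for "unpaired t-test"), otherwise the two-sided
rank-sum (Mann–Whitney) test — exact by full enumeration of labelings when
n₁+n₂ ≤ 12 (mid-ranks, so ties are exact), tie-corrected normal
approximation above. Constant groups are signalled, not silently passed.
The ROC uses midpoints between consecutive unique scores plus ±∞ as
thresholds, calls a case positive at score ≥ threshold, picks the smallest
threshold maximizing Youden's J (ties broken toward sensitivity), and
integrates AUC by trapezoid. Spearman's ρ uses mid-ranks with the two-sided
t-approximation. The cohort summary reports, per variable (SUV_max, Ki_max,
Vd_max and their LBRs), group medians with IQRs and the gated comparison,
plus the pooled paired LBR(Ki)-vs-LBR(SUV) signed-rank contrast and their
Spearman correlation. Raw p-values are reported without multiple-testing
correction, mirroring conventional practice in small prospective cohorts.
Group-wise and pooled LBR views are both reported; they are not mutually
derivable without raw data.

## What passing tests do and do not show

The synthetic generator reproduces the acquisition geometry in time, the
kinetic model class, and the cohort's distributional shape. It does not
reproduce scanner physics (reconstruction, scatter, randoms, PSF), patient
motion, reader variability in lesion delineation, or partial-volume
effects. Passing the end-to-end recovery tests therefore demonstrates the
*estimator chain* is correct and well-conditioned under the stated noise
model, not that clinical numbers would be reproduced on real data; the
statistical calibration tests demonstrate the inference machinery holds its
nominal error rates under the null.

Problem sizes in the default test and acceptance runs — 48³ voxels ×
40 frames for the phantom, 77 lesions for the cohort, 500–2000 replicates
for Monte-Carlo characterizations — were chosen as the smallest sizes at
which the asserted properties are informative.

## Numerical choices

- Input-function grid step 0.01 min; frame sampling 64 trapezoid
  sub-intervals; the 2TC step update uses expm1 to avoid cancellation at
  small (k2+k3)·h and an exact-for-linear-Cp kernel integral.
- Degenerate inputs: empty masks, all-zero volumes, windows outside the
  scanned span, constant statistical groups, and single-class ROC inputs
  all raise with specific messages; per-voxel map failures degrade to
  (0, 0, qc 0).
- Determinism: seeds are explicit everywhere; the pipeline derives its
  stage seeds from the single run seed via `SeedSequence`, and rerunning a
  config yields byte-identical record CSVs.

## Known limitations

- Gaussian duration-scaled noise, not reconstruction-faithful noise.
- No inter-frame motion and no registration; the TOI motion hook is a
  no-op.
- Emergent SUV understates clinical lesion-to-background contrast (no
  partial volume, no max-bias from spatial noise texture in the TAC path).
- Single tracked bed position; no axial bed overlap effects.
- The reversible (k4 > 0) model, Logan analysis, and direct
  reconstruction-space parametric estimation are out of scope.
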
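# Methods

This note documents the models, conventions and defaults behind `limbkin`,
what the synthetic generator does and does not emulate, and the numerical
choices that matter when interpreting its output.

## The measurement model

A limb contacting the instrumented attachment applies a true force
`F(t) = (f_x, f_y, f_z)` (fore–aft, mediolateral, vertical; newtons). The
attachment is compliant: it bends under load, attenuating the registered
force and coupling the channels, more strongly the farther the foot lands
from the load cell. The recorded signal is modeled as static and linear:

    r(t) = G(p) · F(t) + o(p) + ε(t)

with `G(p)` a 3×3 gain matrix and `o(p)` an offset vector, both functions of
the contact position `p` (cm along the attachment, signed, |p| ≤ 5), and
`ε` iid Gaussian sensor noise. Inertial effects of the moving attachment are
not modeled: the attachment is light (140 g) relative to the animals and the
gait is very slow, so acceleration-dependent terms are negligible; the model
is purely static, as is the calibration.

### Calibration

Known loads `w = m·g` (g = 9.80665 m s⁻²; ten masses, 0.1–3.40 kg) are
applied independently along each axis at five positions
(0, ±2.5, ±5 cm). For each (axis `a`, position `p`) cell, ordinary least
squares of each channel reading on the applied force gives slope `β_ab(p)`
and intercept `α_ab(p)`; the slopes form column `a` of `Ĝ(p)` and the
intercepts estimate the channel offsets (averaged over the three loading
axes, since each loading axis observes the same offsets). Per-channel R² is
reported; with the default sensor noise the loaded-channel fits sit at
R² ≈ 0.9997, comfortably above the 0.99 quality bar used to accept a
calibration.

Between grid positions, every entry of `G` and `o` is interpolated linearly
in `p`. This was a genuinely open choice — nothing in the protocol dictates
how compliance varies between calibrated positions — and entry-wise linear
interpolation is the simplest monotone scheme consistent with smooth bending
of a beam. Interpolation at a grid point reproduces the grid fit exactly;
extrapolation beyond ±5 cm is refused rather than guessed.

The x↔y coupling terms cannot be estimated when only single-axis loadings
are available and the horizontal channels are never co-excited; the model
therefore zeroes them by default (`zero_xy_crosstalk=True`), and propagating
a small true coupling `c` through the zeroed correction leaves a bounded
residual of order `‖G⁻¹‖·c·|F_horizontal|` — small here because horizontal
forces are a fraction of body weight. The full-matrix path exists for
calibrations that do co-excite the horizontal axes.

### Correction

Per trial: `F̂ = Ĝ(p)⁻¹ (r − offset)`. The offset is, by default, the
per-trial baseline (channel means over the first 0.5 s of the trace, which
the acquisition protocol leaves unloaded) because unloaded drift is
trial-specific and the baseline subsumes `o(p)`. Subtracting both the
baseline and the regression intercepts would remove the offset twice; the
intercepts are therefore applied only when no unloaded window exists
(`use_model_offsets=True`). Invertibility of `Ĝ` is checked at model build
time (condition number < 1e6 at grid points and midpoints).

## Signal processing

* **Filter.** "Low-pass Fourier filter at 15 Hz" is implemented literally:
  DFT, zero every bin with |f| > 15 Hz, inverse DFT, real part. The filter
  is zero-phase (peak timing preserved), idempotent, preserves DC, and
  removes out-of-band tones to numerical precision. Brickwall truncation can
  ring on signals with sharp discontinuities; stance-phase force profiles
  start and end near zero, where this is immaterial.
* **Contact detection.** A contact begins where |f_z| exceeds 5% of body
  weight sustained for ≥60 samples (50 ms at 1200 Hz) and ends when the
  signal stays below threshold equally long; shorter dropouts are bridged.
  The threshold/persistence pair is a package default (no published rule
  exists): 5% BW sits well above the filtered noise floor, and 50 ms is
  short relative to multi-second stance phases.
* **Canonical frame.** All kinetics are computed in a frame where +x is
  propulsive, +y lateral (away from the midline), and +z the pull on the
  substrate. The remap is a per-axis sign flip determined by travel
  direction, limb side and one camera/platform convention (+y points to the
  animal's left when traveling +x; the lab vertical axis points up, so the
  suspended animal's pull appears negative and is flipped positive). A
  contact and its mirror image (opposite side, opposite travel) canonicalize
  identically.

## Kinetics

Over the detected contact window: V_pk = max f_z; P_pk/B_pk the extreme
positive/negative fore–aft forces; L_pk/M_pk the extreme positive/negative
mediolateral forces; impulses by trapezoidal integration at the native
1200 Hz (discretization error is O((Δt)²), far below every tolerance used).
Peaks and impulses are extracted after filtering. Forces are normalized to
%BW (×100/BW) and impulses to %BWS. Braking and medial quantities are stored
signed-negative; descriptive statistics use magnitudes, since the scientific
comparisons concern magnitude, not direction. The decomposition
`J_P + J_B = net fore–aft impulse` holds exactly by construction (the
positive and negative parts of f_x sum to f_x under a linear quadrature).

A limb is *net propulsive* when the net fore–aft impulse exceeds +1 %BWS,
*net braking* below −1 %BWS, else *neutral*; the ±1 %BWS band quantifies
"approximately zero" and is configurable.

Stride-level weight support divides each limb's impulse by the two-limb
total. Two denominators are in circulation for the propulsive/braking
shares: per-direction totals (default) and the total *vertical* impulse;
both are implemented (`stride_support(..., denominator=...)`) and the
vertical shares sum to 100% under either.

## Speed

Two beam landmarks 106 cm apart calibrate pixel space (scale = separation ÷
median per-frame pixel distance; the median resists tracking jitter). Stride
speed is net CoM displacement over elapsed time — appropriate because trials
are screened for visually steady progression — with a frame-to-frame
averaging option for sensitivity analysis. Pose estimation itself is out of
scope; the input is a tracked-coordinates CSV at 60 Hz.

## The synthetic generator

The generator is the package's test surface and defines its study
conditions; it emulates the *statistical* structure of suspensory-walking
kinetics, not waveform morphology.

* **Profiles.** Each channel is built from half-sine lobes: one vertical
  lobe spanning the contact; a propulsive/braking lobe pair split at time τ;
  a lateral/medial pair split independently. Half-sine lobes give analytic
  peaks (the amplitude) and impulses (`2AΔ/π`), which ride along as ground
  truth. Real traces are smoother and multi-modal; peaks and impulses, not
  waveform shape, are the contract.
* **Cohorts.** Per contact, targets are drawn per limb: vertical peak, net
  fore–aft impulse, lateral and medial peaks, contact duration, speed and
  body mass. The default (`bradypus` preset) encodes the published pooled
  statistics for *Bradypus variegatus*: vertical peaks 82.0±13.2 %BW (hind)
  and 68.6±10.6 %BW (fore); net impulses −40.7 (hind) and +23.6 %BWS
  (fore); lateral peaks 6.1±7.5 and 6.5±5.7 %BW; body mass 3.84±0.3 kg,
  5 animals, 90 hindlimb and 57 forelimb contacts, 1200 Hz. The minor
  fore–aft lobe peak (braking for the forelimb, propulsive for the
  hindlimb) is drawn around 5±2.5 %BW — "modest", consistent with the
  qualitative description of both limbs' minor phases — and the major lobe
  amplitude is *solved* from the sampled net impulse via the closed form,
  so the net-impulse distribution is matched by construction (infeasible
  draws requiring negative amplitudes are resampled, capped and warned).
* **Unprinted defaults**, chosen once on field-plausibility grounds:
  contact duration ~N(3.0, 0.5) s truncated at 1 s (slow sloth gait,
  multi-second stance); fore–aft split fraction 0.75 for the forelimb
  (long early propulsion, late modest braking) and 0.25 for the hindlimb
  (brief early propulsion, dominant braking); medial peaks ~4±3 %BW (fore)
  and 9±5 %BW (hind), making medial force hindlimb-dominant; mediolateral
  split fraction 0.4, lateral lobe first (lateral purchase at touchdown);
  speed ~N(0.12, 0.04) m s⁻¹ truncated at 0.01.
* **Magnitude distributions.** Normal is assumed (the distributional family
  is not reported) and truncated at zero. The parent parameters are solved
  so the *realized* truncated mean equals the target exactly; the realized
  sd matches the target wherever attainable. One target is not: a
  zero-truncated normal cannot exceed a coefficient of variation of ≈0.97,
  so the hindlimb lateral peak (target CV 7.5/6.1 ≈ 1.23) is generated with
  the truncation point capped (realized sd ≈ 5.9 %BW, mean exact). Means
  are the quantities validated downstream.
* **Platform.** The default ground-truth distortion uses diagonal gains
  0.90–0.94 at the center falling by 0.03–0.05 at the span edges, vertical
  cross-talk into x (antisymmetric in p, up to 0.04) and y (0.02–0.04),
  horizontal-into-vertical coupling up to 0.03, offsets of order 0.1 N, and
  zero x↔y coupling (that entry is unobservable under the default protocol,
  so the default truth omits it; a nonzero value exercises the
  bounded-residual path). All entries are piecewise-linear in p with their
  only kink at p = 0 — a calibrated position — so a five-point grid
  calibration can represent the truth exactly; deviations from that
  assumption would appear as interpolation bias between grid points.
  Sensor noise defaults to 0.5% of the calibration full-scale load
  (0.005 × 33.35 N ≈ 0.167 N per channel, iid Gaussian), a level at which
  the calibration meets the R² ≥ 0.99 quality bar and corrected traces
  recover true forces to ≈0.5 %BW RMS.

What passing the closed-loop tests shows: the pipeline undoes the distortion
it models and recovers the generator's distributional targets without bias
beyond sampling error. What it does not show: robustness to non-linear or
frequency-dependent platform behavior, non-half-sine waveforms, overlapping
double contacts, or tracking failures — none of which the generator
produces.

## Problem sizes and determinism

Closed-loop validation uses 500-contact cohorts per limb (sampling SE of the
pooled vertical-peak mean ≈ 0.6 %BW, so a 3-SE band is a ±1.8 %BW check);
law-of-large-numbers checks use 2000 draws; round-trip correction checks use
100 contacts. Every stochastic function takes an explicit seed or
`numpy.random.Generator`; nothing touches global random state, and repeated
runs with the same seed are bit-identical (the CLI `run` command writes
byte-identical tables).

## Known limitations

* Static, linear platform model; no dynamic compensation.
* Contact detection assumes a single clean footfall per trace.
* The generator draws per-contact quantities independently (no
  within-animal correlation beyond shared body mass), so mixed-model
  random-effect variance in exported tables is not calibrated to anything.
* Statistical testing (normality/homoscedasticity checks, mixed-effects
  fits, post hoc contrasts) is deliberately out of scope: the package's
  contract ends at the rank-transformed, model-ready export, since those
  fits are routine in standard statistical software.
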
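# Methods

`trainrattle` models the mechanics of a courting peafowl's train-rattling
display: the bird stridulates its tail feathers (rectrices) against the
erect train at ~25.6 Hz, driving the feather array near resonance, making a
broadband pulsating sound at the same rate, and leaving the iridescent
eyespots almost stationary against a blur of loose barbs. This note
documents the models, the choices made where the design was genuinely open,
and what the synthetic data do and do not establish.

## Cantilever model of the rachis

A feather's central shaft (rachis) of length `L_R` outside the body is an
Euler–Bernoulli cantilever clamped at the insertion. Resonant frequencies
of mode `k` are

    f_k = K_k^2 / (2 π L_R^2) · sqrt(G' I / μ_F)

with `G'` the dynamic storage modulus (default 3.3 GPa, the longitudinal
Young's modulus of display-feather cortex), `I` the second moment of area
of the rachis cross-section and `μ_F` the whole-feather linear density.
`K_k` solves the boundary's characteristic equation, found by bracketed
`brentq` bisection in analytically known brackets (clamped-free roots in
`((k−1)π, kπ)`, clamped-hinged in `(jπ, (j+½)π)`), absolute tolerance
1e−10.

Two boundary conditions are supported. A free tip is the classical
cantilever (K₁ = 1.8751). A hinged tip models a heavy tip ornament — the
eyespot sits just distal to a vibration node, so for higher modes the tip
is effectively pinned; its roots solve `tan K = tanh K` (3.9266, 7.0686,
10.2102, …). Two index conventions coexist and deserve care:

* `beam.characteristic_coefficient("clamped_hinged", k)` follows the field
  convention in which a mode with `k−1` nodes has one node *at the tip*,
  so mode `k` uses the `(k−1)`-th hinged root (`k = 2 → 3.927`); `k = 1`
  is undefined for a hinged tip.
* `synthetic.gen_mode_envelope(boundary, k)` is indexed by *interior* node
  count (`k−1` interior nodes for both boundaries), which is what
  `kinematics.identify_normal_mode` counts on a tracked spatial envelope,
  where an endpoint node cannot be distinguished from the clamp. For the
  hinged envelope of index `k` this is the `k`-th nonzero root.

A concentrated tip mass `M_E` (the eyespot with its interlocked barbules)
lowers every frequency by `1/sqrt(1 + 4.1·M_E/M_F)`, the standard lumped
correction with the tip-to-modal-mass coefficient 4.1 taken as given; `M_F`
is the mass of the rest of the feather. `(I/μ_F)` enters as a
length-weighted average over segments — the plain description "the average
of the ratio" leaves the weighting open, and length weighting makes the
average independent of how finely a region is segmented.

## Cross-section model and buckling

Each rachis segment is a cylindrical (optionally elliptical) cortex shell
of thickness `t` filled with pith. `t` is not observable externally; it is
recovered by inverting the measured linear density
`μ_R = ρ_c A_cortex + ρ_p A_pith` given the outer diameter(s). The
inversion is monotone in `t` whenever `ρ_c > ρ_p`, so the root is unique;
`brentq` with xtol 1e−15 recovers generator-constructed walls to well below
1e−9 m. Cortex and pith densities default to 1150 and 80 kg/m³ —
keratin-cortex and medullary-foam magnitudes — and are explicit parameters
everywhere, never buried constants. Pith contributes mass but, by default,
no bending stiffness (`pith_modulus_ratio = 0`, configurable).

Buckling of the erect feather uses, per segment midpoint with `L_eff` the
distance to the tip:

* Euler (recoverable elastic bowing):
  `σ_E = π² E I / (A_cortex (2 L_eff)²)`, effective-length factor 2 for a
  fixed-free column (the factor is a choice; 2 is the standard value for
  this support).
* Local shell kinking (irreversible): `σ_L = c E t / r` with knock-down
  coefficient `c = 0.6` (classical thin-shell value, configurable).
  Sections with walls within 1 nm of solid get an infinite sentinel —
  there is no wall to kink.

The governing (smaller) critical stress and its minimum location are
reported; on synthetic display-feather profiles Euler governs essentially
everywhere, with the weakest point near the base — the shaft bends
appreciably long before it can kink.

## Transfer functions and Q

A shaker drives the mounted feather with a slow linear frequency sweep
(presets 0.042 Hz/s over 0.5–3 Hz, 0.25 Hz/s over 0–15 Hz, 1.8 Hz/s over
10–120 Hz) while both the shaker head and a feather point are tracked at
240 fps. The drive transfer function is the ratio of short-time Fourier
magnitudes of response and drive evaluated at the instantaneous drive
frequency.

Implementation choices that matter:

* **Single-frequency windowed DFT.** Rather than interpolating a binned
  spectrogram, each frame evaluates a Hann-windowed DFT exactly at the
  sweep's instantaneous frequency. Window attenuation and scalloping are
  identical for the two channels and cancel in the ratio.
* **Per-frame adaptive windows.** The window must span enough drive cycles
  to resolve the line, yet short enough that the sweep moves little
  compared to the narrowest resonant peak within one window (envelope
  smearing biases Q low). Windows target ~1.5 cycles with a 0.2 s floor
  and are rounded so the window spans an integer number of half-cycles,
  which places the negative-frequency image of the tone on a Hann-transform
  null; this keeps even 1.5-cycle windows accurate for narrow
  low-frequency peaks.
* **Noise-floor masking.** Each frame also probes the drive channel a few
  transform nulls away from the line, measuring the broadband noise in the
  same units; bins whose drive magnitude is below 3× that floor are
  flagged invalid instead of silently divided (video discretization noise
  dominated real recordings above ~40–60 Hz).

Optional Savitzky–Golay smoothing (cubic, 1.3 Hz window converted to the
nearest odd point count) is exact on cubic trends and is recommended
before peak fitting on noisy data; on clean data the fit uses the raw
curve, since a 1.3 Hz window would bias peaks narrower than ~2 Hz.

Each detected peak (local maxima, prominence ≥ 5% of the global maximum,
≥ 1 Hz apart; both thresholds configurable) is fitted by nonlinear least
squares with the base-driven damped-oscillator magnitude

    |H(f)| = A₀ / sqrt((1 − (f/f₀)²)² + (f/(f₀ Q))²)

over a window down to 25% of the peak height. "A Lorentzian" admits several
parameterizations; this one is the physical amplitude curve of the system
being measured and is consistent with the width bookkeeping
`Δf_3dB = f_k/Q_k` (drive power halves at that full width). Mode indices
are assigned in ascending frequency, ties broken by amplitude. If a fit
fails to converge the peak is still reported with the width measured
directly from the spectrum (half-power crossings by linear interpolation;
a one-sided crossing is doubled with a warning) and an RMSE of NaN.
Quality factors above 2π indicate weak damping; measured feathers fall in
the strongly damped ½ < Q < 2π range, which is what lets one drive
frequency excite feathers of many lengths. The damped response peak sits
below the natural frequency by `1 − sqrt(1 − 1/(2Q²))` — under 2% for
Q ≥ 3.6, so peak positions are read as resonant frequencies.

Verified estimator performance under the synthetic study conditions:
noise-free single modes are recovered within 0.5% in `f_k` and 5% in `Q_k`
across Q ∈ {2,…,16} and f ∈ {5, 10, 25} Hz; with displacement noise at 10%
of the peak response amplitude, the median Q error over 50 seeded
replicates stays below 15% (with smoothing enabled).

## Tail drive-power model

Rectrices interact weakly, so the power needed to shake the whole tail is
a sum over feathers and modes of independent base-driven oscillators:

    P(f) = Σ_i Σ_k  ½ m_i γ_k Q_ik⁻¹ (2πf)³ A_d² |H_ik(f)|²

with `m_i = μ_i L_i` the feather mass, `γ_k` the effective modal mass
fraction of a uniform clamped-free beam under base excitation (0.613,
0.188, 0.065, …), `A_d` the drive amplitude. This functional form is a
reconstruction of the standard dissipated power of a base-excited damped
oscillator — the original model's exact weighting is not published — and
is isolated in `modal_drive_power` so it can be swapped. Mode parameters
default to uniform-beam frequencies (a stiffness ratio `G'I/μ_F` of
11.1 m⁴ s⁻² puts a 27 cm rectrix fundamental at ~25.6 Hz, matching the
display band) and the measured per-mode mean rectrix Q values (7.8, 5.6,
4.9). The default frequency grid spans 0.5–32 Hz, the band containing all
the shaking behaviors; the model has no trustworthy input above the
~40–60 Hz measurement ceiling. The demonstration tail is generated, not
measured: 18 rectrices graded from 27 to 50 cm with most near full length
(power-ramp exponent 0.25), linear density 3.5 g/m. On that tail the
spectrum shows a broad peak in the 20–30 Hz display band, a second below
10 Hz, and nothing below 5 Hz; lengthening all feathers shifts every peak
down. The absolute peak positions depend on the (unpublished) morphology
of real tails and are not claimed — only the band structure and the
additivity/homogeneity/length-monotonicity properties are.

## Display kinematics

Vibration frequency is estimated by counting frames over 10 cycles
(positive-going zero crossings of the mean-subtracted track; the span is
read to the nearest whole frame, so a 25.6 Hz tone at 240 fps reads
240·10/94 = 25.53 Hz), cross-checked by an FFT estimate with a
higher-harmonic flag at 20% of the fundamental. At display onset the
frequency rises as

    f(t) = f_ss (1 − e^(−t/τ))

— a saturating exponential is the simplest law consistent with a quoted
initial rate (`f_ss/τ`) and time constant; both parameters are fitted by
least squares on the cycle-by-cycle instantaneous frequency (reciprocal
zero-crossing intervals, a choice the source measurements leave open).
Defaults `f_ss = 25.6` Hz, `τ = 0.8` s give an initial rate of 32 Hz/s,
within the measured 43 ± 10 Hz/s.

Bout sampling takes three non-overlapping 10-cycle windows: at peak
amplitude (maximum of a 0.25 s moving-RMS envelope, earliest frame on
ties), immediately before, and immediately after; bouts under 30 cycles
yield only the flagged peak window. Normal modes are identified by
counting interior sign changes of the tracked spatial envelope
(`k = 1 +` nodes). Eyespot displacements convert from pixels via the
40.5 mm mean eyespot diameter, and to visual angle by full-displacement
arctangent — at 1.7 mm from 1 m this is 0.097°, i.e. 0.1° at the viewing
bird's acuity limit, which is why the eyespots look stationary.

The train-length effect is computed from printed regression coefficients
only (0.04 Hz/cm × 43 cm range = 1.7 Hz): the mixed-model fitting behind
those coefficients is routine statistics outside this package's scope, and
naive endpoint propagation of the slope CI (0.4–3.0 Hz) differs slightly
from the model-based interval, which would require the unpublished fitted
covariance.

## Bioacoustics

Spectrograms use a Hann window, 0.01 s short-time window, 95% overlap; the
DFT size defaults to the next power of two (512 at 44.1 kHz), giving the
86.1 Hz bin spacing characteristic of the published analyses (an exact
441-point DFT would give 100 Hz). Power spectra use a 1.00 s window for
1 Hz resolution. Pulse rate is estimated from the amplitude envelope
(rectify + 4th-order Butterworth low-pass at 100 Hz, zero-phase), peak
picking with a refractory period of 1/(50 Hz) and a gain-invariant
relative height threshold; the rate is `(n−1)/span`. On synthetic pulse
trains the estimator is unbiased to <0.5% and stays within 2% at 10 dB
broadband SNR across 20–30 Hz.

The synthetic rattle is band-limited white noise (default 0.5–15 kHz — the
spectral shape of individual pulses is not documented, so the band is a
free parameter) shaped by raised-cosine envelopes of 5 ms repeating at the
pulse rate, RMS-normalized with a peak-clipping guard. WAV I/O supports
16- and 24-bit PCM (24-bit being the native field-recorder depth).

## Allometry

Shaking frequencies scale with body mass as
`log10 f = 1.335 − 1.86 log10 M` (shivering) and
`log10 f = 1.063 − 0.215 log10 M` (shaking dry). The mass unit of the
printed coefficients is not stated; kilograms is adopted (and declared on
the law object) because it places multi-kilogram birds' few-Hz shaking
behaviors inside the shaking-dry band. Confidence bands are user-supplied
half-widths in log10-frequency; without one, classification degrades to
binary above/below with a warning. Train-length measurements are corrected
for feather growth at 0.41 cm/day.

## Synthetic data: what it does and does not show

The generators reproduce the *structure* the analysis assumes:
quasi-steady-state modal responses to slow sweeps (the measured protocol's
stated purpose; transient ODE integration is deliberately omitted),
deterministic seeded Gaussian displacement noise, morphometric profiles
whose taper and wall construction are forward-consistent with the
cross-section inversion, and slenderness calibrated so `L_R/D_avg` runs
from 95 (14 cm) to 293 (112 cm) across the display-feather length range.
They do not reproduce: coupling between loose barbs and rachis (which
makes real long-feather frequencies fall below the uniform-beam model),
inter-feather contact in arrays, mount compliance, out-of-plane motion,
amplitude-dependent damping, or real pulse spectra. Passing tests
therefore validate the estimators and the theory pipeline, not the field
values; quantities like the 25.6 Hz grand mean, measured Q ranges, and
published tail-spectrum peak positions (21.9/6.9 Hz) depend on unpublished
raw data and are treated as plausibility ranges only.

## Numerical notes

* All randomness flows from explicit integer seeds; identical seeds give
  bit-identical outputs.
* Root brackets never evaluate `tan` at a pole; cosh growth is tamed by
  working with `cos K + 1/cosh K` in test oracles.
* Problem sizes: sweeps are the full preset durations (≈ 60 s at 240 fps);
  recovery studies use 50 seeded replicates; spectra use 0.05 Hz grids.
* Degenerate inputs fail loudly: infeasible cross-section densities name
  the offending segment, empty/flat spectra raise, schema violations name
  the missing column, unknown config keys are rejected.
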
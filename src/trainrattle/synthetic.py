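"""Synthetic inputs for every stage of the pipeline.

Laboratory and field measurements of vibrating display feathers are not
deposited in any standard repository, so each consumable of the analysis is
emulated here with the physical structure the analysis assumes:

* tapered pith-filled rachis morphometric profiles,
* paired shaker-drive / feather-response swept-sine recordings built from
  steady-state damped-driven-oscillator responses,
* display trajectories whose vibration frequency rises exponentially to a
  steady state at onset,
* trains of short broadband sound pulses repeating at the display frequency,
* analytic cantilever mode-shape envelopes.

All generators take an explicit integer seed and are bit-for-bit
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import beam
from .datatypes import (
    AudioClip,
    Boundary,
    FeatherClass,
    RachisProfile,
    SweepProtocol,
    TrajectoryTimeSeries,
)

__all__ = [
    "FeatherSpec",
    "OscillatorBank",
    "gen_rachis_profile",
    "gen_swept_sine_pair",
    "gen_display_trajectory",
    "gen_rattle_audio",
    "gen_mode_envelope",
    "lorentzian_magnitude",
]


# Tip diameter as a fraction of the base diameter for a fully tapered
# (taper_exponent = 1) rachis; chosen so profiles thin markedly toward the
# tip, as measured rachises do, while staying strictly positive.
_TIP_DIAMETER_FRACTION = 0.3
# Cortex wall thickness as a fraction of the local outer radius.
_WALL_FRACTION = 0.35
# Barb mass per unit length relative to the local rachis linear density.
_BARB_MASS_FACTOR = 1.2

# Slenderness calibration: mean rachis diameter grows sublinearly with
# length, anchored to L_R/D_avg ~ 293 for the longest (1.12 m) display
# feathers and ~ 95 for the shortest (0.14 m).
_DAVG_REF_L = 1.12  # m
_DAVG_REF = _DAVG_REF_L / 293.0  # m
_DAVG_EXPONENT = math.log((0.14 / 95.0) / _DAVG_REF) / math.log(0.14 / _DAVG_REF_L)

# Default keratin cortex / pith densities (kg/m^3); explicit config keys of
# the generator, not hidden constants.
CORTEX_DENSITY = 1150.0
PITH_DENSITY = 80.0


@dataclass(frozen=True)
class FeatherSpec:
    """Parameters from which a synthetic rachis profile is generated."""

    feather_class: FeatherClass | str
    L_R: float  # m
    n_segments: int = 12
    base_diameter: float | None = None  # m; None -> slenderness calibration
    taper_exponent: float = 1.0
    cortex_density: float = CORTEX_DENSITY
    pith_density: float = PITH_DENSITY
    M_E: float | None = None  # kg; None -> class default
    jitter: float = 0.02  # fractional measurement scatter
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "feather_class", FeatherClass(self.feather_class))
        if self.L_R <= 0:
            raise ValueError("L_R must be positive")
        if self.n_segments < 4:
            raise ValueError("need at least 4 segments")
        if self.cortex_density <= self.pith_density or self.pith_density < 0:
            raise ValueError("require cortex_density > pith_density >= 0")
        if self.base_diameter is not None and self.base_diameter <= 0:
            raise ValueError("base_diameter must be positive")
        if self.M_E is not None and self.M_E < 0:
            raise ValueError("M_E must be non-negative")

    @property
    def resolved_base_diameter(self) -> float:
        if self.base_diameter is not None:
            return self.base_diameter
        # choose D0 so the mean diameter follows the slenderness calibration
        d_avg = _DAVG_REF * (self.L_R / _DAVG_REF_L) ** _DAVG_EXPONENT
        u_mid = (np.arange(self.n_segments) + 0.5) / self.n_segments
        shape = _taper(u_mid, self.taper_exponent)
        return float(d_avg / shape.mean())

    @property
    def resolved_M_E(self) -> float:
        if self.M_E is not None:
            return self.M_E
        return 3.0e-4 if self.feather_class is FeatherClass.EYESPOT else 0.0


def _taper(u: np.ndarray, exponent: float) -> np.ndarray:
    """Diameter shape factor: 1 at the base, tapering toward the tip."""
    return ((1.0 - u) + u * _TIP_DIAMETER_FRACTION) ** exponent


def gen_rachis_profile(spec: FeatherSpec) -> RachisProfile:
    """Generate per-segment morphometrics for one feather.

    The outer diameter tapers monotonically from the base; linear densities
    are computed forward from the cross-section model (cortex shell of
    thickness ``_WALL_FRACTION`` times the local radius around a pith core),
    so the wall-thickness inversion in :mod:`trainrattle.beam` is exactly
    consistent with these profiles.  Multiplicative measurement scatter is
    applied to the diameters; identical seeds give identical profiles.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_segments
    edges = np.linspace(0.0, spec.L_R, n + 1)
    x = edges[:-1]
    dx = np.diff(edges)
    u_mid = (x + 0.5 * dx) / spec.L_R

    D0 = spec.resolved_base_diameter
    D1 = D0 * _taper(u_mid, spec.taper_exponent)
    if spec.jitter > 0:
        # correlated, monotonicity-preserving scatter: jitter the base scale
        # and a smooth low-order perturbation rather than raw per-segment noise
        scale = math.exp(rng.normal(0.0, spec.jitter))
        tilt = rng.normal(0.0, spec.jitter)
        D1 = D1 * scale * np.exp(tilt * (u_mid - 0.5))
    # dorsoventral diameter: stiffer front-to-back, increasingly so toward
    # the tip; the reinforcement follows the taper so the taper_exponent=0
    # limit is an exactly uniform beam
    D2 = D1 * (1.0 + 0.3 * u_mid * spec.taper_exponent)

    t = _WALL_FRACTION * D1 / 2.0
    a1, a2 = D1 / 2.0, D2 / 2.0
    core = np.pi * (a1 - t) * (a2 - t)
    mu_R = spec.cortex_density * (np.pi * a1 * a2 - core) + spec.pith_density * core
    mu_F = mu_R * (1.0 + _BARB_MASS_FACTOR)

    M_E = spec.resolved_M_E
    mu_E = None
    if spec.feather_class is FeatherClass.EYESPOT and M_E > 0:
        eyespot_len = min(0.1 * spec.L_R, 0.06)
        mu_E = M_E / eyespot_len

    return RachisProfile(
        x=x,
        dx=dx,
        D1=D1,
        D2=D2,
        mu_R=mu_R,
        mu_F=mu_F,
        mu_E=mu_E,
        L_R=spec.L_R,
        M_E=M_E,
        feather_class=spec.feather_class,
    )


# ---------------------------------------------------------------------------
# Driven-oscillator sweeps


def lorentzian_magnitude(f, f0: float, Q: float, gain: float = 1.0):
    """Steady-state amplitude ratio of a base-driven damped oscillator.

    ``|H(f)| = gain / sqrt((1 - (f/f0)^2)^2 + (f / (f0 Q))^2)``; equals
    ``gain * Q`` at ``f = f0``.
    """
    f = np.asarray(f, dtype=float)
    r = f / f0
    return gain / np.sqrt((1.0 - r**2) ** 2 + (r / Q) ** 2)


def _oscillator_phase(f, f0: float, Q: float):
    f = np.asarray(f, dtype=float)
    r = f / f0
    return -np.arctan2(r / Q, 1.0 - r**2)


@dataclass(frozen=True)
class OscillatorBank:
    """Modal stand-in for one feather's resonant response.

    ``modes`` is a list of ``(f_k, Q_k, modal_gain)``; frequencies must be
    strictly increasing and every mode underdamped (``Q > 0.5``).
    """

    modes: tuple[tuple[float, float, float], ...]
    boundary: Boundary | str = Boundary.CLAMPED_FREE

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundary", Boundary(self.boundary))
        modes = tuple(tuple(float(v) for v in m) for m in self.modes)
        object.__setattr__(self, "modes", modes)
        if not modes:
            raise ValueError("need at least one mode")
        freqs = [m[0] for m in modes]
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise ValueError("mode frequencies must be strictly increasing")
        if any(m[1] <= 0.5 for m in modes):
            raise ValueError("modes must be underdamped (Q > 0.5)")

    def response_ratio(self, f) -> np.ndarray:
        """Total complex-magnitude response ratio at drive frequency f."""
        f = np.asarray(f, dtype=float)
        h = np.zeros(f.shape, dtype=complex)
        for f0, Q, gain in self.modes:
            h += lorentzian_magnitude(f, f0, Q, gain) * np.exp(
                1j * _oscillator_phase(f, f0, Q)
            )
        return np.abs(h)


def gen_swept_sine_pair(
    bank: OscillatorBank,
    sweep: SweepProtocol,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    fps: float = 240.0,
    seed: int = 0,
) -> tuple[TrajectoryTimeSeries, TrajectoryTimeSeries]:
    """Paired shaker-drive and feather-response displacement series.

    The drive is a pure swept sine of the given amplitude (mm).  The
    response is the quasi-steady-state modal superposition of base-driven
    damped-oscillator solutions evaluated at the instantaneous sweep
    frequency (the laboratory protocol swept slowly enough for the shaking
    amplitude to equilibrate, so no transient integration is needed), plus
    additive Gaussian displacement noise on both channels.
    """
    if sweep.f_stop > fps / 2.0:
        raise ValueError("sweep range exceeds the Nyquist frequency of fps")
    rng = np.random.default_rng(seed)
    n = int(round(sweep.duration * fps))
    t = np.arange(n) / fps
    phase = sweep.phase(t)
    f_inst = sweep.instantaneous_frequency(t)
    drive = amplitude * np.sin(phase)
    resp = np.zeros(n)
    for f0, Q, gain in bank.modes:
        mag = amplitude * lorentzian_magnitude(f_inst, f0, Q, gain)
        resp += mag * np.sin(phase + _oscillator_phase(f_inst, f0, Q))
    if noise_sd > 0:
        drive = drive + rng.normal(0.0, noise_sd, n)
        resp = resp + rng.normal(0.0, noise_sd, n)
    return (
        TrajectoryTimeSeries(drive, fps=fps, label="shaker"),
        TrajectoryTimeSeries(resp, fps=fps, label="tip"),
    )


def gen_display_trajectory(
    f_ss: float,
    tau: float,
    amplitude: float = 5.0,
    duration: float = 10.0,
    fps: float = 240.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    envelope: np.ndarray | None = None,
) -> TrajectoryTimeSeries:
    """Display trajectory with an exponential frequency onset.

    The instantaneous vibration frequency follows
    ``f(t) = f_ss * (1 - exp(-t / tau))`` -- initial rise rate ``f_ss/tau``,
    saturating at the steady display frequency ``f_ss``.  The phase is the
    integral of the instantaneous frequency.  ``envelope``, if given, is an
    amplitude modulation resampled onto the trajectory.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if f_ss <= 0 or duration <= 0:
        raise ValueError("f_ss and duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    if tau == 0:
        phase = 2.0 * np.pi * f_ss * t
    else:
        phase = 2.0 * np.pi * f_ss * (t - tau * (1.0 - np.exp(-t / tau)))
    disp = amplitude * np.sin(phase)
    if envelope is not None:
        env = np.interp(t, np.linspace(0, t[-1], len(envelope)), envelope)
        disp = disp * env
    if noise_sd > 0:
        disp = disp + rng.normal(0.0, noise_sd, n)
    return TrajectoryTimeSeries(disp, fps=fps, label="eyespot")


def gen_rattle_audio(
    pulse_rate: float,
    pulse_dur: float = 0.005,
    band: tuple[float, float] = (500.0, 15000.0),
    duration: float = 3.0,
    fs: float = 44100.0,
    amplitude: float = 1.0,
    rms: float = 0.05,
    seed: int = 0,
) -> AudioClip:
    """Train of band-limited broadband noise pulses.

    Pulses repeat at ``pulse_rate`` (so the inter-pulse interval is
    ``1/pulse_rate``), each shaped by a raised-cosine (Hann) envelope of
    width ``pulse_dur`` and filled with Butterworth-bandpassed white noise.
    The clip is normalized to the requested RMS; ``amplitude = 0`` yields a
    silent clip.
    """
    if pulse_rate <= 0:
        raise ValueError("pulse_rate must be positive")
    if pulse_dur >= 1.0 / pulse_rate:
        raise ValueError(
            f"pulse_dur {pulse_dur} s >= inter-pulse interval "
            f"{1.0 / pulse_rate:.4g} s: pulses would overlap"
        )
    if not (0 < band[0] < band[1] < fs / 2.0):
        raise ValueError("band must satisfy 0 < lo < hi < fs/2")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    noise = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfilt(sos, noise)
    env = np.zeros(n)
    width = max(int(round(pulse_dur * fs)), 4)
    pulse_env = np.hanning(width)
    t_pulse = np.arange(0.0, duration, 1.0 / pulse_rate)
    for tp in t_pulse:
        i0 = int(round(tp * fs))
        i1 = min(i0 + width, n)
        env[i0:i1] += pulse_env[: i1 - i0]
    samples = amplitude * carrier * env
    cur_rms = math.sqrt(float(np.mean(samples**2)))
    if cur_rms > 0:
        samples = samples * (rms / cur_rms)
        peak = float(np.max(np.abs(samples)))
        if peak > 0.99:
            samples = samples * (0.99 / peak)
    return AudioClip(samples, fs=fs)


# ---------------------------------------------------------------------------
# Mode-shape envelopes


def gen_mode_envelope(
    boundary: Boundary | str, k: int, n_points: int = 201
) -> np.ndarray:
    """Euler-Bernoulli mode-shape amplitude envelope over ``u in [0, 1]``.

    Returns the signed mode shape (normalized to unit maximum magnitude)
    with exactly ``k - 1`` interior zero crossings for either boundary.  For
    the clamped-hinged tip the displacement is additionally zero at ``u = 1``
    (an endpoint node, not counted as interior).
    """
    boundary = Boundary(boundary)
    if k < 1:
        raise ValueError("mode index k must be >= 1")
    if n_points < 20:
        raise ValueError("need at least 20 points to resolve the envelope")
    u = np.linspace(0.0, 1.0, n_points)
    if boundary is Boundary.CLAMPED_FREE:
        K = beam.characteristic_coefficient(boundary, k)
        sigma = (math.cosh(K) + math.cos(K)) / (math.sinh(K) + math.sin(K))
    else:
        # the envelope indexed by interior node count uses the k-th nonzero
        # root (paper-style mode index k+1: its tip node is at the endpoint)
        K = beam.characteristic_coefficient(boundary, k + 1)
        sigma = (math.cosh(K) - math.cos(K)) / (math.sinh(K) - math.sin(K))
    phi = (
        np.cosh(K * u)
        - np.cos(K * u)
        - sigma * (np.sinh(K * u) - np.sin(K * u))
    )
    return phi / np.max(np.abs(phi))
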
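"""Vibration kinematics from tracked display trajectories.

High-speed (240 fps) video of displaying birds yields displacement time
series for tracked feather points.  This module estimates vibration
frequencies (by frame counting over 10 cycles, cross-checked by Fourier
analysis), fits the exponential frequency onset at the start of a display
bout, identifies normal modes by counting stationary nodes, and converts
eyespot motion to the visual angle subtended at a watching bird.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import TrajectoryTimeSeries

__all__ = [
    "frequency_by_cycle_count",
    "frequency_by_fft",
    "instantaneous_frequency",
    "fit_onset",
    "OnsetFit",
    "identify_normal_mode",
    "displacement_to_mm",
    "visual_angle",
    "predict_frequency_effect",
    "sample_bout_intervals",
    "BoutWindows",
]

EYESPOT_DIAMETER_MM = 40.5  # mean diameter of the bronze eyespot region


def _upward_crossings(x: np.ndarray) -> np.ndarray:
    """Frame indices of positive-going zero crossings of the mean-subtracted
    signal (the first frame at or above zero)."""
    y = x - np.mean(x)
    s = y >= 0
    return np.nonzero(~s[:-1] & s[1:])[0] + 1


def frequency_by_cycle_count(
    traj: TrajectoryTimeSeries, n_cycles: int = 10, start: int = 0
) -> float:
    """Vibration frequency from counting frames over ``n_cycles`` cycles.

    Cycles are delimited by successive positive-going zero crossings of the
    mean-subtracted displacement; ``f = fps * n_cycles / frames spanned``
    with the span read to the nearest whole frame.  The estimate is
    quantized at the frame level: a true frequency is recovered within one
    frame-count step ``fps*n/m - fps*n/(m+1)``.
    """
    y = traj.displacement - np.mean(traj.displacement)
    crossings = _upward_crossings(traj.displacement)
    if crossings.size < start + n_cycles + 1:
        raise ValueError(
            f"trajectory has {max(crossings.size - 1, 0)} full cycles; "
            f"need {start + n_cycles}"
        )

    def _subframe(i: int) -> float:
        # i is the first frame at/above zero; place the crossing between
        # frames i-1 and i by linear interpolation
        y0, y1 = y[i - 1], y[i]
        return i - 1 + (0.0 - y0) / (y1 - y0) if y1 != y0 else float(i)

    span = _subframe(int(crossings[start + n_cycles])) - _subframe(
        int(crossings[start])
    )
    frames = max(int(round(span)), 1)
    return traj.fps * n_cycles / float(frames)


def frequency_by_fft(
    traj: TrajectoryTimeSeries, harmonic_threshold: float = 0.2
) -> tuple[float, bool]:
    """Dominant frequency by Fourier analysis, plus a higher-harmonic flag.

    Returns the frequency of maximum spectral magnitude (zero-padded grid)
    and ``True`` if any harmonic ``2f, 3f, ...`` carries more than
    ``harmonic_threshold`` of the fundamental's magnitude.
    """
    if traj.duration < 1.0:
        raise ValueError("need at least 1 s of data for Fourier analysis")
    y = traj.displacement - np.mean(traj.displacement)
    if np.allclose(y, 0.0):
        raise ValueError("DC-only signal has no vibration frequency")
    n = y.size
    nfft = int(2 ** math.ceil(math.log2(n * 4)))
    mag = np.abs(np.fft.rfft(y * np.hanning(n), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / traj.fps)
    i0 = int(np.argmax(mag))
    f0 = float(freqs[i0])
    fund = mag[i0]
    flag = False
    df = freqs[1]
    for h in range(2, 6):
        fh = h * f0
        if fh >= traj.fps / 2.0:
            break
        j = int(round(fh / df))
        lo, hi = max(j - 2, 0), min(j + 3, mag.size)
        if np.max(mag[lo:hi]) > harmonic_threshold * fund:
            flag = True
            break
    return f0, flag


def instantaneous_frequency(
    traj: TrajectoryTimeSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle-by-cycle frequency from successive zero-crossing intervals.

    Returns ``(t, f)`` where each frequency is the reciprocal of the
    interval between consecutive positive-going zero crossings, timestamped
    at the interval midpoint.
    """
    crossings = _upward_crossings(traj.displacement)
    if crossings.size < 3:
        raise ValueError("too few cycles for an instantaneous-frequency series")
    t_cross = traj.t0 + crossings / traj.fps
    dt = np.diff(t_cross)
    return 0.5 * (t_cross[:-1] + t_cross[1:]), 1.0 / dt


@dataclass(frozen=True)
class OnsetFit:
    """Saturating-exponential onset of the display vibration frequency.

    ``f(t) = f_ss * (1 - exp(-t/tau))``; the initial rise rate is
    ``f_ss / tau`` and the frequency settles at ``f_ss``.
    """

    f_ss: float
    tau: float
    f_ss_ci: tuple[float, float]
    tau_ci: tuple[float, float]
    rmse: float
    n: int

    @property
    def initial_rate(self) -> float:
        return self.f_ss / self.tau

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f_ss * (1.0 - np.exp(-t / self.tau))


def _onset_model(t, f_ss, tau):
    return f_ss * (1.0 - np.exp(-t / np.maximum(tau, 1e-12)))


def fit_onset(t, freq) -> OnsetFit:
    """Least-squares fit of the exponential frequency-onset model.

    ``t`` and ``freq`` are the instantaneous-frequency series from the
    start of a display bout (``t = 0`` at onset).  The series should span a
    few time constants so the plateau constrains ``f_ss``.
    """
    t = np.asarray(t, dtype=float)
    freq = np.asarray(freq, dtype=float)
    if t.size != freq.size or t.size < 4:
        raise ValueError("need matching t/freq series with >= 4 points")
    f_ss0 = float(np.max(freq))
    if f_ss0 <= 0:
        raise ValueError("frequencies must be positive")
    # crude tau guess: time to reach 63% of the plateau
    above = np.nonzero(freq >= 0.632 * f_ss0)[0]
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else max(
        float(t[-1]) / 5.0, 1e-3
    )
    if np.ptp(freq) < 1e-6 * f_ss0:
        raise ValueError(
            "frequency series is constant: onset already complete (tau -> 0)"
        )
    try:
        popt, pcov = optimize.curve_fit(
            _onset_model, t, freq, p0=[f_ss0, tau0],
            bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as err:
        resid = freq - _onset_model(t, f_ss0, tau0)
        raise RuntimeError(
            f"onset fit did not converge (initial-guess residual rms "
            f"{np.sqrt(np.mean(resid**2)):.3g} Hz)"
        ) from err
    f_ss, tau = (float(v) for v in popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rmse = float(np.sqrt(np.mean((freq - _onset_model(t, *popt)) ** 2)))
    return OnsetFit(
        f_ss=f_ss,
        tau=tau,
        f_ss_ci=(f_ss - 1.96 * se[0], f_ss + 1.96 * se[0]),
        tau_ci=(tau - 1.96 * se[1], tau + 1.96 * se[1]),
        rmse=rmse,
        n=int(t.size),
    )


def identify_normal_mode(
    envelope: np.ndarray, noise_tol: float = 0.02
) -> tuple[int, float]:
    """Normal-mode index from the spatial amplitude envelope.

    ``k = 1 +`` the number of interior sign changes (stationary nodes) of
    the signed envelope over relative position ``u``; endpoints are
    excluded, so a node pinned exactly at the tip is not counted.  Returns
    ``(k, confidence)`` where confidence is the fraction of samples whose
    magnitude clears ``noise_tol`` of the envelope maximum (a noisy envelope
    hovering near zero yields low confidence).
    """
    env = np.asarray(envelope, dtype=float)
    if env.size < 20:
        raise ValueError("envelope must be sampled at >= 20 points")
    scale = float(np.max(np.abs(env)))
    if scale == 0:
        raise ValueError("flat envelope")
    interior = env[1:-1] / scale
    signs = np.sign(np.where(np.abs(interior) < noise_tol, 0.0, interior))
    nz = signs[signs != 0]
    changes = int(np.count_nonzero(np.diff(nz) != 0)) if nz.size else 0
    confidence = float(nz.size / interior.size)
    return changes + 1, confidence


def displacement_to_mm(
    pixel_displacement, eyespot_px: float, eyespot_mm: float = EYESPOT_DIAMETER_MM
):
    """Convert tracked pixel displacement to mm using the eyespot for scale."""
    if eyespot_px <= 0:
        raise ValueError("eyespot pixel diameter must be positive")
    return np.asarray(pixel_displacement, dtype=float) * (eyespot_mm / eyespot_px)


def visual_angle(displacement_mm: float, distance_m: float) -> float:
    """Visual angle (degrees) subtended by a lateral displacement.

    ``arctan(displacement / distance)``; at display geometry (mm of motion
    viewed from ~1 m) this is deep in the small-angle regime, where 1.7 mm
    at 1 m is ~0.1 degrees -- the acuity limit of the watching bird.
    """
    if displacement_mm <= 0 or distance_m <= 0:
        raise ValueError("displacement and distance must be positive")
    return math.degrees(math.atan(displacement_mm / (1000.0 * distance_m)))


def predict_frequency_effect(
    slope_hz_per_cm: float,
    length_range_cm: float,
    slope_ci: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Predicted frequency change over a train-length range.

    Multiplies a fitted slope (Hz/cm of train length) by the observed range
    of train lengths; the CI, if supplied, is propagated linearly (which
    ignores the fitted model's covariance and is therefore slightly wider
    or narrower than a model-based interval).
    """
    effect = slope_hz_per_cm * length_range_cm
    ci = None
    if slope_ci is not None:
        lo, hi = sorted((slope_ci[0] * length_range_cm, slope_ci[1] * length_range_cm))
        ci = (lo, hi)
    return effect, ci


@dataclass(frozen=True)
class BoutWindows:
    """Three 10-cycle sampling windows of a display bout (frame slices)."""

    peak: slice
    pre: slice | None
    post: slice | None
    flagged_short: bool


def _moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    kernel = np.ones(n) / n
    return np.sqrt(np.convolve(x**2, kernel, mode="same"))


def sample_bout_intervals(
    traj: TrajectoryTimeSeries, n_cycles: int = 10, rms_window_s: float = 0.25
) -> BoutWindows:
    """Select peak-, pre- and post-peak 10-cycle windows from a bout.

    The peak window is centered on the maximum of the moving-RMS amplitude
    envelope (ties broken toward the earliest frame); the pre and post
    windows are the ``n_cycles`` immediately before and after it.  Bouts
    shorter than ``3 * n_cycles`` cycles yield only the peak window, with
    ``flagged_short`` set.
    """
    crossings = _upward_crossings(traj.displacement)
    total_cycles = crossings.size - 1
    if total_cycles < n_cycles:
        raise ValueError(f"bout has {total_cycles} cycles; need >= {n_cycles}")
    env = _moving_rms(
        traj.displacement - np.mean(traj.displacement),
        max(int(round(rms_window_s * traj.fps)), 1),
    )
    i_env = int(np.argmax(env))  # argmax returns the earliest tie
    # cycle whose interval contains (or is nearest) the envelope peak
    c_peak = int(np.clip(np.searchsorted(crossings, i_env) - 1, 0, total_cycles - 1))
    half = n_cycles // 2
    c0 = int(np.clip(c_peak - half, 0, total_cycles - n_cycles))
    peak = slice(int(crossings[c0]), int(crossings[c0 + n_cycles]))
    if total_cycles < 3 * n_cycles:
        return BoutWindows(peak=peak, pre=None, post=None, flagged_short=True)
    # shift the peak window inward if needed so both neighbors fit
    c0 = int(np.clip(c0, n_cycles, total_cycles - 2 * n_cycles))
    peak = slice(int(crossings[c0]), int(crossings[c0 + n_cycles]))
    pre = slice(int(crossings[c0 - n_cycles]), int(crossings[c0]))
    post = slice(int(crossings[c0 + n_cycles]), int(crossings[c0 + 2 * n_cycles]))
    return BoutWindows(peak=peak, pre=pre, post=post, flagged_short=False)
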
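"""Transfer functions and resonant-peak analysis of shaking experiments.

A feather mounted on a shaker is driven by a slow swept sine while both the
shaker head and a point on the feather are tracked on high-speed video.
Short-time Fourier magnitudes of the two displacement series, evaluated at
the instantaneous drive frequency, give the drive transfer function
``A/A_d``.  Each resonant peak is fitted with the driven-damped-oscillator
(Lorentzian) magnitude

    |H(f)| = A0 / sqrt((1 - (f/f0)^2)^2 + (f/(f0 Q))^2)

yielding the resonant frequency ``f_k`` and quality factor ``Q_k``; the 3 dB
peak width follows Eq.-of-motion bookkeeping ``delta_f_3dB = f_k / Q_k``
(drive power falls to half peak at that full width).  Good resonators with
weak damping have ``Q > 2 pi``; strong damping spans ``1/2 < Q < 2 pi``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import optimize, signal

from .datatypes import ModePeak, SweepProtocol, TrajectoryTimeSeries, TransferFunction
from .synthetic import lorentzian_magnitude

__all__ = [
    "compute_transfer_function",
    "smooth_transfer",
    "fit_lorentzian_peaks",
    "width_direct",
    "q_from_width",
    "damped_peak_shift",
    "average_transfer_functions",
    "check_reproducibility",
]

# Drive bins whose magnitude falls below this multiple of the broadband
# noise floor are flagged invalid (video discretization noise dominated the
# shaker amplitude above roughly 40-60 Hz in the original recordings).
NOISE_FLOOR_FACTOR = 3.0


def _stft_magnitude_at(
    x: np.ndarray,
    fs: float,
    frame_centers: np.ndarray,
    freqs: np.ndarray,
    win_n: np.ndarray,
) -> np.ndarray:
    """Hann-windowed single-frequency DFT magnitude per frame.

    Evaluating the short-time transform exactly at the instantaneous drive
    frequency avoids bin-interpolation scalloping; because both channels are
    evaluated with the same window at the same frequency, window attenuation
    cancels in the ratio.  ``win_n`` may vary per frame (short windows for
    fast sweeps, long ones to resolve low frequencies).
    """
    out = np.empty(frame_centers.size)
    for i in range(frame_centers.size):
        n = int(win_n[i])
        w = np.hanning(n)
        c = int(round(frame_centers[i] * fs))
        i0 = max(c - n // 2, 0)
        i1 = min(i0 + n, x.size)
        i0 = max(i1 - n, 0)
        seg = x[i0:i1] * w[: i1 - i0]
        ph = 2.0 * np.pi * freqs[i] * np.arange(i1 - i0) / fs
        out[i] = abs(np.dot(seg, np.exp(-1j * ph))) * 2.0 / np.sum(w)
    return out


def _adaptive_window_samples(
    freqs: np.ndarray, fs: float, rate: float, n_total: int
) -> np.ndarray:
    """Per-frame Hann window lengths (samples) for a swept drive.

    Aim for about 1.5 cycles of the local drive frequency (floor 0.2 s),
    then round so the window spans an integer number of half-cycles
    (``2 f T`` integer): that places the negative-frequency image of the
    tone on a null of the Hann transform, so short windows remain accurate.
    Long windows are avoided because the sweep moving ``rate * T`` Hz within
    a window smears narrow resonant peaks.
    """
    base = np.maximum(1.5 / np.maximum(freqs, 0.25), 0.2)
    k = np.ceil(2.0 * freqs * base)
    dur = np.where(freqs > 0.25, k / (2.0 * freqs), base)
    n = np.minimum(np.round(dur * fs).astype(int), n_total)
    return np.maximum(n, 8)


def _noise_floor(
    x: np.ndarray,
    fs: float,
    centers: np.ndarray,
    freqs: np.ndarray,
    win_n: np.ndarray,
) -> np.ndarray:
    """Per-frame broadband noise magnitude in windowed-DFT units.

    Probes each frame a few Hann-transform nulls away from the drive line,
    where leakage of the swept tone vanishes and only noise remains.
    """
    offsets = 6.0 * fs / win_n  # 6 null spacings of each frame's window
    probe = _stft_magnitude_at(x, fs, centers, freqs + offsets, win_n)
    # a rolling-median would track slowly varying noise; the generators use
    # stationary noise, so a global median is robust and simple
    return np.full(centers.size, float(np.median(probe)))


def compute_transfer_function(
    drive: TrajectoryTimeSeries,
    response: TrajectoryTimeSeries,
    sweep: SweepProtocol,
    window_dur: float | None = None,
    hop_dur: float = 0.125,
) -> TransferFunction:
    """Drive transfer function ``A/A_d`` over the swept frequency band.

    Parameters
    ----------
    drive, response : TrajectoryTimeSeries
        Paired shaker-head and feather displacement series with identical
        sampling.
    sweep : SweepProtocol
        Describes the drive's instantaneous frequency over time.
    window_dur : float, optional
        Fixed short-time window length (s).  By default the window adapts
        per frame, balancing two errors: it must span enough drive cycles
        (spectral resolution) while the sweep must not move far compared to
        the narrowest resonant peak within one window (envelope smearing).
    hop_dur : float
        Frame spacing (s); sets the density of the frequency grid.

    Bins where the measured drive magnitude falls below
    ``NOISE_FLOOR_FACTOR`` times the broadband noise floor are flagged
    invalid rather than silently divided.
    """
    if drive.fps != response.fps or len(drive) != len(response):
        raise ValueError("drive and response must share sampling and length")
    fs = drive.fps
    t_end = len(drive) / fs
    margin = window_dur / 2.0 if window_dur is not None else 0.1
    centers = np.arange(margin, t_end - margin, hop_dur)
    if centers.size < 8:
        raise ValueError("recording too short for a transfer function")
    f_d = sweep.instantaneous_frequency(centers)
    if window_dur is None:
        win_n = _adaptive_window_samples(f_d, fs, sweep.rate, len(drive))
    else:
        n = int(round(window_dur * fs))
        if n < 8:
            raise ValueError("window too short for the sampling rate")
        if n > len(drive):
            raise ValueError("window longer than the recording")
        win_n = np.full(centers.size, n)
    mag_d = _stft_magnitude_at(drive.displacement, fs, centers, f_d, win_n)
    mag_r = _stft_magnitude_at(response.displacement, fs, centers, f_d, win_n)
    floor = _noise_floor(drive.displacement, fs, centers, f_d, win_n)
    valid = mag_d > NOISE_FLOOR_FACTOR * floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mag_d > 0, mag_r / np.maximum(mag_d, 1e-300), 0.0)
    return TransferFunction(f_d=f_d, ratio=ratio, valid=valid)


def smooth_transfer(
    tf: TransferFunction, window_hz: float = 1.3, poly_order: int = 3
) -> TransferFunction:
    """Savitzky-Golay smoothing of the transfer function on its grid.

    The window is converted to the nearest odd number of grid points; a
    polynomial of degree <= ``poly_order`` on the grid passes through
    unchanged.
    """
    df = float(np.median(np.diff(tf.f_d)))
    n = int(round(window_hz / df))
    if n % 2 == 0:
        n += 1
    if n < poly_order + 2:
        raise ValueError(
            f"grid spacing {df:.3g} Hz too coarse for a {window_hz} Hz window "
            f"with poly_order={poly_order}; need spacing <= "
            f"{window_hz / (poly_order + 2):.3g} Hz"
        )
    n = min(n, tf.f_d.size if tf.f_d.size % 2 == 1 else tf.f_d.size - 1)
    sm = signal.savgol_filter(tf.ratio, n, poly_order)
    return TransferFunction(
        tf.f_d, tf.ratio, valid=tf.valid, smoothed=np.clip(sm, 0.0, None),
        normalization=tf.normalization,
    )


# ---------------------------------------------------------------------------
# Peak fitting


def _peak_window(y: np.ndarray, i_peak: float, bounds: tuple[int, int]) -> slice:
    """Indices around a peak down to 25% of its height (or the bounds)."""
    i_peak = int(i_peak)
    lo, hi = bounds
    thresh = 0.25 * y[i_peak]
    i0 = i_peak
    while i0 > lo and y[i0] > thresh:
        i0 -= 1
    i1 = i_peak
    while i1 < hi - 1 and y[i1] > thresh:
        i1 += 1
    return slice(i0, i1 + 1)


def fit_lorentzian_peaks(
    tf: TransferFunction,
    max_modes: int = 6,
    prominence_frac: float = 0.05,
    min_separation_hz: float = 1.0,
    use_smoothed: bool = False,
) -> list[ModePeak]:
    """Detect and fit resonant peaks; returns them sorted by frequency.

    Local maxima with prominence >= ``prominence_frac`` of the global
    maximum and minimum separation ``min_separation_hz`` are each fitted by
    nonlinear least squares with the driven-oscillator magnitude model over
    a window around the peak.  Mode indices ``k`` are assigned in ascending
    frequency order (ties broken by amplitude).  If a fit fails to converge
    the peak is still reported, with the width measured directly from the
    spectrum and ``fit_rmse`` set to NaN.
    """
    y = (tf.smoothed if (use_smoothed and tf.smoothed is not None) else tf.ratio).copy()
    f = tf.f_d
    y[~tf.valid] = 0.0
    ymax = float(np.max(y))
    if ymax <= 0:
        return []
    df = float(np.median(np.diff(f)))
    distance = max(int(round(min_separation_hz / df)), 1)
    idx, props = signal.find_peaks(
        y, prominence=prominence_frac * ymax, distance=distance
    )
    if idx.size == 0:
        return []
    # keep the most prominent max_modes, then order by frequency
    order = np.argsort(props["prominences"])[::-1][:max_modes]
    idx = np.sort(idx[order])

    peaks: list[ModePeak] = []
    bounds_edges = np.concatenate(([0], (idx[:-1] + idx[1:]) // 2, [f.size]))
    for j, ip in enumerate(idx):
        win = _peak_window(y, ip, (int(bounds_edges[j]), int(bounds_edges[j + 1])))
        fw, yw = f[win], y[win]
        f0_guess = float(f[ip])
        amp_guess = float(y[ip])
        try:
            dfw = width_direct(tf, f0_guess, use_smoothed=use_smoothed)
            q_guess = max(f0_guess / dfw, 0.6)
        except ValueError:
            q_guess = 5.0
        try:
            popt, _ = optimize.curve_fit(
                lorentzian_magnitude,
                fw,
                yw,
                p0=[f0_guess, q_guess, amp_guess / q_guess],
                bounds=([fw[0], 0.51, 0.0], [fw[-1], 1e4, np.inf]),
                maxfev=10000,
            )
            f0, Q, gain = (float(v) for v in popt)
            rmse = float(np.sqrt(np.mean((lorentzian_magnitude(fw, *popt) - yw) ** 2)))
            peaks.append(
                ModePeak(
                    k=0, f_k=f0, delta_f_3dB=f0 / Q, Q_k=Q,
                    amplitude=gain * Q, fit_rmse=rmse, fit_converged=True,
                )
            )
        except RuntimeError:
            width = width_direct(tf, f0_guess, use_smoothed=use_smoothed)
            peaks.append(
                ModePeak(
                    k=0, f_k=f0_guess, delta_f_3dB=width,
                    Q_k=f0_guess / width, amplitude=amp_guess,
                    fit_rmse=float("nan"), fit_converged=False,
                )
            )
    peaks.sort(key=lambda p: (p.f_k, -p.amplitude))
    return [
        ModePeak(
            k=i + 1, f_k=p.f_k, delta_f_3dB=p.delta_f_3dB, Q_k=p.Q_k,
            amplitude=p.amplitude, fit_rmse=p.fit_rmse, fit_converged=p.fit_converged,
        )
        for i, p in enumerate(peaks)
    ]


def width_direct(
    tf: TransferFunction, peak_freq: float, use_smoothed: bool = False
) -> float:
    """3 dB full width measured directly from the spectrum.

    Width between the two frequencies around ``peak_freq`` where the power
    falls to half the peak value (amplitude to ``1/sqrt(2)``), by linear
    interpolation.  Used for peaks not well approximated by a Lorentzian.
    If the half-power level is not reached on one side within the grid, the
    one-sided width is doubled and a warning is issued.
    """
    y = tf.smoothed if (use_smoothed and tf.smoothed is not None) else tf.ratio
    f = tf.f_d
    ip = int(np.argmin(np.abs(f - peak_freq)))
    # climb to the local maximum in case peak_freq sits on a shoulder
    while 0 < ip < f.size - 1:
        if y[ip + 1] > y[ip]:
            ip += 1
        elif y[ip - 1] > y[ip]:
            ip -= 1
        else:
            break
    peak = y[ip]
    if peak <= 0:
        raise ValueError("no peak amplitude at the requested frequency")
    target = peak / math.sqrt(2.0)

    def _cross(direction: int) -> float | None:
        i = ip
        while 0 < i + direction < f.size:
            j = i + direction
            if y[j] <= target:
                # linear interpolation between i and j
                frac = (y[i] - target) / (y[i] - y[j])
                return float(f[i] + frac * (f[j] - f[i]))
            i = j
        return None

    left = _cross(-1)
    right = _cross(+1)
    if left is None and right is None:
        raise ValueError("half-power level not reached on either side (flat spectrum?)")
    if left is None or right is None:
        warnings.warn(
            "half-power level reached on one side only; doubling the one-sided width",
            stacklevel=2,
        )
        side = right - f[ip] if left is None else f[ip] - left
        return 2.0 * float(side)
    return float(right - left)


def q_from_width(f_k: float, delta_f_3dB: float) -> float:
    """Quality factor ``Q_k = f_k / delta_f_3dB``.

    2 pi times the energy stored per cycle over the energy dissipated per
    cycle, expressed through the resonant frequency and 3 dB peak width.
    """
    if f_k <= 0:
        raise ValueError("f_k must be positive")
    if delta_f_3dB <= 0:
        raise ValueError("delta_f_3dB must be positive")
    return f_k / delta_f_3dB


def damped_peak_shift(Q: float) -> float:
    """Fractional shift of the response peak below the natural frequency.

    ``1 - sqrt(1 - 1/(2 Q^2))``: the relative difference between the
    undamped natural frequency and the frequency of maximum base-driven
    response.  Requires ``Q > 1/sqrt(2)``; at lower Q the response has no
    peak at all.
    """
    if Q <= 1.0 / math.sqrt(2.0):
        raise ValueError("no resonant peak exists for Q <= 1/sqrt(2)")
    return 1.0 - math.sqrt(1.0 - 1.0 / (2.0 * Q**2))


# ---------------------------------------------------------------------------
# Array spectra and reproducibility


def average_transfer_functions(tfs: list[TransferFunction]) -> TransferFunction:
    """Pointwise mean of transfer functions on a common grid.

    Spectra are interpolated onto the first grid.  Averaging responses of
    several nearby-frequency resonators produces a wider compound peak with
    lower effective Q than any single contributor.
    """
    if not tfs:
        raise ValueError("need at least one transfer function")
    base = tfs[0]
    acc = np.zeros(base.f_d.size)
    valid = np.ones(base.f_d.size, dtype=bool)
    for tf in tfs:
        acc += np.interp(base.f_d, tf.f_d, tf.ratio)
        valid &= np.interp(base.f_d, tf.f_d, tf.valid.astype(float)) > 0.5
    return TransferFunction(base.f_d, acc / len(tfs), valid=valid)


def check_reproducibility(
    tfs: list[TransferFunction], f_max: float = 40.0, rtol: float = 0.2
) -> bool:
    """Agreement check across repeated sweeps started from rest.

    True if, below ``f_max`` (the band where video tracking is reliable),
    every normalized spectrum agrees with the pointwise mean within
    ``rtol`` relative deviation at the peak scale.
    """
    if len(tfs) < 2:
        raise ValueError("need at least two repeats")
    norm = [tf.normalized() for tf in tfs]
    base = norm[0]
    mask = (base.f_d <= f_max) & base.valid
    stack = np.vstack([np.interp(base.f_d, tf.f_d, tf.ratio) for tf in norm])
    mean = stack.mean(axis=0)
    dev = np.max(np.abs(stack[:, mask] - mean[mask]), axis=1)
    return bool(np.all(dev <= rtol * np.max(mean[mask])))
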
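"""Shared data containers for the feather-vibration pipeline.

Conventions
-----------
* Positions ``x`` are distances (m) from the feather's insertion point into
  the skin; the calamus is excluded, so the vibrating cantilever spans
  ``x in [0, L_R]`` with ``u = x / L_R`` the relative position.
* All quantities are SI internally; file formats declare units in column
  names (``time_s``, ``displacement_mm`` ...), and readers/writers convert.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Boundary(str, enum.Enum):
    """Tip boundary condition of the cantilevered rachis.

    ``CLAMPED_FREE`` is the classical cantilever (base clamped, tip free);
    ``CLAMPED_HINGED`` pins the tip, which models a vibration node sitting
    just below a heavy tip ornament such as the eyespot.
    """

    CLAMPED_FREE = "clamped_free"
    CLAMPED_HINGED = "clamped_hinged"


class FeatherClass(str, enum.Enum):
    EYESPOT = "eyespot"
    RECTRIX = "rectrix"
    COVERT = "covert"


@dataclass(frozen=True)
class RachisProfile:
    """Per-segment morphometrics of a single feather.

    Attributes
    ----------
    x : ndarray
        Segment start positions from the insertion point (m), strictly
        increasing.
    dx : ndarray
        Segment lengths (m).
    D1 : ndarray
        Rachis outer diameter in the lateral plane (m).
    D2 : ndarray or None
        Rachis outer diameter in the dorsoventral plane (m); ``None`` means
        a circular cross-section (``D2 == D1``).
    mu_R : ndarray
        Linear density of the bare rachis (kg/m).
    mu_F : ndarray
        Linear density of the whole feather, rachis plus barbs (kg/m).
    mu_E : float or None
        Linear density of the tip ornament (eyespot) region (kg/m), if any.
    L_R : float
        Rachis length outside the body (m); the effective cantilever length.
    M_E : float
        Mass of the tip ornament (kg); 0 for plain feathers.
    feather_class : FeatherClass
    """

    x: np.ndarray
    dx: np.ndarray
    D1: np.ndarray
    mu_R: np.ndarray
    mu_F: np.ndarray
    L_R: float
    M_E: float = 0.0
    D2: np.ndarray | None = None
    mu_E: float | None = None
    feather_class: FeatherClass = FeatherClass.EYESPOT

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        dx = np.asarray(self.dx, dtype=float)
        for name in ("x", "dx", "D1", "mu_R", "mu_F"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.D2 is not None:
            object.__setattr__(self, "D2", np.asarray(self.D2, dtype=float))
        n = x.size
        if not all(getattr(self, name).size == n for name in ("dx", "D1", "mu_R", "mu_F")):
            raise ValueError("profile arrays must share one length")
        if n < 2:
            raise ValueError("profile needs at least 2 segments")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.L_R <= 0:
            raise ValueError("L_R must be positive")
        if np.any(self.D1 <= 0) or (self.D2 is not None and np.any(self.D2 <= 0)):
            raise ValueError("diameters must be strictly positive")
        if np.any(self.mu_R < 0) or np.any(self.mu_F < self.mu_R):
            raise ValueError("require mu_F >= mu_R >= 0 elementwise")
        if self.M_E < 0:
            raise ValueError("M_E must be non-negative")
        if not np.isclose(x[-1] + dx[-1], self.L_R, rtol=1e-6, atol=1e-9):
            raise ValueError("segments must tile [0, L_R]: max(x)+last dx != L_R")

    @property
    def u(self) -> np.ndarray:
        """Relative position of segment starts, ``x / L_R``."""
        return self.x / self.L_R

    @property
    def M_F(self) -> float:
        """Mass of the feather excluding the tip ornament (kg)."""
        return float(np.sum(self.mu_F * self.dx))

    @property
    def D_avg(self) -> float:
        """Length-weighted mean lateral diameter (m)."""
        return float(np.sum(self.D1 * self.dx) / np.sum(self.dx))


@dataclass(frozen=True)
class TrajectoryTimeSeries:
    """Uniformly sampled lateral displacement of one tracked point.

    ``displacement`` is in mm (the working unit of the video tracking),
    sampled at ``fps`` frames per second starting at ``t0``.
    """

    displacement: np.ndarray
    fps: float = 240.0
    t0: float = 0.0
    label: str = "tip"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "displacement", np.asarray(self.displacement, dtype=float)
        )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.displacement.size) / self.fps

    @property
    def duration(self) -> float:
        return self.displacement.size / self.fps

    def __len__(self) -> int:
        return self.displacement.size


@dataclass(frozen=True)
class AudioClip:
    """Mono audio samples as float in [-1, 1]."""

    samples: np.ndarray
    fs: float = 44100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class SweepProtocol:
    """Linear frequency sweep of the shaker drive.

    ``f(t) = f_start + rate * t`` for ``t`` in ``[0, (f_stop-f_start)/rate]``.
    """

    f_start: float
    f_stop: float
    rate: float  # Hz/s

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sweep rate must be positive")
        if self.f_stop <= self.f_start:
            raise ValueError("f_stop must exceed f_start")
        if self.f_start < 0:
            raise ValueError("f_start must be non-negative")

    @property
    def duration(self) -> float:
        return (self.f_stop - self.f_start) / self.rate

    def instantaneous_frequency(self, t: np.ndarray) -> np.ndarray:
        return self.f_start + self.rate * np.asarray(t, dtype=float)

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Phase (rad) as the integral of the instantaneous frequency."""
        t = np.asarray(t, dtype=float)
        return 2.0 * np.pi * (self.f_start * t + 0.5 * self.rate * t**2)


# Sweep presets used in the laboratory shaking protocol: slow enough at each
# band for the shaking amplitude to equilibrate before the frequency moves on.
SWEEP_PRESETS: dict[str, SweepProtocol] = {
    "low": SweepProtocol(0.5, 3.0, 0.042),
    "mid": SweepProtocol(1e-9, 15.0, 0.25),  # nominal 0-15 Hz
    "high": SweepProtocol(10.0, 120.0, 1.8),
}


@dataclass(frozen=True)
class TransferFunction:
    """Feather-to-drive Fourier magnitude ratio on a drive-frequency grid.

    ``valid`` flags bins where the drive magnitude was safely above the
    noise floor; ratios at invalid bins are retained but untrustworthy
    (video-tracking discretization noise dominates at high frequency).
    """

    f_d: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    normalization: str = "raw"  # or "unit_max"

    def __post_init__(self) -> None:
        f = np.asarray(self.f_d, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "f_d", f)
        object.__setattr__(self, "ratio", r)
        if f.size != r.size:
            raise ValueError("f_d and ratio must share one length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("magnitude ratio must be non-negative")
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(f.size, dtype=bool))
        else:
            object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        if self.smoothed is not None:
            object.__setattr__(self, "smoothed", np.asarray(self.smoothed, dtype=float))

    @property
    def best(self) -> np.ndarray:
        """Smoothed ratio if available, else the raw ratio."""
        return self.ratio if self.smoothed is None else self.smoothed

    def normalized(self) -> "TransferFunction":
        """Rescale so the maximum (valid) ratio is 1; preserves peak shape."""
        peak = float(np.max(self.ratio[self.valid]))
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero transfer function")
        return TransferFunction(
            self.f_d,
            self.ratio / peak,
            valid=self.valid,
            smoothed=None if self.smoothed is None else self.smoothed / peak,
            normalization="unit_max",
        )


@dataclass(frozen=True)
class ModePeak:
    """One resonant peak of a transfer function.

    ``Q_k = f_k / delta_f_3dB`` (resonant frequency over full width where
    drive power falls to half, i.e. amplitude to 1/sqrt(2)).
    """

    k: int
    f_k: float
    delta_f_3dB: float
    Q_k: float
    amplitude: float
    fit_rmse: float = float("nan")
    fit_converged: bool = True

    def __post_init__(self) -> None:
        if self.delta_f_3dB <= 0:
            raise ValueError("delta_f_3dB must be positive")


@dataclass(frozen=True)
class BucklingAssessment:
    """Critical-stress profiles for global (Euler) and local shell buckling."""

    x: np.ndarray
    sigma_euler: np.ndarray
    sigma_local: np.ndarray
    min_margin_location: float
    euler_governs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "sigma_euler", np.asarray(self.sigma_euler, dtype=float))
        object.__setattr__(self, "sigma_local", np.asarray(self.sigma_local, dtype=float))
        if np.any(self.sigma_euler <= 0) or np.any(self.sigma_local <= 0):
            raise ValueError("critical stresses must be positive")
        if self.euler_governs is None:
            object.__setattr__(
                self, "euler_governs", self.sigma_euler < self.sigma_local
            )
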
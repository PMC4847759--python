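"""Model/Results interfaces for the fitted analyses.

Each class pairs a ``Model`` built from data with a ``fit()`` returning a
``Results`` object that carries estimates, uncertainties and diagnostics
and prints a ``summary()`` table -- the idiom used by statistical modelling
packages.  They wrap the procedural routines in :mod:`trainrattle.spectral`,
:mod:`trainrattle.kinematics` and :mod:`trainrattle.beam`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinematics, spectral
from .beam import ScalingFit, fit_length_scaling
from .datatypes import ModePeak, SweepProtocol, TrajectoryTimeSeries, TransferFunction
from .kinematics import OnsetFit

__all__ = [
    "FeatherResonanceModel",
    "FeatherResonanceResults",
    "OnsetModel",
    "OnsetResults",
    "PowerLawScalingModel",
    "PowerLawScalingResults",
]


def _rule(title: str, width: int = 64) -> str:
    pad = max(width - len(title) - 2, 0)
    return f"{'=' * (pad // 2)} {title} {'=' * (pad - pad // 2)}"


class FeatherResonanceModel:
    """Resonant response of one feather from a laboratory shaking sweep.

    Built from paired shaker-drive and feather-response displacement series
    plus the sweep protocol; ``fit()`` computes the drive transfer function,
    optionally smooths it, and fits each resonant peak with the
    driven-oscillator Lorentzian to estimate ``f_k`` and ``Q_k``.
    """

    def __init__(
        self,
        drive: TrajectoryTimeSeries,
        response: TrajectoryTimeSeries,
        sweep: SweepProtocol,
        feather_id: str = "feather",
    ) -> None:
        self.drive = drive
        self.response = response
        self.sweep = sweep
        self.feather_id = feather_id

    @classmethod
    def from_csv(
        cls, drive_path, response_path, sweep: SweepProtocol, **kwargs
    ) -> "FeatherResonanceModel":
        from .io import read_trajectory_csv

        return cls(
            read_trajectory_csv(drive_path, label="shaker"),
            read_trajectory_csv(response_path, label="tip"),
            sweep,
            **kwargs,
        )

    def fit(
        self,
        smooth: bool = False,
        sg_window_hz: float = 1.3,
        max_modes: int = 6,
        prominence_frac: float = 0.05,
        normalize: bool = False,
    ) -> "FeatherResonanceResults":
        tf = spectral.compute_transfer_function(self.drive, self.response, self.sweep)
        if smooth:
            tf = spectral.smooth_transfer(tf, window_hz=sg_window_hz)
        if normalize:
            tf = tf.normalized()
        peaks = spectral.fit_lorentzian_peaks(
            tf, max_modes=max_modes, prominence_frac=prominence_frac,
            use_smoothed=smooth,
        )
        return FeatherResonanceResults(self, tf, peaks)


@dataclass
class FeatherResonanceResults:
    model: FeatherResonanceModel
    transfer_function: TransferFunction
    peaks: list[ModePeak]

    @property
    def f_k(self) -> np.ndarray:
        return np.array([p.f_k for p in self.peaks])

    @property
    def Q_k(self) -> np.ndarray:
        return np.array([p.Q_k for p in self.peaks])

    def peaks_frame(self) -> pd.DataFrame:
        """Peak table in the on-disk CSV schema."""
        return pd.DataFrame(
            {
                "feather_id": self.model.feather_id,
                "k": [p.k for p in self.peaks],
                "f_k_hz": [p.f_k for p in self.peaks],
                "delta_f_3db_hz": [p.delta_f_3dB for p in self.peaks],
                "q_k": [p.Q_k for p in self.peaks],
                "amplitude": [p.amplitude for p in self.peaks],
                "fit_rmse": [p.fit_rmse for p in self.peaks],
            }
        )

    def summary(self) -> str:
        lines = [
            _rule("Feather resonance"),
            f"feather: {self.model.feather_id}   "
            f"sweep: {self.model.sweep.f_start:g}-{self.model.sweep.f_stop:g} Hz "
            f"at {self.model.sweep.rate:g} Hz/s",
            f"modes found: {len(self.peaks)}",
            f"{'k':>3} {'f_k (Hz)':>10} {'df_3dB (Hz)':>12} {'Q_k':>8} "
            f"{'damping':>10} {'rmse':>9}",
        ]
        for p in self.peaks:
            regime = "weak" if p.Q_k > 2 * np.pi else "strong"
            lines.append(
                f"{p.k:>3} {p.f_k:>10.3f} {p.delta_f_3dB:>12.3f} {p.Q_k:>8.2f} "
                f"{regime:>10} {p.fit_rmse:>9.3g}"
            )
        return "\n".join(lines)


class OnsetModel:
    """Exponential rise of the vibration frequency at display onset.

    ``f(t) = f_ss (1 - exp(-t/tau))``.  Built from an instantaneous
    frequency series, or from a raw trajectory via zero-crossing intervals.
    """

    def __init__(self, t, freq) -> None:
        self.t = np.asarray(t, dtype=float)
        self.freq = np.asarray(freq, dtype=float)

    @classmethod
    def from_trajectory(cls, traj: TrajectoryTimeSeries) -> "OnsetModel":
        t, f = kinematics.instantaneous_frequency(traj)
        return cls(t, f)

    def fit(self) -> "OnsetResults":
        return OnsetResults(self, kinematics.fit_onset(self.t, self.freq))


@dataclass
class OnsetResults:
    model: OnsetModel
    params: OnsetFit

    @property
    def f_ss(self) -> float:
        return self.params.f_ss

    @property
    def tau(self) -> float:
        return self.params.tau

    @property
    def initial_rate(self) -> float:
        return self.params.initial_rate

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                _rule("Frequency-onset fit"),
                f"f_ss  = {p.f_ss:8.3f} Hz   95% CI [{p.f_ss_ci[0]:.3f}, {p.f_ss_ci[1]:.3f}]",
                f"tau   = {p.tau:8.3f} s    95% CI [{p.tau_ci[0]:.3f}, {p.tau_ci[1]:.3f}]",
                f"initial rate f_ss/tau = {p.initial_rate:.1f} Hz/s",
                f"rmse = {p.rmse:.3g} Hz over n = {p.n} cycle estimates",
            ]
        )


class PowerLawScalingModel:
    """Power law ``f_k ∝ L^-b`` between resonant frequency and length."""

    def __init__(self, lengths, frequencies) -> None:
        self.lengths = np.asarray(lengths, dtype=float)
        self.frequencies = np.asarray(frequencies, dtype=float)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, length_col: str = "L_R_m", freq_col: str = "f_k_hz"
    ) -> "PowerLawScalingModel":
        return cls(df[length_col].to_numpy(), df[freq_col].to_numpy())

    def fit(self) -> "PowerLawScalingResults":
        return PowerLawScalingResults(self, fit_length_scaling(self.lengths, self.frequencies))


@dataclass
class PowerLawScalingResults:
    model: PowerLawScalingModel
    params: ScalingFit

    @property
    def b(self) -> float:
        return self.params.b

    def predict(self, lengths) -> np.ndarray:
        return self.params.predict(np.asarray(lengths, dtype=float))

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                _rule("Frequency-length scaling"),
                f"f = a * L^-b with b = {p.b:.3f}  "
                f"95% CI [{p.b_ci[0]:.3f}, {p.b_ci[1]:.3f}]",
                f"prefactor a = {p.prefactor:.4g} Hz m^b",
                f"R^2 = {p.r_squared:.4f}  (n = {p.n})",
            ]
        )
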
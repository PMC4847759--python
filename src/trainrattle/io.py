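"""File formats and run configuration.

CSV schemas (comma-separated, UTF-8, mandatory header, SI-derived units in
the column names):

* trajectory:     ``time_s, displacement_mm``
* morphometrics:  ``x_m, dx_m, D1_mm, D2_mm, dM_R_mg, dM_F_mg``
* tail composition: ``feather_id, L_R_m, mu_F_kg_per_m``

WAV files are mono PCM at 16- or 24-bit depth (24-bit is the native depth
of the field recorder); samples are converted to float in [-1, 1] on read.
"""

from __future__ import annotations

import hashlib
import json
import wave
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .datatypes import AudioClip, RachisProfile, TrajectoryTimeSeries

__all__ = [
    "RunConfig",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_morphometrics_csv",
    "write_morphometrics_csv",
    "read_wav",
    "write_wav",
    "SchemaError",
]


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


class RunConfig(BaseModel):
    """Pipeline-wide constants, thresholds and seeds.

    Unknown keys are rejected so typos in config files fail loudly.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    G_prime_pa: float = Field(3.3e9, gt=0)  # dynamic storage modulus
    eyespot_diameter_mm: float = Field(40.5, gt=0)
    fps: float = Field(240.0, gt=0)
    fs: float = Field(44100.0, gt=0)
    cortex_density: float = Field(1150.0, gt=0)
    pith_density: float = Field(80.0, ge=0)
    local_buckling_coeff: float = Field(0.6, gt=0)
    peak_prominence_frac: float = Field(0.05, gt=0, lt=1)
    noise_floor_factor: float = Field(3.0, gt=0)
    sg_window_hz: float = Field(1.3, gt=0)
    sg_poly_order: int = Field(3, ge=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def provenance(self) -> dict:
        """Machine-readable record of the parameters governing a run."""
        payload = self.model_dump()
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"config": payload, "config_hash": digest}


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise SchemaError(f"{path}: empty file") from err
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_trajectory_csv(
    path: str | Path, jitter_tol: float = 1e-3, label: str = "tip"
) -> TrajectoryTimeSeries:
    df = _read_csv(path)
    _require_columns(df, ["time_s", "displacement_mm"], path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size > 1:
        if np.any(dt <= 0):
            raise SchemaError(f"{path}: time_s must be strictly increasing")
        step = np.median(dt)
        if np.max(np.abs(dt - step)) > jitter_tol * step:
            raise SchemaError(f"{path}: non-uniform sampling beyond tolerance")
        fps = 1.0 / step
    else:
        fps = 240.0
    return TrajectoryTimeSeries(
        df["displacement_mm"].to_numpy(dtype=float),
        fps=float(fps),
        t0=float(t[0]),
        label=label,
    )


def write_trajectory_csv(path: str | Path, traj: TrajectoryTimeSeries) -> None:
    pd.DataFrame({"time_s": traj.t, "displacement_mm": traj.displacement}).to_csv(
        path, index=False
    )


_MORPH_COLS = ["x_m", "dx_m", "D1_mm", "D2_mm", "dM_R_mg", "dM_F_mg"]


def read_morphometrics_csv(path: str | Path, **profile_kwargs) -> RachisProfile:
    df = _read_csv(path)
    _require_columns(df, _MORPH_COLS, path)
    x = df["x_m"].to_numpy(dtype=float)
    dx = df["dx_m"].to_numpy(dtype=float)
    return RachisProfile(
        x=x,
        dx=dx,
        D1=df["D1_mm"].to_numpy(dtype=float) * 1e-3,
        D2=df["D2_mm"].to_numpy(dtype=float) * 1e-3,
        mu_R=df["dM_R_mg"].to_numpy(dtype=float) * 1e-6 / dx,
        mu_F=df["dM_F_mg"].to_numpy(dtype=float) * 1e-6 / dx,
        L_R=float(x[-1] + dx[-1]),
        **profile_kwargs,
    )


def write_morphometrics_csv(path: str | Path, profile: RachisProfile) -> None:
    D2 = profile.D2 if profile.D2 is not None else profile.D1
    pd.DataFrame(
        {
            "x_m": profile.x,
            "dx_m": profile.dx,
            "D1_mm": profile.D1 * 1e3,
            "D2_mm": D2 * 1e3,
            "dM_R_mg": profile.mu_R * profile.dx * 1e6,
            "dM_F_mg": profile.mu_F * profile.dx * 1e6,
        }
    ).to_csv(path, index=False)


def read_wav(path: str | Path) -> AudioClip:
    """Read a mono 16- or 24-bit PCM WAV file to float samples."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with wave.open(str(path), "rb") as w:
        n_ch, sampwidth, fs, n_frames = (
            w.getnchannels(),
            w.getsampwidth(),
            w.getframerate(),
            w.getnframes(),
        )
        raw = w.readframes(n_frames)
    if sampwidth == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 2**15
    elif sampwidth == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        as32 = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        as32 = np.where(as32 >= 2**23, as32 - 2**24, as32)
        data = as32.astype(np.float64) / 2**23
    else:
        raise SchemaError(f"{path}: unsupported sample width {sampwidth * 8} bit")
    if n_ch > 1:
        data = data.reshape(-1, n_ch).mean(axis=1)
    if data.size == 0:
        raise SchemaError(f"{path}: empty audio")
    return AudioClip(data, fs=float(fs))


def write_wav(path: str | Path, clip: AudioClip, bit_depth: int = 24) -> None:
    """Write mono PCM WAV at 16- or 24-bit depth."""
    if bit_depth not in (16, 24):
        raise ValueError("bit_depth must be 16 or 24")
    x = np.clip(clip.samples, -1.0, 1.0)
    if bit_depth == 16:
        q = np.round(x * (2**15 - 1)).astype("<i2")
        raw = q.tobytes()
        width = 2
    else:
        q = np.round(x * (2**23 - 1)).astype(np.int32)
        q = np.where(q < 0, q + 2**24, q).astype(np.uint32)
        b = np.empty((q.size, 3), dtype=np.uint8)
        b[:, 0] = q & 0xFF
        b[:, 1] = (q >> 8) & 0xFF
        b[:, 2] = (q >> 16) & 0xFF
        raw = b.tobytes()
        width = 3
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(width)
        w.setframerate(int(round(clip.fs)))
        w.writeframes(raw)
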
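"""Core data containers: flow waveforms, 4D velocity fields, pressure traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FlowWaveform", "PressureWaveform", "VelocityField4D"]

MMHG_PA = 133.322  # 1 mmHg in Pa


@dataclass
class FlowWaveform:
    """Volumetric flow rate vs time at a named cross-section plane.

    ``times_ms`` spans one cardiac cycle starting at 0; ``flow_ml_s`` is in
    mL/s (clinical convention). The waveform is treated as periodic with
    period ``period_ms`` (defaults to ``times_ms[-1] + dt``, i.e. the sample
    at the period would wrap onto the one at 0).
    """

    times_ms: np.ndarray
    flow_ml_s: np.ndarray
    plane: str = ""
    period_ms: float | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.flow_ml_s = np.asarray(self.flow_ml_s, dtype=float)
        if self.times_ms.shape != self.flow_ml_s.shape:
            raise ValueError("times and flow must have the same length")
        if len(self.times_ms) and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.period_ms is None and len(self.times_ms) > 1:
            dt = self.times_ms[1] - self.times_ms[0]
            self.period_ms = float(self.times_ms[-1] - self.times_ms[0] + dt)

    @property
    def times_s(self) -> np.ndarray:
        return self.times_ms * 1e-3

    @property
    def flow_m3_s(self) -> np.ndarray:
        return self.flow_ml_s * 1e-6

    def cycle_mean(self) -> float:
        """Trapezoidal cycle mean (mL/s) over the periodic extension."""
        t = np.append(self.times_ms, self.times_ms[0] + self.period_ms)
        q = np.append(self.flow_ml_s, self.flow_ml_s[0])
        return float(np.trapezoid(q, t) / self.period_ms)

    def interp_m3_s(self, t_s) -> np.ndarray:
        """Periodic linear interpolation at time(s) ``t_s`` in seconds."""
        period = self.period_ms * 1e-3
        tt = np.mod(np.asarray(t_s, dtype=float) - self.times_s[0], period) + self.times_s[0]
        t_ext = np.append(self.times_s, self.times_s[0] + period)
        q_ext = np.append(self.flow_m3_s, self.flow_m3_s[0])
        return np.interp(tt, t_ext, q_ext)


@dataclass
class PressureWaveform:
    """Pressure vs time; stored in Pa, reportable in mmHg."""

    times_ms: np.ndarray
    pressure_pa: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.pressure_pa = np.asarray(self.pressure_pa, dtype=float)
        if self.times_ms.shape != self.pressure_pa.shape:
            raise ValueError("times and pressure must have the same length")
        if not np.all(np.isfinite(self.pressure_pa)):
            raise ValueError("pressure must be finite")

    @property
    def pressure_mmhg(self) -> np.ndarray:
        return self.pressure_pa / MMHG_PA


@dataclass
class VelocityField4D:
    """Time series of 3D velocity vectors on a regular voxel grid.

    Attributes
    ----------
    origin : (3,) mm, coordinates of the first voxel centre
    spacing : (3,) mm, positive
    frame_times_ms : (nt,) strictly increasing
    velocities : (nt, nx, ny, nz, 3) float, m/s; zero outside the lumen
    lumen_mask : (nx, ny, nz) bool, voxel centres inside the lumen
    """

    origin: np.ndarray
    spacing: np.ndarray
    frame_times_ms: np.ndarray
    velocities: np.ndarray
    lumen_mask: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        self.velocities = np.asarray(self.velocities)
        self.lumen_mask = np.asarray(self.lumen_mask, dtype=bool)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if len(self.frame_times_ms) > 1 and np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValueError("frame times must be strictly increasing")
        nt = len(self.frame_times_ms)
        if self.velocities.shape[0] != nt or self.velocities.shape[-1] != 3:
            raise ValueError("velocities must have shape (nt, nx, ny, nz, 3)")
        if self.velocities.shape[1:4] != self.lumen_mask.shape:
            raise ValueError("lumen_mask shape must match the voxel grid")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")

    @property
    def shape(self) -> tuple:
        return self.lumen_mask.shape

    @property
    def n_frames(self) -> int:
        return len(self.frame_times_ms)

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate axes (mm) along x, y, z."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i]) for i in range(3)
        )

    def frame_index(self, t_ms: float) -> int:
        """Index of the frame nearest to ``t_ms`` (periodic if >1 frame)."""
        if self.n_frames == 1:
            return 0
        dt = self.frame_times_ms[1] - self.frame_times_ms[0]
        period = self.frame_times_ms[-1] - self.frame_times_ms[0] + dt
        tt = np.mod(t_ms - self.frame_times_ms[0], period) + self.frame_times_ms[0]
        return int(np.argmin(np.abs(self.frame_times_ms - tt)))

    def scaled(self, c: float) -> "VelocityField4D":
        """Copy with all velocities multiplied by ``c``."""
        return VelocityField4D(
            origin=self.origin.copy(),
            spacing=self.spacing.copy(),
            frame_times_ms=self.frame_times_ms.copy(),
            velocities=self.velocities * c,
            lumen_mask=self.lumen_mask.copy(),
        )
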
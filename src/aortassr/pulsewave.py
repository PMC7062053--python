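"""Reduced-order pulse-wave model: 1D elastic tube with Windkessel outlet.

This is the desk-scale surrogate used to exercise the stiffness and
flow-split calibration loops. The tube law is linear, P = P_ref +
rho_f*c0^2*(A - A0)/A0 with c0 = sqrt(E*h/(2*rho_f*r)), so the linearised
wave speed equals the Moens-Korteweg speed exactly (no (1 - nu^2) factor;
the Poisson ratio is carried as metadata only). Governing equations in
area-flow (A, Q) form:

    dA/dt + dQ/dx = -psi(x, t)            (distributed branch outflow)
    dQ/dt + d(Q^2/A + c0^2 A^2 / (2 A0))/dx = -8 pi nu Q / A

solved with the two-step (Richtmyer) Lax-Wendroff scheme on a uniform grid;
inlet flow is prescribed and the outlet couples to a 2-element Windkessel
(Q = P/R + C dP/dt) through the outgoing characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FlowWaveform, PressureWaveform
from .synthetic import MU_BLOOD, RHO_BLOOD

__all__ = [
    "WindkesselParams",
    "BranchSink",
    "TubeModel1D",
    "PulseWaveResult",
    "solve_windkessel",
    "simulate_pulsewave",
    "measure_pwv",
    "CFLError",
]


class CFLError(RuntimeError):
    """Raised when the time step violates the CFL stability condition."""


@dataclass
class WindkesselParams:
    """2-element Windkessel: peripheral resistance R and compliance C."""

    R: float  # Pa s / m^3
    C: float  # m^3 / Pa
    p_venous: float = 0.0  # Pa, distal reference pressure

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0:
            raise ValueError("Windkessel R and C must be positive")


@dataclass
class BranchSink:
    """Distributed mid-tube outflow emulating the supra-aortic branch split.

    The sink withdraws g(x)*(P - p_ref_sink)/resistance per unit length,
    with g a Gaussian bump (area 1) centred at ``center_frac`` of the tube.
    """

    resistance: float  # Pa s / m^3
    center_frac: float = 0.5
    width_frac: float = 0.08
    p_ref_sink: float = 0.0  # Pa

    def density(self, x: np.ndarray, length: float) -> np.ndarray:
        sigma = self.width_frac * length
        g = np.exp(-0.5 * ((x - self.center_frac * length) / sigma) ** 2)
        return g / np.trapezoid(g, x)


@dataclass
class TubeModel1D:
    """Straight elastic tube (SI units)."""

    length: float = 0.3  # m
    radius: float = 0.0125  # m
    thickness: float = 0.00125  # m
    E: float = 1.25e6  # Pa
    rho_f: float = RHO_BLOOD
    mu_f: float = MU_BLOOD
    rho_s: float = 1100.0  # kg/m^3, metadata only (solid not modelled in 1D)
    nu_poisson: float = 0.45  # metadata only; wave speed has no (1-nu^2) factor
    p_ref: float = 9975.0  # Pa (~75 mmHg) transmural pressure at A = A0
    n_cells: int = 200
    cfl: float = 0.9
    branch: BranchSink | None = None

    def __post_init__(self) -> None:
        if min(self.length, self.radius, self.thickness, self.E) <= 0:
            raise ValueError("tube dimensions and stiffness must be positive")

    @property
    def c0(self) -> float:
        """Moens-Korteweg wave speed sqrt(E*h / (2*rho_f*r)) in m/s."""
        return float(np.sqrt(self.E * self.thickness / (2 * self.rho_f * self.radius)))

    @property
    def area0(self) -> float:
        return float(np.pi * self.radius**2)


def solve_windkessel(
    Q: FlowWaveform,
    params: WindkesselParams,
    P0: float = 0.0,
    n_cycles: int = 50,
    substeps: int = 4000,
) -> PressureWaveform:
    """Integrate C dP/dt = Q(t) - (P - p_venous)/R to a periodic steady state.

    Classic RK4 at ``substeps`` per cycle; stops early once the
    cycle-to-cycle RMS pressure change falls below 0.1% (relative to the
    cycle's RMS), or after ``n_cycles``. Returns the last integrated cycle.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    T = Q.period_ms * 1e-3
    dt = T / substeps
    t_local = np.arange(substeps + 1) * dt

    def dPdt(t, P):
        return (Q.interp_m3_s(t) - (P - params.p_venous) / params.R) / params.C

    P = float(P0)
    prev_cycle = None
    cycle = None
    for cyc in range(n_cycles):
        cycle = np.empty(substeps + 1)
        cycle[0] = P
        t0 = cyc * T
        for i in range(substeps):
            t = t0 + t_local[i]
            k1 = dPdt(t, P)
            k2 = dPdt(t + dt / 2, P + dt / 2 * k1)
            k3 = dPdt(t + dt / 2, P + dt / 2 * k2)
            k4 = dPdt(t + dt, P + dt * k3)
            P = P + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            cycle[i + 1] = P
        if prev_cycle is not None:
            scale = max(np.sqrt(np.mean(cycle**2)), 1e-300)
            if np.sqrt(np.mean((cycle - prev_cycle) ** 2)) / scale < 1e-3:
                break
        prev_cycle = cycle
    return PressureWaveform(times_ms=t_local * 1e3, pressure_pa=cycle)


@dataclass
class PulseWaveResult:
    """Last periodic cycle of a 1D pulse-wave simulation."""

    x: np.ndarray  # m
    times_ms: np.ndarray  # recorded times within the cycle
    Q: np.ndarray  # (nt, nx) m^3/s
    P: np.ndarray  # (nt, nx) Pa
    A: np.ndarray  # (nt, nx) m^2
    converged: bool
    n_cycles_run: int
    cycle_change: float
    char_impedance: float = 0.0  # rho_f * c0 / A0, Pa s / m^3
    p_ref: float = 0.0

    def flow_waveform(self, x_pos: float) -> FlowWaveform:
        """Flow waveform (mL/s) at the grid node nearest ``x_pos`` (m)."""
        i = int(np.argmin(np.abs(self.x - x_pos)))
        return FlowWaveform(
            times_ms=self.times_ms,
            flow_ml_s=self.Q[:, i] * 1e6,
            plane=f"x={self.x[i]:.3f}m",
            period_ms=float(self.times_ms[-1] - self.times_ms[0] + np.diff(self.times_ms)[0]),
        )

    def forward_flow_waveform(self, x_pos: float) -> FlowWaveform:
        """Forward-running (incident) flow component at ``x_pos`` (mL/s).

        Linear wave separation with the characteristic impedance Zc =
        rho_f*c0/A0: Q_f = (dQ + dP/Zc)/2 relative to the reference state.
        At a periodic steady state the raw outlet peak is shaped by the
        Windkessel reflection; the forward component is reflection-free, so
        its systolic-peak transit time is the meaningful one on a short tube.
        """
        i = int(np.argmin(np.abs(self.x - x_pos)))
        qf = 0.5 * (self.Q[:, i] + (self.P[:, i] - self.p_ref) / self.char_impedance)
        return FlowWaveform(
            times_ms=self.times_ms,
            flow_ml_s=qf * 1e6,
            plane=f"forward x={self.x[i]:.3f}m",
            period_ms=float(self.times_ms[-1] - self.times_ms[0] + np.diff(self.times_ms)[0]),
        )

    def mean_flow(self, x_pos: float) -> float:
        """Cycle-mean flow (m^3/s) at the node nearest ``x_pos``."""
        i = int(np.argmin(np.abs(self.x - x_pos)))
        return float(np.trapezoid(self.Q[:, i], self.times_ms) / (self.times_ms[-1] - self.times_ms[0]))


def _newton_inlet(Q_in, W2b, A_guess, c0, A0):
    """Solve Q_in/A - 2 c0 sqrt(A/A0) = W2b for A."""
    A = A_guess
    for _ in range(30):
        sq = np.sqrt(A / A0)
        f = Q_in / A - 2 * c0 * sq - W2b
        fp = -Q_in / A**2 - c0 / np.sqrt(A * A0)
        step = f / fp
        A_new = A - step
        if A_new <= 0:
            A_new = 0.5 * A
        if abs(A_new - A) < 1e-14 * A0:
            return A_new
        A = A_new
    return A


def _newton_outlet(W1b, A_guess, c0, A0, beta, p_ref, wk: WindkesselParams, P_prev, dt):
    """Outlet area from the incoming characteristic + backward-Euler Windkessel."""
    A = A_guess
    for _ in range(30):
        sq = np.sqrt(A / A0)
        u = W1b - 2 * c0 * sq
        P = p_ref + beta * (A - A0)
        f = u * A - (P - wk.p_venous) / wk.R - wk.C * (P - P_prev) / dt
        fp = W1b - 3 * c0 * sq - beta / wk.R - beta * wk.C / dt
        step = f / fp
        A_new = A - step
        if A_new <= 0:
            A_new = 0.5 * A
        if abs(A_new - A) < 1e-14 * A0:
            return A_new
        A = A_new
    return A


def simulate_pulsewave(
    model: TubeModel1D,
    inlet: FlowWaveform,
    outlet: WindkesselParams,
    n_cycles: int = 8,
    rec_dt_ms: float = 0.5,
    cycle_tol: float = 5e-3,
) -> PulseWaveResult:
    """Run the 1D tube to a periodic steady state and return the last cycle.

    Stops once the cycle-to-cycle relative L2 change of the recorded flow
    field drops below ``cycle_tol`` (default 0.5%), or after ``n_cycles``.

    Raises
    ------
    CFLError
        If the wave ever outruns the grid (names the required time step).
    RuntimeError
        On blow-up (non-finite state).
    """
    nx = model.n_cells
    dx = model.length / (nx - 1)
    x = np.linspace(0.0, model.length, nx)
    A0 = model.area0
    c0 = model.c0
    beta = model.rho_f * c0**2 / A0
    nu = model.mu_f / model.rho_f
    kr = 8 * np.pi * nu
    T = inlet.period_ms * 1e-3

    u_est = max(2.0, 2.5 * abs(inlet.flow_m3_s).max() / A0)
    dt_target = model.cfl * dx / (1.25 * c0 + u_est)
    steps_per_cycle = int(np.ceil(T / dt_target))
    dt = T / steps_per_cycle
    rec_stride = max(1, int(round(rec_dt_ms * 1e-3 / dt)))
    rec_idx = np.arange(0, steps_per_cycle, rec_stride)

    if model.branch is not None:
        g = model.branch.density(x, model.length)
    else:
        g = None

    A = np.full(nx, A0)
    Q = np.full(nx, float(inlet.interp_m3_s(0.0)))
    P_wk = model.p_ref

    def pressure(Aa):
        return model.p_ref + beta * (Aa - A0)

    def flux(Aa, Qq):
        return Qq, Qq**2 / Aa + c0**2 * Aa**2 / (2 * A0)

    def sources(Aa, Qq):
        s1 = np.zeros_like(Aa)
        if g is not None:
            s1 = -g * (pressure(Aa) - model.branch.p_ref_sink) / model.branch.resistance
        s2 = -kr * Qq / Aa
        return s1, s2

    prev_rec = None
    rec_Q = rec_P = rec_A = None
    converged = False
    change = np.inf
    cycles_run = 0
    # blow-ups are detected and reported at cycle ends, not via warnings
    np_err = dict(invalid="ignore", over="ignore", divide="ignore")
    for cyc in range(n_cycles):
        rec_Q = np.empty((len(rec_idx), nx))
        rec_P = np.empty_like(rec_Q)
        rec_A = np.empty_like(rec_Q)
        rec_k = 0
        t_cycle = cyc * T
        with np.errstate(**np_err):
            for step in range(steps_per_cycle):
                t = t_cycle + step * dt
                if step % rec_stride == 0:
                    rec_Q[rec_k] = Q
                    rec_P[rec_k] = pressure(A)
                    rec_A[rec_k] = A
                    rec_k += 1

                # interior update (Richtmyer two-step Lax-Wendroff)
                F1, F2 = flux(A, Q)
                S1, S2 = sources(A, Q)
                A_h = 0.5 * (A[:-1] + A[1:]) - dt / (2 * dx) * (F1[1:] - F1[:-1]) \
                    + dt / 4 * (S1[:-1] + S1[1:])
                Q_h = 0.5 * (Q[:-1] + Q[1:]) - dt / (2 * dx) * (F2[1:] - F2[:-1]) \
                    + dt / 4 * (S2[:-1] + S2[1:])
                G1, G2 = flux(A_h, Q_h)
                A_new = A.copy()
                Q_new = Q.copy()
                A_new[1:-1] = A[1:-1] - dt / dx * (G1[1:] - G1[:-1]) + dt * S1[1:-1]
                Q_new[1:-1] = Q[1:-1] - dt / dx * (G2[1:] - G2[:-1]) + dt * S2[1:-1]

                # inlet: prescribed flow + outgoing characteristic W2 = u - 2c
                Q_bc = float(inlet.interp_m3_s(t + dt))
                W2b = Q[1] / A[1] - 2 * c0 * np.sqrt(A[1] / A0)
                A_new[0] = _newton_inlet(Q_bc, W2b, A[0], c0, A0)
                Q_new[0] = Q_bc

                # outlet: incoming characteristic W1 = u + 2c into the Windkessel
                W1b = Q[-2] / A[-2] + 2 * c0 * np.sqrt(A[-2] / A0)
                A_out = _newton_outlet(W1b, A[-1], c0, A0, beta, model.p_ref, outlet, P_wk, dt)
                u_out = W1b - 2 * c0 * np.sqrt(A_out / A0)
                A_new[-1] = A_out
                Q_new[-1] = u_out * A_out
                P_wk = pressure(A_out)

                A, Q = A_new, Q_new

        cycles_run = cyc + 1
        if not np.all(np.isfinite(A)) or not np.all(np.isfinite(Q)):
            raise RuntimeError("1D pulse-wave solver blew up (non-finite state)")
        cmax = float(np.max(np.abs(Q / A) + c0 * np.sqrt(A / A0)))
        if cmax * dt > dx:
            raise CFLError(
                f"CFL violated: wave speed {cmax:.2f} m/s needs dt <= "
                f"{dx / cmax:.3e} s (used {dt:.3e} s)"
            )
        if prev_rec is not None:
            scale = max(np.sqrt(np.mean(prev_rec**2)), 1e-300)
            change = float(np.sqrt(np.mean((rec_Q - prev_rec) ** 2)) / scale)
            if change < cycle_tol:
                converged = True
                break
        prev_rec = rec_Q

    return PulseWaveResult(
        x=x,
        times_ms=rec_idx * dt * 1e3,
        Q=rec_Q,
        P=rec_P,
        A=rec_A,
        converged=converged,
        n_cycles_run=cycles_run,
        cycle_change=change,
        char_impedance=model.rho_f * c0 / A0,
        p_ref=model.p_ref,
    )


def _refined_peak_time(times_ms: np.ndarray, values: np.ndarray) -> tuple[float, bool]:
    """Peak time with quadratic sub-sample refinement; flags flat waveforms."""
    i = int(np.argmax(values))
    flat = np.allclose(values, values[0])
    if flat or i == 0 or i == len(values) - 1:
        return float(times_ms[i]), flat
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(times_ms[i]), flat
    delta = 0.5 * (y0 - y2) / denom
    dt = times_ms[i] - times_ms[i - 1]
    return float(times_ms[i] + np.clip(delta, -1, 1) * dt), flat


def _xcorr_lag_ms(wave_in: FlowWaveform, wave_out: FlowWaveform) -> float:
    """Circular cross-correlation lag of wave_out behind wave_in (ms).

    Both waveforms must share a uniform time grid over one period. The lag
    maximising sum_t q_in(t) q_out(t + lag) over the first half-period is
    refined by a quadratic fit around the correlation maximum.
    """
    if len(wave_in.times_ms) != len(wave_out.times_ms) or not np.allclose(
        wave_in.times_ms, wave_out.times_ms
    ):
        raise ValueError("cross-correlation needs a common uniform time grid")
    a = wave_in.flow_ml_s - wave_in.flow_ml_s.mean()
    b = wave_out.flow_ml_s - wave_out.flow_ml_s.mean()
    n = len(a)
    corr = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n)
    dt = wave_in.times_ms[1] - wave_in.times_ms[0]
    k = int(np.argmax(corr[: n // 2]))
    y0, y1, y2 = corr[(k - 1) % n], corr[k], corr[(k + 1) % n]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float((k + np.clip(delta, -1, 1)) * dt)


def measure_pwv(
    wave_in: FlowWaveform, wave_out: FlowWaveform, dx: float, method: str = "peak"
) -> float:
    """Transit-time pulse wave velocity (m/s) between two waveforms.

    ``method="peak"`` (default): dt is the difference of systolic-peak times
    with quadratic sub-sample refinement. ``method="xcorr"``: dt is the
    circular cross-correlation lag of the full (periodic) waveforms — robust
    when reflections put competing local maxima near the systolic crest.
    PWV = dx / dt with ``dx`` in metres.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if method == "peak":
        t_in, _ = _refined_peak_time(wave_in.times_ms, wave_in.flow_ml_s)
        t_out, _ = _refined_peak_time(wave_out.times_ms, wave_out.flow_ml_s)
        dt_ms = t_out - t_in
    elif method == "xcorr":
        dt_ms = _xcorr_lag_ms(wave_in, wave_out)
    else:
        raise ValueError("method must be 'peak' or 'xcorr'")
    if dt_ms <= 0:
        raise ValueError(
            f"non-physical timing: outlet systole does not lag the inlet "
            f"(dt = {dt_ms:.3f} ms); PWV undefined"
        )
    return dx / (dt_ms * 1e-3)
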
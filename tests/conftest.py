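"""Shared fixtures: straight-tube geometries and analytic voxel fields."""

import numpy as np
import pytest

from aortassr.fields import VelocityField4D
from aortassr.geometry import build_tube_geometry

R_TUBE_MM = 12.5
MU = 0.035


def straight_tube(n_stations=27, length_mm=40.0, radius_mm=R_TUBE_MM, n_circ=32):
    cl = np.column_stack(
        [np.zeros(n_stations), np.zeros(n_stations), np.linspace(0, length_mm, n_stations)]
    )
    return build_tube_geometry(cl, radius_mm, 1.25, n_circ)


@pytest.fixture(scope="session")
def straight_geo():
    """Straight tube along z: R = 12.5 mm, L = 40 mm."""
    return straight_tube()


def analytic_tube_field(
    geo, spacing_mm, Q_m3_s=1e-4, swirl_k=0.0, solid_omega=0.0, parabolic=True
):
    """Axial Poiseuille (flow Q) plus azimuthal swirl sampled on a voxel grid.

    swirl_k adds u_theta = k * rho^2 (wall shear mu*k*R); solid_omega adds
    rigid rotation u_theta = omega * rho (zero wall shear).
    """
    R = geo.radius[0] * 1e-3
    lo = geo.vertices.min(axis=0) - 2
    hi = geo.vertices.max(axis=0) + 2
    shape = np.ceil((hi - lo) / spacing_mm).astype(int) + 1
    axes = [lo[i] + spacing_mm * np.arange(shape[i]) for i in range(3)]
    X, Y, _ = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt(X**2 + Y**2) * 1e-3
    mask = rho <= R
    v = np.zeros(tuple(shape) + (3,))
    if Q_m3_s:
        profile = 2 * Q_m3_s / (np.pi * R**2)
        v[..., 2] = np.where(mask, profile * (1 - (rho / R) ** 2) if parabolic else profile, 0.0)
    u_theta = swirl_k * rho**2 + solid_omega * rho
    if swirl_k or solid_omega:
        with np.errstate(invalid="ignore", divide="ignore"):
            tx = np.where(rho > 0, -Y * 1e-3 / rho, 0.0)
            ty = np.where(rho > 0, X * 1e-3 / rho, 0.0)
        v[..., 0] += np.where(mask, u_theta * tx, 0.0)
        v[..., 1] += np.where(mask, u_theta * ty, 0.0)
    return VelocityField4D(
        origin=lo,
        spacing=[spacing_mm] * 3,
        frame_times_ms=[0.0],
        velocities=v[None],
        lumen_mask=mask,
    )


def interior_vertices(geo, wss_valid=None, margin=5):
    """Vertices away from the tube ends (end stations lack axial support)."""
    sel = (geo.vertex_station >= margin) & (geo.vertex_station < geo.n_stations - margin)
    if wss_valid is not None:
        sel &= wss_valid
    return sel
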
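"""Vessel geometry: centerline frames, tube surfaces, segment and quadrant labels.

The vessel is modelled as a tube swept along a 3D centerline. Cross-section
frames are rotation-minimizing (parallel transport), not Frenet, so that the
quadrant reference axes stay stable on near-straight sections where torsion
is undefined. Coordinates are millimetres, right-handed; arc length is
measured from the inlet (the sinotubular-junction analogue); station indexing
is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VesselGeometry",
    "SectionPlane",
    "build_tube_geometry",
    "local_frame",
    "quadrant_labels",
    "segment_split",
    "QUADRANT_CONVENTIONS",
    "DEFAULT_SEGMENT_BOUNDS",
    "DEFAULT_SEGMENT_NAMES",
]

#: Four 90-degree sector label sets, listed counter-clockwise starting at the
#: reference axis (theta = 0).  Two naming conventions are supported; neither
#: is asserted to match any particular patient's image axes.
QUADRANT_CONVENTIONS = {
    "anterior_left_posterior_right": ("anterior", "left", "posterior", "right"),
    "interior_anterior_exterior_posterior": (
        "interior",
        "anterior",
        "exterior",
        "posterior",
    ),
}

#: Default arc-length fractions splitting the vessel into named segments.
#: The ascending segment is further split into proximal/distal halves by
#: :func:`segment_split`, giving five segments in total.
DEFAULT_SEGMENT_BOUNDS = (0.0, 0.30, 0.55, 0.775, 1.0)
DEFAULT_SEGMENT_NAMES = ("ascending", "arch", "descending-proximal", "descending-distal")


@dataclass
class SectionPlane:
    """A cross-section plane attached to the centerline.

    ``tangent`` points downstream; ``in_plane_axes`` are two unit vectors
    spanning the plane (the first is the quadrant reference axis, theta = 0).
    """

    origin: np.ndarray
    tangent: np.ndarray
    in_plane_axes: np.ndarray  # shape (2, 3)
    lumen_radius: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        self.in_plane_axes = np.asarray(self.in_plane_axes, dtype=float)
        g = np.vstack([self.tangent, self.in_plane_axes])
        if not np.allclose(g @ g.T, np.eye(3), atol=1e-8):
            raise ValueError("section plane axes must be orthonormal")


@dataclass
class VesselGeometry:
    """Tube geometry swept along a centerline.

    Attributes
    ----------
    centerline_points : (n_stations, 3) float, mm
    arclength : (n_stations,) float, mm, strictly increasing from 0
    radius : (n_stations,) float, mm, lumen radius per station
    thickness : (n_stations,) float, mm, wall thickness per station
    tangents, normals, binormals : (n_stations, 3) parallel-transport frames
    vertices : (n_stations * n_circ, 3) wall surface points, mm
    faces : (n_faces, 3) int triangle indices (closed tube, no caps)
    vertex_normals : outward unit normals per surface vertex
    vertex_station : station index per surface vertex
    vertex_theta : angular coordinate per surface vertex, degrees in [0, 360)
    segment_bounds : arc-length fractions delimiting named segments
    segment_names : one name per bounds interval
    """

    centerline_points: np.ndarray
    arclength: np.ndarray
    radius: np.ndarray
    thickness: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    binormals: np.ndarray
    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray
    vertex_station: np.ndarray
    vertex_theta: np.ndarray
    n_circ: int
    segment_bounds: tuple = DEFAULT_SEGMENT_BOUNDS
    segment_names: tuple = DEFAULT_SEGMENT_NAMES

    @property
    def n_stations(self) -> int:
        return len(self.centerline_points)

    @property
    def length(self) -> float:
        """Total centerline arc length (mm)."""
        return float(self.arclength[-1])

    def radius_at(self, s) -> np.ndarray:
        """Lumen radius (mm) at arc length ``s`` (mm), linear interpolation."""
        return np.interp(s, self.arclength, self.radius)

    def thickness_at(self, s) -> np.ndarray:
        return np.interp(s, self.arclength, self.thickness)

    def station_fractions(self) -> np.ndarray:
        """Arc-length fraction in [0, 1] of every station."""
        return self.arclength / self.arclength[-1]


def _parallel_transport_frames(points: np.ndarray, anterior: np.ndarray):
    """Rotation-minimizing frames along a polyline.

    The initial normal is the projection of ``anterior`` into the first
    cross-section; subsequent normals are parallel-transported by rotating
    with the minimal rotation that maps each tangent onto the next.
    """
    diffs = np.diff(points, axis=0)
    seglen = np.linalg.norm(diffs, axis=1)
    # tangent per station: central differences, second-order one-sided ends
    tangents = np.empty_like(points)
    if len(points) > 2:
        mid = points[2:] - points[:-2]
        tangents[1:-1] = mid / np.linalg.norm(mid, axis=1)[:, None]
        t0 = -3.0 * points[0] + 4.0 * points[1] - points[2]
        t1 = 3.0 * points[-1] - 4.0 * points[-2] + points[-3]
        tangents[0] = t0 / np.linalg.norm(t0)
        tangents[-1] = t1 / np.linalg.norm(t1)
    else:
        tangents[0] = diffs[0] / seglen[0]
        tangents[-1] = diffs[-1] / seglen[-1]

    n0 = anterior - np.dot(anterior, tangents[0]) * tangents[0]
    norm0 = np.linalg.norm(n0)
    if norm0 < 1e-12:
        # anterior parallel to the first tangent: fall back to any orthogonal
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, tangents[0])) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n0 = trial - np.dot(trial, tangents[0]) * tangents[0]
        norm0 = np.linalg.norm(n0)
    normals = np.empty_like(points)
    normals[0] = n0 / norm0
    # double-reflection rotation-minimizing frames (second-order accurate)
    for i in range(1, len(points)):
        v1 = points[i] - points[i - 1]
        c1 = np.dot(v1, v1)
        rL = normals[i - 1] - (2.0 / c1) * np.dot(v1, normals[i - 1]) * v1
        tL = tangents[i - 1] - (2.0 / c1) * np.dot(v1, tangents[i - 1]) * v1
        v2 = tangents[i] - tL
        c2 = np.dot(v2, v2)
        n = rL if c2 < 1e-28 else rL - (2.0 / c2) * np.dot(v2, rL) * v2
        n = n - np.dot(n, tangents[i]) * tangents[i]
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def build_tube_geometry(
    centerline: np.ndarray,
    radius_profile,
    thickness_profile,
    circumferential_resolution: int = 32,
    anterior=(0.0, 1.0, 0.0),
    segment_bounds=DEFAULT_SEGMENT_BOUNDS,
    segment_names=DEFAULT_SEGMENT_NAMES,
) -> VesselGeometry:
    """Sweep a closed tube surface along a centerline polyline.

    Parameters
    ----------
    centerline : (n, 3) array, mm; at least two distinct points.
    radius_profile, thickness_profile : scalar or (n,) array, mm, positive.
    circumferential_resolution : vertices per cross-section circle.
    anterior : reference direction fixing theta = 0 in every section.

    Raises
    ------
    ValueError
        For degenerate centerlines (repeated points, kinks of 90 degrees or
        more between consecutive segments — a proxy for self-intersection) or
        non-positive radii/thicknesses.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("centerline must be an (n>=2, 3) array")
    n = len(pts)
    r = np.broadcast_to(np.asarray(radius_profile, dtype=float), (n,)).copy()
    h = np.broadcast_to(np.asarray(thickness_profile, dtype=float), (n,)).copy()
    if np.any(r <= 0) or np.any(h <= 0):
        raise ValueError("radius and thickness must be positive everywhere")

    diffs = np.diff(pts, axis=0)
    seglen = np.linalg.norm(diffs, axis=1)
    if np.any(seglen <= 0):
        raise ValueError("centerline has repeated points (non-monotone arc length)")
    arclength = np.concatenate([[0.0], np.cumsum(seglen)])
    unit = diffs / seglen[:, None]
    if len(unit) > 1:
        cosang = np.sum(unit[:-1] * unit[1:], axis=1)
        if np.any(cosang <= 0.0):
            i = int(np.argmax(cosang <= 0.0))
            raise ValueError(
                f"centerline kinks by >=90 deg at interior point {i + 1}; "
                "likely self-intersecting"
            )

    tangents, normals, binormals = _parallel_transport_frames(pts, np.asarray(anterior, float))

    m = int(circumferential_resolution)
    if m < 3:
        raise ValueError("circumferential_resolution must be >= 3")
    theta = np.arange(m) * (2 * np.pi / m)
    ct, st = np.cos(theta), np.sin(theta)
    # radial directions per station x circumferential sample
    radial = ct[None, :, None] * normals[:, None, :] + st[None, :, None] * binormals[:, None, :]
    vertices = (pts[:, None, :] + r[:, None, None] * radial).reshape(-1, 3)
    vertex_normals = radial.reshape(-1, 3)
    vertex_station = np.repeat(np.arange(n), m)
    vertex_theta = np.tile(np.degrees(theta) % 360.0, n)

    faces = []
    for i in range(n - 1):
        for j in range(m):
            a = i * m + j
            b = i * m + (j + 1) % m
            c = (i + 1) * m + j
            d = (i + 1) * m + (j + 1) % m
            faces.append((a, b, d))
            faces.append((a, d, c))
    faces = np.asarray(faces, dtype=np.int64)

    return VesselGeometry(
        centerline_points=pts,
        arclength=arclength,
        radius=r,
        thickness=h,
        tangents=tangents,
        normals=normals,
        binormals=binormals,
        vertices=vertices,
        faces=faces,
        vertex_normals=vertex_normals,
        vertex_station=vertex_station,
        vertex_theta=vertex_theta,
        n_circ=m,
        segment_bounds=tuple(segment_bounds),
        segment_names=tuple(segment_names),
    )


def local_frame(geometry: VesselGeometry, s: float) -> SectionPlane:
    """Rotation-minimizing cross-section frame at arc length ``s`` (mm).

    Frames are interpolated linearly between stations and re-orthonormalised,
    so they vary continuously along the vessel.
    """
    sl = geometry.arclength
    if not (sl[0] <= s <= sl[-1]):
        raise ValueError(f"arc length {s} outside [{sl[0]}, {sl[-1]}]")
    i = int(np.clip(np.searchsorted(sl, s) - 1, 0, len(sl) - 2))
    w = (s - sl[i]) / (sl[i + 1] - sl[i])
    origin = (1 - w) * geometry.centerline_points[i] + w * geometry.centerline_points[i + 1]
    t = (1 - w) * geometry.tangents[i] + w * geometry.tangents[i + 1]
    t /= np.linalg.norm(t)
    nrm = (1 - w) * geometry.normals[i] + w * geometry.normals[i + 1]
    nrm = nrm - np.dot(nrm, t) * t
    nrm /= np.linalg.norm(nrm)
    b = np.cross(t, nrm)
    return SectionPlane(
        origin=origin,
        tangent=t,
        in_plane_axes=np.vstack([nrm, b]),
        lumen_radius=float(geometry.radius_at(s)),
    )


def quadrant_labels(
    geometry: VesselGeometry,
    convention: str = "anterior_left_posterior_right",
) -> np.ndarray:
    """Assign each surface vertex to one of four 90-degree sectors.

    Sector ``k`` (centre ``c_k = 90k`` degrees) collects vertices with
    ``theta in [c_k - 45, c_k + 45)``; theta is measured from the geometry's
    anterior reference axis, counter-clockwise when viewed downstream.
    """
    try:
        names = QUADRANT_CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown quadrant convention {convention!r}; "
            f"choose from {sorted(QUADRANT_CONVENTIONS)}"
        ) from None
    sector = ((geometry.vertex_theta + 45.0) % 360.0 / 90.0).astype(int) % 4
    return np.asarray(names, dtype=object)[sector]


def segment_split(geometry: VesselGeometry) -> np.ndarray:
    """Label every surface vertex with its named segment.

    Segments are half-open arc-length-fraction intervals
    ``[b_k, b_{k+1})`` (the last closed at 1). A segment named
    ``"ascending"`` is additionally split at the arithmetic midpoint of its
    range into ``"ascending-proximal"`` and ``"ascending-distal"``.
    """
    bounds = np.asarray(geometry.segment_bounds, dtype=float)
    names = list(geometry.segment_names)
    if len(names) != len(bounds) - 1:
        raise ValueError("need one segment name per bounds interval")
    if np.any(bounds < 0) or np.any(bounds > 1) or np.any(np.diff(bounds) <= 0):
        raise ValueError("segment bounds must be strictly increasing within [0, 1]")
    frac = geometry.station_fractions()[geometry.vertex_station]
    idx = np.clip(np.searchsorted(bounds, frac, side="right") - 1, 0, len(names) - 1)
    labels = np.asarray(names, dtype=object)[idx]
    if "ascending" in names:
        k = names.index("ascending")
        mid = 0.5 * (bounds[k] + bounds[k + 1])
        asc = labels == "ascending"
        labels = labels.astype(object)
        labels[asc & (frac < mid)] = "ascending-proximal"
        labels[asc & (frac >= mid)] = "ascending-distal"
    return labels
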
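"""Case-level pipeline glue: from a synthetic case to markers and regional SSR.

Keeps the per-case processing (field realisation, wall shear, SSR, quadrant
and percentile summaries, plane markers on fine vs MRI-like fields) in one
place so the analysis drivers, tests and the acceptance script all run the
same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fields import VelocityField4D
from .geometry import VesselGeometry, local_frame, quadrant_labels, segment_split
from .markers import plane_markers, ssr, wall_shear
from .regional import RegionalSummary, cumulative_frequency, percentile, quadrant_mean_ssr
from .synthetic import Case

__all__ = ["case_regional_summary", "case_marker_rows", "ANALYSIS_SEGMENT"]

#: Default region for the cumulative SSR analysis: the distal half of the
#: ascending aorta, where the group differences concentrate.
ANALYSIS_SEGMENT = "ascending-distal"


def case_regional_summary(
    case: Case,
    geometry: VesselGeometry,
    field: VelocityField4D,
    t_peak_ms: float,
    segment: str | tuple = ANALYSIS_SEGMENT,
    convention: str = "interior_anterior_exterior_posterior",
) -> RegionalSummary:
    """Peak-systolic SSR summary of one case within the analysis segment."""
    wss = ssr(wall_shear(field, geometry, mu=case.flow.mu_f, t_ms=t_peak_ms))
    quads = quadrant_labels(geometry, convention)
    segs = segment_split(geometry)
    qmeans = quadrant_mean_ssr(wss, quads, segs, segment)
    wanted = (segment,) if isinstance(segment, str) else tuple(segment)
    sel = wss.valid & ~wss.ssr_flagged & np.isin(segs, wanted)
    if not sel.any():
        raise ValueError(f"no valid SSR vertices in segment {segment!r}")
    vals = wss.ssr[sel]
    x, f = cumulative_frequency(vals)
    return RegionalSummary(
        case=case.name,
        group=case.group,
        quadrant_means=qmeans,
        percentile_90=percentile(vals, 90),
        ecdf_x=x,
        ecdf_f=f,
    )


def case_marker_rows(
    case: Case,
    geometry: VesselGeometry,
    fine: VelocityField4D,
    mri: VelocityField4D,
    plane_s_mm: float | None = None,
) -> list[dict]:
    """Plane-marker rows (fine vs MRI-like vs generator truth) for one case.

    The analysis plane sits in the proximal ascending segment (arc-length
    fraction 0.10) unless ``plane_s_mm`` is given: proximal to the helical
    envelope, where the forward-flow maximum is the jet core and the
    generator parameters are exact ground truth (jet offset, jet angle, and
    peak velocity 2*Q_peak/(pi*(R - d)^2)/cos(angle)). Inside the helical
    window the velocity maximum can be swirl-dominated and no closed form
    applies.
    """
    s = 0.10 * geometry.length if plane_s_mm is None else plane_s_mm
    plane = local_frame(geometry, s)
    wf = case.waveform()
    q_peak = wf.flow_m3_s.max()
    r_jet = (geometry.radius_at(s) - case.flow.jet_offset) * 1e-3
    truth = {
        "flow_displacement_mm": case.flow.jet_offset,
        "jet_angle_deg": case.flow.jet_angle_true,
        "max_velocity_m_s": 2 * q_peak / (np.pi * r_jet**2)
        / np.cos(np.radians(case.flow.jet_angle_true)),
    }
    rows = []
    m_fine = plane_markers(fine, plane, plane_id=f"s={s:.0f}mm")
    m_mri = plane_markers(mri, plane, plane_id=f"s={s:.0f}mm")
    for marker in truth:
        rows.append(
            {
                "case": case.name,
                "group": case.group,
                "plane": m_fine.plane_id,
                "marker": marker,
                "value_fine": getattr(m_fine, marker),
                "value_mri": getattr(m_mri, marker),
                "value_truth": truth[marker],
            }
        )
    return rows
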
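#!/usr/bin/env python
"""Build the synthetic study cohort: 4 controls, 4 stable, 4 dilating.

Draws per-case parameters (target PWV within each group's measured range,
helical strength 1x/2x/6x by group, jet offset/angle growing with disease
severity), writes the cohort manifest and, for one example case, the inlet
waveform, centerline and labelled wall surface. Voxel fields are large and
are re-generated on demand by the downstream scripts (an example HDF5 field
goes to scratch/).
"""

import json
import sys
from pathlib import Path

import numpy as np

from aortassr.geometry import quadrant_labels, segment_split
from aortassr.io import (
    write_centerline_csv,
    write_field_hdf5,
    write_stl,
    write_vtk_polydata,
    write_waveform_csv,
)
from aortassr.synthetic import CohortSpec, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=seed)
    cases, manifest = generate_cohort(spec)
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"cohort of {len(cases)} cases (seed {seed}):")
    for c in cases:
        print(
            f"  {c.name:3s} {c.group:8s} target PWV {c.target_pwv:5.2f} m/s, "
            f"jet offset {c.flow.jet_offset:.2f} mm, angle {c.flow.jet_angle_true:.1f} deg, "
            f"helical k {c.flow.helical_strength:.0f} /(m s)"
        )

    example = cases[0]
    geo = example.geometry()
    write_centerline_csv(
        OUT / f"{example.name}_centerline.csv",
        geo.centerline_points, geo.radius, geo.thickness,
    )
    write_waveform_csv(OUT / f"{example.name}_inlet_waveform.csv", example.waveform())
    quads = quadrant_labels(geo, "interior_anterior_exterior_posterior")
    segs = segment_split(geo)
    write_vtk_polydata(
        OUT / f"{example.name}_surface.vtk",
        geo.vertices,
        geo.faces,
        {
            "quadrant_code": np.searchsorted(np.unique(quads), quads).astype(np.int64),
            "segment_code": np.searchsorted(np.unique(segs), segs).astype(np.int64),
            "theta_deg": geo.vertex_theta,
        },
    )
    write_stl(OUT / f"{example.name}_surface.stl", geo.vertices, geo.faces)
    print(f"example case {example.name}: centerline, waveform and surface under {OUT}")

    SCRATCH.mkdir(exist_ok=True)
    _, fine, _ = example.realize(spacing=1.25, frame_times_ms=np.arange(0.0, 250.0, 25.0))
    write_field_hdf5(SCRATCH / f"{example.name}_field_1p25mm.h5", fine)
    print(f"example voxel field (1.25 mm preview) in {SCRATCH}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
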
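"""On-disk formats for waveforms, indentation records, surface fields, images.

Dialects
--------
Waveform CSV: columns ``time_s, p_vent_mmHg, p_ao_mmHg, q_mls``; the cycle
period travels in a JSON sidecar ``<file>.meta.json`` (``{"cycle_period_s"}``).

Indentation CSV: ``time_s, displacement_um, load_uN, segment``.

Surface fields: a directory holding ``nodes.csv`` (x/y/z mm), ``faces.csv``
(n0/n1/n2), ``times.csv`` (time_s) and one ``wss_<k>.csv`` (taux/tauy/tauz,
dynes/cm²) per timestep; plus an optional legacy-VTK ASCII export of the mesh
with per-node TAWSS/OSI scalars for external viewers.

Images: 8-bit grayscale PNG with a JSON sidecar carrying ``mm_per_px`` and
``timestamp_s``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .hydrodynamics import PressureFlowWaveform
from .nanoindentation import IndentationRecord
from .planimetry import OrificeFrame
from .wallshear import WSSSurfaceField

__all__ = [
    "write_waveform_csv",
    "read_waveform_csv",
    "write_indentation_csv",
    "read_indentation_csv",
    "write_surface_dir",
    "read_surface_dir",
    "write_vtk_surface",
    "write_frame_png",
    "read_frame_png",
]


def write_waveform_csv(w: PressureFlowWaveform, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"time_s": w.time, "p_vent_mmHg": w.p_vent, "p_ao_mmHg": w.p_ao, "q_mls": w.q}
    ).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"cycle_period_s": w.cycle_period})
    )


def read_waveform_csv(path, cycle_period: float | None = None) -> PressureFlowWaveform:
    path = Path(path)
    df = pd.read_csv(path)
    if cycle_period is None:
        meta = path.with_suffix(path.suffix + ".meta.json")
        cycle_period = json.loads(meta.read_text())["cycle_period_s"]
    return PressureFlowWaveform(
        time=df["time_s"].to_numpy(),
        p_vent=df["p_vent_mmHg"].to_numpy(),
        p_ao=df["p_ao_mmHg"].to_numpy(),
        q=df["q_mls"].to_numpy(),
        cycle_period=float(cycle_period),
    )


def write_indentation_csv(r: IndentationRecord, path) -> None:
    pd.DataFrame(
        {
            "time_s": r.time,
            "displacement_um": r.displacement,
            "load_uN": r.load,
            "segment": r.segment_labels,
        }
    ).to_csv(path, index=False)


def read_indentation_csv(path) -> IndentationRecord:
    df = pd.read_csv(path)
    return IndentationRecord(
        time=df["time_s"].to_numpy(),
        displacement=df["displacement_um"].to_numpy(),
        load=df["load_uN"].to_numpy(),
        segment_labels=df["segment"].to_numpy(dtype=object),
    )


def write_surface_dir(field: WSSSurfaceField, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(field.nodes, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        d / "nodes.csv", index=False
    )
    pd.DataFrame(field.triangles, columns=["n0", "n1", "n2"]).to_csv(
        d / "faces.csv", index=False
    )
    pd.DataFrame({"time_s": field.times}).to_csv(d / "times.csv", index=False)
    for k in range(field.times.size):
        pd.DataFrame(
            field.wss_vectors[k], columns=["taux", "tauy", "tauz"]
        ).to_csv(d / f"wss_{k}.csv", index=False)


def read_surface_dir(directory) -> WSSSurfaceField:
    d = Path(directory)
    nodes = pd.read_csv(d / "nodes.csv").to_numpy()
    triangles = pd.read_csv(d / "faces.csv").to_numpy()
    times = pd.read_csv(d / "times.csv")["time_s"].to_numpy()
    wss = np.stack(
        [pd.read_csv(d / f"wss_{k}.csv").to_numpy() for k in range(times.size)]
    )
    return WSSSurfaceField(nodes=nodes, triangles=triangles, times=times, wss_vectors=wss)


def write_vtk_surface(field: WSSSurfaceField, path, point_scalars: dict | None = None) -> None:
    """Write the mesh (+ optional per-node scalars) as legacy ASCII VTK polydata."""
    lines = [
        "# vtk DataFile Version 3.0",
        "valvekit leaflet surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(field.nodes)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in field.nodes]
    m = len(field.triangles)
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in field.triangles]
    if point_scalars:
        lines.append(f"POINT_DATA {len(field.nodes)}")
        for name, values in point_scalars.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in np.asarray(values, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_frame_png(frame: OrificeFrame, path) -> None:
    path = Path(path)
    iio.imwrite(path, frame.pixels)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"mm_per_px": frame.mm_per_px, "timestamp_s": frame.timestamp})
    )


def read_frame_png(path, mm_per_px: float | None = None) -> OrificeFrame:
    path = Path(path)
    pixels = iio.imread(path)
    timestamp = 0.0
    sidecar = path.with_suffix(path.suffix + ".json")
    if mm_per_px is None or sidecar.exists():
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        mm_per_px = mm_per_px if mm_per_px is not None else meta["mm_per_px"]
        timestamp = meta.get("timestamp_s", 0.0)
    return OrificeFrame(pixels=pixels, mm_per_px=float(mm_per_px), timestamp=timestamp)
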
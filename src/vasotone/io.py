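"""Output writers: trajectory CSV, VTU field snapshots, JSON run summary."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Mesh

__all__ = ["trajectory_frame", "write_trajectory", "write_vtu",
           "write_summary", "run_summary"]


def trajectory_frame(records) -> pd.DataFrame:
    """Slow-time trajectory as a DataFrame (one row per committed step)."""
    return pd.DataFrame([asdict(r) for r in records])


def write_trajectory(records, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory_frame(records).to_csv(path, index=False)
    return path


def write_vtu(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None,
              displacement: np.ndarray | None = None) -> Path:
    """Minimal ASCII VTU (unstructured grid of quads) writer.

    Region tags are always included as cell data; optional nodal
    ``point_data``/elementwise ``cell_data`` arrays are appended.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    xy = mesh.nodes if displacement is None else mesh.nodes + displacement
    n_pts, n_cel = mesh.n_nodes, mesh.n_elements
    cell_data = {"region": mesh.region.astype(float), **(cell_data or {})}
    point_data = point_data or {}

    def arr(a, per_line=6):
        a = np.asarray(a).ravel()
        return "\n".join(" ".join(f"{v:.10g}" for v in a[i:i + per_line])
                         for i in range(0, len(a), per_line))

    pieces = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cel}">',
        '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(np.column_stack([xy, np.zeros(n_pts)])),
        '</DataArray></Points>',
        '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(mesh.elems, 8),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(4 * np.arange(1, n_cel + 1), 12),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.full(n_cel, 9), 20),  # VTK_QUAD
        '</DataArray>',
        '</Cells>',
    ]
    if point_data:
        pieces.append('<PointData>')
        for name, vals in point_data.items():
            vals = np.asarray(vals)
            ncomp = 1 if vals.ndim == 1 else vals.shape[1]
            pieces += [f'<DataArray type="Float64" Name="{name}" '
                       f'NumberOfComponents="{ncomp}" format="ascii">',
                       arr(vals), '</DataArray>']
        pieces.append('</PointData>')
    pieces.append('<CellData>')
    for name, vals in cell_data.items():
        pieces += [f'<DataArray type="Float64" Name="{name}" format="ascii">',
                   arr(vals), '</DataArray>']
    pieces.append('</CellData>')
    pieces += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    path.write_text("\n".join(pieces))
    return path


def run_summary(records, reference_records=None, config_dict=None) -> dict:
    """JSON-ready run summary; percentage changes vs an optional paired
    reference run computed by the same code path."""
    last = records[-1]
    out = {
        "final": asdict(last),
        "n_slow_steps": len(records),
    }
    if reference_records is not None:
        ref = reference_records[-1]
        amp = last.p_sys - last.p_dia
        amp_ref = ref.p_sys - ref.p_dia
        out["vs_reference_percent"] = {
            "tawss": 100.0 * (last.tau / ref.tau - 1.0),
            "sys_dia_amplitude": 100.0 * (amp / amp_ref - 1.0),
            "mean_pressure": 100.0 * (last.p_mean / ref.p_mean - 1.0),
            "radius_at_mean_pressure": 100.0 * (last.r_mean / ref.r_mean - 1.0),
        }
    if config_dict is not None:
        out["config"] = config_dict
    try:
        from importlib.metadata import version
        out["code_version"] = version("vasotone")
    except Exception:
        out["code_version"] = "unknown"
    return out


def write_summary(summary: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, default=float))
    return path
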
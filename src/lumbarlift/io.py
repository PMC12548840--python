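"""File formats: delimited-text series, VTK legacy meshes, STL, JSON reports.

Marker tables are wide-format TSV (frame, time_s, then LABEL_X/Y/Z in mm);
force-plate tables are (sample, time_s, Fx, Fy, Fz, COPx, COPy).  Numeric
columns are written with 17 significant digits so a write/read round trip
is bitwise exact.  Meshes and stress fields go out as VTK legacy ASCII
unstructured grids (readable by ParaView and read back here for census
checks) and optional STL surfaces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import PhaseSegmentation, TorqueSeries
from .errors import ParseError
from .femodel import LumbarMesh
from .kinematics import AngleSeries

_FLOAT_FMT = "%.17g"


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path, required_columns=()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in required_columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: malformed value near line {row}")
    return df


def write_markers(markers: pd.DataFrame, path) -> Path:
    return write_table(markers, path)


def read_markers(path) -> pd.DataFrame:
    return read_table(path, required_columns=("frame", "time_s"))


def write_grf(grf: pd.DataFrame, path) -> Path:
    return write_table(grf, path)


def read_grf(path) -> pd.DataFrame:
    return read_table(path, required_columns=("sample", "time_s", "Fx", "Fy", "Fz"))


def write_torque(series: TorqueSeries, path) -> Path:
    return write_table(
        pd.DataFrame({"time_s": series.time_s, "torque_Nm": series.torque_Nm}), path
    )


def read_torque(path) -> TorqueSeries:
    df = read_table(path, required_columns=("time_s", "torque_Nm"))
    return TorqueSeries(time_s=df["time_s"].to_numpy(), torque_Nm=df["torque_Nm"].to_numpy())


def write_angles(series: AngleSeries, path) -> Path:
    return write_table(
        pd.DataFrame({"time_s": series.time_s, "flexion_deg": series.flexion_deg}), path
    )


def write_phases(seg: PhaseSegmentation, torque: TorqueSeries, path) -> Path:
    path = Path(path)
    report = [
        {
            "phase": name,
            "start_frame": int(seg.intervals[name][0]),
            "end_frame": int(seg.intervals[name][1]),
            "peak_torque_Nm": float(
                np.max(torque.torque_Nm[seg.intervals[name][0] : seg.intervals[name][1] + 1])
            ),
        }
        for name in seg.PHASES
    ]
    path.write_text(json.dumps(report, indent=2))
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# VTK legacy ASCII


def write_vtk(
    mesh: LumbarMesh,
    path,
    cell_data: dict | None = None,
    point_data: dict | None = None,
) -> Path:
    """Unstructured-grid export: tets + ligament lines with part ids."""
    path = Path(path)
    n_tet, n_line = len(mesh.tets), len(mesh.lines)
    lines = [
        "# vtk DataFile Version 3.0",
        "lumbarlift mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {n_tet + n_line} {5 * n_tet + 3 * n_line}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines += ["2 " + " ".join(map(str, l)) for l in mesh.lines]
    lines.append(f"CELL_TYPES {n_tet + n_line}")
    lines += ["10"] * n_tet + ["3"] * n_line
    lines.append(f"CELL_DATA {n_tet + n_line}")
    part = np.concatenate([mesh.tet_part, mesh.line_part]) if n_line else mesh.tet_part
    lines.append("SCALARS part_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(p)) for p in part]
    for name, values in (cell_data or {}).items():
        vals = np.asarray(values, dtype=float)
        if len(vals) == n_tet:  # pad line cells
            vals = np.concatenate([vals, np.zeros(n_line)])
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in vals]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            vals = np.asarray(values, dtype=float)
            if vals.ndim == 2 and vals.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.9g}" for x in v) for v in vals]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in vals]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_census(path) -> dict:
    """Minimal legacy-VTK reader: point/cell counts and part-id histogram."""
    path = Path(path)
    toks = path.read_text().split("\n")
    n_points = n_cells = None
    part_ids = []
    i = 0
    try:
        while i < len(toks):
            line = toks[i].strip()
            if line.startswith("POINTS"):
                n_points = int(line.split()[1])
            elif line.startswith("CELLS "):
                n_cells = int(line.split()[1])
            elif line.startswith("SCALARS part_id"):
                i += 2  # skip LOOKUP_TABLE
                part_ids = [int(toks[i + k]) for k in range(n_cells)]
                i += n_cells - 1
            i += 1
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed VTK file near line {i + 1}") from exc
    if n_points is None or n_cells is None:
        raise ParseError(f"{path}: not a legacy VTK unstructured grid")
    uniq, counts = (np.unique(part_ids, return_counts=True) if part_ids else ([], []))
    return {
        "points": n_points,
        "cells": n_cells,
        "parts": {int(u): int(c) for u, c in zip(uniq, counts)},
    }


def write_stl(mesh: LumbarMesh, path) -> Path:
    """Outer-surface STL via trimesh (boundary faces of the tet mesh)."""
    import trimesh

    faces = _boundary_faces(mesh.tets)
    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=faces, process=True)
    tm.export(Path(path), file_type="stl_ascii")
    return Path(path)


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    faces = np.vstack(
        [tets[:, [0, 2, 1]], tets[:, [0, 1, 3]], tets[:, [1, 2, 3]], tets[:, [0, 3, 2]]]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]
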
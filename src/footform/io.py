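"""File formats: STL surfaces, an Abaqus-.inp tet-mesh subset, plantar
pressure CSV (plus a loose Pedar-style ASCII export), legacy-VTK unstructured
grids and scalar-mapped PLY surfaces.

Internal ids are 0-based; on-disk .inp ids are 1-based (Abaqus dialect).
"""

from __future__ import annotations

import logging
import os
import re

import numpy as np
import pandas as pd
import trimesh

from .types import ParameterError, PressureSeries, SurfaceMesh, TetMesh

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def write_stl(mesh: SurfaceMesh, path: str, binary: bool = True) -> None:
    """Write a surface as binary (default) or ASCII STL."""
    if mesh.n_triangles == 0:
        raise ParameterError("refusing to write an empty mesh")
    tm = mesh.to_trimesh()
    tm.export(path, file_type="stl" if binary else "stl_ascii")


def read_stl(path: str, label: str | None = None) -> SurfaceMesh:
    """Read an STL surface, welding duplicate vertices at 1e-6 mm.

    STL stores one float32 vertex triple per triangle corner; welding
    restores shared connectivity. Truncated or empty files raise
    :class:`ParseError` with the offending byte size.
    """
    size = os.path.getsize(path)
    try:
        tm = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:
        raise ParseError(f"unreadable STL {path!r} ({size} bytes): {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ParseError(f"STL {path!r} ({size} bytes) contains no triangles")
    tm.merge_vertices(digits_vertex=6)
    return SurfaceMesh(
        np.asarray(tm.vertices, float),
        np.asarray(tm.faces, int),
        label=label or os.path.splitext(os.path.basename(path))[0],
    )


# ---------------------------------------------------------------------------
# Abaqus .inp subset
# ---------------------------------------------------------------------------

def write_inp(mesh: TetMesh, path: str, heading: str = "footform tet mesh") -> None:
    """Write the mesh as an Abaqus-.inp subset: *NODE, *ELEMENT TYPE=C3D4,
    *NSET and *ELSET blocks with 1-based ids."""
    with open(path, "w") as fh:
        fh.write(f"*HEADING\n{heading}\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
        fh.write("*ELEMENT, TYPE=C3D4\n")
        for e, tet in enumerate(mesh.tets, start=1):
            a, b, c, d = (int(v) + 1 for v in tet)
            fh.write(f"{e}, {a}, {b}, {c}, {d}\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            _write_id_lines(fh, np.asarray(ids) + 1)
        for name, ids in mesh.element_sets.items():
            fh.write(f"*ELSET, ELSET={name}\n")
            _write_id_lines(fh, np.asarray(ids) + 1)


def _write_id_lines(fh, ids: np.ndarray, per_line: int = 10) -> None:
    ids = np.asarray(ids, int)
    for i in range(0, len(ids), per_line):
        fh.write(", ".join(str(v) for v in ids[i : i + per_line]) + "\n")


def read_inp(path: str) -> TetMesh:
    """Parse the Abaqus-.inp subset: *NODE, *ELEMENT TYPE=C3D4, *NSET/*ELSET
    (plain and GENERATE forms). Unsupported keywords are skipped with a
    warning; 1-based file ids map to 0-based internal ids (the node-id map is
    kept in ``metadata['inp_node_ids']``)."""
    nodes: dict[int, tuple[float, float, float]] = {}
    elements: list[tuple[int, tuple[int, int, int, int]]] = []
    nsets: dict[str, list[int]] = {}
    elsets: dict[str, list[int]] = {}
    mode = None          # ('node'|'element'|'nset'|'elset'|'skip')
    target: list[int] | None = None
    generate = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                kw = line.split(",")[0].strip().upper()
                opts = {
                    k.strip().upper(): v.strip()
                    for k, v in (
                        p.split("=", 1) for p in line.split(",")[1:] if "=" in p
                    )
                }
                flags = {p.strip().upper() for p in line.split(",")[1:] if "=" not in p}
                generate = "GENERATE" in flags
                if kw == "*NODE":
                    mode = "node"
                elif kw == "*ELEMENT":
                    etype = opts.get("TYPE", "").upper()
                    if etype != "C3D4":
                        log.warning("skipping unsupported element type %s", etype)
                        mode = "skip"
                    else:
                        mode = "element"
                elif kw == "*NSET":
                    name = opts.get("NSET", "")
                    target = nsets.setdefault(name, [])
                    mode = "nset"
                elif kw == "*ELSET":
                    name = opts.get("ELSET", "")
                    target = elsets.setdefault(name, [])
                    mode = "elset"
                else:
                    if kw not in ("*HEADING",):
                        log.warning("skipping unsupported keyword %s", kw)
                    mode = "skip" if kw != "*HEADING" else "heading"
                continue
            if mode in (None, "skip", "heading"):
                continue
            parts = [p for p in re.split(r"[,\s]+", line) if p]
            try:
                if mode == "node":
                    nid = int(parts[0])
                    nodes[nid] = tuple(float(v) for v in parts[1:4])
                elif mode == "element":
                    eid = int(parts[0])
                    conn = tuple(int(v) for v in parts[1:5])
                    elements.append((eid, conn))
                else:
                    vals = [int(v) for v in parts]
                    if generate:
                        first, last = vals[0], vals[1]
                        step = vals[2] if len(vals) > 2 else 1
                        target.extend(range(first, last + 1, step))
                    else:
                        target.extend(vals)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: cannot parse {line!r}") from exc

    if not nodes or not elements:
        raise ParseError(f"{path}: no *NODE / *ELEMENT TYPE=C3D4 data found")

    node_ids = sorted(nodes)
    nid_to_idx = {nid: i for i, nid in enumerate(node_ids)}
    coords = np.array([nodes[n] for n in node_ids])

    elements.sort(key=lambda e: e[0])
    eid_to_idx = {eid: i for i, (eid, _) in enumerate(elements)}
    tets = np.empty((len(elements), 4), int)
    for i, (eid, conn) in enumerate(elements):
        for j, nid in enumerate(conn):
            if nid not in nid_to_idx:
                raise ParseError(
                    f"{path}: element {eid} references unknown node {nid}"
                )
            tets[i, j] = nid_to_idx[nid]

    def map_ids(vals, table, kind, name):
        out = []
        for v in vals:
            if v not in table:
                raise ParseError(f"{path}: set {name!r} references unknown {kind} {v}")
            out.append(table[v])
        return np.asarray(sorted(set(out)), int)

    return TetMesh(
        nodes=coords,
        tets=tets,
        node_sets={k: map_ids(v, nid_to_idx, "node", k) for k, v in nsets.items()},
        element_sets={k: map_ids(v, eid_to_idx, "element", k) for k, v in elsets.items()},
        metadata={
            "inp_node_ids": np.asarray(node_ids),
            "inp_element_ids": np.asarray([e for e, _ in elements]),
        },
    )


# ---------------------------------------------------------------------------
# Pressure CSV
# ---------------------------------------------------------------------------

def write_pressure_csv(series: PressureSeries, path: str) -> None:
    """One row per frame: time_s then row-major cell pressures in kPa.

    Grid geometry travels in '#'-prefixed header comments so the file is
    self-describing.
    """
    rows, cols = series.grid_shape
    with open(path, "w") as fh:
        fh.write(f"# grid_rows={rows}\n# grid_cols={cols}\n")
        fh.write(f"# cell_dy_mm={series.cell_size[0]:.9g}\n")
        fh.write(f"# cell_dx_mm={series.cell_size[1]:.9g}\n")
        fh.write(f"# origin_y_mm={series.origin[0]:.9g}\n")
        fh.write(f"# origin_x_mm={series.origin[1]:.9g}\n")
        for key in ("archetype", "foot_length", "foot_width", "body_mass"):
            if key in series.metadata:
                fh.write(f"# {key}={series.metadata[key]}\n")
        header = ["time_s"] + [
            f"p_r{r}c{c}_kpa" for r in range(rows) for c in range(cols)
        ]
        fh.write(",".join(header) + "\n")
        for t, frame in zip(series.times, series.pressures):
            vals = ",".join(f"{v:.9g}" for v in frame.ravel())
            fh.write(f"{t:.9g},{vals}\n")


def read_pressure_csv(path: str) -> PressureSeries:
    """Read the CSV dialect written by :func:`write_pressure_csv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    try:
        rows = int(meta["grid_rows"])
        cols = int(meta["grid_cols"])
        dy = float(meta["cell_dy_mm"])
        dx = float(meta["cell_dx_mm"])
    except KeyError as exc:
        raise ParseError(f"{path}: missing grid metadata header {exc}") from exc
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    if df.shape[1] != 1 + rows * cols:
        raise ParseError(
            f"{path}: expected {1 + rows * cols} columns, found {df.shape[1]}"
        )
    extra = {
        k: (float(v) if k in ("foot_length", "foot_width", "body_mass") else v)
        for k, v in meta.items()
        if k in ("archetype", "foot_length", "foot_width", "body_mass")
    }
    return PressureSeries(
        times=df.iloc[:, 0].to_numpy(),
        pressures=df.iloc[:, 1:].to_numpy().reshape(-1, rows, cols),
        cell_size=(dy, dx),
        origin=(float(meta.get("origin_y_mm", 0.0)), float(meta.get("origin_x_mm", 0.0))),
        metadata=extra,
    )


def read_pedar_ascii(
    path: str,
    cell_size: tuple[float, float],
    sampling_hz: float = 50.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> PressureSeries:
    """Read a loose Pedar-style ASCII export: one whitespace-separated
    pressure matrix (kPa) per frame, frames separated by blank lines.
    The sensor geometry is not stored in such exports and must be supplied.
    """
    frames: list[np.ndarray] = []
    block: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith(("time", "frame")):
                if block:
                    frames.append(np.asarray(block))
                    block = []
                continue
            try:
                block.append([float(v) for v in re.split(r"[,\s]+", line)])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric row") from exc
    if block:
        frames.append(np.asarray(block))
    if not frames:
        raise ParseError(f"{path}: no pressure frames found")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ParseError(f"{path}: inconsistent frame shapes {shapes}")
    arr = np.stack(frames)
    return PressureSeries(
        times=np.arange(len(frames)) / sampling_hz,
        pressures=arr,
        cell_size=cell_size,
        origin=origin,
        metadata={"source": "pedar_ascii"},
    )


# ---------------------------------------------------------------------------
# VTK / PLY result export
# ---------------------------------------------------------------------------

def write_vtk(
    mesh: TetMesh,
    path: str,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a legacy-ASCII VTK unstructured grid with optional scalar
    cell/point data (for external viewers such as ParaView)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfootform results\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        fh.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for tet in mesh.tets:
            fh.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["10"] * mesh.n_elements) + "\n")

        def scalars(data: dict[str, np.ndarray], n: int, kind: str):
            fh.write(f"{kind} {n}\n")
            for name, vals in data.items():
                vals = np.asarray(vals, float)
                if len(vals) != n:
                    raise ParameterError(f"{name}: wrong data length")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in vals) + "\n")

        if cell_data:
            scalars(cell_data, mesh.n_elements, "CELL_DATA")
        if point_data:
            scalars(point_data, mesh.n_nodes, "POINT_DATA")


def write_ply(
    mesh: SurfaceMesh, path: str, vertex_scalar: np.ndarray | None = None
) -> None:
    """ASCII PLY with an optional per-vertex scalar (property 'quality'),
    e.g. a signed error map for colour mapping in external viewers."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if vertex_scalar is not None:
            if len(vertex_scalar) != mesh.n_vertices:
                raise ParameterError("vertex scalar has wrong length")
            fh.write("property double quality\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i, (x, y, z) in enumerate(mesh.vertices):
            if vertex_scalar is not None:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {vertex_scalar[i]:.9g}\n")
            else:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        for tri in mesh.triangles:
            fh.write("3 " + " ".join(str(int(v)) for v in tri) + "\n")


def write_error_map_csv(path: str, distances: np.ndarray) -> None:
    """Per-vertex error map as CSV (vertex id, signed distance mm)."""
    pd.DataFrame(
        {"vertex": np.arange(len(distances)), "distance_mm": distances}
    ).to_csv(path, index=False)
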
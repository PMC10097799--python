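"""Minimal legacy-ASCII VTK unstructured-grid writer/reader.

Covers exactly what the package exports: hexahedral meshes with scalar cell
data (tissue densities, stimuli, region labels) and scalar point data
(transport fields).  Files round-trip through :func:`read_vtk`.
"""

from __future__ import annotations

import numpy as np

VTK_HEXAHEDRON = 12


def write_vtk(path, nodes, elements, cell_data=None, point_data=None, title="tendonheal fields"):
    nodes = np.asarray(nodes, dtype=float)
    elements = np.asarray(elements, dtype=np.int64)
    cell_data = cell_data or {}
    point_data = point_data or {}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for p in nodes:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write(f"CELLS {len(elements)} {len(elements) * 9}\n")
        for conn in elements:
            fh.write("8 " + " ".join(str(int(i)) for i in conn) + "\n")
        fh.write(f"CELL_TYPES {len(elements)}\n")
        fh.write("\n".join([str(VTK_HEXAHEDRON)] * len(elements)) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {len(elements)}\n")
            for name, values in cell_data.items():
                _write_scalars(fh, name, values)
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, values in point_data.items():
                _write_scalars(fh, name, values)


def _write_scalars(fh, name, values):
    values = np.asarray(values)
    kind = "int" if np.issubdtype(values.dtype, np.integer) else "double"
    fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
    fmt = (lambda v: str(int(v))) if kind == "int" else (lambda v: f"{v:.10g}")
    fh.write("\n".join(fmt(v) for v in values) + "\n")


def read_vtk(path):
    """Read a file written by :func:`write_vtk`.

    Returns ``(nodes, elements, cell_data, point_data)``.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)
    nodes = elements = None
    cell_data: dict[str, np.ndarray] = {}
    point_data: dict[str, np.ndarray] = {}
    current = None
    line = next(it)
    try:
        while True:
            parts = line.split()
            if not parts:
                line = next(it)
                continue
            key = parts[0]
            if key == "POINTS":
                n = int(parts[1])
                nodes = np.array([next(it).split() for _ in range(n)], dtype=float)
            elif key == "CELLS":
                n = int(parts[1])
                elements = np.array([next(it).split()[1:] for _ in range(n)], dtype=np.int64)
            elif key == "CELL_TYPES":
                for _ in range(int(parts[1])):
                    next(it)
            elif key == "CELL_DATA":
                current = cell_data
            elif key == "POINT_DATA":
                current = point_data
            elif key == "SCALARS":
                name, kind = parts[1], parts[2]
                next(it)  # LOOKUP_TABLE line
                n = len(elements) if current is cell_data else len(nodes)
                vals = [next(it) for _ in range(n)]
                current[name] = np.array(vals, dtype=np.int64 if kind == "int" else float)
            line = next(it)
    except StopIteration:
        pass
    return nodes, elements, cell_data, point_data
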
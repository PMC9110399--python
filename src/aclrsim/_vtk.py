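"""Minimal legacy-ASCII VTK unstructured-grid writer/reader.

Supports the two cell types this toolkit exports: triangles (type 5) and
hexahedra (type 12), plus tetrahedra (type 10) for tet grafts.  The files
are plain text and readable by ParaView and standard VTK readers.
"""

from __future__ import annotations

import numpy as np

from .errors import ExportError

_CELL_NODES = {5: 3, 10: 4, 12: 8}


def write_vtk(path, points, cells, cell_type: int, title: str = "aclrsim mesh"):
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    cells = np.asarray(cells, dtype=int)
    if cell_type not in _CELL_NODES:
        raise ExportError(f"unsupported VTK cell type {cell_type}")
    if cells.ndim != 2 or cells.shape[1] != _CELL_NODES[cell_type]:
        raise ExportError("cell connectivity shape does not match cell type")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        n = _CELL_NODES[cell_type]
        fh.write(f"CELLS {len(cells)} {len(cells) * (n + 1)}\n")
        for c in cells:
            fh.write(f"{n} " + " ".join(map(str, c)) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        for _ in range(len(cells)):
            fh.write(f"{cell_type}\n")


def read_vtk(path):
    """Read back a legacy ASCII unstructured grid written by :func:`write_vtk`.

    Returns ``(points, cells, cell_type)``.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        return tokens.index(word)
    i = find("POINTS")
    npts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * npts], dtype=float).reshape(npts, 3)
    i = find("CELLS")
    ncells = int(tokens[i + 1])
    total = int(tokens[i + 2])
    raw = np.array(tokens[i + 3 : i + 3 + total], dtype=int)
    i = find("CELL_TYPES")
    ctype = int(tokens[i + 2])
    per = _CELL_NODES[ctype] + 1
    cells = raw.reshape(ncells, per)[:, 1:]
    return pts, cells, ctype
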
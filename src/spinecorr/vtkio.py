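"""Minimal VTK legacy-ASCII unstructured-grid export (tet4 meshes).

Covers what the reports need: points, tet cells, one vector point field and
scalar cell fields.  A matching reader is provided for round-trip checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk_unstructured", "read_vtk_unstructured"]


def write_vtk_unstructured(
    path,
    points: np.ndarray,
    tets: np.ndarray,
    point_vectors: dict[str, np.ndarray] | None = None,
    cell_scalars: dict[str, np.ndarray] | None = None,
    title: str = "spinecorr output",
) -> None:
    points = np.asarray(points, dtype=float)
    tets = np.asarray(tets, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        for t in tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {len(tets)}\n")
        fh.write("\n".join(["10"] * len(tets)) + "\n")
        if point_vectors:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_vectors.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"VECTORS {name} double\n")
                for v in arr:
                    fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        if cell_scalars:
            fh.write(f"CELL_DATA {len(tets)}\n")
            for name, arr in cell_scalars.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.17g}" for v in arr) + "\n")


def read_vtk_unstructured(path):
    """Parse a file written by :func:`write_vtk_unstructured`."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = lines.index("DATASET UNSTRUCTURED_GRID") + 1
    assert lines[i].startswith("POINTS")
    n_pts = int(lines[i].split()[1])
    pts = np.array([[float(x) for x in lines[i + 1 + k].split()] for k in range(n_pts)])
    i += 1 + n_pts
    assert lines[i].startswith("CELLS")
    n_cells = int(lines[i].split()[1])
    cells = np.array(
        [[int(x) for x in lines[i + 1 + k].split()[1:]] for k in range(n_cells)]
    )
    i += 1 + n_cells
    assert lines[i].startswith("CELL_TYPES")
    types = np.array([int(lines[i + 1 + k]) for k in range(n_cells)])
    i += 1 + n_cells
    point_vectors, cell_scalars = {}, {}
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("POINT_DATA") or ln.startswith("CELL_DATA") or not ln:
            i += 1
            continue
        if ln.startswith("VECTORS"):
            name = ln.split()[1]
            arr = np.array(
                [[float(x) for x in lines[i + 1 + k].split()] for k in range(n_pts)]
            )
            point_vectors[name] = arr
            i += 1 + n_pts
        elif ln.startswith("SCALARS"):
            name = ln.split()[1]
            arr = np.array([float(lines[i + 2 + k]) for k in range(n_cells)])
            cell_scalars[name] = arr
            i += 2 + n_cells
        else:
            i += 1
    return {
        "points": pts,
        "cells": cells,
        "cell_types": types,
        "point_vectors": point_vectors,
        "cell_scalars": cell_scalars,
    }
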
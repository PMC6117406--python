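"""Minimal legacy-ASCII VTK writer for the hexahedral LV mesh.

Writes unstructured grids with optional point data (vectors such as
displacement) and cell data (scalars such as layer index, vectors such as
fiber directions), viewable in ParaView.  Plain text by design.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import LVMesh

__all__ = ["write_vtk"]

_VTK_HEX = 12


def write_vtk(
    path: str | Path,
    mesh: LVMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    displacement: np.ndarray | None = None,
) -> None:
    """Write the mesh (optionally deformed by ``displacement``) as a
    legacy ASCII VTK unstructured grid."""
    pts = mesh.nodes if displacement is None else mesh.nodes + displacement.reshape(-1, 3)
    lines = [
        "# vtk DataFile Version 3.0",
        "lvmech left-ventricle mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in pts]
    ne = mesh.n_elems
    lines.append(f"CELLS {ne} {9 * ne}")
    lines += ["8 " + " ".join(str(i) for i in e) for e in mesh.elems]
    lines.append(f"CELL_TYPES {ne}")
    lines += [str(_VTK_HEX)] * ne

    def emit(data: dict[str, np.ndarray]) -> None:
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)

    if point_data or displacement is not None:
        pd_all = dict(point_data or {})
        if displacement is not None:
            pd_all.setdefault("displacement", displacement.reshape(-1, 3))
        lines.append(f"POINT_DATA {len(pts)}")
        emit(pd_all)
    if cell_data:
        lines.append(f"CELL_DATA {ne}")
        emit(cell_data)
    Path(path).write_text("\n".join(lines) + "\n")
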
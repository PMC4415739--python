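"""Export helpers: legacy ASCII VTK for field maps, CSV for profiles."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fem import FieldSolution
from .field_analysis import LineProfile


def export_vtk(sol: FieldSolution, path: str | Path) -> None:
    """Write the mesh with |phi|, Re(phi) and |E| as a legacy VTK file.

    The legacy ASCII format is readable by ParaView/VisIt and needs no
    extra dependency.
    """
    mesh = sol.mesh
    _, _, emag = sol.electric_field()
    lines = [
        "# vtk DataFile Version 3.0",
        f"cellimp field solution shape={sol.layout.shape} f={sol.f:g} V={sol.V:g}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9e} {y:.9e} 0.0")
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["5"] * mesh.n_elements)
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    for name, data in (
        ("phi_re", sol.phi.real),
        ("phi_abs", np.abs(sol.phi)),
    ):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9e}" for v in data)
    lines.append(f"CELL_DATA {mesh.n_elements}")
    lines.append("SCALARS e_mag double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(f"{v:.9e}" for v in emag)
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(r)) for r in mesh.element_region)
    Path(path).write_text("\n".join(lines) + "\n")


def profile_to_csv(profile: LineProfile, path: str | Path,
                   metadata: dict | None = None) -> None:
    """Write a line profile as CSV with a ``#``-prefixed metadata header."""
    lines = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
    lines.append("position_m,e_mag_v_per_m,region")
    for pos, mag, flag in zip(
        profile.positions, profile.magnitudes, profile.region_flags
    ):
        lines.append(f"{pos:.9e},{mag:.9e},{int(flag)}")
    Path(path).write_text("\n".join(lines) + "\n")
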
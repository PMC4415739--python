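"""Reduction of field solutions to reported scalar quantities.

The study characterises each electrode geometry by the electric-field
magnitude along the axis joining the electrodes (a line profile through
the cell centre) and by field statistics inside the cell versus in the
PBS immediately surrounding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import FieldSolution
from .geometry import RegionLabel


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class LineProfile:
    """|E| sampled along an axis-parallel line through the cell centre.

    ``magnitudes`` is NaN where the sample falls inside electrode metal
    (the field is not defined in a perfect conductor).
    """

    axis: str
    positions: np.ndarray
    magnitudes: np.ndarray
    region_flags: np.ndarray  # RegionLabel codes per sample


@dataclass(frozen=True)
class FieldExtremaReport:
    """Min/max/mean |E| (V/m) inside the cell and in nearby PBS."""

    intracellular_min: float
    intracellular_max: float
    intracellular_mean: float
    extracellular_min: float
    extracellular_max: float
    extracellular_mean: float
    window: float


def _locate_elements(sol: FieldSolution, pts: np.ndarray) -> np.ndarray:
    """Containing-element index per query point (-1 if none).

    Brute force via barycentric coordinates, vectorised over elements in
    chunks; fine for the ~1e3 samples a profile needs.
    """
    mesh = sol.mesh
    tri = mesh.triangles
    p = mesh.nodes[tri]
    out = np.full(len(pts), -1, dtype=int)
    x0, y0 = p[:, 0, 0], p[:, 0, 1]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d2[:, 0] * d1[:, 1]
    eps = 1e-9
    for k, (qx, qy) in enumerate(pts):
        rx, ry = qx - x0, qy - y0
        u = (rx * d2[:, 1] - ry * d2[:, 0]) / det
        v = (ry * d1[:, 0] - rx * d1[:, 1]) / det
        inside = (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
        idx = np.flatnonzero(inside)
        if len(idx):
            out[k] = idx[0]
    return out


def line_profile(
    sol: FieldSolution, axis: str = "x", n_samples: int | None = None
) -> LineProfile:
    """Sample |E| along the ``axis``-parallel line through the cell centre.

    Sampling is dense enough to put at least 200 samples across the cell
    diameter; within each element the P1 field is constant, so the
    profile is piecewise constant.
    """
    if axis not in ("x", "y"):
        raise AnalysisError(f"axis must be 'x' or 'y', got {axis!r}")
    layout = sol.layout
    cx, cy = layout.cell_center
    if axis == "x":
        lo, hi, fixed = -layout.half_width, layout.half_width, cy
    else:
        lo, hi, fixed = -layout.half_height, layout.half_height, cx
    if n_samples is None:
        span = hi - lo
        per_cell = 200 if layout.cell_radius <= 0 else max(
            200, int(np.ceil(200 * span / (2 * layout.cell_radius)))
        )
        n_samples = per_cell + 1
    # offset off the exact axis so samples do not sit on element edges
    # shared by mirror-image triangles
    delta = 1e-3 * sol.mesh.resolution
    coords = np.linspace(lo + 1e-9 * abs(hi), hi - 1e-9 * abs(hi), n_samples)
    if axis == "x":
        pts = np.column_stack([coords, np.full_like(coords, fixed + delta)])
    else:
        pts = np.column_stack([np.full_like(coords, fixed + delta), coords])

    flags = layout.classify(pts[:, 0], pts[:, 1])
    metal = (flags == RegionLabel.ELECTRODE_A) | (flags == RegionLabel.ELECTRODE_B)
    if metal.all():
        raise AnalysisError("profile line lies entirely inside electrode metal")
    _, _, mag = sol.electric_field()
    elem = _locate_elements(sol, pts)
    values = np.full(n_samples, np.nan)
    ok = (elem >= 0) & ~metal
    values[ok] = mag[elem[ok]]
    return LineProfile(axis=axis, positions=coords, magnitudes=values, region_flags=flags)


def field_extrema(
    sol: FieldSolution, window: float = 5e-6, axis_band: float | None = None
) -> FieldExtremaReport:
    """Field statistics inside the cell and in PBS near the cell boundary.

    Intracellular statistics run over the cell elements; extracellular
    statistics over PBS elements whose centroids lie within ``window``
    of the cell boundary (an annular shell).  ``axis_band`` optionally
    restricts both sets to a band of that half-width around the drive
    axis; the default is no band, because for electrode families whose
    metal sits on the drive axis the banded extracellular set would be
    empty (the metal displaces the nearby PBS).
    """
    mesh = sol.mesh
    layout = sol.layout
    if layout.cell_radius <= 0:
        raise AnalysisError("layout has no cell region")
    if window < mesh.resolution:
        raise AnalysisError("window must be at least one element size")
    _, _, mag = sol.electric_field()
    cent = mesh.centroids()
    cx, cy = layout.cell_center
    r = np.hypot(cent[:, 0] - cx, cent[:, 1] - cy)
    if axis_band is None:
        band = np.ones(len(cent), dtype=bool)
    else:
        perp = cent[:, 1] - cy if layout.drive_axis == "x" else cent[:, 0] - cx
        band = np.abs(perp) <= axis_band
    intra = (mesh.element_region == RegionLabel.CELL) & band
    extra = (
        (mesh.element_region == RegionLabel.PBS)
        & band
        & (r > layout.cell_radius)
        & (r <= layout.cell_radius + window)
    )
    if not intra.any() or not extra.any():
        raise AnalysisError("empty element set for field statistics")
    return FieldExtremaReport(
        intracellular_min=float(mag[intra].min()),
        intracellular_max=float(mag[intra].max()),
        intracellular_mean=float(mag[intra].mean()),
        extracellular_min=float(mag[extra].min()),
        extracellular_max=float(mag[extra].max()),
        extracellular_mean=float(mag[extra].mean()),
        window=window,
    )


def intracellular_mean(sol: FieldSolution) -> float:
    """Area-weighted mean |E| over the whole cell disc (V/m)."""
    mesh = sol.mesh
    _, _, mag = sol.electric_field()
    cell = mesh.element_region == RegionLabel.CELL
    if not cell.any():
        raise AnalysisError("layout has no cell region")
    areas = mesh.areas()
    return float((mag[cell] * areas[cell]).sum() / areas[cell].sum())


def intracellular_ratio(sol_a: FieldSolution, sol_b: FieldSolution) -> float:
    """Ratio of mean intracellular |E|, device A over device B.

    Both solutions must share the operating point so the comparison
    isolates the electrode geometry.
    """
    if not np.isclose(sol_a.f, sol_b.f) or not np.isclose(sol_a.V, sol_b.V):
        raise AnalysisError("solutions are at different operating points")
    denom = intracellular_mean(sol_b)
    if denom == 0:
        raise AnalysisError("zero intracellular field in the reference solution")
    return intracellular_mean(sol_a) / denom
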
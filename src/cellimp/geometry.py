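"""Parametric 2-D layouts of the microfluidic single-cell impedance device.

The chamber is a 100 x 100 um square with the origin at its centre.  A
single cell (disc, default radius 10 um) sits at the centre, suspended in
PBS, between a pair of gold electrodes whose facing surfaces are 8 um
apart.  Four electrode families are modelled:

``standard``
    two rectangular fingers approaching tip-to-tip along x;
``cross``
    plus-shaped electrodes: a narrow arm points at the cell and a
    perpendicular crossbar sits at the arm's midpoint, so only the
    narrow arm tip faces the cell;
``circle``
    electrodes whose face is a circular arc concave toward the cell,
    cupping it; the stated gap is the face separation on the drive
    axis;
``parallel``
    two bars above and below the cell, drive axis y, bar length
    matched to the cell so the whole inner face contacts it.

The finger/bar/arc dimensions are parametric defaults of this package,
chosen so the four families reproduce the qualitative behaviour that
distinguishes them (field-strength, impedance and sensitivity
orderings); see ``docs/methods.md`` for the reasoning.

Two further families exist purely as analytic test devices: ``plate``
(electrodes on the whole top and bottom domain edges, closed-form linear
potential) and ``annulus`` (concentric disc/ring electrodes, closed-form
logarithmic potential).

Electrodes are perfect conductors: they are never meshed as material,
only used as Dirichlet boundaries, and where an electrode footprint
overlaps the cell disc the metal wins (the cell is wider than the gap,
so every electrode family contacts the cell directly).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml


class GeometryError(ValueError):
    """Raised for invalid layout parameters."""


class RegionLabel(enum.IntEnum):
    PBS = 0
    CELL = 1
    ELECTRODE_A = 2
    ELECTRODE_B = 3


SHAPES = ("cross", "circle", "parallel", "standard", "plate", "annulus")

_UM = 1e-6

#: Geometric tolerance (m): far below any feature size, far above float
#: rounding of grid coordinates, so points on a region boundary classify
#: into the higher-precedence region deterministically.
_TOL = 1e-12

#: Default dimensions per shape (m).  The gap and cell size are the
#: device's stated dimensions; the remaining finger/bar/arc dimensions
#: are this package's parametric defaults (see docs/methods.md).
_SHAPE_DEFAULTS: dict[str, dict[str, float]] = {
    "standard": {"tip_width": 6 * _UM},
    "cross": {"arm_width": 4 * _UM, "arm_length": 20 * _UM},
    "circle": {"arc_radius": 10 * _UM, "cup_span": 12 * _UM},
    "parallel": {"bar_length": 18 * _UM, "bar_thickness": 10 * _UM},
    "plate": {},
    "annulus": {"inner_radius": 5 * _UM, "outer_radius": 40 * _UM},
}


@dataclass(frozen=True)
class DeviceLayout:
    """Resolved description of one device geometry.

    All lengths in metres, coordinates centred on the chamber midpoint.
    ``drive_voltage`` is the potential applied to electrode A; electrode
    B is grounded.
    """

    shape: str
    width: float = 100 * _UM
    height: float = 100 * _UM
    gap: float = 8 * _UM
    cell_center: tuple[float, float] = (0.0, 0.0)
    cell_radius: float = 10 * _UM
    drive_voltage: float = 1.0
    shape_params: dict[str, float] = field(default_factory=dict)

    # -- derived ----------------------------------------------------------
    @property
    def drive_axis(self) -> str:
        """Axis joining the electrodes: ``y`` for parallel/plate, else ``x``."""
        return "y" if self.shape in ("parallel", "plate") else "x"

    @property
    def half_width(self) -> float:
        return self.width / 2

    @property
    def half_height(self) -> float:
        return self.height / 2

    def param(self, name: str) -> float:
        return self.shape_params[name]

    # -- region predicates (vectorised) ------------------------------------
    def in_domain(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (np.abs(x) <= self.half_width + _TOL) & (
            np.abs(y) <= self.half_height + _TOL
        )

    def in_cell(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.cell_radius <= 0:
            return np.zeros(np.shape(x), dtype=bool)
        cx, cy = self.cell_center
        return (x - cx) ** 2 + (y - cy) ** 2 <= (self.cell_radius + _TOL) ** 2

    def _finger_a(self, x, y, tip_width):
        return (x <= -self.gap / 2 + _TOL) & (np.abs(y) <= tip_width / 2 + _TOL)

    def in_electrode_a(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        p = self.shape_params
        if self.shape == "standard":
            return self._finger_a(x, y, p["tip_width"])
        if self.shape == "cross":
            # plus-shaped electrode: only the narrow arm tip faces the cell
            aw, al = p["arm_width"], p["arm_length"]
            tipx = -self.gap / 2
            arm = (
                (x >= tipx - al - _TOL)
                & (x <= tipx + _TOL)
                & (np.abs(y) <= aw / 2 + _TOL)
            )
            cx = tipx - al / 2
            bar = (
                (x >= cx - aw / 2 - _TOL)
                & (x <= cx + aw / 2 + _TOL)
                & (np.abs(y) <= al / 2 + _TOL)
            )
            return arm | bar
        if self.shape == "circle":
            # cupping arc face: on-axis separation equals the gap
            R, w = p["arc_radius"], p["cup_span"]
            c = R - self.gap / 2
            return (
                (x <= 0.0 + _TOL)
                & (np.abs(y) <= w / 2 + _TOL)
                & ((x - c) ** 2 + y**2 >= (R - _TOL) ** 2)
            )
        if self.shape == "parallel":
            return (
                (np.abs(x) <= p["bar_length"] / 2 + _TOL)
                & (y >= self.gap / 2 - _TOL)
                & (y <= self.gap / 2 + p["bar_thickness"] + _TOL)
            )
        if self.shape == "plate":
            return y >= self.half_height - _TOL
        if self.shape == "annulus":
            return x**2 + y**2 <= (p["inner_radius"] + _TOL) ** 2
        raise GeometryError(f"unknown shape {self.shape!r}")

    def in_electrode_b(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # every family is the mirror image of electrode A through the
        # plane perpendicular to the drive axis
        if self.shape == "annulus":
            r2 = x**2 + y**2
            return (r2 >= (self.param("outer_radius") - _TOL) ** 2) & self.in_domain(x, y)
        if self.drive_axis == "x":
            return self.in_electrode_a(-x, y)
        return self.in_electrode_a(x, -y)

    def classify(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Region code per point; precedence ELECTRODE > CELL > PBS."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(x.shape, dtype=np.uint8)
        out[self.in_cell(x, y)] = RegionLabel.CELL
        out[self.in_electrode_a(x, y)] = RegionLabel.ELECTRODE_A
        out[self.in_electrode_b(x, y)] = RegionLabel.ELECTRODE_B
        return out

    def snap_circles(self) -> list[tuple[float, float, float, float]]:
        """Circles (cx, cy, r, y_band) that the mesher snaps nodes onto.

        ``y_band`` limits snapping to ``|y| <= y_band`` (the circle-shape
        arc is a material boundary only across the finger face).
        """
        inf = float("inf")
        circles: list[tuple[float, float, float, float]] = []
        if self.cell_radius > 0:
            circles.append((*self.cell_center, self.cell_radius, inf))
        if self.shape == "annulus":
            circles.append((0.0, 0.0, self.param("inner_radius"), inf))
            circles.append((0.0, 0.0, self.param("outer_radius"), inf))
        if self.shape == "circle":
            R, w = self.param("arc_radius"), self.param("cup_span")
            c = R - self.gap / 2
            circles.append((c, 0.0, R, w / 2))
            circles.append((-c, 0.0, R, w / 2))
        return circles


def classify_point(layout: DeviceLayout, p: tuple[float, float]) -> RegionLabel:
    """Label a single point; raises outside the chamber."""
    x, y = p
    if not layout.in_domain(np.float64(x), np.float64(y)):
        raise GeometryError(f"point {p} outside the {layout.width:g} m domain")
    return RegionLabel(int(layout.classify(np.float64(x), np.float64(y))))


def build_layout(shape: str, overrides: dict[str, Any] | None = None) -> DeviceLayout:
    """Construct a validated layout for one of the shape families.

    ``overrides`` may set any :class:`DeviceLayout` field plus entries of
    ``shape_params`` directly by name (e.g. ``{"gap": 16e-6}`` or
    ``{"bar_length": 40e-6}``).
    """
    if shape not in SHAPES:
        raise GeometryError(f"unknown shape {shape!r}; expected one of {SHAPES}")
    overrides = dict(overrides or {})
    params = dict(_SHAPE_DEFAULTS[shape])
    for key in list(overrides):
        if key in params:
            params[key] = float(overrides.pop(key))
    layout = DeviceLayout(shape=shape, shape_params=params, **overrides)
    _validate(layout)
    return layout


def _validate(layout: DeviceLayout) -> None:
    if layout.width <= 0 or layout.height <= 0:
        raise GeometryError("domain dimensions must be positive")
    if layout.gap <= 0:
        raise GeometryError(f"electrode gap must be positive, got {layout.gap:g}")
    for name, val in layout.shape_params.items():
        if val <= 0:
            raise GeometryError(f"shape parameter {name} must be positive, got {val:g}")
    cx, cy = layout.cell_center
    if layout.cell_radius > 0 and (
        abs(cx) + layout.cell_radius > layout.half_width
        or abs(cy) + layout.cell_radius > layout.half_height
    ):
        raise GeometryError("cell disc does not fit inside the chamber")
    p = layout.shape_params
    if layout.shape == "circle":
        if p["cup_span"] >= 2 * p["arc_radius"]:
            raise GeometryError("circle cup_span must be smaller than the arc diameter")
        if layout.gap / 2 > p["arc_radius"]:
            raise GeometryError("circle gap exceeds the arc diameter")
        c = p["arc_radius"] - layout.gap / 2
        if c >= math.sqrt(p["arc_radius"] ** 2 - (p["cup_span"] / 2) ** 2):
            raise GeometryError("circle cup corners would cross the device midplane")
    if layout.shape == "annulus":
        if p["inner_radius"] >= p["outer_radius"]:
            raise GeometryError("annulus inner radius must be below outer radius")
    if layout.shape == "cross" and p["arm_width"] >= layout.half_width - layout.gap / 2:
        raise GeometryError("cross arm too deep for the chamber")
    # electrode disjointness: a shared point would short the device
    n = 400
    xs = np.linspace(-layout.half_width, layout.half_width, n)
    ys = np.linspace(-layout.half_height, layout.half_height, n)
    X, Y = np.meshgrid(xs, ys)
    if np.any(layout.in_electrode_a(X, Y) & layout.in_electrode_b(X, Y)):
        raise GeometryError("electrode regions overlap")


def electrode_gap_distance(layout: DeviceLayout, step: float | None = None) -> float:
    """Minimum distance between the two electrode regions.

    Rasterises both regions on a fine grid, extracts their boundary
    pixels and returns the smallest pairwise distance (KD-tree), so it
    works for any shape family without per-shape case analysis.
    """
    from scipy.spatial import cKDTree

    if step is None:
        step = min(layout.gap / 32, 0.25 * _UM)
    xs = np.arange(-layout.half_width, layout.half_width + step / 2, step)
    ys = np.arange(-layout.half_height, layout.half_height + step / 2, step)
    X, Y = np.meshgrid(xs, ys)
    pts = []
    for mask in (layout.in_electrode_a(X, Y), layout.in_electrode_b(X, Y)):
        interior = np.zeros_like(mask)
        interior[1:-1, 1:-1] = (
            mask[1:-1, 1:-1]
            & mask[:-2, 1:-1] & mask[2:, 1:-1]
            & mask[1:-1, :-2] & mask[1:-1, 2:]
        )
        edge = mask & ~interior
        pts.append(np.column_stack([X[edge], Y[edge]]))
    if not len(pts[0]) or not len(pts[1]):
        raise GeometryError("an electrode region is empty")
    d, _ = cKDTree(pts[1]).query(pts[0])
    return float(d.min())


# -- config round trip -----------------------------------------------------

def layout_to_dict(layout: DeviceLayout) -> dict[str, Any]:
    """Fully resolved layout as a plain dict (lengths in um) for provenance."""
    return {
        "shape": layout.shape,
        "width_um": layout.width / _UM,
        "height_um": layout.height / _UM,
        "gap_um": layout.gap / _UM,
        "cell_center_um": [c / _UM for c in layout.cell_center],
        "cell_radius_um": layout.cell_radius / _UM,
        "drive_voltage_V": layout.drive_voltage,
        "shape_params_um": {k: v / _UM for k, v in layout.shape_params.items()},
    }


def layout_from_dict(cfg: dict[str, Any]) -> DeviceLayout:
    overrides: dict[str, Any] = {}
    for key, target in (
        ("width_um", "width"), ("height_um", "height"), ("gap_um", "gap"),
        ("cell_radius_um", "cell_radius"),
    ):
        if key in cfg:
            overrides[target] = float(cfg[key]) * _UM
    if "cell_center_um" in cfg:
        overrides["cell_center"] = tuple(float(c) * _UM for c in cfg["cell_center_um"])
    if "drive_voltage_V" in cfg:
        overrides["drive_voltage"] = float(cfg["drive_voltage_V"])
    for k, v in cfg.get("shape_params_um", {}).items():
        overrides[k] = float(v) * _UM
    return build_layout(cfg["shape"], overrides)


def write_layout(layout: DeviceLayout, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(layout_to_dict(layout), sort_keys=False))


def read_layout(path: str | Path) -> DeviceLayout:
    return layout_from_dict(yaml.safe_load(Path(path).read_text()))


def with_cell_removed(layout: DeviceLayout) -> DeviceLayout:
    """The same device with the cell disc replaced by PBS (cell_radius 0)."""
    return replace(layout, cell_radius=0.0)
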
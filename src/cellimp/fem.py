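"""P1 finite-element solver for the electro-quasistatic potential.

At the operating frequencies of the device (kHz range) magnetic
induction is negligible and the complex potential ``phi`` obeys

    div( kappa grad(phi) ) = 0,      kappa = sigma + j*omega*eps0*eps_r,

with ``phi`` prescribed on the metal electrodes (perfect conductors:
``V`` on electrode A, ``0`` on electrode B) and zero normal current on
the remaining chamber walls (insulating boundary).

The mesh is a structured triangulation of the rectangular chamber with
nodes near curved material boundaries (the cell circle, arc electrode
faces) radially snapped onto them, which restores the O(h^2) accuracy a
boundary-fitted mesh would give.  Elements are labelled by classifying
their centroids; elements inside electrode metal are excluded from the
assembly (the metal is a boundary condition, not a material).  The
complex sparse system is solved by direct LU factorisation, so results
carry no iteration-tolerance ambiguity and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DeviceLayout, RegionLabel


class MeshError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass
class Mesh:
    """Conforming triangulation of a device layout.

    ``triangles`` indexes ``nodes``; ``element_region``/``node_region``
    hold :class:`RegionLabel` codes.  ``active_elements`` marks the
    elements assembled into the PDE (everything outside electrode
    metal); ``dirichlet_a``/``dirichlet_b`` are node masks for the two
    electrode surfaces.
    """

    nodes: np.ndarray            # (N, 2) float
    triangles: np.ndarray        # (M, 3) int
    element_region: np.ndarray   # (M,) uint8
    node_region: np.ndarray      # (N,) uint8
    resolution: float
    layout: DeviceLayout

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def active_elements(self) -> np.ndarray:
        return (self.element_region != RegionLabel.ELECTRODE_A) & (
            self.element_region != RegionLabel.ELECTRODE_B
        )

    @property
    def dirichlet_a(self) -> np.ndarray:
        return self.node_region == RegionLabel.ELECTRODE_A

    @property
    def dirichlet_b(self) -> np.ndarray:
        return self.node_region == RegionLabel.ELECTRODE_B

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)


def generate_mesh(layout: DeviceLayout, resolution: float) -> Mesh:
    """Structured, boundary-snapped triangulation at a target edge length.

    ``resolution`` must resolve the electrode gap (``<= gap/4``).  Each
    grid square is split into two triangles with the diagonal direction
    alternating in a checkerboard, which keeps the mesh mirror-symmetric
    about the domain axes.
    """
    if resolution > layout.gap / 4 + 1e-15:
        raise MeshError(
            f"resolution {resolution:g} m too coarse: must be <= gap/4 "
            f"= {layout.gap / 4:g} m to resolve the electrode gap"
        )
    nx = max(2, round(layout.width / resolution))
    ny = max(2, round(layout.height / resolution))
    hx = layout.width / nx
    hy = layout.height / ny
    # coordinates as exact multiples of the step keep boundary nodes at
    # the same float values as the analytic feature coordinates
    xs = (np.arange(nx + 1) - nx / 2) * hx
    ys = (np.arange(ny + 1) - ny / 2) * hy
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    interior = (
        (np.abs(nodes[:, 0]) < layout.half_width - 1e-15)
        & (np.abs(nodes[:, 1]) < layout.half_height - 1e-15)
    )
    unsnapped = nodes.copy()
    snapped = _snap_to_circles(nodes, layout, 0.45 * min(hx, hy), movable=interior)

    def nid(i, j):  # column i, row j
        return j * (nx + 1) + i

    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    I, J = I.ravel(), J.ravel()
    n00, n10 = nid(I, J), nid(I + 1, J)
    n01, n11 = nid(I, J + 1), nid(I + 1, J + 1)
    even = (I + J) % 2 == 0
    # checkerboard diagonals: even squares split along SW-NE, odd along NW-SE
    t1 = np.where(even[:, None], np.column_stack([n00, n10, n11]),
                  np.column_stack([n00, n10, n01]))
    t2 = np.where(even[:, None], np.column_stack([n00, n11, n01]),
                  np.column_stack([n10, n11, n01]))
    triangles = np.vstack([t1, t2])

    nodes = _revert_degenerate(snapped, nodes, unsnapped, triangles, 0.05 * hx * hy)

    cent = nodes[triangles].mean(axis=1)
    element_region = layout.classify(cent[:, 0], cent[:, 1])
    node_region = layout.classify(nodes[:, 0], nodes[:, 1])
    mesh = Mesh(nodes, triangles, element_region, node_region, resolution, layout)
    if not mesh.dirichlet_a.any() or not mesh.dirichlet_b.any():
        raise MeshError("an electrode carries no mesh nodes at this resolution")
    return mesh


def _snap_to_circles(nodes, layout, max_move, movable):
    """Radially project nodes near snap circles onto them (in place)."""
    snapped = np.zeros(len(nodes), dtype=bool)
    for cx, cy, r, y_band in layout.snap_circles():
        dx = nodes[:, 0] - cx
        dy = nodes[:, 1] - cy
        rho = np.hypot(dx, dy)
        sel = (np.abs(rho - r) < max_move) & (rho > 1e-12) & movable
        if np.isfinite(y_band):
            sel &= np.abs(nodes[:, 1]) <= y_band
        scale = r / rho[sel]
        nodes[sel, 0] = cx + dx[sel] * scale
        nodes[sel, 1] = cy + dy[sel] * scale
        snapped |= sel
    return snapped


def _revert_degenerate(snapped, nodes, unsnapped, triangles, min_area, max_rounds=4):
    """Undo snaps that flattened triangles below the area floor."""
    for _ in range(max_rounds):
        p = nodes[triangles]
        areas = 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )
        bad = areas < min_area
        if not bad.any():
            return nodes
        culprits = np.unique(triangles[bad])
        culprits = culprits[snapped[culprits]]
        if len(culprits) == 0:
            raise MeshError("degenerate triangles not caused by boundary snapping")
        nodes[culprits] = unsnapped[culprits]
        snapped[culprits] = False
    raise MeshError("could not remove degenerate triangles by reverting snaps")


@dataclass
class FieldSolution:
    """Complex nodal potential for one (layout, f, V) operating point."""

    mesh: Mesh
    phi: np.ndarray                     # (N,) complex
    f: float
    V: float
    kappa_map: Mapping[int, complex]    # RegionLabel -> admittivity used
    _K_full: sp.csr_matrix = field(repr=False, default=None)
    _grads: tuple = field(repr=False, default=None)

    @property
    def layout(self) -> DeviceLayout:
        return self.mesh.layout

    def electric_field(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-element complex (Ex, Ey) and real magnitude |E| in V/m.

        ``E = -grad(phi)`` is constant on each P1 element; the magnitude
        combines the complex moduli of the two components.  Entries for
        electrode-metal elements are zero.
        """
        bmat, cmat = self._grads
        tri = self.mesh.triangles
        ph = self.phi[tri]
        Ex = -(bmat * ph).sum(axis=1)
        Ey = -(cmat * ph).sum(axis=1)
        inactive = ~self.mesh.active_elements
        Ex[inactive] = 0.0
        Ey[inactive] = 0.0
        mag = np.sqrt(np.abs(Ex) ** 2 + np.abs(Ey) ** 2)
        return Ex, Ey, mag


def _element_gradients(mesh: Mesh):
    """Shape-function gradient coefficients b, c per element (1/m)."""
    p = mesh.nodes[mesh.triangles]
    x = p[:, :, 0]
    y = p[:, :, 1]
    det = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (
        y[:, 1] - y[:, 0]
    )
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    return b / det[:, None], c / det[:, None], np.abs(det) / 2


def assemble_stiffness(mesh: Mesh, kappa_elem: np.ndarray) -> sp.csr_matrix:
    """Galerkin stiffness K_ij = sum_e kappa_e * int grad(N_i).grad(N_j).

    Only active (non-metal) elements contribute.  ``kappa_elem`` is the
    complex admittivity per element (values on inactive elements are
    ignored).
    """
    act = mesh.active_elements
    b, c, area = _element_gradients(mesh)
    b, c, area = b[act], c[act], area[act]
    tri = mesh.triangles[act]
    coef = (kappa_elem[act] * area)[:, None, None]
    klocal = coef * (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :])
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    K = sp.coo_matrix(
        (klocal.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def kappa_per_element(mesh: Mesh, kappa_map: Mapping[int, complex]) -> np.ndarray:
    """Expand a region->kappa mapping to a per-element complex array."""
    out = np.zeros(mesh.n_elements, dtype=complex)
    for region in (RegionLabel.PBS, RegionLabel.CELL):
        out[mesh.element_region == region] = kappa_map.get(int(region), 0.0)
    return out


def solve_field(
    mesh: Mesh, kappa_map: Mapping[int, complex], V: float, f: float = 0.0
) -> FieldSolution:
    """Solve the quasistatic potential problem on a meshed layout.

    Parameters
    ----------
    mesh
        Output of :func:`generate_mesh`.
    kappa_map
        Complex admittivity per region code, e.g. ``{RegionLabel.PBS:
        kappa_pbs, RegionLabel.CELL: kappa_cell}``.
    V
        Drive voltage on electrode A (electrode B grounded).
    f
        Frequency the admittivities were evaluated at (metadata only).
    """
    for region in (RegionLabel.PBS, RegionLabel.CELL):
        present = np.any(mesh.element_region == region)
        if present and int(region) not in kappa_map:
            raise SolverError(f"no admittivity supplied for region {region.name}")
        if present:
            k = complex(kappa_map[int(region)])
            if not (k.real > 0 or k.imag > 0):
                raise SolverError(f"non-dissipative admittivity {k} for {region.name}")

    kappa_elem = kappa_per_element(mesh, kappa_map)
    K = assemble_stiffness(mesh, kappa_elem)

    phi = np.zeros(mesh.n_nodes, dtype=complex)
    phi[mesh.dirichlet_a] = V
    dirichlet = mesh.dirichlet_a | mesh.dirichlet_b
    used = np.zeros(mesh.n_nodes, dtype=bool)
    used[np.unique(mesh.triangles[mesh.active_elements])] = True
    free = used & ~dirichlet
    if free.sum() == 0:
        raise SolverError("no free unknowns: electrodes cover the whole mesh")

    rhs = -K[free][:, dirichlet] @ phi[dirichlet]
    A = K[free][:, free].tocsc()
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:  # singular factorisation
        raise SolverError(f"sparse LU failed: {exc}") from None
    phi[free] = lu.solve(rhs)
    if not np.all(np.isfinite(phi)):
        raise SolverError("solver produced non-finite potentials")

    b, c, _ = _element_gradients(mesh)
    return FieldSolution(
        mesh=mesh, phi=phi, f=f, V=V, kappa_map=dict(kappa_map),
        _K_full=K, _grads=(b, c),
    )
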
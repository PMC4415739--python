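"""Synthetic devices and material tables with known analytic behaviour.

Every stage of the package is testable without the packaged cell
tables:

``plate``
    homogeneous medium between full-width plate electrodes; the
    potential is exactly linear and ``Z = g / (kappa * w * depth)``.
``annulus``
    concentric electrodes (disc radius ``a``, ring at ``b``) in a
    homogeneous medium; ``phi(r) = V * ln(b/r)/ln(b/a)`` and
    ``I = 2*pi*kappa*V / ln(b/a)`` per unit depth.
``homogeneous_cell``
    a regular device whose cell is assigned the PBS admittivity — the
    null-contrast control in which sensitivity must vanish.
``synthetic_tables``
    (f, V) material grids generated from a smooth parametric law
    ``sigma = sigma0 * (f/f0)^a * exp(b*V)``, ``eps_r = eps0``, written
    in the standard CSV dialect; monotone by construction, so they pass
    table validation and exercise interpolation with a known ground
    truth.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np

from . import materials
from .geometry import DeviceLayout, build_layout
from .impedance import CircuitModel, ImpedanceSpectrum, circuit_impedance


class FixtureError(ValueError):
    pass


def plate_fixture(
    kappa: complex = materials.PBS_SIGMA + 0j,
    depth: float = 1.0,
    width: float = 100e-6,
    height: float = 100e-6,
) -> tuple[DeviceLayout, complex, complex]:
    """Plate-electrode device; returns (layout, kappa, reference Z).

    ``height`` is the plate separation (the slab thickness), ``width``
    the plate extent, so ``Z = height / (kappa * width * depth)``.
    """
    layout = build_layout(
        "plate", {"cell_radius": 0.0, "width": width, "height": height,
                  "gap": height},
    )
    z_ref = layout.height / (kappa * layout.width * depth)
    return layout, kappa, z_ref


def annulus_fixture(
    kappa: complex = materials.PBS_SIGMA + 0j,
    inner_radius: float = 5e-6,
    outer_radius: float = 40e-6,
    depth: float = 1.0,
) -> tuple[DeviceLayout, complex, complex]:
    """Concentric-electrode device; returns (layout, kappa, reference Z)."""
    layout = build_layout(
        "annulus",
        {"cell_radius": 0.0, "inner_radius": inner_radius,
         "outer_radius": outer_radius, "gap": outer_radius - inner_radius},
    )
    z_ref = math.log(outer_radius / inner_radius) / (2 * math.pi * kappa * depth)
    return layout, kappa, z_ref


def annulus_potential(layout: DeviceLayout, r: np.ndarray, V: float) -> np.ndarray:
    """Closed-form annulus potential at radius ``r`` for drive ``V``."""
    a = layout.param("inner_radius")
    b = layout.param("outer_radius")
    return V * np.log(b / np.clip(r, a, b)) / math.log(b / a)


def homogeneous_cell_kappa_map(f: float) -> dict[int, complex]:
    """Region->kappa map with the cell set equal to PBS (null contrast)."""
    kappa = materials.complex_admittivity(materials.PBS, f)
    return {0: kappa, 1: kappa}


def synthetic_tables(
    sigma0: float = 1e-4,
    a: float = 1.0,
    b: float = 2.0,
    eps0: float = 5e3,
    freqs_hz: np.ndarray | None = None,
    volts: np.ndarray | None = None,
) -> tuple[materials.CellDielectricTable, materials.CellDielectricTable]:
    """Material grids from the parametric law (see module docstring)."""
    if sigma0 <= 0 or eps0 < 1 or a < 0:
        raise FixtureError("need sigma0 > 0, eps0 >= 1 and a >= 0")
    if freqs_hz is None:
        freqs_hz = np.arange(5e3, 105e3, 5e3)
    if volts is None:
        volts = np.round(np.arange(0.1, 1.05, 0.1), 10)
    f0 = float(freqs_hz[0])
    F, V = np.meshgrid(freqs_hz, volts, indexing="ij")
    sigma = sigma0 * (F / f0) ** a * np.exp(b * V)
    eps = np.full_like(sigma, float(eps0))
    s_tab = materials.CellDielectricTable(
        freqs=np.asarray(freqs_hz, float), volts=np.asarray(volts, float),
        values=sigma, kind="conductivity",
    )
    e_tab = materials.CellDielectricTable(
        freqs=np.asarray(freqs_hz, float), volts=np.asarray(volts, float),
        values=eps, kind="permittivity",
    )
    return s_tab, e_tab


def synthetic_spectrum(
    model: CircuitModel,
    freqs: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int | None = None,
    shape: str = "synthetic",
    V: float = 0.1,
) -> ImpedanceSpectrum:
    """Spectrum generated from a known circuit, optionally noisy.

    ``noise`` is the relative scale of multiplicative complex
    perturbations; it requires an explicit ``seed`` (the only random
    element in the package).
    """
    if freqs is None:
        freqs = np.logspace(2, 8, 25)
    z = np.asarray(circuit_impedance(model, freqs), dtype=complex)
    if noise > 0:
        if seed is None:
            raise FixtureError("noisy spectra require an explicit seed")
        rng = np.random.default_rng(seed)
        z = z * (1.0 + noise * rng.standard_normal(len(z))) * np.exp(
            1j * noise * rng.standard_normal(len(z))
        )
    return ImpedanceSpectrum(shape=shape, V=V, freqs=np.asarray(freqs, float), Z=z)


def make_fixture(kind: str, params: dict[str, Any] | None = None,
                 outdir: str | Path | None = None) -> dict[str, Any]:
    """Build a named fixture; optionally write its files under ``outdir``.

    Returns a metadata dict including any closed-form reference values.
    """
    from .geometry import layout_to_dict, write_layout

    params = dict(params or {})
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if kind == "plate":
        depth = float(params.pop("depth", 1.0))
        kappa = complex(params.pop("kappa", materials.PBS_SIGMA))
        layout, kappa, z_ref = plate_fixture(kappa, depth)
        meta = {
            "kind": kind, "layout": layout_to_dict(layout), "depth_m": depth,
            "kappa": [kappa.real, kappa.imag],
            "reference_Z_ohm": [z_ref.real, z_ref.imag],
        }
    elif kind == "annulus":
        depth = float(params.pop("depth", 1.0))
        kappa = complex(params.pop("kappa", materials.PBS_SIGMA))
        layout, kappa, z_ref = annulus_fixture(kappa, depth=depth, **params)
        meta = {
            "kind": kind, "layout": layout_to_dict(layout), "depth_m": depth,
            "kappa": [kappa.real, kappa.imag],
            "reference_Z_ohm": [z_ref.real, z_ref.imag],
        }
    elif kind == "homogeneous_cell":
        layout = build_layout(params.pop("shape", "parallel"), params)
        meta = {
            "kind": kind, "layout": layout_to_dict(layout),
            "note": "cell admittivity equals PBS; expected sensitivity 0",
        }
    elif kind == "synthetic_tables":
        s_tab, e_tab = synthetic_tables(**params)
        meta = {"kind": kind, "law": "sigma = sigma0*(f/f0)^a*exp(b*V); eps_r = eps0",
                "params": params}
        if outdir is not None:
            materials.write_cell_table(s_tab, outdir / "synthetic_conductivity.csv")
            materials.write_cell_table(e_tab, outdir / "synthetic_permittivity.csv")
            meta["files"] = ["synthetic_conductivity.csv", "synthetic_permittivity.csv"]
    else:
        raise FixtureError(f"unknown fixture kind {kind!r}")

    if outdir is not None:
        if kind in ("plate", "annulus", "homogeneous_cell"):
            write_layout(layout, outdir / "layout.yaml")
        (outdir / "fixture.json").write_text(json.dumps(meta, indent=2))
    return meta
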
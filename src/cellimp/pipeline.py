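"""Study orchestration: sweep the (shape, f, V) grid end to end.

For every grid point the pipeline builds the layout, looks up the cell
dielectric properties, meshes, solves the quasistatic field with the
cell present — and, when sensitivity is requested, again with the cell
disc replaced by PBS — then reduces the solutions to impedance, field
statistics and sensitivity.  Without-cell impedance does not depend on
the drive voltage (the PDE is linear per operating point; voltage
nonlinearity enters only through the cell tables), so it is solved once
per (shape, frequency) and shared across voltages.

Everything is deterministic: identical configurations produce
bit-identical output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from . import materials
from .fem import generate_mesh, solve_field
from .field_analysis import field_extrema
from .geometry import RegionLabel, build_layout, layout_to_dict
from .impedance import fem_impedance, magnitude_phase

log = logging.getLogger("cellimp")

DEFAULT_FREQS = (5e3, 10e3, 20e3, 30e3, 40e3, 50e3, 60e3, 70e3, 80e3, 90e3, 100e3)
DEFAULT_VOLTS = tuple(round(0.1 * k, 1) for k in range(1, 11))
ALL_SHAPES = ("cross", "circle", "parallel", "standard")


class PipelineError(ValueError):
    pass


@dataclass
class SweepConfig:
    """Resolved configuration of one study run (SI units internally)."""

    shapes: tuple[str, ...] = ALL_SHAPES
    frequencies: tuple[float, ...] = DEFAULT_FREQS
    voltages: tuple[float, ...] = DEFAULT_VOLTS
    resolution: float = 1e-6
    depth: float = 20e-6  # out-of-plane chamber depth (= cell diameter)
    window: float = 5e-6
    with_sensitivity: bool = True
    with_extrema: bool = True
    policy: materials.InterpPolicy = "strict"
    sigma_table: str | None = None   # CSV path; None -> packaged table
    eps_table: str | None = None
    layout_overrides: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.shapes:
            raise PipelineError("config lists no electrode shapes")
        if not self.frequencies or not self.voltages:
            raise PipelineError("config lists no frequencies or voltages")
        bad = [s for s in self.shapes if s not in ALL_SHAPES]
        if bad:
            raise PipelineError(f"unknown shapes {bad}; expected subset of {ALL_SHAPES}")
        if self.resolution <= 0 or self.depth <= 0 or self.window <= 0:
            raise PipelineError("resolution, depth and window must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "SweepConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key in ("shapes", "frequencies", "voltages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "shapes": list(self.shapes),
            "frequencies_hz": list(self.frequencies),
            "voltages_v": list(self.voltages),
            "resolution_m": self.resolution,
            "depth_m": self.depth,
            "window_m": self.window,
            "with_sensitivity": self.with_sensitivity,
            "with_extrema": self.with_extrema,
            "policy": self.policy,
            "sigma_table": self.sigma_table,
            "eps_table": self.eps_table,
            "layout_overrides": dict(self.layout_overrides),
        }


@dataclass
class StudyReport:
    """All tabular outputs of one sweep plus provenance."""

    spectra: pd.DataFrame          # with-cell impedance per (shape, V, f)
    solution_spectra: pd.DataFrame # without-cell impedance per (shape, f)
    extrema: pd.DataFrame
    sensitivity: pd.DataFrame
    errors: pd.DataFrame
    provenance: dict[str, Any]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.spectra.to_csv(outdir / "spectra.csv", index=False)
        self.solution_spectra.to_csv(outdir / "solution_spectra.csv", index=False)
        self.extrema.to_csv(outdir / "field_extrema.csv", index=False)
        self.sensitivity.to_csv(outdir / "sensitivity.csv", index=False)
        self.errors.to_csv(outdir / "errors.csv", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )


def _load_tables(cfg: SweepConfig):
    if cfg.sigma_table is None and cfg.eps_table is None:
        return materials.load_hela_tables()
    if cfg.sigma_table is None or cfg.eps_table is None:
        raise PipelineError("supply both material tables or neither")
    return (
        materials.load_cell_table(cfg.sigma_table, "conductivity"),
        materials.load_cell_table(cfg.eps_table, "permittivity"),
    )


def run_study(cfg: SweepConfig) -> StudyReport:
    """Execute the full sweep described by ``cfg``.

    A failure at one grid point is logged with its cause and recorded in
    the report's ``errors`` table; the remaining grid points still run.
    """
    sigma_tab, eps_tab = _load_tables(cfg)
    spectra_rows: list[dict] = []
    solution_rows: list[dict] = []
    extrema_rows: list[dict] = []
    sens_rows: list[dict] = []
    error_rows: list[dict] = []
    t0 = time.perf_counter()

    for shape in cfg.shapes:
        layout = build_layout(shape, dict(cfg.layout_overrides))
        mesh = generate_mesh(layout, cfg.resolution)
        log.info("%s: meshed %d nodes / %d elements", shape, mesh.n_nodes,
                 mesh.n_elements)

        z_solution: dict[float, float] = {}
        for f in cfg.frequencies:
            kappa_pbs = materials.complex_admittivity(materials.PBS, f)
            if cfg.with_sensitivity:
                try:
                    sol0 = solve_field(
                        mesh,
                        {int(RegionLabel.PBS): kappa_pbs,
                         int(RegionLabel.CELL): kappa_pbs},
                        V=1.0, f=f,
                    )
                    z0 = fem_impedance(sol0, cfg.depth)
                    mag0, ph0 = magnitude_phase(z0)
                    z_solution[f] = mag0
                    solution_rows.append({
                        "shape": shape, "f_hz": f, "Z_real": z0.real,
                        "Z_imag": z0.imag, "mag_ohm": mag0, "phase_deg": ph0,
                    })
                except Exception as exc:  # logged, grid point marked missing
                    log.error("%s f=%g without-cell failed: %s", shape, f, exc)
                    error_rows.append({"shape": shape, "f_hz": f, "V": None,
                                       "stage": "without_cell", "error": str(exc)})

            for V in cfg.voltages:
                try:
                    props = materials.cell_properties(
                        sigma_tab, eps_tab, f, V, cfg.policy
                    )
                    kappa_cell = materials.complex_admittivity(props, f)
                    sol = solve_field(
                        mesh,
                        {int(RegionLabel.PBS): kappa_pbs,
                         int(RegionLabel.CELL): kappa_cell},
                        V=V, f=f,
                    )
                    z = fem_impedance(sol, cfg.depth)
                    mag, ph = magnitude_phase(z)
                    spectra_rows.append({
                        "shape": shape, "V": V, "f_hz": f, "Z_real": z.real,
                        "Z_imag": z.imag, "mag_ohm": mag, "phase_deg": ph,
                    })
                    if cfg.with_extrema:
                        rep = field_extrema(sol, cfg.window)
                        extrema_rows.append({
                            "shape": shape, "V": V, "f_hz": f,
                            "intra_min": rep.intracellular_min,
                            "intra_max": rep.intracellular_max,
                            "intra_mean": rep.intracellular_mean,
                            "extra_min": rep.extracellular_min,
                            "extra_max": rep.extracellular_max,
                            "extra_mean": rep.extracellular_mean,
                        })
                    if cfg.with_sensitivity and f in z_solution:
                        sens_rows.append({
                            "shape": shape, "V": V, "f_hz": f,
                            "Z_solution_mag": z_solution[f],
                            "Z_cell_mag": mag,
                            "sensitivity": (z_solution[f] - mag) / z_solution[f],
                        })
                except Exception as exc:
                    log.error("%s f=%g V=%g failed: %s", shape, f, V, exc)
                    error_rows.append({"shape": shape, "f_hz": f, "V": V,
                                       "stage": "with_cell", "error": str(exc)})

    provenance = {
        "package_version": _pkg_version,
        "config": cfg.to_dict(),
        "layouts": {s: layout_to_dict(build_layout(s, dict(cfg.layout_overrides)))
                    for s in cfg.shapes},
        "runtime_s": round(time.perf_counter() - t0, 3),
        "n_with_cell_solves": len(spectra_rows),
        "n_without_cell_solves": len(solution_rows),
    }
    return StudyReport(
        spectra=pd.DataFrame(spectra_rows),
        solution_spectra=pd.DataFrame(solution_rows),
        extrema=pd.DataFrame(extrema_rows),
        sensitivity=pd.DataFrame(sens_rows),
        errors=pd.DataFrame(error_rows),
        provenance=provenance,
    )
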
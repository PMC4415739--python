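"""Dielectric material model for the single-cell impedance device.

The suspension medium (phosphate-buffered saline, PBS) is described by a
single frequency-independent conductivity/permittivity pair.  The cell is
described empirically: measured conductivity ``sigma(f, V)`` and relative
permittivity ``eps_r(f, V)`` tables over a frequency x operating-voltage
grid.  The voltage dependence captures field-induced nonlinearity of the
membrane (stronger drive opens ion channels and raises the apparent
cytoplasm conductivity); within one ``(f, V)`` operating point the
governing PDE stays linear and the material enters it only through the
complex admittivity ``kappa = sigma + j*omega*eps0*eps_r``.

Tables follow a fixed CSV dialect: first column = frequency in kHz,
header row = operating voltage in V, cells = sigma in S/m (conductivity
table) or dimensionless eps_r (permittivity table).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

EPS0 = 8.8541878128e-12
"""Vacuum permittivity (F/m)."""

#: PBS conductivity (S/m) and relative permittivity used throughout the
#: study.  The conductivity is the literature value adopted for this
#: device model; users with a different buffer substitute their own
#: :class:`MediumProperties` (see ``docs/methods.md`` for discussion).
PBS_SIGMA = 2e-6
PBS_EPS_R = 136.0

InterpPolicy = Literal["strict", "clamp", "extrapolate"]


class MaterialTableError(ValueError):
    """Raised when a material table file is malformed."""


class RangeError(ValueError):
    """Raised when a lookup falls outside the tabulated (f, V) hull."""


@dataclass(frozen=True)
class MediumProperties:
    """Isotropic dielectric description of one medium.

    Parameters
    ----------
    sigma
        Conductivity in S/m, ``>= 0``.
    eps_r
        Relative permittivity, ``>= 1``.
    """

    sigma: float
    eps_r: float

    def __post_init__(self) -> None:
        if not (self.sigma >= 0):
            raise ValueError(f"conductivity must be >= 0, got {self.sigma}")
        if not (self.eps_r >= 1):
            raise ValueError(f"relative permittivity must be >= 1, got {self.eps_r}")


PBS = MediumProperties(sigma=PBS_SIGMA, eps_r=PBS_EPS_R)


def complex_admittivity(props: MediumProperties, f: float) -> complex:
    """Complex admittivity ``kappa = sigma + j*2*pi*f*eps0*eps_r`` (S/m).

    This is the single material coefficient of the electro-quasistatic
    potential equation ``div(kappa grad(phi)) = 0``: the real part carries
    conduction current, the imaginary part displacement current.

    Parameters
    ----------
    props
        Medium description.
    f
        Frequency in Hz, ``>= 0``.
    """
    if f < 0:
        raise ValueError(f"frequency must be >= 0, got {f}")
    return complex(props.sigma, 2.0 * math.pi * f * EPS0 * props.eps_r)


_NUM_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.\d*)?|[+-]?\.\d+)\s*(?:[eE]\s*([+-]?\s*\d+)"
    r"|(?:[x×✕]\s*10\s*\^?\s*([+-−]?\s*\d+)))?\s*$"
)


def parse_number(token: str) -> float:
    """Parse a table cell in either plain/E notation or ``a x 10^n`` notation.

    Accepts e.g. ``2.25e-4``, ``1.06E - 02``, ``2.25 x 10^-4`` and the
    unicode multiplication-sign / minus-sign variants that appear in
    typeset tables.
    """
    token = token.strip().replace("−", "-")
    m = _NUM_RE.match(token)
    if m is None:
        raise MaterialTableError(f"cannot parse numeric cell {token!r}")
    exp_txt = m.group(2) or m.group(3) or "0"
    # compose a plain literal so float() does the (correctly rounded) work
    return float(f"{m.group(1)}e{exp_txt.replace(' ', '')}")


@dataclass(frozen=True)
class CellDielectricTable:
    """One measured cell property tabulated on a frequency x voltage grid.

    Attributes
    ----------
    freqs
        Strictly increasing frequencies in Hz.
    volts
        Strictly increasing operating voltages in V.
    values
        2-D array indexed ``[freq, volt]`` (S/m or dimensionless).
    kind
        ``"conductivity"`` or ``"permittivity"``; controls validation
        bounds (sigma > 0 vs eps_r >= 1).
    """

    freqs: np.ndarray
    volts: np.ndarray
    values: np.ndarray
    kind: Literal["conductivity", "permittivity"] = "conductivity"
    monotonicity_violations: tuple[str, ...] = field(default=(), compare=False)

    @property
    def f_min(self) -> float:
        return float(self.freqs[0])

    @property
    def f_max(self) -> float:
        return float(self.freqs[-1])

    @property
    def v_min(self) -> float:
        return float(self.volts[0])

    @property
    def v_max(self) -> float:
        return float(self.volts[-1])

    def lookup(self, f: float, V: float, policy: InterpPolicy = "strict") -> float:
        """Value at ``(f, V)``: exact on grid nodes, bilinear in between.

        ``policy`` controls behaviour outside the tabulated hull:

        ``"strict"``
            raise :class:`RangeError`.  This is the default because the
            table is empirical and, below its lowest frequency, electrode
            double-layer effects make any extension physically dubious.
        ``"clamp"``
            clamp ``f`` and ``V`` to the grid edges.
        ``"extrapolate"``
            clamp ``V``, but extrapolate in frequency from the two
            nearest grid rows: log-log (power law) for conductivity,
            log-linear for permittivity.
        """
        f = float(f)
        V = float(V)
        out_f = f < self.f_min or f > self.f_max
        out_v = V < self.v_min or V > self.v_max
        if policy == "strict" and (out_f or out_v):
            raise RangeError(
                f"({f:g} Hz, {V:g} V) outside tabulated range "
                f"[{self.f_min:g}, {self.f_max:g}] Hz x "
                f"[{self.v_min:g}, {self.v_max:g}] V; "
                "pass policy='clamp' or 'extrapolate' to override"
            )
        V = min(max(V, self.v_min), self.v_max)
        if out_f and policy == "extrapolate":
            return self._extrapolate_f(f, V)
        f = min(max(f, self.f_min), self.f_max)
        i = int(np.searchsorted(self.freqs, f, side="right") - 1)
        i = min(max(i, 0), len(self.freqs) - 2) if len(self.freqs) > 1 else 0
        j = int(np.searchsorted(self.volts, V, side="right") - 1)
        j = min(max(j, 0), len(self.volts) - 2) if len(self.volts) > 1 else 0
        f0, f1 = self.freqs[i], self.freqs[i + 1]
        v0, v1 = self.volts[j], self.volts[j + 1]
        tf = 0.0 if f1 == f0 else (f - f0) / (f1 - f0)
        tv = 0.0 if v1 == v0 else (V - v0) / (v1 - v0)
        z = self.values
        return float(
            (1 - tf) * (1 - tv) * z[i, j]
            + tf * (1 - tv) * z[i + 1, j]
            + (1 - tf) * tv * z[i, j + 1]
            + tf * tv * z[i + 1, j + 1]
        )

    def _extrapolate_f(self, f: float, V: float) -> float:
        # two grid rows nearest the out-of-range side anchor the trend
        if f < self.f_min:
            fa, fb = float(self.freqs[0]), float(self.freqs[1])
        else:
            fa, fb = float(self.freqs[-2]), float(self.freqs[-1])
        ya = self.lookup(fa, V, policy="clamp")
        yb = self.lookup(fb, V, policy="clamp")
        t = (math.log(f) - math.log(fa)) / (math.log(fb) - math.log(fa))
        if self.kind == "conductivity":
            return math.exp((1 - t) * math.log(ya) + t * math.log(yb))
        return (1 - t) * ya + t * yb


def _validate_grid(
    freqs: np.ndarray,
    volts: np.ndarray,
    values: np.ndarray,
    kind: str,
    source: str,
) -> tuple[str, ...]:
    if freqs.ndim != 1 or volts.ndim != 1:
        raise MaterialTableError(f"{source}: axes must be one-dimensional")
    if values.shape != (len(freqs), len(volts)):
        raise MaterialTableError(
            f"{source}: grid shape {values.shape} does not match "
            f"{len(freqs)} frequencies x {len(volts)} voltages"
        )
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise MaterialTableError(
            f"{source}: missing/non-numeric cell at row {i + 1} (f = "
            f"{freqs[i] / 1e3:g} kHz), column {j + 1} (V = {volts[j]:g} V)"
        )
    for name, ax in (("frequency", freqs), ("voltage", volts)):
        if len(ax) < 2 or np.any(np.diff(ax) <= 0):
            raise MaterialTableError(
                f"{source}: {name} axis must be strictly increasing "
                f"with at least two entries"
            )
    lo = 0.0 if kind == "conductivity" else 1.0
    if np.any(values <= lo) if kind == "conductivity" else np.any(values < lo):
        i, j = map(int, np.argwhere(values <= lo if kind == "conductivity" else values < lo)[0])
        raise MaterialTableError(
            f"{source}: {kind} value {values[i, j]:g} out of physical range "
            f"at f = {freqs[i] / 1e3:g} kHz, V = {volts[j]:g} V"
        )
    # Monotone trends (sigma rising with f and with V) hold throughout the
    # packaged cell table; for user tables a violation is reported, not fixed.
    violations: list[str] = []
    if kind == "conductivity":
        for j in range(len(volts)):
            if np.any(np.diff(values[:, j]) < 0):
                violations.append(f"sigma not non-decreasing in f at V = {volts[j]:g} V")
        for i in range(len(freqs)):
            if np.any(np.diff(values[i, :]) < 0):
                violations.append(
                    f"sigma not non-decreasing in V at f = {freqs[i] / 1e3:g} kHz"
                )
    return tuple(violations)


def load_cell_table(
    path: str | Path,
    kind: Literal["conductivity", "permittivity"] = "conductivity",
) -> CellDielectricTable:
    """Load and validate a cell property table from its CSV dialect.

    First column = frequency in kHz, header row = voltages in V.  Any
    ragged row, non-numeric or missing cell, or unsorted axis raises
    :class:`MaterialTableError` naming the offending row/column.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise MaterialTableError(f"{path.name}: need a header row and data rows")
    header = lines[0].split(",")
    try:
        volts = np.array([parse_number(tok) for tok in header[1:]])
    except MaterialTableError as exc:
        raise MaterialTableError(f"{path.name}: bad voltage header: {exc}") from None
    freqs = []
    rows = []
    for r, ln in enumerate(lines[1:], start=2):
        toks = ln.split(",")
        if len(toks) != len(header):
            raise MaterialTableError(
                f"{path.name}: row {r} has {len(toks) - 1} cells, "
                f"expected {len(header) - 1}"
            )
        try:
            freqs.append(parse_number(toks[0]) * 1e3)  # kHz -> Hz
            rows.append([parse_number(t) for t in toks[1:]])
        except MaterialTableError as exc:
            raise MaterialTableError(f"{path.name}: row {r}: {exc}") from None
    freqs_arr = np.array(freqs)
    values = np.array(rows)
    violations = _validate_grid(freqs_arr, volts, values, kind, path.name)
    return CellDielectricTable(
        freqs=freqs_arr, volts=volts, values=values, kind=kind,
        monotonicity_violations=violations,
    )


def write_cell_table(table: CellDielectricTable, path: str | Path) -> None:
    """Write a table back to the CSV dialect (kHz rows, V columns).

    Uses ``repr``-precision floats so that a load/write/load round trip
    reproduces every grid value bit-exactly.
    """
    path = Path(path)
    out = ["freq_khz," + ",".join(repr(float(v)) for v in table.volts)]
    for i, f in enumerate(table.freqs):
        out.append(
            repr(float(f) / 1e3)
            + ","
            + ",".join(repr(float(x)) for x in table.values[i])
        )
    path.write_text("\n".join(out) + "\n")


def cell_properties(
    sigma_table: CellDielectricTable,
    eps_table: CellDielectricTable,
    f: float,
    V: float,
    policy: InterpPolicy = "strict",
) -> MediumProperties:
    """Cell sigma/eps_r at an operating point from the two tables."""
    return MediumProperties(
        sigma=sigma_table.lookup(f, V, policy),
        eps_r=eps_table.lookup(f, V, policy),
    )


def _packaged(name: str) -> Path:
    return Path(str(resources.files("cellimp").joinpath("data", name)))


def load_hela_tables() -> tuple[CellDielectricTable, CellDielectricTable]:
    """The packaged HeLa-cell (sigma, eps_r) tables, 5-100 kHz x 0.1-1 V."""
    sigma = load_cell_table(_packaged("hela_conductivity.csv"), "conductivity")
    eps = load_cell_table(_packaged("hela_permittivity.csv"), "permittivity")
    return sigma, eps
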
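"""Minimal PNG helpers for line profiles and impedance spectra."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .field_analysis import LineProfile  # noqa: E402


def plot_profile(profile: LineProfile, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.positions * 1e6, profile.magnitudes, lw=1.2)
    ax.set_xlabel(f"{profile.axis} (um)")
    ax.set_ylabel("|E| (V/m)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_spectra(spectra: pd.DataFrame, path: str | Path) -> None:
    """Magnitude vs frequency, one line per (shape, V)."""
    fig, ax = plt.subplots(figsize=(5.5, 3.6))
    for (shape, volt), grp in spectra.groupby(["shape", "V"]):
        ax.loglog(grp["f_hz"], grp["mag_ohm"], lw=0.9,
                  label=f"{shape} {volt:g} V")
    ax.set_xlabel("f (Hz)")
    ax.set_ylabel("|Z| (ohm)")
    if spectra["shape"].nunique() * spectra["V"].nunique() <= 8:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
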
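"""Bundled radionuclide photon emission spectra.

Spectra for Tc-99m, F-18 and I-131 are shipped as plain-text tables (one
emission line per row: energy in keV, photons per decay).  F-18 is
represented by its annihilation photons only and I-131 by its photon
emissions only: the framework scores external photon dose at tens of
centimetres and beyond, where beta/conversion-electron emissions do not
contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "EmissionLine",
    "Radionuclide",
    "available_nuclides",
    "load_nuclide",
    "total_yield",
    "simplify_spectrum",
]


@dataclass(frozen=True)
class EmissionLine:
    """One photon emission: energy (keV) and photons emitted per decay."""

    energy: float
    intensity: float

    def __post_init__(self):
        if self.energy <= 0:
            raise ValueError(f"emission energy must be positive, got {self.energy}")
        if not (0 < self.intensity <= 2):
            raise ValueError(
                f"intensity must be in (0, 2] photons/decay, got {self.intensity}"
            )


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide: name, physical half-life (s), emission lines sorted by energy."""

    name: str
    half_life: float  # seconds
    lines: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.half_life <= 0:
            raise ValueError("half-life must be positive")
        energies = [ln.energy for ln in self.lines]
        if energies != sorted(energies):
            raise ValueError("emission lines must be sorted by energy")
        if len(set(energies)) != len(energies):
            raise ValueError("duplicate emission energies")

    @property
    def decay_constant(self):
        """Physical decay constant (1/s)."""
        return np.log(2.0) / self.half_life

    @property
    def decay_constant_per_min(self):
        return 60.0 * self.decay_constant

    def energies(self):
        return np.array([ln.energy for ln in self.lines])

    def intensities(self):
        return np.array([ln.intensity for ln in self.lines])


def total_yield(nuclide: Radionuclide) -> float:
    """Total photon emission probability (photons per decay).

    Used to convert per-emitted-particle Monte Carlo tallies to per-decay
    quantities.
    """
    return float(sum(ln.intensity for ln in nuclide.lines))


def simplify_spectrum(nuclide: Radionuclide, threshold: float) -> Radionuclide:
    """Keep only emission lines with intensity strictly above ``threshold``.

    A threshold of 0.01 reproduces the common "lines contributing more than
    1% of disintegrations" simplification.  The input is left untouched.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = tuple(ln for ln in nuclide.lines if ln.intensity > threshold)
    return Radionuclide(nuclide.name, nuclide.half_life, kept)


def available_nuclides():
    files = resources.files("nmdose.data.nuclides")
    return sorted(p.name[:-4] for p in files.iterdir() if p.name.endswith(".txt"))


def load_nuclide(name: str) -> Radionuclide:
    """Load a bundled nuclide table by name (``Tc99m``, ``F18``, ``I131``)."""
    try:
        text = (
            resources.files("nmdose.data.nuclides").joinpath(f"{name}.txt").read_text()
        )
    except FileNotFoundError:
        raise KeyError(f"no bundled nuclide {name!r}; available: {available_nuclides()}")
    half_life = None
    lines = []
    for raw in text.splitlines():
        stripped = raw.strip()
        if stripped.startswith("# half_life_s:"):
            half_life = float(stripped.split(":", 1)[1])
        elif stripped and not stripped.startswith("#"):
            e, i = stripped.split()
            lines.append(EmissionLine(float(e), float(i)))
    if half_life is None:
        raise ValueError(f"nuclide file {name} lacks a half_life_s header")
    lines.sort(key=lambda ln: ln.energy)
    return Radionuclide(name, half_life, tuple(lines))
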
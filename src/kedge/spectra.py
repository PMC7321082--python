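"""Spectrum container, I/O, resampling and lifetime broadening.

Ab initio K-edge cross-sections come out of a multiple-scattering code
as sharp, unconvoluted curves.  To compare with experiment they are
broadened with an energy-dependent width

    Gamma(E) = Gamma_i + Gamma_f * (1/2 + (1/pi) * arctan(
                 (pi/3) * (Gamma_f/E_w) * (e/E_c - E_c**2/e**2))),
    e = E - E_f,

which rises smoothly from the core-level width Gamma_i just above the
edge to Gamma_i + Gamma_f far above it (final-state broadening switches
on over the arctangent centred at E_c with width set by E_w).  Below the
reference energy E_f the limiting value Gamma_i is used.  The broadening
kernel is a unit-area Lorentzian by default (the lifetime-broadening
convention); a Gaussian is available as an option.

Broadening is applied only as a post-processing step on model outputs
and targets; models are trained on unconvoluted cross-sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import erf

__all__ = [
    "Spectrum",
    "ConvolutionParams",
    "gamma",
    "arctan_convolve",
    "resample",
    "normalise",
    "read_spectrum",
    "write_spectrum",
]


@dataclass
class Spectrum:
    """A cross-section sampled on a strictly increasing energy grid (eV)."""

    energies: np.ndarray
    intensities: np.ndarray
    convoluted: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if e.ndim != 1 or y.shape != e.shape:
            raise ValueError("energies and intensities must be equal-length vectors")
        if len(e) > 1 and np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(e)):
            raise ValueError("spectrum values must be finite")
        self.energies, self.intensities = e, y

    def __len__(self) -> int:
        return len(self.energies)

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.energies)
        return bool(len(d) == 0 or np.allclose(d, d[0], rtol=rtol))


@dataclass(frozen=True)
class ConvolutionParams:
    """Widths (eV) of the energy-dependent broadening.

    ``gamma_i``: core-level width; ``gamma_f``: final-state width;
    ``e_c``/``e_w``: centre and width of the arctangent switch-on;
    ``e_f``: reference (Fermi/edge) energy on the spectrum's scale.
    Defaults are placeholders typical for a transition-metal K edge on a
    relative energy grid; all are expected to be set per dataset.
    """

    gamma_i: float = 1.25
    gamma_f: float = 15.0
    e_c: float = 30.0
    e_w: float = 30.0
    e_f: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_i < 0 or self.gamma_f < 0:
            raise ValueError("widths must be non-negative")
        if self.e_c <= 0 or self.e_w <= 0:
            raise ValueError("e_c and e_w must be positive")


def gamma(energy: np.ndarray | float, params: ConvolutionParams) -> np.ndarray | float:
    """Energy-dependent Lorentzian width Gamma(E) in eV.

    For E <= e_f the arctangent argument diverges to -inf and Gamma
    takes its limiting value gamma_i; the same convention handles the
    e -> 0 singularity of the E_c**2/e**2 term without overflow.
    """
    e = np.asarray(energy, dtype=float) - params.e_f
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    out = np.full(e.shape, params.gamma_i)
    pos = e > 0
    if params.gamma_f > 0 and np.any(pos):
        ep = e[pos]
        arg = (np.pi / 3.0) * (params.gamma_f / params.e_w) * (
            ep / params.e_c - params.e_c**2 / ep**2
        )
        out[pos] = params.gamma_i + params.gamma_f * (
            0.5 + np.arctan(arg) / np.pi
        )
    return float(out[0]) if scalar else out


def _lorentzian_cell_integral(lo: np.ndarray, hi: np.ndarray, width: float) -> np.ndarray:
    """Integral of a unit-area Lorentzian of FWHM ``width`` over [lo, hi]."""
    if width <= 0:
        # delta-function limit: indicator of the cell containing zero
        return ((lo <= 0) & (hi > 0)).astype(float)
    h = width / 2.0
    return (np.arctan(hi / h) - np.arctan(lo / h)) / np.pi


def _gaussian_cell_integral(lo: np.ndarray, hi: np.ndarray, width: float) -> np.ndarray:
    if width <= 0:
        return ((lo <= 0) & (hi > 0)).astype(float)
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf(hi / s) - erf(lo / s))


def arctan_convolve(
    spectrum: Spectrum,
    params: ConvolutionParams,
    kernel: str = "lorentzian",
) -> Spectrum:
    """Broaden an unconvoluted spectrum with the energy-dependent width.

    Each output point is the integral of the input (treated as
    piecewise-constant over its grid cells) against a unit-area kernel
    of FWHM Gamma(E_out) centred at E_out; the width varies with the
    *output* energy.  The per-cell kernel integrals are evaluated in
    closed form, so the identity limit Gamma -> 0 is exact and the total
    intensity is conserved up to the kernel tails that leave the grid.

    The spectrum must live on a uniform grid (resample first) and must
    not already be convoluted.
    """
    if spectrum.convoluted:
        raise ValueError("spectrum is already convoluted; refusing to broaden twice")
    if not spectrum.is_uniform():
        raise ValueError("non-uniform energy grid: resample onto a uniform grid first")
    if kernel == "lorentzian":
        cell = _lorentzian_cell_integral
    elif kernel == "gaussian":
        cell = _gaussian_cell_integral
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    e = spectrum.energies
    de = e[1] - e[0] if len(e) > 1 else 1.0
    widths = np.atleast_1d(gamma(e, params))
    out = np.empty_like(spectrum.intensities)
    lo = e - 0.5 * de
    hi = e + 0.5 * de
    for i, (ei, w) in enumerate(zip(e, widths)):
        out[i] = spectrum.intensities @ cell(lo - ei, hi - ei, float(w))
    meta = dict(spectrum.metadata)
    meta["convolution"] = {
        "kernel": kernel,
        **{k: getattr(params, k) for k in ("gamma_i", "gamma_f", "e_c", "e_w", "e_f")},
    }
    return Spectrum(e.copy(), out, convoluted=True, metadata=meta)


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid`` (must lie within the source range)."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < spectrum.energies[0] - 1e-12 or grid.max() > spectrum.energies[-1] + 1e-12:
        raise ValueError(
            f"target grid [{grid.min():g}, {grid.max():g}] extends beyond the "
            f"source range [{spectrum.energies[0]:g}, {spectrum.energies[-1]:g}]"
        )
    y = np.interp(grid, spectrum.energies, spectrum.intensities)
    return Spectrum(grid, y, spectrum.convoluted, dict(spectrum.metadata))


def normalise(spectrum: Spectrum, mode: str = "max1") -> Spectrum:
    """Normalise intensities; the mode is recorded in the metadata.

    ``max1`` divides by the maximum intensity (idempotent); ``none`` is
    the identity.
    """
    if mode == "none":
        out = Spectrum(
            spectrum.energies.copy(), spectrum.intensities.copy(),
            spectrum.convoluted, dict(spectrum.metadata),
        )
    elif mode == "max1":
        peak = spectrum.intensities.max()
        if peak == 0:
            raise ValueError("cannot max-normalise an all-zero spectrum")
        out = Spectrum(
            spectrum.energies.copy(), spectrum.intensities / peak,
            spectrum.convoluted, dict(spectrum.metadata),
        )
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    out.metadata["normalisation"] = mode
    return out


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column text: energy (eV) and intensity, with a ``#`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# convoluted={spectrum.convoluted}\n")
        for key, val in spectrum.metadata.items():
            fh.write(f"# {key}={val!r}\n")
        fh.write("# energy_eV intensity\n")
        for e, y in zip(spectrum.energies, spectrum.intensities):
            fh.write(f"{e: .8f} {y: .10e}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read two-column text; tolerates leading comment/header lines."""
    path = Path(path)
    energies, intensities = [], []
    convoluted = False
    for line in path.read_text().splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith(("#", "!", "//")):
            if "convoluted=True" in s:
                convoluted = True
            continue
        parts = s.split()
        try:
            e, y = float(parts[0]), float(parts[1])
        except (IndexError, ValueError):
            continue  # FDMNES-style textual header lines
        energies.append(e)
        intensities.append(y)
    if not energies:
        raise ValueError(f"{path}: no numeric two-column data found")
    return Spectrum(np.array(energies), np.array(intensities), convoluted)
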
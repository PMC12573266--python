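"""Lite excitation–emission matrix (EEM) fluorescence processing.

Covers the corrections needed to read leachate FDOM signals off a
spectrofluorometer grid (default excitation 240–450 nm in 5 nm steps,
emission 300–560 nm in 2 nm steps):

* absorbance-based inner-filter correction — each cell is multiplied by
  ``10^((A(ex) + A(em))/2)`` with A the 1-cm absorbance spectrum;
* Raman normalization — division by the trapezoid-integrated area of the
  water Raman band (emission 371–428 nm at 350 nm excitation), converting
  arbitrary counts to Raman Units (RU);
* control (blank) subtraction to produce net EEMs;
* Rayleigh-scatter masking (±10 nm around em = ex and em = 2·ex); and
* peak extraction within conventional fluorophore regions — protein-like
  (peak-T, Ex 275–300 / Em 320–360) and humic-like (peak-C, Ex 320–365 /
  Em 420–460).

No PARAFAC decomposition is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EEMError",
    "EEMatrix",
    "AbsorbanceSpectrum",
    "FluorescenceRegion",
    "PROTEIN_LIKE",
    "HUMIC_LIKE",
    "RAMAN_BAND_NM",
    "inner_filter_correct",
    "raman_normalize",
    "raman_area",
    "net_eem",
    "mask_rayleigh",
    "peak_pick",
    "gaussian_eem",
    "read_eem_csv",
    "write_eem_csv",
    "read_spectrum_csv",
]

#: Emission integration limits (nm) of the water Raman band at Ex 350 nm.
RAMAN_BAND_NM = (371.0, 428.0)


class EEMError(ValueError):
    """Invalid EEM input (grid mismatch, range, degenerate blank...)."""


def _default_excitation() -> np.ndarray:
    return np.arange(240.0, 450.0 + 1e-9, 5.0)


def _default_emission() -> np.ndarray:
    return np.arange(300.0, 560.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class EEMatrix:
    """Fluorescence intensity over an excitation × emission grid.

    ``intensity[i, j]`` belongs to ``excitation[i]`` / ``emission[j]``;
    ``units`` is ``"raw"`` or ``"raman_units"``.
    """

    excitation: np.ndarray
    emission: np.ndarray
    intensity: np.ndarray
    units: str = "raw"

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "intensity", z)
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise EEMError("wavelength grids must be strictly increasing")
        if z.shape != (len(ex), len(em)):
            raise EEMError(
                f"intensity shape {z.shape} does not match grids "
                f"({len(ex)}, {len(em)})"
            )
        if self.units not in ("raw", "raman_units"):
            raise EEMError(f"unknown units state {self.units!r}")

    def same_grid(self, other: "EEMatrix") -> bool:
        return (
            self.excitation.shape == other.excitation.shape
            and self.emission.shape == other.emission.shape
            and np.array_equal(self.excitation, other.excitation)
            and np.array_equal(self.emission, other.emission)
        )


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Dimensionless absorbance (1 cm path) versus wavelength (nm)."""

    wavelength: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise EEMError("wavelength and absorbance must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise EEMError("wavelengths must be strictly increasing")
        if np.any(ab < 0):
            raise EEMError("absorbance must be >= 0")

    def at(self, wavelengths: np.ndarray) -> np.ndarray:
        wavelengths = np.asarray(wavelengths, dtype=float)
        lo, hi = self.wavelength[0], self.wavelength[-1]
        if wavelengths.min() < lo or wavelengths.max() > hi:
            raise EEMError(
                f"absorbance spectrum covers {lo}-{hi} nm but "
                f"{wavelengths.min()}-{wavelengths.max()} nm was requested"
            )
        return np.interp(wavelengths, self.wavelength, self.absorbance)


@dataclass(frozen=True)
class FluorescenceRegion:
    name: str
    ex_window: tuple[float, float]
    em_window: tuple[float, float]


PROTEIN_LIKE = FluorescenceRegion("protein-like", (275.0, 300.0), (320.0, 360.0))
HUMIC_LIKE = FluorescenceRegion("humic-like", (320.0, 365.0), (420.0, 460.0))


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------


def inner_filter_correct(eem: EEMatrix, absorbance: AbsorbanceSpectrum) -> EEMatrix:
    """Absorbance-based inner-filter correction.

    Multiplies each cell by ``10^((A(ex)+A(em))/2)``; with non-negative
    absorbance the factor is >= 1, so intensities never decrease.
    """
    a_ex = absorbance.at(eem.excitation)
    a_em = absorbance.at(eem.emission)
    factor = 10.0 ** (0.5 * (a_ex[:, None] + a_em[None, :]))
    return replace(eem, intensity=eem.intensity * factor)


def raman_area(
    scan_emission: np.ndarray,
    scan_intensity: np.ndarray,
    band: tuple[float, float] = RAMAN_BAND_NM,
) -> float:
    """Trapezoid-integrated area of a Raman emission scan over ``band``.

    The scan (at 350 nm excitation) is linearly interpolated at the band
    edges so the integral covers exactly [band[0], band[1]].
    """
    em = np.asarray(scan_emission, dtype=float)
    y = np.asarray(scan_intensity, dtype=float)
    lo, hi = band
    if em[0] > lo or em[-1] < hi:
        raise EEMError(
            f"Raman scan covers {em[0]}-{em[-1]} nm; needs {lo}-{hi} nm"
        )
    inside = (em > lo) & (em < hi)
    xs = np.concatenate(([lo], em[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, em, y)], y[inside], [np.interp(hi, em, y)]))
    return float(np.trapezoid(ys, xs))


def raman_normalize(
    eem: EEMatrix,
    scan_emission: np.ndarray,
    scan_intensity: np.ndarray,
    band: tuple[float, float] = RAMAN_BAND_NM,
) -> EEMatrix:
    """Convert to Raman Units by dividing by the Raman band area."""
    area = raman_area(scan_emission, scan_intensity, band)
    if area <= 0:
        raise EEMError(f"degenerate Raman blank: band area {area} is not positive")
    return replace(eem, intensity=eem.intensity / area, units="raman_units")


def net_eem(sample: EEMatrix, control: EEMatrix) -> EEMatrix:
    """Cellwise sample − control; negative differences are retained."""
    if not sample.same_grid(control):
        raise EEMError("sample and control are on different wavelength grids")
    if sample.units != control.units:
        raise EEMError(
            f"units mismatch: sample {sample.units!r} vs control {control.units!r}"
        )
    return replace(sample, intensity=sample.intensity - control.intensity)


def mask_rayleigh(eem: EEMatrix, width: float = 10.0) -> EEMatrix:
    """Mask first/second-order Rayleigh scatter bands with NaN.

    Cells with ``|em − ex| <= width`` or ``|em − 2·ex| <= width`` are set to
    NaN; downstream peak picking ignores NaNs.
    """
    ex = eem.excitation[:, None]
    em = eem.emission[None, :]
    mask = (np.abs(em - ex) <= width) | (np.abs(em - 2.0 * ex) <= width)
    z = eem.intensity.copy()
    z[mask] = np.nan
    return replace(eem, intensity=z)


def peak_pick(
    eem: EEMatrix, region: FluorescenceRegion
) -> tuple[float, float, float]:
    """Maximum intensity in a region: ``(value, ex_at_max, em_at_max)``.

    NaN cells (masked scatter) are ignored; ties resolve to the lowest
    excitation, then the lowest emission.
    """
    ex_sel = (eem.excitation >= region.ex_window[0]) & (
        eem.excitation <= region.ex_window[1]
    )
    em_sel = (eem.emission >= region.em_window[0]) & (
        eem.emission <= region.em_window[1]
    )
    if not ex_sel.any() or not em_sel.any():
        raise EEMError(f"region {region.name!r} contains no grid points")
    sub = eem.intensity[np.ix_(ex_sel, em_sel)]
    if np.all(np.isnan(sub)):
        raise EEMError(f"region {region.name!r} is fully masked")
    best = np.nanmax(sub)
    # row-major argwhere scan = lowest excitation first, then lowest emission
    i, j = np.argwhere(sub == best)[0]
    return (
        float(best),
        float(eem.excitation[ex_sel][i]),
        float(eem.emission[em_sel][j]),
    )


# ---------------------------------------------------------------------------
# Synthetic EEMs and CSV I/O
# ---------------------------------------------------------------------------


def gaussian_eem(
    peaks: list[tuple[float, float, float]],
    excitation: np.ndarray | None = None,
    emission: np.ndarray | None = None,
    sigma_ex: float = 15.0,
    sigma_em: float = 25.0,
    units: str = "raw",
) -> EEMatrix:
    """Synthetic EEM as a sum of separable Gaussian peaks.

    ``peaks`` are ``(amplitude, ex_center, em_center)`` triples; used by the
    tests and the worked examples as a stand-in for instrument output.
    """
    ex = _default_excitation() if excitation is None else np.asarray(excitation, float)
    em = _default_emission() if emission is None else np.asarray(emission, float)
    z = np.zeros((len(ex), len(em)))
    for amp, ex0, em0 in peaks:
        z += (
            amp
            * np.exp(-0.5 * ((ex - ex0) / sigma_ex) ** 2)[:, None]
            * np.exp(-0.5 * ((em - em0) / sigma_em) ** 2)[None, :]
        )
    return EEMatrix(excitation=ex, emission=em, intensity=z, units=units)


def write_eem_csv(eem: EEMatrix, path) -> None:
    """CSV layout: first row = emission grid, first column = excitation grid."""
    frame = pd.DataFrame(eem.intensity, index=eem.excitation, columns=eem.emission)
    frame.to_csv(path, index_label="ex_nm\\em_nm")


def read_eem_csv(path, units: str = "raw") -> EEMatrix:
    frame = pd.read_csv(path, index_col=0)
    return EEMatrix(
        excitation=frame.index.to_numpy(dtype=float),
        emission=np.array([float(c) for c in frame.columns]),
        intensity=frame.to_numpy(dtype=float),
        units=units,
    )


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column CSV (wavelength_nm, value) -> arrays."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise EEMError("spectrum CSV needs two columns (wavelength, value)")
    return (
        frame.iloc[:, 0].to_numpy(dtype=float),
        frame.iloc[:, 1].to_numpy(dtype=float),
    )
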
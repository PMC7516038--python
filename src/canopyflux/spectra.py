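"""Light-source spectra and spectrum-weighted photobiology quantities.

A :class:`SpectralDistribution` holds photon flux density per unit wavelength
(µmol m⁻² s⁻¹ nm⁻¹) on a strictly increasing wavelength grid. From it we
compute waveband photon fluxes and fractions (blue/green/red/far-red), the
daily light integral, the phytochrome photoequilibrium (PPE) — an estimate of
the fraction of the phytochrome pool in the active far-red-absorbing form —
and the fraction of incident photons absorbed by a single leaf layer,
weighted by the source spectrum.

All integrals are trapezoidal on the native grid, with band edges handled by
linear interpolation of the flux density at the edge wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDistribution",
    "AbsorptanceSpectrum",
    "PhotoconversionCoefficients",
    "Waveband",
    "BLUE",
    "GREEN",
    "RED",
    "FAR_RED",
    "DEFAULT_BANDS",
    "integrate_photon_flux",
    "waveband_fractions",
    "daily_light_integral",
    "compute_ppe",
    "leaf_photon_absorption",
    "load_spectrum_csv",
    "load_absorptance_csv",
    "load_coefficients_csv",
    "default_photoconversion_coefficients",
]


def _validate_grid(wavelength_nm: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelength_nm, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least 2 points")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return wl


@dataclass(frozen=True)
class SpectralDistribution:
    """Photon flux density per wavelength for a light source or treatment.

    Parameters
    ----------
    wavelength_nm : array
        Strictly increasing wavelength grid (nm), spanning at least 400-750 nm.
    flux_density : array
        Photon flux density (µmol m⁻² s⁻¹ nm⁻¹) at each grid point, ≥ 0.
    """

    wavelength_nm: np.ndarray
    flux_density: np.ndarray

    def __post_init__(self) -> None:
        wl = _validate_grid(self.wavelength_nm)
        fd = np.asarray(self.flux_density, dtype=float)
        if fd.shape != wl.shape:
            raise ValueError("flux_density must match the wavelength grid shape")
        if np.any(fd < 0):
            raise ValueError("flux_density must be nonnegative")
        if wl[0] > 400.0 or wl[-1] < 750.0:
            raise ValueError("spectrum grid must span at least [400, 750] nm")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "flux_density", fd)

    def scaled(self, factor: float) -> "SpectralDistribution":
        return SpectralDistribution(self.wavelength_nm, self.flux_density * factor)

    def total_flux(self, lo_nm: float = 400.0, hi_nm: float = 750.0) -> float:
        """Total photon flux (µmol m⁻² s⁻¹) integrated over [lo, hi]."""
        return integrate_photon_flux(self, Waveband(lo_nm, hi_nm, "total"))


@dataclass(frozen=True)
class AbsorptanceSpectrum:
    """Fraction of photons absorbed by one leaf layer, per wavelength."""

    wavelength_nm: np.ndarray
    absorptance: np.ndarray

    def __post_init__(self) -> None:
        wl = _validate_grid(self.wavelength_nm)
        a = np.asarray(self.absorptance, dtype=float)
        if a.shape != wl.shape:
            raise ValueError("absorptance must match the wavelength grid shape")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("absorptance must lie in [0, 1]")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "absorptance", a)


@dataclass(frozen=True)
class PhotoconversionCoefficients:
    """Relative photoconversion cross-sections of phytochrome P_r and P_fr.

    sigma_r is the cross-section of the red-absorbing (inactive) form P_r and
    sigma_fr that of the far-red-absorbing (active) form P_fr. Only the ratio
    of the two matters for the photoequilibrium, so the scale is arbitrary.
    """

    wavelength_nm: np.ndarray
    sigma_r: np.ndarray
    sigma_fr: np.ndarray

    def __post_init__(self) -> None:
        wl = _validate_grid(self.wavelength_nm)
        sr = np.asarray(self.sigma_r, dtype=float)
        sf = np.asarray(self.sigma_fr, dtype=float)
        if sr.shape != wl.shape or sf.shape != wl.shape:
            raise ValueError("coefficient arrays must match the wavelength grid")
        if np.any(sr < 0) or np.any(sf < 0):
            raise ValueError("photoconversion coefficients must be nonnegative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "sigma_r", sr)
        object.__setattr__(self, "sigma_fr", sf)


@dataclass(frozen=True)
class Waveband:
    """A contiguous wavelength band [lo_nm, hi_nm]."""

    lo_nm: float
    hi_nm: float
    label: str = field(default="custom")

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError("waveband requires lo_nm < hi_nm")


# Contiguous partition of 400-750 nm. The conventional discrete-nm labels
# (501-600, 601-700) denote the same partition for continuous integration.
BLUE = Waveband(400.0, 500.0, "blue")
GREEN = Waveband(500.0, 600.0, "green")
RED = Waveband(600.0, 700.0, "red")
FAR_RED = Waveband(700.0, 750.0, "far_red")
DEFAULT_BANDS = (BLUE, GREEN, RED, FAR_RED)


def _band_grid(wl: np.ndarray, values: np.ndarray, lo: float, hi: float):
    """Restrict (wl, values) to [lo, hi], interpolating the edge points."""
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, wl, values)], values[inside], [np.interp(hi, wl, values)])
    )
    return xs, ys


def integrate_photon_flux(spectrum: SpectralDistribution, band: Waveband) -> float:
    """Photon flux (µmol m⁻² s⁻¹) in `band`: trapezoidal integral of the
    flux density over [lo_nm, hi_nm]."""
    wl = spectrum.wavelength_nm
    if band.lo_nm < wl[0] or band.hi_nm > wl[-1]:
        raise ValueError(
            f"band [{band.lo_nm}, {band.hi_nm}] outside spectrum grid "
            f"[{wl[0]}, {wl[-1]}]"
        )
    xs, ys = _band_grid(wl, spectrum.flux_density, band.lo_nm, band.hi_nm)
    return float(np.trapezoid(ys, xs))


def waveband_fractions(spectrum: SpectralDistribution) -> dict[str, float]:
    """Fractions of the total 400-750 nm photon flux in the blue (400-500),
    green (500-600), red (600-700) and far-red (700-750) bands.

    The four fractions sum to 1 because the bands partition 400-750 nm.
    """
    fluxes = {b.label: integrate_photon_flux(spectrum, b) for b in DEFAULT_BANDS}
    total = sum(fluxes.values())
    if total <= 0:
        raise ValueError("waveband fractions undefined for zero total flux")
    return {label: flux / total for label, flux in fluxes.items()}


def daily_light_integral(total_ppfd: float, photoperiod_h: float) -> float:
    """Daily light integral (mol m⁻² d⁻¹) from a constant photon flux density
    (µmol m⁻² s⁻¹) applied for `photoperiod_h` hours per day."""
    if total_ppfd < 0 or photoperiod_h < 0:
        raise ValueError("total_ppfd and photoperiod_h must be nonnegative")
    return total_ppfd * photoperiod_h * 3600.0 * 1e-6


def _interp_to(wl_target: np.ndarray, wl: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.interp(wl_target, wl, values)


def compute_ppe(
    spectrum: SpectralDistribution, coeffs: PhotoconversionCoefficients
) -> float:
    """Phytochrome photoequilibrium under a spectrum.

    PPE = ∫N(λ)σ_r(λ)dλ / ∫N(λ)[σ_r(λ) + σ_fr(λ)]dλ, where N is the photon
    flux density. Lies in [0, 1]; invariant to uniform scaling of N and to a
    common rescaling of the coefficients.
    """
    wl = spectrum.wavelength_nm
    if coeffs.wavelength_nm[0] > wl[0] or coeffs.wavelength_nm[-1] < wl[-1]:
        # Cross-sections are ~0 outside the phytochrome absorption range, so
        # extend with the edge values only when support is actually covered.
        support = wl[spectrum.flux_density > 0]
        if support.size and (
            support[0] < coeffs.wavelength_nm[0] or support[-1] > coeffs.wavelength_nm[-1]
        ):
            raise ValueError("coefficient grid does not cover the spectral support")
    sr = _interp_to(wl, coeffs.wavelength_nm, coeffs.sigma_r)
    sf = _interp_to(wl, coeffs.wavelength_nm, coeffs.sigma_fr)
    n = spectrum.flux_density
    num = np.trapezoid(n * sr, wl)
    den = np.trapezoid(n * (sr + sf), wl)
    if den <= 0:
        raise ValueError("PPE undefined: spectrum does not overlap the coefficients")
    return float(num / den)


def leaf_photon_absorption(
    spectrum: SpectralDistribution, leaf: AbsorptanceSpectrum
) -> float:
    """Fraction of incident photons absorbed by a single leaf layer,
    spectrum-weighted: ∫N(λ)a(λ)dλ / ∫N(λ)dλ over the spectrum grid."""
    wl = spectrum.wavelength_nm
    a = _interp_to(wl, leaf.wavelength_nm, leaf.absorptance)
    n = spectrum.flux_density
    total = np.trapezoid(n, wl)
    if total <= 0:
        raise ValueError("leaf photon absorption undefined for zero total flux")
    return float(np.trapezoid(n * a, wl) / total)


# ---------------------------------------------------------------------------
# CSV interfaces


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.sort_values(columns[0]).reset_index(drop=True)


def load_spectrum_csv(path: str | Path) -> SpectralDistribution:
    """Read `wavelength_nm,flux_umol_m2_s_nm` CSV (``#`` comments allowed)."""
    df = _read_csv(path, ["wavelength_nm", "flux_umol_m2_s_nm"])
    return SpectralDistribution(
        df["wavelength_nm"].to_numpy(), df["flux_umol_m2_s_nm"].to_numpy()
    )


def load_absorptance_csv(path: str | Path) -> AbsorptanceSpectrum:
    """Read `wavelength_nm,absorptance` CSV."""
    df = _read_csv(path, ["wavelength_nm", "absorptance"])
    return AbsorptanceSpectrum(
        df["wavelength_nm"].to_numpy(), df["absorptance"].to_numpy()
    )


def load_coefficients_csv(path: str | Path) -> PhotoconversionCoefficients:
    """Read `wavelength_nm,sigma_r,sigma_fr` CSV."""
    df = _read_csv(path, ["wavelength_nm", "sigma_r", "sigma_fr"])
    return PhotoconversionCoefficients(
        df["wavelength_nm"].to_numpy(),
        df["sigma_r"].to_numpy(),
        df["sigma_fr"].to_numpy(),
    )


def default_photoconversion_coefficients() -> PhotoconversionCoefficients:
    """Bundled SYNTHETIC phytochrome photoconversion coefficient table.

    The measured cross-section tables from the photoconversion literature are
    not redistributable here, so the package ships a synthetic Gaussian
    parameterization of P_r (red-absorbing, peak 665 nm) and P_fr
    (far-red-absorbing, peak 730 nm) calibrated to reproduce the canonical
    photoequilibrium behaviour: PPE ≈ 0.89 under monochromatic red, ≈ 0.5
    under blue, and a strong drop under far-red-enriched spectra. Substitute
    a measured table via :func:`load_coefficients_csv` for real work.
    """
    with resources.as_file(
        resources.files("canopyflux").joinpath(
            "data/phytochrome_coefficients_synthetic.csv"
        )
    ) as p:
        return load_coefficients_csv(p)
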
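"""Canopy photon capture from top-down images and a Beer-Lambert multilayer
correction.

Fractional ground cover is the ratio of green (plant) pixels to the pixel
count of a region of interest equal to the chamber ground area. Capture is
cover × within-cover photon absorption; for a single leaf layer the
within-cover absorption is the spectrum-weighted single-leaf absorption, and
once leaves overlap it is the Beer-Lambert value 1 − e^(−k·L) with L leaf
layers (total canopy leaf area / projected covered area) and k = −ln(1 − a)
anchored so L = 1 reproduces the single-leaf absorption a.

Total leaf area between the young-canopy phase (where projected area is a
good estimate of total area) and harvest is interpolated with an exponential
growth fit in log space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ground_cover_fraction",
    "fit_exponential_growth",
    "leaf_layers",
    "extinction_coefficient",
    "beer_lambert_absorption",
    "canopy_capture",
    "capture_series",
]


def _as_float_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("image must be H x W x 3 (RGB)")
    if np.issubdtype(img.dtype, np.integer):
        return img[..., :3].astype(float) / 255.0
    return img[..., :3].astype(float)


def ground_cover_fraction(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    green_threshold: float = 0.15,
) -> float:
    """Fraction of plant (green) pixels within the region of interest.

    A pixel is classified as plant tissue iff its green channel exceeds both
    the red and blue channels and exceeds ``green_threshold`` of full scale.
    The classifier is deliberately simple and swappable; it matches the
    green-dominance heuristic used for nadir canopy photographs.

    Parameters
    ----------
    image : array
        RGB image, uint8 (0-255) or float (0-1).
    roi : (row0, row1, col0, col1), optional
        Pixel rectangle matching the chamber ground area; whole image if None.
    """
    img = _as_float_image(image)
    if roi is not None:
        r0, r1, c0, c1 = roi
        img = img[r0:r1, c0:c1]
    if img.size == 0:
        raise ValueError("empty region of interest")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    green = (g > r) & (g > b) & (g > green_threshold)
    return float(green.mean())


def fit_exponential_growth(times_d, areas_m2):
    """Least-squares fit of A(t) = A₀·e^(r·t) via OLS of ln(area) on time.

    Returns ``(A0, r)``. Requires ≥ 2 points and strictly positive areas.
    """
    t = np.asarray(times_d, dtype=float)
    a = np.asarray(areas_m2, dtype=float)
    if t.size < 2:
        raise ValueError("exponential fit needs at least 2 points")
    if np.any(a <= 0):
        raise ValueError("areas must be positive for a log-space fit")
    slope, intercept = np.polyfit(t, np.log(a), 1)
    return float(np.exp(intercept)), float(slope)


def leaf_layers(total_leaf_area_m2, projected_area_m2):
    """Leaf layers within the covered area: total / projected, floored at 1
    (pre-overlap canopies are treated as a single layer)."""
    proj = np.asarray(projected_area_m2, dtype=float)
    if np.any(proj <= 0):
        raise ValueError("projected area must be positive")
    result = np.maximum(np.asarray(total_leaf_area_m2, dtype=float) / proj, 1.0)
    return float(result) if np.ndim(result) == 0 else result


def extinction_coefficient(single_layer_absorption: float) -> float:
    """Beer-Lambert extinction coefficient k = −ln(1 − a) anchored so that
    one leaf layer absorbs fraction ``a`` (e.g. a = 0.798 gives k ≈ 1.6)."""
    a = float(single_layer_absorption)
    if not 0.0 < a < 1.0:
        raise ValueError("single-layer absorption must lie in (0, 1)")
    return -np.log1p(-a)


def beer_lambert_absorption(k, layers):
    """Fraction of photons absorbed within the covered area:
    1 − e^(−k·layers)."""
    k_arr = np.asarray(k, dtype=float)
    l_arr = np.asarray(layers, dtype=float)
    if np.any(k_arr <= 0):
        raise ValueError("extinction coefficient must be positive")
    if np.any(l_arr < 0):
        raise ValueError("leaf layers must be nonnegative")
    result = -np.expm1(-k_arr * l_arr)
    return float(result) if np.ndim(result) == 0 else result


def canopy_capture(cover, within_cover_absorption):
    """Canopy photon capture (mol absorbed / mol incident): ground cover ×
    within-cover absorption. Both factors lie in [0, 1], so capture ≤ cover."""
    c = np.asarray(cover, dtype=float)
    a = np.asarray(within_cover_absorption, dtype=float)
    if np.any((c < 0) | (c > 1)) or np.any((a < 0) | (a > 1)):
        raise ValueError("cover and absorption must lie in [0, 1]")
    result = c * a
    return float(result) if np.ndim(result) == 0 else result


def capture_series(
    cover: pd.DataFrame,
    single_leaf_absorption: float,
    harvest_total_leaf_area_m2: float,
    chamber_area_m2: float = 0.17,
    young_days: int | None = None,
) -> pd.DataFrame:
    """Daily canopy photon capture for one chamber from a cover time series.

    Parameters
    ----------
    cover : DataFrame
        Columns ``day`` and ``cover_fraction`` for one chamber, one row per
        day, ending on the harvest day.
    single_leaf_absorption : float
        Spectrum-weighted single-leaf photon absorption for this treatment
        (sets the extinction coefficient k = −ln(1 − a)).
    harvest_total_leaf_area_m2 : float
        Measured total canopy leaf area at harvest.
    chamber_area_m2 : float
        Ground area of the chamber; projected area = cover × chamber area.
    young_days : int, optional
        Number of leading days whose projected area is taken as total leaf
        area for the exponential interpolation; defaults to all but the final
        7 days (overlap typically begins about a week before harvest).

    Returns
    -------
    DataFrame with ``day``, ``cover_fraction``, ``projected_area_m2``,
    ``total_leaf_area_m2`` (interpolated), ``leaf_layers``,
    ``capture_fraction`` and the attribute-style column ``k`` used.
    """
    df = cover.sort_values("day").reset_index(drop=True)
    if df.empty:
        raise ValueError("cover series is empty")
    proj = df["cover_fraction"].to_numpy(dtype=float) * chamber_area_m2
    days = df["day"].to_numpy(dtype=float)
    if young_days is None:
        young_days = max(len(df) - 7, 2)
    young_days = int(min(max(young_days, 2), len(df)))

    positive = proj[:young_days] > 0
    t_fit = np.concatenate([days[:young_days][positive], [days[-1]]])
    a_fit = np.concatenate([proj[:young_days][positive], [harvest_total_leaf_area_m2]])
    a0, r = fit_exponential_growth(t_fit, a_fit)
    total = a0 * np.exp(r * days)

    k = extinction_coefficient(single_leaf_absorption)
    layers = np.ones_like(proj)
    overlap = (total > proj) & (proj > 0)
    layers[overlap] = total[overlap] / proj[overlap]
    within = beer_lambert_absorption(k, layers)
    capture = canopy_capture(df["cover_fraction"].to_numpy(dtype=float), within)

    out = df.copy()
    out["projected_area_m2"] = proj
    out["total_leaf_area_m2"] = total
    out["leaf_layers"] = layers
    out["capture_fraction"] = capture
    out["k"] = k
    return out
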
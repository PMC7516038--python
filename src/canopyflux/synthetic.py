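"""Synthetic canopy gas-exchange experiments with known ground truth.

Generates every input stream the analysis pipeline consumes — LED treatment
spectra, leaf absorptance profiles, daily canopy growth and top-down canopy
images, and a per-second multiplexed chamber CO₂ stream — from a small set of
physiological parameters, and records the exact per-day truth so recovery of
quantum yield, carbon use efficiency and biomass can be tested end to end.

Default conditions emulate a four-chamber lettuce study: four treatments
(red/blue or white background, with or without ~15% far-red substitution) at
equal total photon flux of 350 µmol m⁻² s⁻¹ over 400-750 nm and 31.5% blue,
14/10 h photoperiod, 0.17 m² chambers, 18-day runs from seedling to near
canopy closure, air flow ramping from 11 to 37 mmol s⁻¹, a true canopy
quantum yield of 0.057 mol CO₂ per mol absorbed photons, and a mature-plant
carbon use efficiency of 0.61 approached from ~0.4 over the first 10 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from skimage.draw import ellipse as draw_ellipse

from .gas_exchange import UMOL_S_TO_MOL_H, CarbonConversion, SamplingSchedule
from .photon_capture import beer_lambert_absorption, extinction_coefficient
from .spectra import (
    DEFAULT_BANDS,
    AbsorptanceSpectrum,
    SpectralDistribution,
    integrate_photon_flux,
    leaf_photon_absorption,
)

__all__ = [
    "TreatmentSpec",
    "GrowthParams",
    "PhysiologyParams",
    "ExperimentTruth",
    "SyntheticExperiment",
    "DEFAULT_TREATMENTS",
    "make_led_spectrum",
    "make_absorptance",
    "simulate_canopy_growth",
    "simulate_chamber_stream",
    "render_canopy_image",
    "simulate_experiment",
]

DEFAULT_GRID_NM = np.arange(380.0, 780.5, 1.0)


# ---------------------------------------------------------------------------
# Treatment spectra


@dataclass(frozen=True)
class TreatmentSpec:
    """Recipe for one LED treatment spectrum.

    ``peaks`` are Gaussian components (center nm, sd nm, initial weight);
    component weights are re-calibrated so the 400-750 nm waveband fractions
    match ``target_fractions`` (blue, green, red, far_red) and the 400-750 nm
    integral equals ``total_ppfd`` exactly.
    """

    name: str
    total_ppfd: float
    peaks: tuple[tuple[float, float, float], ...]
    target_fractions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.total_ppfd <= 0:
            raise ValueError("total_ppfd must be positive")
        if any(w <= 0 for _, _, w in self.peaks):
            raise ValueError("component weights must be positive")


def _rb_peaks(blue_w: float, red_w: float):
    return ((443.0, 12.0, blue_w), (663.0, 13.0, red_w))


def _white_peaks(blue_w: float, green_w: float, red_w: float):
    return ((450.0, 12.0, blue_w), (560.0, 35.0, green_w), (640.0, 25.0, red_w))


_FR_PEAK = (730.0, 11.0, 1.0)

#: The four bundled treatments: red/blue and white backgrounds, each with or
#: without 50 µmol m⁻² s⁻¹ of far-red substituting for 400-700 nm photons.
#: All share 31.5% blue; white has green:red 45.2:23.3, red/blue 0.1:68.4.
DEFAULT_TREATMENTS: tuple[TreatmentSpec, ...] = (
    TreatmentSpec("RB 350", 350.0, _rb_peaks(0.315, 0.685), (0.315, 0.001, 0.684, 0.0)),
    TreatmentSpec(
        "RB 300 + FR 50",
        350.0,
        _rb_peaks(0.27, 0.5871) + (_FR_PEAK[:2] + (50.0 / 350.0,),),
        (0.27, 0.00086, 0.58628, 50.0 / 350.0),
    ),
    TreatmentSpec(
        "white 350",
        350.0,
        _white_peaks(0.315, 0.452, 0.233),
        (0.315, 0.452, 0.233, 0.0),
    ),
    TreatmentSpec(
        "white 300 + FR 50",
        350.0,
        _white_peaks(0.27, 0.3874, 0.1997) + (_FR_PEAK[:2] + (50.0 / 350.0,),),
        (0.27, 0.38743, 0.19971, 50.0 / 350.0),
    ),
)


def make_led_spectrum(
    spec: TreatmentSpec, grid_nm: np.ndarray | None = None
) -> SpectralDistribution:
    """Build a Gaussian-mixture LED spectrum calibrated to a treatment spec.

    Component weights are solved by nonnegative least squares so the
    blue/green/red/far-red fractions of the 400-750 nm flux match the
    spec's targets; the spectrum is then rescaled so its 400-750 nm integral
    equals ``total_ppfd`` exactly.
    """
    wl = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    comps = []
    for center, sd, _ in spec.peaks:
        shape = np.exp(-((wl - center) ** 2) / (2.0 * sd * sd))
        dist = SpectralDistribution(wl, shape)
        total = dist.total_flux()
        if total <= 0:
            raise ValueError(f"component at {center} nm carries no 400-750 nm flux")
        comps.append(shape / total)

    # Band-fraction matrix: A[band, comp] for unit-flux components.
    a_mat = np.empty((4, len(comps)))
    for j, comp in enumerate(comps):
        dist = SpectralDistribution(wl, comp)
        for i, band in enumerate(DEFAULT_BANDS):
            a_mat[i, j] = integrate_photon_flux(dist, band)
    target = np.asarray(spec.target_fractions, dtype=float)
    target = target / target.sum()
    weights, residual = nnls(a_mat, target)
    if residual > 0.005 or weights.sum() <= 0:
        raise ValueError(
            f"{spec.name}: target waveband fractions unreachable with the given "
            f"components (residual {residual:.4f})"
        )
    flux = np.sum([w * c for w, c in zip(weights, comps)], axis=0)
    dist = SpectralDistribution(wl, flux)
    return dist.scaled(spec.total_ppfd / dist.total_flux())


# ---------------------------------------------------------------------------
# Leaf absorptance


def make_absorptance(
    peak: float = 0.955,
    green_dip: float = 0.24,
    fr_level: float = 0.30,
    red_edge_nm: float = 715.0,
    edge_width_nm: float = 12.0,
    grid_nm: np.ndarray | None = None,
) -> AbsorptanceSpectrum:
    """Synthetic leaf absorptance profile.

    A chlorophyll-like shape: high absorptance (``peak``) in the blue and red,
    a Gaussian dip of depth ``green_dip`` centered at 550 nm, and a logistic
    red-edge decline to ``fr_level`` beyond ``red_edge_nm`` (leaves transmit
    and reflect far-red strongly). Far-red-grown leaves are emulated with a
    lower peak, deeper green dip and lower far-red absorptance (thinner
    leaves, less chlorophyll).
    """
    wl = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    main = peak - green_dip * np.exp(-((wl - 550.0) ** 2) / (2.0 * 45.0**2))
    edge = 1.0 / (1.0 + np.exp((wl - red_edge_nm) / edge_width_nm))
    a = fr_level + (main - fr_level) * edge
    return AbsorptanceSpectrum(wl, np.clip(a, 0.0, 1.0))


#: Absorptance profiles for control-grown vs far-red-grown leaves.
CONTROL_LEAF = dict(peak=0.955, green_dip=0.24, fr_level=0.30)
FR_GROWN_LEAF = dict(peak=0.92, green_dip=0.30, fr_level=0.22)


# ---------------------------------------------------------------------------
# Canopy growth


@dataclass(frozen=True)
class GrowthParams:
    """Logistic canopy leaf-area growth.

    Total leaf area follows A(t) = K / (1 + ((K−A₀)/A₀)·e^(−r·t)), whose
    early phase is exponential with rate ``relative_growth_rate``. Projected
    (covered) area equals total area until ``overlap_onset_area_m2``; beyond
    it, projected area saturates smoothly toward the chamber area while total
    area keeps growing, so leaf layers exceed 1. The far-red expansion
    multiplier scales the growth rate to emulate phytochrome-mediated leaf
    expansion.
    """

    initial_area_m2: float = 0.004
    relative_growth_rate: float = 0.2817
    saturation_area_m2: float = 0.60
    fr_expansion_multiplier: float = 1.0
    overlap_onset_area_m2: float = 0.08
    specific_leaf_area_m2_g: float = 0.037

    def __post_init__(self) -> None:
        vals = (
            self.initial_area_m2,
            self.saturation_area_m2,
            self.fr_expansion_multiplier,
            self.overlap_onset_area_m2,
            self.specific_leaf_area_m2_g,
        )
        if any(v <= 0 for v in vals) or self.relative_growth_rate < 0:
            raise ValueError("growth parameters must be positive (growth rate >= 0)")
        if self.saturation_area_m2 < self.initial_area_m2:
            raise ValueError("saturation area must be >= initial area")


def simulate_canopy_growth(
    params: GrowthParams, days: int, chamber_area_m2: float = 0.17
) -> pd.DataFrame:
    """Daily true leaf area, projected area, cover and leaf layers.

    Returns a DataFrame over days 0..days−1 with ``total_leaf_area_m2``,
    ``projected_area_m2``, ``cover_fraction`` and ``leaf_layers``.
    """
    t = np.arange(days, dtype=float)
    k_area = params.saturation_area_m2
    a0 = params.initial_area_m2
    r = params.relative_growth_rate * params.fr_expansion_multiplier
    total = k_area / (1.0 + (k_area - a0) / a0 * np.exp(-r * t))

    onset = min(params.overlap_onset_area_m2, chamber_area_m2 * 0.999)
    span = chamber_area_m2 - onset
    projected = np.where(
        total <= onset,
        total,
        chamber_area_m2 - span * np.exp(-(total - onset) / span),
    )
    projected = np.minimum(projected, chamber_area_m2)
    cover = projected / chamber_area_m2
    layers = np.maximum(total / projected, 1.0)
    return pd.DataFrame(
        {
            "day": np.arange(days),
            "total_leaf_area_m2": total,
            "projected_area_m2": projected,
            "cover_fraction": cover,
            "leaf_layers": layers,
        }
    )


# ---------------------------------------------------------------------------
# Chamber CO₂ stream


@dataclass(frozen=True)
class PhysiologyParams:
    """True canopy physiology driving the simulated CO₂ stream.

    ``true_quantum_yield`` is mol CO₂ fixed in gross photosynthesis per mol
    absorbed photons (400-750 nm); ``true_cue`` the mature-plant carbon use
    efficiency. Effective CUE ramps linearly from ``seedling_cue`` to
    ``true_cue`` over ``cue_ramp_days`` to emulate the observed rise during
    establishment. Air flow ramps linearly from ``flow_start_mol_s`` to
    ``flow_end_mol_s`` over the run, mirroring how flow is raised as canopies
    grow.
    """

    true_quantum_yield: float = 0.057
    true_cue: float = 0.61
    seedling_cue: float = 0.40
    cue_ramp_days: int = 10
    delta_co2_noise_sd: float = 0.5
    flow_start_mol_s: float = 0.011
    flow_end_mol_s: float = 0.037
    photoperiod_h: float = 14.0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_quantum_yield <= 0.125:
            raise ValueError("true quantum yield must lie in (0, 0.125]")
        if not 0.0 < self.true_cue <= 1.0:
            raise ValueError("true CUE must lie in (0, 1]")
        if self.delta_co2_noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")
        if min(self.flow_start_mol_s, self.flow_end_mol_s) <= 0:
            raise ValueError("flows must be positive")

    def effective_cue(self, day: np.ndarray) -> np.ndarray:
        frac = np.clip(np.asarray(day, dtype=float) / self.cue_ramp_days, 0.0, 1.0)
        return self.seedling_cue + (self.true_cue - self.seedling_cue) * frac


def _daily_rates(
    capture: np.ndarray,
    total_ppfd: float,
    phys: PhysiologyParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day gross assimilation and respiration fluxes (µmol m⁻² s⁻¹)."""
    days = np.arange(capture.size)
    gross = phys.true_quantum_yield * total_ppfd * capture
    cue = phys.effective_cue(days)
    resp = phys.photoperiod_h * gross * (1.0 - cue) / 24.0
    if np.any(resp < 0):
        raise ValueError("infeasible CUE: implied respiration is negative")
    return gross, resp


def simulate_chamber_stream(
    capture_by_chamber: np.ndarray,
    phys: PhysiologyParams,
    schedule: SamplingSchedule,
    seed: int,
    ground_area_m2: float = 0.17,
    total_ppfd: float = 350.0,
    day_length_s: int = 86400,
) -> pd.DataFrame:
    """Per-second multiplexed analyzer stream for all chambers.

    Parameters
    ----------
    capture_by_chamber : array, shape (n_chambers, n_days)
        True daily canopy photon capture per chamber.
    phys, schedule, seed
        Physiology, multiplexer rotation, and RNG seed (streams are
        reproducible: the same seed yields an identical stream).

    The light-period net flux of chamber c on day d is
    ``true_QY × total_ppfd × capture[c, d] − resp[c, d]`` and the dark-period
    flux is ``−resp[c, d]``, with respiration set from the effective CUE via
    resp = photoperiod × gross × (1 − CUE) / 24. The analyzer reading is
    ΔCO₂ = flux × area / flow plus Gaussian noise; purge-window seconds carry
    a contaminated mixture of the current and previous chamber signals (they
    must be discarded by the demultiplexer).
    """
    capture = np.atleast_2d(np.asarray(capture_by_chamber, dtype=float))
    n_chambers, n_days = capture.shape
    if n_chambers != schedule.n_chambers:
        raise ValueError("capture rows must match schedule.n_chambers")
    gross = np.empty_like(capture)
    resp = np.empty_like(capture)
    for c in range(n_chambers):
        gross[c], resp[c] = _daily_rates(capture[c], total_ppfd, phys)

    t = np.arange(n_days * day_length_s, dtype=np.int64)
    day = (t // day_length_s).astype(np.intp)
    light = (t % day_length_s) < phys.photoperiod_h * 3600.0
    chamber = schedule.chamber_at(t.astype(float))
    prev_chamber = (chamber - 1) % n_chambers

    def flux_of(ch: np.ndarray) -> np.ndarray:
        return np.where(light, gross[ch, day] - resp[ch, day], -resp[ch, day])

    flow = np.interp(
        day, [0, max(n_days - 1, 1)], [phys.flow_start_mol_s, phys.flow_end_mol_s]
    )
    flux = flux_of(chamber)
    in_sample = schedule.in_sample_window(t.astype(float))
    # Purge seconds read a mixed signal from the shared tubing.
    flux = np.where(in_sample, flux, 0.5 * (flux + flux_of(prev_chamber)))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, phys.delta_co2_noise_sd, size=t.size)
    delta = flux * ground_area_m2 / flow + noise

    return pd.DataFrame(
        {
            "timestamp_s": t,
            "chamber_id": chamber.astype(np.int16),
            "flow_mol_s": flow,
            "delta_co2_umol_mol": delta,
            "light_on": light,
        }
    )


# ---------------------------------------------------------------------------
# Canopy images

_PLANT_RGB = np.array([60, 160, 70], dtype=float)
_SOIL_RGB = np.array([130, 90, 70], dtype=float)


def render_canopy_image(
    cover_fraction: float,
    size: tuple[int, int] = (200, 200),
    seed: int = 0,
    tol: float = 0.002,
) -> np.ndarray:
    """Render a top-down canopy image with a known green-pixel fraction.

    Green ellipses ("leaves") are placed at random over a soil-colored
    background until the realized green fraction is within ``tol`` of the
    request (the final ellipse is shrunk by bisection to land inside the
    tolerance). Returns an RGB uint8 image; the realized fraction is
    recoverable exactly by counting green-dominant pixels.
    """
    if not 0.0 <= cover_fraction <= 1.0:
        raise ValueError("cover fraction must lie in [0, 1]")
    h, w = size
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=bool)
    n_px = h * w

    if cover_fraction >= 1.0 - tol / 2:
        mask[:] = cover_fraction >= 1.0
    if not mask.all() and cover_fraction > 0:
        for _ in range(2000):
            frac = mask.sum() / n_px
            if frac >= cover_fraction - tol:
                break
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry = rng.uniform(0.04, 0.16) * h
            rx = rng.uniform(0.04, 0.16) * w
            rot = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
            trial = mask.copy()
            trial[rr, cc] = True
            if trial.sum() / n_px <= cover_fraction + tol:
                mask = trial
                continue
            # Overshoot: bisect the ellipse scale to land inside tolerance.
            lo_s, hi_s = 0.0, 1.0
            for _ in range(30):
                mid = 0.5 * (lo_s + hi_s)
                rr, cc = draw_ellipse(
                    cy, cx, max(ry * mid, 0.5), max(rx * mid, 0.5),
                    shape=(h, w), rotation=rot,
                )
                trial = mask.copy()
                trial[rr, cc] = True
                f = trial.sum() / n_px
                if f > cover_fraction + tol:
                    hi_s = mid
                elif f < cover_fraction - tol:
                    lo_s = mid
                else:
                    mask = trial
                    break
            else:
                continue
            break
        else:
            raise ValueError(
                f"could not reach cover {cover_fraction:.3f} within tolerance"
            )

    img = np.empty((h, w, 3), dtype=float)
    img[:] = _SOIL_RGB
    img[mask] = _PLANT_RGB
    # Texture noise small enough to never flip the green-dominance classifier.
    img += rng.normal(0.0, 8.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Full experiment


@dataclass(frozen=True)
class ExperimentTruth:
    """Ground truth for a generated experiment.

    ``per_day`` has one row per chamber-day with the true leaf area, cover,
    capture, fluxes, P_gross, DCG and cumulative biomass; biomass obeys
    biomass(d) = initial + Σ_{j≤d} DCG(j) exactly.
    """

    seed: int
    phys: PhysiologyParams
    growth: dict[int, GrowthParams]
    treatments: dict[int, str]
    leaf_absorption: dict[int, float]
    per_day: pd.DataFrame
    initial_dry_mass_g: float


@dataclass(frozen=True)
class SyntheticExperiment:
    """A complete generated experiment: all pipeline inputs plus truth."""

    spectra: dict[int, SpectralDistribution]
    absorptance: dict[int, AbsorptanceSpectrum]
    stream: pd.DataFrame
    cover_images: dict[tuple[int, int], np.ndarray]
    harvest: pd.DataFrame
    schedule: SamplingSchedule
    conversion: CarbonConversion
    total_ppfd: float
    truth: ExperimentTruth | None


def _default_growth(fr: bool) -> GrowthParams:
    # FR expansion multiplier calibrated so the final-leaf-area ratio of the
    # FR vs control treatments is ~1.4 (harvest contrast of far-red-grown
    # canopies).
    return GrowthParams(fr_expansion_multiplier=1.164 if fr else 1.0)


def simulate_experiment(
    seed: int,
    n_days: int = 18,
    treatments: tuple[TreatmentSpec, ...] = DEFAULT_TREATMENTS,
    phys: PhysiologyParams | None = None,
    schedule: SamplingSchedule | None = None,
    conversion: CarbonConversion | None = None,
    growth_by_chamber: dict[int, GrowthParams] | None = None,
    initial_dry_mass_g: float = 0.05,
    image_size: tuple[int, int] = (200, 200),
    render_images: bool = True,
) -> SyntheticExperiment:
    """Generate a full multi-chamber experiment with recorded ground truth.

    One chamber per treatment; far-red treatments get the far-red-grown leaf
    absorptance profile and a faster leaf-expansion rate. All randomness
    derives from ``seed``; repeated calls with the same seed are identical.
    """
    phys = phys or PhysiologyParams()
    schedule = schedule or SamplingSchedule(n_chambers=len(treatments))
    conversion = conversion or CarbonConversion(photoperiod_h=phys.photoperiod_h,
                                                dark_h=24.0 - phys.photoperiod_h)
    if schedule.n_chambers != len(treatments):
        raise ValueError("schedule.n_chambers must equal the number of treatments")
    area = conversion.ground_area_m2
    total_ppfd = treatments[0].total_ppfd

    spectra: dict[int, SpectralDistribution] = {}
    absorptance: dict[int, AbsorptanceSpectrum] = {}
    leaf_abs: dict[int, float] = {}
    growth: dict[int, GrowthParams] = {}
    rows = []
    capture = np.empty((len(treatments), n_days))

    for ch, spec in enumerate(treatments):
        has_fr = spec.target_fractions[3] > 0.01
        spectra[ch] = make_led_spectrum(spec)
        absorptance[ch] = make_absorptance(**(FR_GROWN_LEAF if has_fr else CONTROL_LEAF))
        leaf_abs[ch] = leaf_photon_absorption(spectra[ch], absorptance[ch])
        growth[ch] = (growth_by_chamber or {}).get(ch, _default_growth(has_fr))

        traj = simulate_canopy_growth(growth[ch], n_days, area)
        k = extinction_coefficient(leaf_abs[ch])
        within = beer_lambert_absorption(k, traj["leaf_layers"].to_numpy())
        cap = traj["cover_fraction"].to_numpy() * within
        capture[ch] = cap

        gross, resp = _daily_rates(cap, total_ppfd, phys)
        pnl = (gross - resp) * UMOL_S_TO_MOL_H
        rd = -resp * UMOL_S_TO_MOL_H
        pgross = (pnl + np.abs(rd)) * conversion.photoperiod_h * area * conversion.g_per_mol_co2
        dcg = (
            pnl * conversion.photoperiod_h - np.abs(rd) * conversion.dark_h
        ) * area * conversion.g_per_mol_co2
        biomass = initial_dry_mass_g + np.cumsum(dcg)
        frame = traj.copy()
        frame["chamber_id"] = ch
        frame["capture_fraction"] = cap
        frame["gross_flux_umol_m2_s"] = gross
        frame["resp_flux_umol_m2_s"] = resp
        frame["pnet_light_mol_m2_h"] = pnl
        frame["rdark_mol_m2_h"] = rd
        frame["pgross_g_d"] = pgross
        frame["dcg_g_d"] = dcg
        frame["cue"] = dcg / pgross
        frame["biomass_g"] = biomass
        rows.append(frame)

    per_day = pd.concat(rows, ignore_index=True)
    stream = simulate_chamber_stream(
        capture, phys, schedule, seed=seed, ground_area_m2=area, total_ppfd=total_ppfd
    )

    images: dict[tuple[int, int], np.ndarray] = {}
    if render_images:
        child_seeds = np.random.SeedSequence(seed).spawn(len(treatments) * n_days)
        for ch in range(len(treatments)):
            cov = per_day.loc[per_day["chamber_id"] == ch, "cover_fraction"].to_numpy()
            for d in range(n_days):
                s = int(child_seeds[ch * n_days + d].generate_state(1)[0] % 2**31)
                images[(ch, d)] = render_canopy_image(cov[d], image_size, seed=s)

    harvest_rows = []
    for ch in range(len(treatments)):
        grp = per_day[per_day["chamber_id"] == ch]
        harvest_rows.append(
            {
                "chamber_id": ch,
                "treatment": treatments[ch].name,
                "total_leaf_area_m2": float(grp["total_leaf_area_m2"].iloc[-1]),
                "dry_mass_g": float(grp["biomass_g"].iloc[-1]),
                "initial_dry_mass_g": initial_dry_mass_g,
            }
        )
    harvest = pd.DataFrame(harvest_rows)

    truth = ExperimentTruth(
        seed=seed,
        phys=phys,
        growth=growth,
        treatments={ch: t.name for ch, t in enumerate(treatments)},
        leaf_absorption=leaf_abs,
        per_day=per_day,
        initial_dry_mass_g=initial_dry_mass_g,
    )
    return SyntheticExperiment(
        spectra=spectra,
        absorptance=absorptance,
        stream=stream,
        cover_images=images,
        harvest=harvest,
        schedule=schedule,
        conversion=conversion,
        total_ppfd=total_ppfd,
        truth=truth,
    )
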
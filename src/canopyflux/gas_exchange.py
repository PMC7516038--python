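"""Chamber gas-exchange stream processing and daily carbon metrics.

A multiplexed infra-red gas analyzer (IRGA) samples several growth chambers
in a fixed rotation: each chamber is sampled for ``sample_s`` seconds, then
the shared tubing is purged for ``purge_s`` seconds before the next chamber.
:func:`demultiplex_stream` discards purge-window readings, drops an
equilibration interval at the start of each sampling window, and averages the
remainder into one record per chamber visit.

Net CO₂ flux is computed from mass flow and the pre-minus-post chamber CO₂
mole-fraction difference (signed so net uptake is positive and dark
respiration negative). Daily light/dark period means then feed the canopy
carbon bookkeeping:

    P_gross = (P_net,light + |R_dark|) · photoperiod · area · g_per_mol
    DCG     = (P_net,light · photoperiod − |R_dark| · dark_h) · area · g_per_mol
    CUE     = DCG / P_gross

with period means in mol CO₂ m⁻² h⁻¹ and P_gross, DCG in g dry mass d⁻¹
(30 g per mol CO₂ assimilated, i.e. a tissue carbon fraction of 0.4 g g⁻¹).
Respiration in the light is assumed equal to dark respiration, the standard
assumption in canopy photosynthesis work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SamplingSchedule",
    "CarbonConversion",
    "demultiplex_stream",
    "net_flux",
    "flux_series",
    "daily_period_means",
    "gross_photosynthesis",
    "daily_carbon_gain",
    "carbon_use_efficiency",
    "predict_harvest_mass",
    "daily_summaries",
]

#: µmol s⁻¹ → mol h⁻¹
UMOL_S_TO_MOL_H = 3600.0 * 1e-6

RAW_STREAM_COLUMNS = [
    "timestamp_s",
    "chamber_id",
    "flow_mol_s",
    "delta_co2_umol_mol",
    "light_on",
]


@dataclass(frozen=True)
class SamplingSchedule:
    """Multiplexer rotation: each of ``n_chambers`` is sampled for
    ``sample_s`` seconds then the line is purged for ``purge_s`` seconds."""

    n_chambers: int = 4
    sample_s: float = 30.0
    purge_s: float = 40.0

    def __post_init__(self) -> None:
        if self.n_chambers < 1:
            raise ValueError("n_chambers must be >= 1")
        if self.sample_s <= 0 or self.purge_s < 0:
            raise ValueError("sample_s must be > 0 and purge_s >= 0")

    @property
    def slot_s(self) -> float:
        return self.sample_s + self.purge_s

    @property
    def cycle_s(self) -> float:
        """Revisit period of a single chamber (280 s for 4 × (30 + 40))."""
        return self.n_chambers * self.slot_s

    def chamber_at(self, timestamp_s: np.ndarray) -> np.ndarray:
        """Chamber index (0-based) connected to the analyzer at each time."""
        return (
            np.floor(np.asarray(timestamp_s) % self.cycle_s / self.slot_s)
        ).astype(int) % self.n_chambers

    def in_sample_window(self, timestamp_s: np.ndarray) -> np.ndarray:
        """True where a reading falls in a sampling (non-purge) window."""
        return (np.asarray(timestamp_s) % self.slot_s) < self.sample_s


@dataclass(frozen=True)
class CarbonConversion:
    """Constants converting period-mean fluxes into daily carbon terms.

    Defaults: 14 h photoperiod, 10 h dark, 0.17 m² chamber ground area and
    30 g dry mass per mol CO₂ assimilated (carbon fraction 0.4 g g⁻¹).
    """

    photoperiod_h: float = 14.0
    dark_h: float = 10.0
    ground_area_m2: float = 0.17
    g_per_mol_co2: float = 30.0

    def __post_init__(self) -> None:
        if min(self.photoperiod_h, self.dark_h, self.ground_area_m2, self.g_per_mol_co2) <= 0:
            raise ValueError("all conversion constants must be positive")
        if abs(self.photoperiod_h + self.dark_h - 24.0) > 1e-9:
            raise ValueError("photoperiod_h + dark_h must equal 24")


def demultiplex_stream(
    records: pd.DataFrame,
    schedule: SamplingSchedule,
    window_discard_s: float = 10.0,
) -> pd.DataFrame:
    """Reduce a raw multiplexed analyzer stream to per-visit chamber records.

    Parameters
    ----------
    records : DataFrame
        Timestamp-ordered raw readings with columns ``timestamp_s``,
        ``chamber_id``, ``flow_mol_s``, ``delta_co2_umol_mol``, ``light_on``.
        ``delta_co2_umol_mol`` is signed so that net uptake is positive.
    schedule : SamplingSchedule
        Rotation used to identify purge windows and chamber slots.
    window_discard_s : float
        Equilibration interval discarded at the start of every sampling
        window before the remainder is averaged to one record per visit.

    Returns
    -------
    DataFrame with one row per chamber visit: ``timestamp_s`` (window
    midpoint), ``chamber_id``, ``flow_mol_s``, ``delta_co2_umol_mol``
    (means over the retained seconds), ``light_on``.
    """
    missing = [c for c in RAW_STREAM_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"raw stream missing columns {missing}")
    ts = records["timestamp_s"].to_numpy(dtype=float)
    if np.any(np.diff(ts) < 0):
        raise ValueError("raw stream must be timestamp-ordered")
    if window_discard_s >= schedule.sample_s:
        raise ValueError("window_discard_s must be shorter than the sampling window")

    expected = schedule.chamber_at(ts)
    observed = records["chamber_id"].to_numpy()
    in_window = schedule.in_sample_window(ts)
    if not np.array_equal(np.unique(observed), np.unique(expected)):
        raise ValueError(
            "stream chamber ids inconsistent with the sampling schedule "
            f"(stream has {np.unique(observed)}, schedule implies {np.unique(expected)})"
        )

    offset = ts % schedule.slot_s
    keep = in_window & (offset >= window_discard_s)
    kept = records.loc[keep].copy()
    if kept.empty:
        raise ValueError("no readings retained; schedule/stream mismatch")
    # One visit = one sampling window: index by slot number since t=0.
    kept["_visit"] = (kept["timestamp_s"].to_numpy() // schedule.slot_s).astype(np.int64)
    grouped = kept.groupby(["chamber_id", "_visit"], sort=True).agg(
        timestamp_s=("timestamp_s", "mean"),
        flow_mol_s=("flow_mol_s", "mean"),
        delta_co2_umol_mol=("delta_co2_umol_mol", "mean"),
        light_on=("light_on", "max"),
    )
    out = grouped.reset_index().drop(columns="_visit")
    out = out.sort_values("timestamp_s").reset_index(drop=True)
    return out[["timestamp_s", "chamber_id", "flow_mol_s", "delta_co2_umol_mol", "light_on"]]


def net_flux(flow_mol_s, delta_co2_umol_mol, ground_area_m2):
    """Net CO₂ flux P_net (µmol m⁻²_ground s⁻¹) from mass flow (mol s⁻¹) and
    the uptake-signed pre-minus-post CO₂ difference (µmol mol⁻¹)."""
    flow = np.asarray(flow_mol_s, dtype=float)
    if np.any(flow <= 0):
        raise ValueError("flow must be positive")
    if np.any(np.asarray(ground_area_m2, dtype=float) <= 0):
        raise ValueError("ground area must be positive")
    result = flow * np.asarray(delta_co2_umol_mol, dtype=float) / ground_area_m2
    return float(result) if np.ndim(result) == 0 else result


def flux_series(chamber_records: pd.DataFrame, ground_area_m2: float) -> pd.DataFrame:
    """Attach per-record net flux (µmol m⁻² s⁻¹) to demultiplexed records."""
    out = chamber_records.copy()
    out["pnet_umol_m2_s"] = net_flux(
        out["flow_mol_s"].to_numpy(),
        out["delta_co2_umol_mol"].to_numpy(),
        ground_area_m2,
    )
    return out


def daily_period_means(
    flux: pd.DataFrame,
    photoperiod_h: float = 14.0,
    transition_exclusion_min: float = 10.0,
    min_fraction: float = 0.8,
    day_length_s: float = 86400.0,
) -> pd.DataFrame:
    """Per-day, per-chamber light- and dark-period mean fluxes.

    Days are delimited by the lights-on event (time 0 of each day), the first
    ``photoperiod_h`` hours being the light period. Records within
    ``transition_exclusion_min`` minutes after either light switch are
    excluded from the means because the chamber is not at steady state. A
    chamber-day is reported only when both periods retain at least
    ``min_fraction`` of the records expected from the revisit rate; otherwise
    an incomplete-day error is raised.

    Returns a DataFrame with ``day``, ``chamber_id``,
    ``pnet_light_mol_m2_h`` and ``rdark_mol_m2_h`` (µmol s⁻¹ means × 3600e-6).
    """
    if "pnet_umol_m2_s" not in flux.columns:
        raise ValueError("flux frame must carry pnet_umol_m2_s (see flux_series)")
    ts = flux["timestamp_s"].to_numpy(dtype=float)
    t_in_day = ts % day_length_s
    day = (ts // day_length_s).astype(int)
    light_window_s = photoperiod_h * 3600.0
    excl_s = transition_exclusion_min * 60.0

    in_light = t_in_day < light_window_s
    light_flag = flux["light_on"].to_numpy(dtype=bool)
    # Averaged sampling windows can straddle a switch; flag/schedule
    # mismatches mark those non-steady-state records, which are excluded
    # alongside the post-switch transition window.
    mismatch = in_light != light_flag
    if mismatch.mean() > 0.05:
        raise ValueError("light_on flags inconsistent with the photoperiod schedule")
    after_on = t_in_day < excl_s
    after_off = (~in_light) & (t_in_day - light_window_s < excl_s)
    excluded = after_on | after_off | mismatch

    frame = pd.DataFrame(
        {
            "day": day,
            "chamber_id": flux["chamber_id"].to_numpy(),
            "light": in_light,
            "pnet": flux["pnet_umol_m2_s"].to_numpy(),
            "excluded": excluded,
        }
    )
    kept = frame.loc[~frame["excluded"]]

    rows = []
    for (d, ch), grp in kept.groupby(["day", "chamber_id"], sort=True):
        light_grp = grp.loc[grp["light"], "pnet"]
        dark_grp = grp.loc[~grp["light"], "pnet"]
        if light_grp.empty or dark_grp.empty:
            raise ValueError(f"day {d} chamber {ch}: missing light or dark samples")
        # Expected visit counts from the observed revisit rate for this chamber
        n_total = len(grp)
        expected_light = n_total * (light_window_s - excl_s) / (
            day_length_s - 2 * excl_s
        )
        expected_dark = n_total - expected_light
        if (
            len(light_grp) < min_fraction * expected_light
            or len(dark_grp) < min_fraction * expected_dark
        ):
            raise ValueError(f"day {d} chamber {ch}: incomplete coverage")
        rows.append(
            {
                "day": d,
                "chamber_id": ch,
                "pnet_light_mol_m2_h": light_grp.mean() * UMOL_S_TO_MOL_H,
                "rdark_mol_m2_h": dark_grp.mean() * UMOL_S_TO_MOL_H,
            }
        )
    return pd.DataFrame(rows)


def gross_photosynthesis(pnet_light_mol_m2_h, rdark_mol_m2_h, conv: CarbonConversion) -> float:
    """Daily gross photosynthesis (g dry mass d⁻¹):
    (P_net,light + |R_dark|) × photoperiod_h × area × g_per_mol."""
    pnl = np.asarray(pnet_light_mol_m2_h, dtype=float)
    rd = np.abs(np.asarray(rdark_mol_m2_h, dtype=float))
    result = (pnl + rd) * conv.photoperiod_h * conv.ground_area_m2 * conv.g_per_mol_co2
    return float(result) if np.ndim(result) == 0 else result


def daily_carbon_gain(pnet_light_mol_m2_h, rdark_mol_m2_h, conv: CarbonConversion) -> float:
    """Daily carbon gain (g dry mass d⁻¹): day-time net uptake minus
    night-time respiration, (P_net,light·photoperiod − |R_dark|·dark_h) ×
    area × g_per_mol."""
    pnl = np.asarray(pnet_light_mol_m2_h, dtype=float)
    rd = np.abs(np.asarray(rdark_mol_m2_h, dtype=float))
    result = (
        pnl * conv.photoperiod_h - rd * conv.dark_h
    ) * conv.ground_area_m2 * conv.g_per_mol_co2
    return float(result) if np.ndim(result) == 0 else result


def carbon_use_efficiency(dcg_g_d, pgross_g_d):
    """CUE = DCG / P_gross; ≤ 1 whenever R_dark ≤ 0."""
    pg = np.asarray(pgross_g_d, dtype=float)
    if np.any(pg <= 0):
        raise ValueError("CUE undefined for non-positive gross photosynthesis")
    result = np.asarray(dcg_g_d, dtype=float) / pg
    return float(result) if np.ndim(result) == 0 else result


def daily_summaries(period_means: pd.DataFrame, conv: CarbonConversion) -> pd.DataFrame:
    """Daily carbon bookkeeping per chamber-day from period means."""
    out = period_means.copy()
    out["pgross_g_d"] = gross_photosynthesis(
        out["pnet_light_mol_m2_h"].to_numpy(), out["rdark_mol_m2_h"].to_numpy(), conv
    )
    out["dcg_g_d"] = daily_carbon_gain(
        out["pnet_light_mol_m2_h"].to_numpy(), out["rdark_mol_m2_h"].to_numpy(), conv
    )
    out["cue"] = carbon_use_efficiency(
        out["dcg_g_d"].to_numpy(), out["pgross_g_d"].to_numpy()
    )
    return out


def predict_harvest_mass(
    dcg_g_d, initial_dry_mass_g: float = 0.0, measured_dry_mass_g: float | None = None
):
    """Harvest dry mass predicted by cumulative daily carbon gain.

    Returns ``initial + Σ DCG`` (g); when a measured mass is supplied, also
    returns predicted/measured as a percentage (the mass-balance closure of
    the gas-exchange record).
    """
    predicted = float(initial_dry_mass_g + np.sum(np.asarray(dcg_g_d, dtype=float)))
    if measured_dry_mass_g is None:
        return predicted
    if measured_dry_mass_g <= 0:
        raise ValueError("measured dry mass must be positive")
    return predicted, 100.0 * predicted / measured_dry_mass_g
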
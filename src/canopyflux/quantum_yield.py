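"""Canopy quantum yield for CO₂ fixation and photosynthesis-vs-capture
regression.

Canopy quantum yield is the number of moles of CO₂ fixed in gross
photosynthesis per mole of photons absorbed by the canopy (400-750 nm):

    QY = P_gross,incident / capture

where P_gross,incident is gross photosynthesis expressed per mole of
*incident* photons — P_gross in g d⁻¹ divided by the g-per-mol conversion,
the chamber ground area, and the daily light integral — and capture is the
fraction of incident photons the canopy absorbs.

Because growth differences between light treatments can arise from photon
capture rather than photosynthetic efficiency, the module also regresses
P_gross (or daily carbon gain) on capture, per treatment and pooled, and
reports a common-slope diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .gas_exchange import CarbonConversion

__all__ = [
    "RegressionResult",
    "pgross_per_incident_photon",
    "canopy_quantum_yield",
    "regress_on_capture",
    "treatment_report",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of photosynthesis on photon capture."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float


def pgross_per_incident_photon(
    pgross_g_d, conv: CarbonConversion, dli_mol_m2_d: float
):
    """Convert P_gross from g d⁻¹ to mol CO₂ per mol incident photons:
    divide by g_per_mol, by chamber ground area, and by the daily light
    integral."""
    if dli_mol_m2_d <= 0:
        raise ValueError("daily light integral must be positive")
    result = (
        np.asarray(pgross_g_d, dtype=float)
        / conv.g_per_mol_co2
        / conv.ground_area_m2
        / dli_mol_m2_d
    )
    return float(result) if np.ndim(result) == 0 else result


def canopy_quantum_yield(pgross_incident, capture):
    """Moles of CO₂ fixed in gross photosynthesis per mole of *absorbed*
    photons: P_gross,incident / capture."""
    cap = np.asarray(capture, dtype=float)
    if np.any((cap <= 0) | (cap > 1)):
        raise ValueError("capture must lie in (0, 1]")
    result = np.asarray(pgross_incident, dtype=float) / cap
    return float(result) if np.ndim(result) == 0 else result


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: x has zero variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = max(x.size - 2, 1)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(x.size),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def regress_on_capture(
    capture,
    y,
    treatment=None,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> dict:
    """Regress P_gross (or DCG) on canopy photon capture.

    Returns a dict with the pooled ``RegressionResult``, per-treatment fits
    when ``treatment`` labels are given, and a ``common slope`` diagnostic:
    the maximum pairwise relative difference between treatment slopes
    (descriptive, optionally with bootstrap slope standard errors).
    """
    x = np.asarray(capture, dtype=float)
    yv = np.asarray(y, dtype=float)
    out: dict = {"pooled": _ols(x, yv)}
    if treatment is None:
        return out

    labels = np.asarray(treatment)
    per = {}
    for lab in pd.unique(labels):
        m = labels == lab
        if m.sum() >= 3 and np.ptp(x[m]) > 0:  # skip degenerate groups
            per[str(lab)] = _ols(x[m], yv[m])
    out["per_treatment"] = per

    slopes = np.array([r.slope for r in per.values()])
    if len(slopes) >= 2 and np.all(np.abs(slopes) > 0):
        rel_diff = max(
            abs(a - b) / max(abs(a), abs(b)) for a, b in combinations(slopes, 2)
        )
    else:
        rel_diff = float("nan")
    out["max_pairwise_slope_rel_diff"] = float(rel_diff)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        se = {}
        for lab in per:
            m = labels == np.asarray(lab, dtype=labels.dtype)
            xi, yi = x[m], yv[m]
            draws = []
            for _ in range(n_bootstrap):
                idx = rng.integers(0, xi.size, xi.size)
                if np.ptp(xi[idx]) == 0:
                    continue
                draws.append(stats.linregress(xi[idx], yi[idx]).slope)
            se[lab] = float(np.std(draws)) if draws else float("nan")
        out["bootstrap_slope_se"] = se
    return out


def treatment_report(
    summaries: pd.DataFrame,
    captures: pd.DataFrame,
    conv: CarbonConversion,
    dli_mol_m2_d: float,
    harvest: pd.DataFrame | None = None,
    treatments: dict[int, str] | None = None,
    seedling_days: int = 7,
    cue_window_days: int = 6,
) -> dict:
    """Assemble the per-treatment analysis report.

    Parameters
    ----------
    summaries : DataFrame
        Per chamber-day gas-exchange summary (``day``, ``chamber_id``,
        ``pnet_light_mol_m2_h``, ``rdark_mol_m2_h``, ``pgross_g_d``,
        ``dcg_g_d``, ``cue``).
    captures : DataFrame
        Per chamber-day capture (``day``, ``chamber_id``, ``cover_fraction``,
        ``leaf_layers``, ``capture_fraction``).
    harvest : DataFrame, optional
        Per chamber ``chamber_id``, ``dry_mass_g`` (and optionally
        ``initial_dry_mass_g``) for mass-balance closure.
    treatments : dict, optional
        chamber_id → treatment name for labelling.
    seedling_days : int
        Leading days excluded from the quantum-yield aggregate (capture
        estimates are least reliable for small seedlings).
    cue_window_days : int
        Trailing window for the mature-plant CUE aggregate (default: the
        final six days before harvest).

    Returns a JSON-serializable dict: ``treatments[]`` each with ``daily[]``
    rows and a ``harvest{}`` aggregate block, plus a pooled
    photosynthesis-vs-capture regression.
    """
    merged = summaries.merge(captures, on=["day", "chamber_id"], how="inner")
    if merged.empty:
        raise ValueError("no aligned day/chamber rows between summaries and captures")
    if len(merged) < len(summaries):
        raise ValueError("summaries contain chamber-days missing from captures")
    merged["pgross_incident"] = pgross_per_incident_photon(
        merged["pgross_g_d"].to_numpy(), conv, dli_mol_m2_d
    )
    merged["quantum_yield"] = canopy_quantum_yield(
        merged["pgross_incident"].to_numpy(), merged["capture_fraction"].to_numpy()
    )

    report: dict = {"treatments": [], "dli_mol_m2_d": dli_mol_m2_d}
    last_day = int(merged["day"].max())
    for ch, grp in merged.groupby("chamber_id", sort=True):
        grp = grp.sort_values("day")
        mature = grp[grp["day"] > last_day - cue_window_days]
        post_seedling = grp[grp["day"] >= seedling_days]
        qy_source = post_seedling if not post_seedling.empty else grp
        entry = {
            "chamber_id": int(ch),
            "name": (treatments or {}).get(int(ch), f"chamber_{ch}"),
            "daily": grp[
                [
                    "day",
                    "pnet_light_mol_m2_h",
                    "rdark_mol_m2_h",
                    "pgross_g_d",
                    "dcg_g_d",
                    "cue",
                    "cover_fraction",
                    "leaf_layers",
                    "capture_fraction",
                    "quantum_yield",
                ]
            ].to_dict(orient="records"),
            "harvest": {
                "mean_quantum_yield": float(qy_source["quantum_yield"].mean()),
                "mean_cue_final_days": float(mature["cue"].mean()),
                "final_cover": float(grp["cover_fraction"].iloc[-1]),
                "final_capture": float(grp["capture_fraction"].iloc[-1]),
                "cumulative_dcg_g": float(grp["dcg_g_d"].sum()),
            },
        }
        # Regression-through-origin slope of P_gross,incident on capture is
        # an alternative quantum-yield estimate; report both.
        cap = grp["capture_fraction"].to_numpy()
        entry["harvest"]["quantum_yield_regression_through_origin"] = float(
            np.sum(cap * grp["pgross_incident"].to_numpy()) / np.sum(cap**2)
        )
        if harvest is not None:
            row = harvest.loc[harvest["chamber_id"] == ch]
            if not row.empty:
                measured = float(row["dry_mass_g"].iloc[0])
                initial = (
                    float(row["initial_dry_mass_g"].iloc[0])
                    if "initial_dry_mass_g" in row.columns
                    else 0.0
                )
                predicted = initial + entry["harvest"]["cumulative_dcg_g"]
                entry["harvest"]["predicted_dry_mass_g"] = predicted
                entry["harvest"]["measured_dry_mass_g"] = measured
                entry["harvest"]["predicted_pct_of_measured"] = (
                    100.0 * predicted / measured
                )
        report["treatments"].append(entry)

    cap_all = merged["capture_fraction"].to_numpy()
    if len(merged) >= 3 and np.ptp(cap_all) > 0:
        pooled = regress_on_capture(
            cap_all,
            merged["pgross_g_d"].to_numpy(),
            treatment=merged["chamber_id"].to_numpy(),
        )
        report["pgross_vs_capture"] = {
            "pooled": asdict(pooled["pooled"]),
            "per_treatment": {k: asdict(v) for k, v in pooled["per_treatment"].items()},
            "max_pairwise_slope_rel_diff": pooled["max_pairwise_slope_rel_diff"],
        }
    else:
        report["pgross_vs_capture"] = None
    return report
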
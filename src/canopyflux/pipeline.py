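"""End-to-end analysis: raw multiplexed stream + spectra + images + harvest
→ per-treatment report.

The chain is: demultiplex the analyzer stream into per-visit chamber records;
convert to net flux and daily light/dark period means; apply the daily carbon
bookkeeping (P_gross, DCG, CUE); estimate daily cover from the top-down
images and canopy photon capture via the exponential-interpolation +
Beer-Lambert correction; then combine into canopy quantum yield and the
photosynthesis-vs-capture regression.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import gas_exchange as gx
from . import photon_capture as pc
from . import quantum_yield as qy
from .spectra import (
    daily_light_integral,
    leaf_photon_absorption,
    load_absorptance_csv,
    load_spectrum_csv,
)
from .synthetic import SyntheticExperiment

__all__ = ["analyze_experiment", "analyze_files", "cover_table_from_images"]

IMAGE_NAME_RE = re.compile(r"chamber(?P<ch>\d+)_day(?P<day>\d+)\.(png|jpg|jpeg)$")


def cover_table_from_images(
    images: dict[tuple[int, int], np.ndarray],
    roi: tuple[int, int, int, int] | None = None,
    green_threshold: float = 0.15,
) -> pd.DataFrame:
    """Daily ground-cover fractions from (chamber, day) → RGB image arrays."""
    rows = [
        {
            "chamber_id": ch,
            "day": day,
            "cover_fraction": pc.ground_cover_fraction(img, roi, green_threshold),
        }
        for (ch, day), img in sorted(images.items())
    ]
    return pd.DataFrame(rows)


def analyze_experiment(
    exp: SyntheticExperiment,
    seedling_days: int = 7,
    cue_window_days: int = 6,
    transition_exclusion_min: float = 10.0,
    window_discard_s: float = 10.0,
    cover: pd.DataFrame | None = None,
) -> dict:
    """Run the full pipeline on a generated (or equivalently structured)
    experiment and return the treatment report.

    ``cover`` may supply a precomputed ``day, chamber_id, cover_fraction``
    table; otherwise it is derived from the experiment's images (falling back
    to truth cover if images were not rendered).
    """
    conv = exp.conversion
    records = gx.demultiplex_stream(exp.stream, exp.schedule, window_discard_s)
    flux = gx.flux_series(records, conv.ground_area_m2)
    means = gx.daily_period_means(
        flux,
        photoperiod_h=conv.photoperiod_h,
        transition_exclusion_min=transition_exclusion_min,
    )
    summaries = gx.daily_summaries(means, conv)

    if cover is None:
        if exp.cover_images:
            cover = cover_table_from_images(exp.cover_images)
        else:
            cover = exp.truth.per_day[["chamber_id", "day", "cover_fraction"]].copy()

    captures = []
    for ch, grp in cover.groupby("chamber_id", sort=True):
        leaf_abs = leaf_photon_absorption(exp.spectra[ch], exp.absorptance[ch])
        harvest_area = float(
            exp.harvest.loc[exp.harvest["chamber_id"] == ch, "total_leaf_area_m2"].iloc[0]
        )
        series = pc.capture_series(
            grp, leaf_abs, harvest_area, chamber_area_m2=conv.ground_area_m2
        )
        series["chamber_id"] = ch
        captures.append(series)
    captures = pd.concat(captures, ignore_index=True)

    dli = daily_light_integral(exp.total_ppfd, conv.photoperiod_h)
    return qy.treatment_report(
        summaries,
        captures[["day", "chamber_id", "cover_fraction", "leaf_layers", "capture_fraction"]],
        conv,
        dli,
        harvest=exp.harvest,
        treatments=exp.truth.treatments if exp.truth else None,
        seedling_days=seedling_days,
        cue_window_days=cue_window_days,
    )


def _load_images_dir(images_dir: Path) -> dict[tuple[int, int], np.ndarray]:
    images = {}
    for p in sorted(Path(images_dir).iterdir()):
        m = IMAGE_NAME_RE.search(p.name)
        if m:
            images[(int(m["ch"]), int(m["day"]))] = np.asarray(Image.open(p).convert("RGB"))
    if not images:
        raise ValueError(f"no chamber{{ID}}_day{{D}} images found in {images_dir}")
    return images


def analyze_files(
    raw_csv: str | Path,
    spectra_csvs: dict[int, str | Path],
    absorptance_csvs: dict[int, str | Path],
    images_dir: str | Path,
    harvest_csv: str | Path,
    out_json: str | Path | None = None,
    total_ppfd: float | None = None,
    conversion: gx.CarbonConversion | None = None,
    schedule: gx.SamplingSchedule | None = None,
    **kwargs,
) -> dict:
    """File-based variant of :func:`analyze_experiment` for the CLI.

    ``raw_csv`` follows `timestamp_s,chamber_id,flow_mol_s,delta_co2_umol_mol,
    light_on`; ``harvest_csv`` needs `chamber_id,total_leaf_area_m2,
    dry_mass_g` (optional `initial_dry_mass_g`).
    """
    from .spectra import SpectralDistribution  # noqa: F401 (type context)

    stream = pd.read_csv(raw_csv, comment="#")
    stream["light_on"] = stream["light_on"].astype(bool)
    harvest = pd.read_csv(harvest_csv, comment="#")
    spectra = {ch: load_spectrum_csv(p) for ch, p in spectra_csvs.items()}
    absorptance = {ch: load_absorptance_csv(p) for ch, p in absorptance_csvs.items()}
    images = _load_images_dir(Path(images_dir))
    schedule = schedule or gx.SamplingSchedule(n_chambers=len(spectra))
    conversion = conversion or gx.CarbonConversion()
    if total_ppfd is None:
        total_ppfd = float(np.mean([s.total_flux() for s in spectra.values()]))

    exp = SyntheticExperiment(
        spectra=spectra,
        absorptance=absorptance,
        stream=stream,
        cover_images=images,
        harvest=harvest,
        schedule=schedule,
        conversion=conversion,
        total_ppfd=total_ppfd,
        truth=None,
    )
    report = analyze_experiment(exp, **kwargs)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2))
    return report
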
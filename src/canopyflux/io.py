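"""Writers for generated experiments (the `simulate` CLI output layout)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import SyntheticExperiment

__all__ = ["write_experiment"]


def write_experiment(exp: SyntheticExperiment, out_dir: str | Path) -> Path:
    """Write all pipeline inputs plus ``truth.json`` to a directory.

    Layout: ``spectrum_chamber{ID}.csv``, ``absorptance_chamber{ID}.csv``,
    ``raw_stream.csv``, ``images/chamber{ID}_day{D}.png``, ``harvest.csv``,
    ``truth.json`` and ``truth_per_day.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for ch, spectrum in exp.spectra.items():
        pd.DataFrame(
            {
                "wavelength_nm": spectrum.wavelength_nm,
                "flux_umol_m2_s_nm": spectrum.flux_density,
            }
        ).to_csv(out / f"spectrum_chamber{ch}.csv", index=False)
    for ch, leaf in exp.absorptance.items():
        pd.DataFrame(
            {"wavelength_nm": leaf.wavelength_nm, "absorptance": leaf.absorptance}
        ).to_csv(out / f"absorptance_chamber{ch}.csv", index=False)

    exp.stream.to_csv(out / "raw_stream.csv", index=False)
    exp.harvest.to_csv(out / "harvest.csv", index=False)

    if exp.cover_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for (ch, day), arr in exp.cover_images.items():
            Image.fromarray(arr).save(img_dir / f"chamber{ch}_day{day}.png")

    if exp.truth is not None:
        truth = exp.truth
        truth.per_day.to_csv(out / "truth_per_day.csv", index=False)
        meta = {
            "seed": truth.seed,
            "physiology": asdict(truth.phys),
            "growth": {str(ch): asdict(g) for ch, g in truth.growth.items()},
            "treatments": {str(ch): name for ch, name in truth.treatments.items()},
            "leaf_absorption": {
                str(ch): float(a) for ch, a in truth.leaf_absorption.items()
            },
            "initial_dry_mass_g": truth.initial_dry_mass_g,
            "schedule": asdict(exp.schedule),
            "conversion": asdict(exp.conversion),
            "total_ppfd": exp.total_ppfd,
        }
        (out / "truth.json").write_text(json.dumps(meta, indent=2))
    return out
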
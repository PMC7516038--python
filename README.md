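# canopyflux

Canopy gas-exchange analysis for controlled-environment growth studies.
`canopyflux` separates plant growth into its three mechanistic components —
**canopy photon capture**, **canopy quantum yield for CO₂ fixation**, and
**carbon use efficiency (CUE)** — from the four data streams such studies
produce: a multiplexed chamber IRGA (infra-red gas analyzer) CO₂ stream,
LED treatment spectra, daily top-down canopy photographs, and harvest
measurements. It is aimed at plant physiologists running steady-state
whole-canopy chambers, e.g. to quantify whether far-red photons (700–750 nm)
drive photosynthesis as efficiently as traditionally defined photosynthetic
photons (400–700 nm).

Because raw chamber streams from such systems are rarely deposited, the
package also ships a synthetic-experiment generator that emulates all four
input streams with known ground truth, so the entire pipeline is testable
end to end without instruments.

## The model

Daily light/dark period means of net CO₂ flux (mol m⁻² h⁻¹) feed the canopy
carbon bookkeeping (defaults: 14 h photoperiod, 10 h dark, 0.17 m² chamber,
30 g dry mass per mol CO₂, i.e. a carbon fraction of 0.4 g g⁻¹):

```
P_gross = (P_net,light + |R_dark|) · 14 h · 0.17 m² · 30 g mol⁻¹     [g d⁻¹]
DCG     = (P_net,light · 14 h − |R_dark| · 10 h) · 0.17 m² · 30 g mol⁻¹
CUE     = DCG / P_gross
```

Canopy photon capture combines green-pixel ground cover from nadir images
with spectrum-weighted single-leaf absorption `a` and a Beer–Lambert
multilayer correction once leaves overlap:

```
k = −ln(1 − a),   within-cover absorption = 1 − e^(−k·L),
capture = cover · (1 − e^(−k·L))
```

with `L` leaf layers (total canopy leaf area / projected covered area,
interpolated exponentially between the young-canopy phase and harvest).
Canopy quantum yield is then

```
QY = P_gross [mol CO₂ / mol incident photons] / capture     [mol CO₂ / mol absorbed photons]
```

The spectra module additionally computes waveband fluxes and fractions
(blue 400–500, green 500–600, red 600–700, far-red 700–750 nm), the daily
light integral, phytochrome photoequilibrium (PPE) and spectrum-weighted
leaf photon absorption.

## Worked example

```python
from canopyflux import simulate_experiment, analyze_experiment

exp = simulate_experiment(seed=42, n_days=18)   # 4 treatments, ground truth recorded
report = analyze_experiment(exp)                 # demux -> flux -> capture -> QY
for t in report["treatments"]:
    h = t["harvest"]
    print(t["name"], round(h["mean_quantum_yield"], 4), round(h["mean_cue_final_days"], 3))
```

prints

```
RB 350 0.057 0.61
RB 300 + FR 50 0.0574 0.61
white 350 0.0569 0.61
white 300 + FR 50 0.0573 0.61
```

i.e. the pipeline recovers the generator's true quantum yield (0.057 mol CO₂
per mol absorbed photons, identical across treatments by construction) and
the true mature-plant CUE (0.61, averaged over the final six days), from the
raw multiplexed stream and the rendered canopy images alone. The report also
contains the P_gross-vs-capture regression: a pooled r² ≈ 0.999 with ~1%
maximum pairwise slope difference between treatments, the signature that
growth differences are driven by photon capture rather than photosynthetic
efficiency. Runnable narrative scripts live in `examples/`.

A thin CLI mirrors the two entry points:

```
canopyflux simulate --seed 42 --out run1/
canopyflux analyze --raw run1/raw_stream.csv --data-dir run1/ --out report.json
```

## Layout

- `src/canopyflux/spectra.py` — spectral distributions, waveband fluxes, DLI, PPE, leaf absorption
- `src/canopyflux/gas_exchange.py` — stream demultiplexing, net flux, daily carbon equations
- `src/canopyflux/photon_capture.py` — green-pixel cover, exponential leaf-area interpolation, Beer–Lambert
- `src/canopyflux/quantum_yield.py` — quantum yield, capture regression, treatment report
- `src/canopyflux/synthetic.py` — synthetic experiments with recorded ground truth
- `src/canopyflux/pipeline.py` — end-to-end analysis (in-memory and file-based)
- `docs/methods.md` — model assumptions, parameter defaults, numerical choices, limitations
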
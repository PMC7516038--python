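"""Build the four bundled LED treatment spectra and summarize their
photobiology: waveband fractions, daily light integral, phytochrome
photoequilibrium, and spectrum-weighted leaf photon absorption."""

from canopyflux import (
    compute_ppe,
    daily_light_integral,
    default_photoconversion_coefficients,
    leaf_photon_absorption,
    make_led_spectrum,
    waveband_fractions,
)
from canopyflux.synthetic import CONTROL_LEAF, DEFAULT_TREATMENTS, FR_GROWN_LEAF, make_absorptance

coeffs = default_photoconversion_coefficients()
print(f"daily light integral at 350 umol/m2/s, 14 h: "
      f"{daily_light_integral(350, 14):.2f} mol/m2/d\n")

for spec in DEFAULT_TREATMENTS:
    s = make_led_spectrum(spec)
    f = waveband_fractions(s)
    has_fr = spec.target_fractions[3] > 0.01
    leaf = make_absorptance(**(FR_GROWN_LEAF if has_fr else CONTROL_LEAF))
    print(f"{spec.name:18s} B:G:R:FR = "
          f"{100*f['blue']:.1f}:{100*f['green']:.1f}:{100*f['red']:.1f}:{100*f['far_red']:.1f} %"
          f"  PPE={compute_ppe(s, coeffs):.2f}"
          f"  leaf absorption={leaf_photon_absorption(s, leaf):.3f}")

# PPE is the estimated fraction of phytochrome in the active far-red-absorbing
# form: far-red substitution lowers it, which drives leaf expansion. Leaf
# absorption is the fraction of incident photons one leaf layer captures —
# lower for far-red-rich light because leaves transmit/reflect far-red.
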
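"""Physical constants and unit conversions used across the package.

Units are Å for length, elementary charge e for charge, volts for
potential, MV/cm for electric fields and ppm for shieldings/shifts.
"""

from __future__ import annotations

import math

#: Coulomb constant in V·Å·e⁻¹ (1/(4πε₀) with q in e and r in Å).
COULOMB_CONSTANT = 14.39964

#: 1 V/Å expressed in MV/cm.
V_PER_ANGSTROM_TO_MV_PER_CM = 100.0

#: Gyromagnetic ratios in 10⁷ rad s⁻¹ T⁻¹ (signed).
GYROMAGNETIC_RATIOS = {
    "1H": 26.7522128,
    "13C": 6.728284,
    "15N": -2.71261804,
    "17O": -3.62808,
}

#: Element symbol → NMR-active nucleus handled by this package.
ELEMENT_TO_NUCLEUS = {"H": "1H", "C": "13C", "N": "15N", "O": "17O"}

#: Maximum Shannon entropy of a 20-letter amino-acid column, in bits.
MAX_COLUMN_ENTROPY_BITS = math.log2(20.0)


def gyromagnetic_scale(nucleus: str, reference: str = "13C") -> float:
    """Return |γ(nucleus)| / |γ(reference)|.

    Multiplying a chemical-shift difference (in ppm) of ``nucleus`` by this
    factor places it on a frequency scale equivalent to the reference
    nucleus, so that e.g. ¹⁵N and ¹³C perturbations become comparable.
    """
    try:
        num = GYROMAGNETIC_RATIOS[nucleus]
        den = GYROMAGNETIC_RATIOS[reference]
    except KeyError as exc:  # pragma: no cover - trivial
        raise KeyError(f"unknown nucleus: {exc.args[0]!r}") from None
    return abs(num) / abs(den)
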
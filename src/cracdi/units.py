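"""Unit helpers.

All internal computation is in SI units: metres, seconds, amperes, volts,
and molar (mol/L) for concentrations.  The evaluation of the microdomain
formula silently spans ~15 orders of magnitude, so conversion happens at a
single, explicit boundary: these multiplicative constants.  Write
``8 * mM`` or ``2.2 * fA`` at call sites; never bake scale factors into
formulas.
"""

# length
nm = 1e-9
um = 1e-6

# current
fA = 1e-15
pA = 1e-12

# concentration (relative to molar)
mM = 1e-3
uM = 1e-6

# voltage
mV = 1e-3

# time
ms = 1e-3


def to_uM(molar: float) -> float:
    """Express a molar concentration in micromolar."""
    return molar / uM


def to_nm(metres: float) -> float:
    """Express a length in nanometres."""
    return metres / nm
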
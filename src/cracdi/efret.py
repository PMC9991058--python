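"""Three-cube sensitized-emission FRET (E-FRET).

Apparent FRET efficiency from donor (I_DD), acceptor (I_AA) and raw FRET
(I_DA) intensities, all background-subtracted:

    Fc     = I_DA - a * I_AA - d * I_DD
    E_FRET = Fc / (Fc + G * I_DD)

``a`` and ``d`` are the acceptor and donor bleed-through fractions into the
FRET channel and ``G`` the instrument factor relating sensitized emission
to quenched donor fluorescence.  The constants ``b`` and ``c`` (the minor
cross-talk terms some four-constant formalisms use) are stored for
completeness but unused by the default two-constant correction.

Analysis is restricted to cells whose acceptor/donor expression ratio
(I_AA/I_DD) lies in a fixed band (2-6 by default) so efficiencies are
compared at matched stoichiometry.  ROI-level scalars are the core
operation; arrays pass through unchanged, so per-pixel images work with
the same functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "FretConstants",
    "FretMeasurement",
    "compute_fc",
    "compute_efret",
    "ratio_gate",
    "synthetic_measurement",
]


@dataclass(frozen=True)
class FretConstants:
    """Microscope calibration constants for sensitized-emission FRET."""

    a: float = 0.12  # acceptor bleed-through into the FRET channel
    b: float = 0.008
    c: float = 0.002
    d: float = 0.33  # donor bleed-through into the FRET channel
    g: float = 1.85  # instrument G factor

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not self.g > 0:
            raise InvalidParameterError("G factor must be > 0")


@dataclass(frozen=True)
class FretMeasurement:
    """Background-subtracted intensities for one ROI (arbitrary units)."""

    i_dd: float  # donor excitation / donor emission (CFP)
    i_aa: float  # acceptor excitation / acceptor emission (YFP)
    i_da: float  # donor excitation / acceptor emission (raw FRET)

    def __post_init__(self) -> None:
        for name in ("i_dd", "i_aa", "i_da"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    @property
    def ratio(self) -> float:
        """Acceptor/donor expression ratio I_AA / I_DD."""
        return self.i_aa / self.i_dd


def compute_fc(m: FretMeasurement, k: FretConstants) -> float:
    """Bleed-through-corrected sensitized emission; may be negative."""
    return m.i_da - k.a * m.i_aa - k.d * m.i_dd


def compute_efret(m: FretMeasurement, k: FretConstants) -> float:
    """Apparent FRET efficiency Fc / (Fc + G * I_DD), in [0, 1).

    A negative corrected Fc (pure-bleed-through noise) is reported as
    efficiency 0 rather than a negative efficiency.
    """
    if m.i_dd <= 0:
        raise InvalidParameterError(
            f"i_dd must be > 0 for efficiency computation, got {m.i_dd}"
        )
    fc = compute_fc(m, k)
    if fc < 0:
        return 0.0
    return fc / (fc + k.g * m.i_dd)


def ratio_gate(
    measurements: Iterable[FretMeasurement],
    lo: float = 2.0,
    hi: float = 6.0,
) -> tuple[list[FretMeasurement], int]:
    """Keep measurements with lo <= I_AA/I_DD <= hi (inclusive).

    Returns the kept measurements and the rejection count.
    """
    kept: list[FretMeasurement] = []
    rejected = 0
    for m in measurements:
        if lo <= m.ratio <= hi:
            kept.append(m)
        else:
            rejected += 1
    return kept, rejected


def synthetic_measurement(
    true_e: float,
    ratio: float,
    k: FretConstants | None = None,
    i_dd: float = 1000.0,
) -> FretMeasurement:
    """Construct intensities whose corrected efficiency is exactly ``true_e``.

    Inverts the formalism: Fc = E/(1-E) * G * I_DD, then adds the
    bleed-through terms back onto I_DA.  Round-tripping through
    :func:`compute_efret` recovers ``true_e`` to machine precision.
    """
    if k is None:
        k = FretConstants()
    if not 0 <= true_e < 1:
        raise InvalidParameterError(f"true_e must be in [0, 1), got {true_e}")
    i_aa = ratio * i_dd
    fc = true_e / (1.0 - true_e) * k.g * i_dd
    i_da = fc + k.a * i_aa + k.d * i_dd
    return FretMeasurement(i_dd=i_dd, i_aa=i_aa, i_da=i_da)
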
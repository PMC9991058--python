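"""Three-state Ca2+-dependent inactivation (CDI) kinetics.

The scheme is

    Ca + O  <=k1/k2=>  Ca.O  <=alpha/beta=>  I

Ca2+ binds to the open channel (O) with on-rate ``k1`` (M^-1 s^-1) and
off-rate ``k2`` (s^-1); the Ca2+-bound open channel (Ca.O) converts to the
inactivated state (I) with forward rate ``alpha`` and recovers with
``beta``.  O and Ca.O both conduct by default; only I is silent, so the
binding step and the inactivating conformational step remain distinct.

The chain is linear in the occupancies, so for piecewise-constant Ca2+ the
propagator over a step is the matrix exponential of the rate matrix; the
integrator uses exactly that, caching propagators per (Ca2+, dt) pair.

Whole-cell simulation couples the scheme to the single-channel microdomain:
the inactivation sensor at a fixed distance from the pore sees the local
[Ca2+] generated by its own channel's unitary flux at the present voltage
(microdomain collapse is sub-microsecond, far faster than gating, so the
steady-state profile applies instantaneously).  Below the net reversal
potential the sensor flux follows linear driving-force scaling of the
unitary current; above it a small residual fraction of the reference flux
remains (default 5%), because the net-current reversal (+53.5 mV) reflects
mixed ionic flux while the Nernst potential for Ca2+ itself lies far
positive — unidirectional Ca2+ entry does not stop at +53.5 mV.  This
residual term is what makes recovery at +100 mV depend on external Ca2+,
as observed in paired-pulse experiments; set ``residual_ca_fraction=0`` to
switch it off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .analysis import CdiFit, CurrentTrace, extent_of_inactivation
from .errors import (
    DegenerateModelError,
    InvalidParameterError,
    ProtocolError,
)
from .microdomain import (
    SENSOR_DISTANCE,
    MicrodomainModel,
    UnitaryCurrentModel,
    local_ca,
    scale_unitary_current,
)
from .protocols import VoltageProtocol

__all__ = [
    "CdiKineticModel",
    "StateOccupancy",
    "CA_O_SCALE",
    "ca_o_factor",
    "steady_state_occupancy",
    "rate_matrix",
    "integrate",
    "simulate_whole_cell",
    "paired_pulse",
]

STATES = ("O", "CaO", "I")

#: Multiplicative unitary-current factors emulating the external Ca2+
#: conditions, relative to the standard 20 mM Ringer's.  "DVF" (divalent
#: free) zeroes the sensor Ca2+ flux; the conducted (monovalent) current is
#: handled separately by the simulator.
CA_O_SCALE = {2.0: 0.35, 20.0: 1.0, 110.0: 2.0, "DVF": 0.0}


def ca_o_factor(ca_o) -> tuple[float, bool]:
    """(unitary-current scale, is_divalent_free) for an external-Ca2+ label."""
    if isinstance(ca_o, str):
        if ca_o.upper() == "DVF":
            return 0.0, True
        raise LookupError(f"unknown external-Ca2+ condition {ca_o!r}")
    try:
        return CA_O_SCALE[float(ca_o)], False
    except KeyError:
        raise LookupError(
            f"no unitary-current factor for {ca_o} mM external Ca2+ "
            f"(known: {sorted(k for k in CA_O_SCALE if not isinstance(k, str))})"
        ) from None


@dataclass(frozen=True)
class StateOccupancy:
    """Occupancy of the three states; a probability simplex."""

    p_o: float
    p_cao: float
    p_i: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise InvalidParameterError(f"occupancies outside [0,1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"occupancies must sum to 1 (got {arr.sum()!r})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p_o, self.p_cao, self.p_i], dtype=float)

    @classmethod
    def from_array(cls, p: np.ndarray) -> "StateOccupancy":
        return cls(float(p[0]), float(p[1]), float(p[2]))


@dataclass(frozen=True)
class CdiKineticModel:
    """Rate constants of the CDI scheme plus the conductance rule.

    ``k1`` in M^-1 s^-1; ``k2``, ``alpha``, ``beta`` in s^-1.  ``K_d`` of
    the Ca2+-binding step is ``k2/k1``.
    """

    k1: float
    k2: float
    alpha: float
    beta: float
    n_channels: int = 10_000
    conducting_states: tuple[str, ...] = ("O", "CaO")
    variant_label: str = ""

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "alpha", "beta"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_channels < 1:
            raise InvalidParameterError("n_channels must be >= 1")
        unknown = set(self.conducting_states) - set(STATES)
        if unknown:
            raise InvalidParameterError(f"unknown conducting states {unknown}")

    @property
    def kd(self) -> float:
        """Dissociation constant of the Ca2+-binding step (M)."""
        if self.k1 == 0:
            raise DegenerateModelError("K_d undefined for k1 = 0")
        return self.k2 / self.k1

    def with_kd(self, kd: float) -> "CdiKineticModel":
        """Shift the binding K_d by rescaling k1 (k2 preserved)."""
        if not kd > 0:
            raise InvalidParameterError(f"kd must be > 0, got {kd}")
        return replace(self, k1=self.k2 / kd)

    def conducting_mask(self) -> np.ndarray:
        return np.array([s in self.conducting_states for s in STATES])


def rate_matrix(model: CdiKineticModel, ca: float) -> np.ndarray:
    """Generator Q of dp/dt = Q p for occupancies ordered (O, CaO, I)."""
    if ca < 0:
        raise InvalidParameterError(f"ca must be >= 0, got {ca}")
    b = model.k1 * ca
    return np.array(
        [
            [-b, model.k2, 0.0],
            [b, -(model.k2 + model.alpha), model.beta],
            [0.0, model.alpha, -model.beta],
        ]
    )


def steady_state_occupancy(model: CdiKineticModel, ca: float) -> StateOccupancy:
    """Equilibrium occupancy at a fixed Ca2+ concentration.

    The chain satisfies detailed balance, so the relative weights are
    O : Ca.O : I = 1 : (k1 ca / k2) : (k1 ca / k2)(alpha / beta), with
    limiting forms when unbinding or recovery rates vanish.
    """
    if ca < 0:
        raise InvalidParameterError(f"ca must be >= 0, got {ca}")
    if model.k1 == 0 and model.k2 == 0 and model.alpha == 0 and model.beta == 0:
        raise DegenerateModelError("all rates are zero; steady state undefined")
    b = model.k1 * ca
    if ca == 0 or model.k1 == 0:
        return StateOccupancy(1.0, 0.0, 0.0)
    if b > 0 and model.k2 == 0 and model.alpha == 0 and model.beta == 0:
        # everything drains irreversibly into Ca.O
        return StateOccupancy(0.0, 1.0, 0.0)
    if model.beta == 0 and model.alpha > 0 and b > 0:
        return StateOccupancy(0.0, 0.0, 1.0)  # I is absorbing
    if model.k2 == 0:
        # O drains; equilibrium between Ca.O and I only
        if model.alpha == 0:
            return StateOccupancy(0.0, 1.0, 0.0)
        w_cao, w_i = model.beta, model.alpha
        tot = w_cao + w_i
        return StateOccupancy(0.0, w_cao / tot, w_i / tot)
    w_o = 1.0
    w_cao = b / model.k2
    w_i = 0.0 if model.alpha == 0 else w_cao * model.alpha / model.beta
    tot = w_o + w_cao + w_i
    return StateOccupancy(w_o / tot, w_cao / tot, w_i / tot)


def integrate(
    model: CdiKineticModel,
    ca_of_t: np.ndarray,
    t_grid: np.ndarray,
    init: StateOccupancy,
) -> np.ndarray:
    """Propagate occupancies over ``t_grid`` with piecewise-constant Ca2+.

    ``ca_of_t[i]`` holds on the interval ``[t_grid[i], t_grid[i+1])``.
    Returns an ``(len(t_grid), 3)`` array; row ``i`` is the occupancy at
    ``t_grid[i]`` (row 0 is ``init``).  Each step uses the exact matrix
    exponential, so the simplex is preserved to round-off.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    ca_of_t = np.asarray(ca_of_t, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise InvalidParameterError("t_grid must be a 1-d array")
    if np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing")
    if len(ca_of_t) != len(t_grid):
        raise InvalidParameterError("ca_of_t must align with t_grid")

    out = np.empty((len(t_grid), 3))
    p = init.as_array()
    out[0] = p
    cache: dict[tuple[float, float], np.ndarray] = {}
    for i in range(len(t_grid) - 1):
        dt = t_grid[i + 1] - t_grid[i]
        key = (float(ca_of_t[i]), float(dt))
        prop = cache.get(key)
        if prop is None:
            prop = expm(rate_matrix(model, key[0]) * key[1])
            cache[key] = prop
        p = prop @ p
        out[i + 1] = p
    return out


def _sensor_flux(
    ucm: UnitaryCurrentModel,
    v: float,
    ca_o_scale: float,
    residual_ca_fraction: float,
    dvf: bool,
) -> float:
    """Unitary Ca2+ flux (A) feeding the inactivation sensor at voltage v."""
    if dvf:
        return 0.0
    if v < ucm.e_rev:
        return scale_unitary_current(ucm, v) * ca_o_scale
    return residual_ca_fraction * ucm.i_ref * ca_o_scale


def _conducted_current(
    ucm: UnitaryCurrentModel,
    v: float,
    ca_o_scale: float,
    dvf: bool,
    i_mono_ref: float,
    e_rev_mono: float,
) -> float:
    """Unitary conducted current magnitude (A); zero above reversal."""
    if dvf:
        scale = (e_rev_mono - v) / (e_rev_mono - ucm.v_ref)
        return i_mono_ref * max(scale, 0.0)
    return scale_unitary_current(ucm, v) * ca_o_scale


def simulate_whole_cell(
    model: CdiKineticModel,
    protocol: VoltageProtocol,
    micro: MicrodomainModel,
    ucm: UnitaryCurrentModel | None = None,
    sensor_distance: float = SENSOR_DISTANCE,
    dt: float = 2e-4,
    ca_o_scale: float = 1.0,
    residual_ca_fraction: float = 0.05,
    dvf: bool = False,
    i_mono_ref: float = 8e-15,
    e_rev_mono: float = 0.050,
) -> CurrentTrace:
    """Synthesize a whole-cell current trace for a voltage protocol.

    The initial occupancy is the steady state at the holding potential, so
    resting inactivation at +30 mV emerges from the model rather than being
    imposed.  The whole-cell current is
    ``I(t) = -n_channels * i_u(V) * sum(p over conducting states)`` with
    inward current negative; above the net reversal the conducted Ca2+
    current is zero.
    """
    if ucm is None:
        ucm = UnitaryCurrentModel.driving_force()
    if not dt > 0:
        raise InvalidParameterError("dt must be > 0")

    n = int(round(protocol.total_duration / dt))
    t = np.arange(n) * dt
    v = protocol.sample_voltages(t)

    # sensor Ca2+ per sample (steady-state microdomain, instantaneous in V);
    # local_ca is linear in the flux, so one per-ampere coefficient suffices
    if ucm.mode == "driving_force":
        below = v < ucm.e_rev
        df = ucm.i_ref * (ucm.e_rev - v) / (ucm.e_rev - ucm.v_ref)
        flux = np.where(below, df * ca_o_scale,
                        residual_ca_fraction * ucm.i_ref * ca_o_scale)
        if dvf:
            flux = np.zeros_like(v)
        i_unit = np.where(below, df * ca_o_scale, 0.0)
        if dvf:
            mono = i_mono_ref * (e_rev_mono - v) / (e_rev_mono - ucm.v_ref)
            i_unit = np.maximum(mono, 0.0)
    else:
        flux = np.array(
            [_sensor_flux(ucm, vk, ca_o_scale, residual_ca_fraction, dvf)
             for vk in v]
        )
        i_unit = np.array(
            [_conducted_current(ucm, vk, ca_o_scale, dvf, i_mono_ref,
                                e_rev_mono) for vk in v]
        )
    ca_per_amp = local_ca(micro, 1.0, sensor_distance) - micro.ca_ss
    ca = micro.ca_ss + ca_per_amp * flux

    hold_flux = _sensor_flux(ucm, protocol.holding, ca_o_scale,
                             residual_ca_fraction, dvf)
    hold_ca = micro.ca_ss + ca_per_amp * hold_flux
    init = steady_state_occupancy(model, hold_ca)

    occ = integrate(model, ca, t, init)
    p_cond = occ[:, model.conducting_mask()].sum(axis=1)
    current = -model.n_channels * i_unit * p_cond

    meta = {
        "variant": model.variant_label,
        "buffer": micro.buffer.label,
        "ca_o": "DVF" if dvf else None,
        "ca_o_scale": ca_o_scale,
        "protocol": protocol.name,
        "sampling_rate_hz": 1.0 / dt,
        "junction_corrected": True,
        "leak_subtracted": False,
    }
    trace = CurrentTrace(t=t, v=v, i=current, meta=meta)
    trace.occupancies = occ  # model-side extra, not part of the file format
    return trace


def paired_pulse(
    model: CdiKineticModel,
    protocol: VoltageProtocol,
    micro: MicrodomainModel,
    ucm: UnitaryCurrentModel | None = None,
    **simulate_kwargs,
) -> tuple[CdiFit, CdiFit, float]:
    """Run a paired-pulse protocol and quantify recovery from inactivation.

    The protocol must contain exactly two hyperpolarizing test steps
    separated by one depolarized recovery step.  Returns the per-pulse
    CDI fits and ``peak_ratio = |peak_2| / |peak_1|``.
    """
    windows = [
        (t0, t1, seg) for (t0, t1, seg) in protocol.segment_windows()
    ]
    hyper = [(t0, t1) for (t0, t1, seg) in windows if seg.v_start < 0]
    depol = [
        (t0, t1) for (t0, t1, seg) in windows if seg.v_start > protocol.holding
    ]
    if len(hyper) != 2 or len(depol) != 1:
        raise ProtocolError(
            "paired-pulse protocol needs two hyperpolarizing steps separated "
            f"by one depolarized recovery step (got {len(hyper)} hyper, "
            f"{len(depol)} depolarized)"
        )
    if not (hyper[0][1] <= depol[0][0] <= hyper[1][0]):
        raise ProtocolError("recovery step must lie between the two test steps")

    trace = simulate_whole_cell(model, protocol, micro, ucm, **simulate_kwargs)
    fit1 = extent_of_inactivation(trace, hyper[0])
    fit2 = extent_of_inactivation(trace, hyper[1])
    peak_ratio = abs(fit2.i_peak) / abs(fit1.i_peak)
    return fit1, fit2, peak_ratio
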
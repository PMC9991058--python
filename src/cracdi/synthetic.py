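"""Synthetic whole-cell recording generator.

Emulates the statistical structure of the study's patch-clamp recordings:
deterministic gating simulation at an oversampled rate, a per-cell
multiplicative current scale (lognormal, emulating cell-to-cell channel
count variation), a causal 4-pole Bessel low-pass at 1 kHz (the recording
amplifier's filter; applied forward only, as in hardware), decimation to
the 5 kHz acquisition rate, and additive Gaussian noise.  Everything is
reproducible from a seed, and per-condition seeds are derived from a base
seed through a counter scheme so that changing one condition never touches
another's traces.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .analysis import CurrentTrace
from .errors import InvalidParameterError
from .kinetics import CdiKineticModel, ca_o_factor, simulate_whole_cell
from .microdomain import BufferSpec, MicrodomainModel
from .presets import WT_KD, variant
from .protocols import VoltageProtocol, builtin_protocol

__all__ = [
    "NoiseModel",
    "ConditionGrid",
    "generate_trace",
    "generate_experiment",
    "stim1_normalization_toggle",
]


@dataclass(frozen=True)
class NoiseModel:
    """Recording-chain noise and variability parameters.

    ``sigma`` is the additive Gaussian noise s.d. in amperes after
    filtering; ``cell_scale_cv`` the coefficient of variation of the
    per-cell lognormal current scale.
    """

    sigma: float = 0.5e-12
    lowpass_cutoff: float = 1000.0  # Hz; 0 disables filtering
    cell_scale_cv: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.cell_scale_cv < 0:
            raise InvalidParameterError("cell_scale_cv must be >= 0")


def _default_buffers() -> tuple[BufferSpec, ...]:
    return (
        BufferSpec.egta(10.0),
        BufferSpec.egta(20.0),
        BufferSpec.bapta(0.8),
        BufferSpec.bapta(8.0),
        BufferSpec.bapta(20.0),
    )


@dataclass(frozen=True)
class ConditionGrid:
    """The experimental condition grid the generator covers."""

    buffers: tuple[BufferSpec, ...] = field(default_factory=_default_buffers)
    ca_o: tuple = (2.0, 20.0, 110.0, "DVF")
    variants: tuple[str, ...] = (
        "wt_like", "sensitized", "sensitized_with_stim1",
    )
    protocols: tuple[str, ...] = ("cdi_family",)
    n_cells: int = 6
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")

    @property
    def n_traces(self) -> int:
        return (len(self.buffers) * len(self.ca_o) * len(self.variants)
                * len(self.protocols) * self.n_cells)


def _bessel_filter(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    """Causal 4-pole Bessel low-pass, state pre-charged to the first sample."""
    if cutoff <= 0 or cutoff >= fs / 2:
        raise InvalidParameterError(
            f"lowpass cutoff {cutoff} Hz must lie in (0, fs/2={fs / 2}) Hz"
        )
    sos = signal.bessel(4, cutoff, btype="low", fs=fs, output="sos")
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def generate_trace(
    model: CdiKineticModel,
    protocol: VoltageProtocol,
    buffer: BufferSpec,
    ca_o,
    noise: NoiseModel,
    seed: int,
    oversample: int = 5,
    **simulate_kwargs,
) -> CurrentTrace:
    """One noisy whole-cell trace for a single condition, reproducible from seed."""
    if oversample < 1:
        raise InvalidParameterError("oversample must be >= 1")
    scale, dvf = ca_o_factor(ca_o)
    micro = MicrodomainModel(buffer=buffer)
    fs = protocol.sampling_rate * oversample
    trace = simulate_whole_cell(
        model, protocol, micro, dt=1.0 / fs,
        ca_o_scale=scale, dvf=dvf, **simulate_kwargs,
    )

    rng = np.random.default_rng(seed)
    # lognormal with unit mean and the stated CV
    sigma_ln = np.sqrt(np.log1p(noise.cell_scale_cv ** 2))
    cell_scale = float(rng.lognormal(mean=-0.5 * sigma_ln ** 2, sigma=sigma_ln))
    i = trace.i * cell_scale

    if noise.lowpass_cutoff:
        i = _bessel_filter(i, noise.lowpass_cutoff, fs)

    sl = slice(None, None, oversample)
    t, v, i = trace.t[sl], trace.v[sl], i[sl]
    i = i + rng.normal(0.0, noise.sigma, size=len(i))

    meta = dict(trace.meta)
    meta.update(
        ca_o=("DVF" if dvf else float(ca_o)),
        seed=int(seed),
        sampling_rate_hz=protocol.sampling_rate,
        cell_scale=cell_scale,
        noise_sigma_A=noise.sigma,
        lowpass_cutoff_hz=noise.lowpass_cutoff,
    )
    return CurrentTrace(t=t, v=v, i=i, meta=meta)


def condition_seed(base_seed: int, condition: str) -> int:
    """Per-trace seed derived from the condition identity.

    Hashing the condition label (variant/protocol/buffer/Ca2+_o/cell) keeps
    each condition's stream independent of the rest of the grid: adding or
    removing other conditions never changes the traces of this one.
    """
    digest = zlib.crc32(condition.encode())
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(digest,))
    return int(ss.generate_state(1)[0])


def generate_experiment(
    grid: ConditionGrid,
    noise: NoiseModel | None = None,
    out_dir: str | Path | None = None,
    oversample: int = 5,
) -> tuple[list[CurrentTrace], pd.DataFrame]:
    """Generate the full condition grid; returns traces plus a manifest.

    The manifest has one row per trace (variant, buffer, Ca2+_o, protocol,
    cell, seed, file).  With ``out_dir`` set, traces are written in the
    package trace format and the manifest as ``manifest.csv``.
    """
    from . import io as trace_io  # local import to avoid cycle at import time

    if noise is None:
        noise = NoiseModel()
    traces: list[CurrentTrace] = []
    rows: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for variant_name in grid.variants:
        model = variant(variant_name)
        for protocol_name in grid.protocols:
            protocol = builtin_protocol(protocol_name)
            for buffer in grid.buffers:
                for ca_o in grid.ca_o:
                    for cell in range(grid.n_cells):
                        condition = (
                            f"{variant_name}|{protocol_name}|{buffer.label}|"
                            f"{ca_o}|{cell}"
                        )
                        seed = condition_seed(grid.base_seed, condition)
                        trace = generate_trace(
                            model, protocol, buffer, ca_o, noise, seed,
                            oversample=oversample,
                        )
                        trace.meta["cell"] = cell
                        fname = ""
                        if out_path is not None:
                            fname = (
                                f"{variant_name}_{protocol_name}_"
                                f"{buffer.name}{buffer.concentration * 1e3:g}mM_"
                                f"cao{ca_o}_cell{cell}.csv"
                            )
                            trace_io.write_trace(trace, out_path / fname)
                        rows.append(
                            dict(
                                variant=variant_name,
                                buffer=buffer.label,
                                ca_o=str(ca_o),
                                protocol=protocol_name,
                                cell=cell,
                                seed=seed,
                                file=fname,
                            )
                        )
                        traces.append(trace)
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return traces, manifest


def stim1_normalization_toggle(model: CdiKineticModel) -> CdiKineticModel:
    """Model the STIM1 normalization of aberrant buffer dependence.

    Returns the sensitized model with its Ca2+-binding K_d restored to the
    wild-type value; all other rates are preserved.
    """
    if not model.variant_label.startswith("sensitized") or \
            model.variant_label == "sensitized_with_stim1":
        raise LookupError(
            f"normalization toggle applies to the sensitized variant, "
            f"got {model.variant_label!r}"
        )
    from dataclasses import replace

    return replace(model.with_kd(WT_KD), variant_label="sensitized_with_stim1")
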
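"""Declarative voltage-clamp protocols.

A protocol is an ordered list of sweeps; each sweep is an ordered list of
step/ramp segments delivered from a holding potential, repeated at a fixed
sweep interval.  Segment boundaries are half-open ``[start, end)`` so a
sample never belongs to two segments; between the last segment of a sweep
and the start of the next sweep the command sits at the holding potential.

Voltages are stored as the reported (junction-corrected) values; the
``junction_correction`` field records the liquid-junction offset (-10 mV
for the standard pipette/bath pair) as metadata and is never re-applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import InvalidParameterError, ProtocolError

__all__ = ["VoltageSegment", "VoltageProtocol", "builtin_protocol"]


@dataclass(frozen=True)
class VoltageSegment:
    """One piece of a voltage command: a step or a linear ramp."""

    kind: str  # "step" | "ramp"
    duration: float  # s
    v_start: float  # V
    v_end: float  # V (== v_start for steps)

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp"):
            raise InvalidParameterError(f"unknown segment kind {self.kind!r}")
        if not self.duration > 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.kind == "step" and self.v_start != self.v_end:
            raise InvalidParameterError("step segments need v_start == v_end")

    @classmethod
    def step(cls, duration: float, v: float) -> "VoltageSegment":
        return cls("step", duration, v, v)

    @classmethod
    def ramp(cls, duration: float, v_start: float, v_end: float) -> "VoltageSegment":
        return cls("ramp", duration, v_start, v_end)

    def voltage_at(self, t_in_segment: float) -> float:
        if self.kind == "step":
            return self.v_start
        frac = t_in_segment / self.duration
        return self.v_start + (self.v_end - self.v_start) * frac


@dataclass(frozen=True)
class VoltageProtocol:
    """A sequence of sweeps delivered from a holding potential.

    ``sweeps`` is a tuple of sweeps, each a tuple of segments.  Time zero is
    the onset of the first segment of the first sweep; sweep ``k`` starts at
    ``k * sweep_interval``.
    """

    sweeps: tuple[tuple[VoltageSegment, ...], ...]
    holding: float = 0.030  # V
    sweep_interval: float = 1.0  # s
    sampling_rate: float = 5000.0  # Hz
    junction_correction: float = -0.010  # V, metadata only
    name: str = ""

    def __post_init__(self) -> None:
        if not self.sweeps or any(len(s) == 0 for s in self.sweeps):
            raise ProtocolError("protocol needs at least one non-empty sweep")
        if not self.sampling_rate > 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        for sweep in self.sweeps:
            if self.sweep_interval < sum(seg.duration for seg in sweep):
                raise InvalidParameterError(
                    "sweep_interval must be >= total segment duration"
                )

    @classmethod
    def single_sweep(cls, segments: Sequence[VoltageSegment], **kwargs) -> "VoltageProtocol":
        return cls(sweeps=(tuple(segments),), **kwargs)

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    @property
    def total_duration(self) -> float:
        return self.n_sweeps * self.sweep_interval

    def segment_windows(self) -> Iterator[tuple[float, float, VoltageSegment]]:
        """Absolute ``(t_start, t_end, segment)`` for every segment."""
        for k, sweep in enumerate(self.sweeps):
            t = k * self.sweep_interval
            for seg in sweep:
                yield (t, t + seg.duration, seg)
                t += seg.duration

    def voltage_at(self, t: float) -> float:
        """Command voltage at absolute time ``t`` >= 0 (holding outside segments)."""
        if t < 0:
            raise InvalidParameterError(f"t must be >= 0, got {t}")
        k = int(t // self.sweep_interval)
        if k >= self.n_sweeps:
            return self.holding
        t_in = t - k * self.sweep_interval
        for seg in self.sweeps[k]:
            if t_in < seg.duration:
                return seg.voltage_at(t_in)
            t_in -= seg.duration
        return self.holding

    def sample_times(self) -> np.ndarray:
        n = int(round(self.total_duration * self.sampling_rate))
        return np.arange(n) / self.sampling_rate

    def sample_voltages(self, times: np.ndarray | None = None) -> np.ndarray:
        """Vectorized command voltage at each sample time.

        Same half-open segment semantics as :meth:`voltage_at`.
        """
        if times is None:
            times = self.sample_times()
        times = np.asarray(times, dtype=float)
        v = np.full(times.shape, self.holding)
        for t0, t1, seg in self.segment_windows():
            mask = (times >= t0) & (times < t1)
            if not np.any(mask):
                continue
            if seg.kind == "step":
                v[mask] = seg.v_start
            else:
                frac = (times[mask] - t0) / seg.duration
                v[mask] = seg.v_start + (seg.v_end - seg.v_start) * frac
        return v


def builtin_protocol(name: str, sampling_rate: float = 5000.0) -> VoltageProtocol:
    """The stimuli used throughout the study.

    ``standard_ramp``
        100 ms step to -100 mV, then a 100 ms ramp from -100 to +100 mV,
        delivered at 1 s intervals from +30 mV holding.
    ``cdi_family``
        300 ms steps to -120, -100, -80 and -60 mV, one per sweep.
    ``paired_pulse``
        300 ms at -100 mV, 200 ms recovery at +100 mV, 300 ms at -100 mV.
    """
    if name == "standard_ramp":
        sweep = (
            VoltageSegment.step(0.100, -0.100),
            VoltageSegment.ramp(0.100, -0.100, 0.100),
        )
        return VoltageProtocol(sweeps=(sweep,), sweep_interval=1.0,
                               sampling_rate=sampling_rate, name=name)
    if name == "cdi_family":
        sweeps = tuple(
            (VoltageSegment.step(0.300, v),)
            for v in (-0.120, -0.100, -0.080, -0.060)
        )
        return VoltageProtocol(sweeps=sweeps, sweep_interval=1.0,
                               sampling_rate=sampling_rate, name=name)
    if name == "paired_pulse":
        sweep = (
            VoltageSegment.step(0.300, -0.100),
            VoltageSegment.step(0.200, 0.100),
            VoltageSegment.step(0.300, -0.100),
        )
        return VoltageProtocol(sweeps=(sweep,), sweep_interval=1.0,
                               sampling_rate=sampling_rate, name=name)
    raise LookupError(f"unknown builtin protocol {name!r}")
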
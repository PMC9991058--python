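"""Trace file format and run configuration.

Traces are plain CSV with unit-bearing column names (``time_s``,
``voltage_mV``, ``current_pA``) plus a JSON metadata sidecar next to the
data file (``<stem>.meta.json``): buffer, external Ca2+, variant, protocol,
seed, sampling rate, correction flags.  Values are written with 17
significant digits; the time column round-trips bit-exactly, and the
scaled columns round-trip bit-exactly wherever the double is representable
as ``column_value * unit`` (the writer nudges entries by one ulp to make
that so) and to within half an ulp otherwise — decimal unit scaling in
binary floating point cannot reach every double.

Run configuration is a JSON document with one section per module
(microdomain, kinetics, protocol, noise, grid, efret) plus a version
stamp; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import CurrentTrace
from .errors import ConfigError, TraceFormatError
from .units import mV, pA

__all__ = ["read_trace", "write_trace", "load_config", "CONFIG_SECTIONS"]

_COLUMNS = ("time_s", "voltage_mV", "current_pA")

_DEFAULT_META = {
    "buffer": "unknown",
    "ca_o": "unknown",
    "variant": "unknown",
    "protocol": "unknown",
    "seed": None,
    "sampling_rate_hz": None,
    "junction_corrected": False,
    "leak_subtracted": False,
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _exact_scaled(values: np.ndarray, unit: float) -> np.ndarray:
    """Column values c such that c * unit reproduces ``values`` bit-exactly.

    Decimal unit scaling (V -> mV, A -> pA) rounds, so the naive quotient can
    be one ulp off after the return conversion; nudge such entries to the
    neighbouring float that does invert exactly.
    """
    c = values / unit
    bad = np.flatnonzero(c * unit != values)
    for k in bad:
        for candidate in (np.nextafter(c[k], np.inf),
                          np.nextafter(c[k], -np.inf)):
            if candidate * unit == values[k]:
                c[k] = candidate
                break
    return c


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write a trace as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    v_col = _exact_scaled(trace.v, mV)
    i_col = _exact_scaled(trace.i, pA)
    with open(path, "w") as fh:
        fh.write(",".join(_COLUMNS) + "\n")
        for t, v, i in zip(trace.t, v_col, i_col):
            fh.write(f"{t:.17g},{v:.17g},{i:.17g}\n")
    meta = {**_DEFAULT_META, **trace.meta}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
        fh.write("\n")
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`.

    A missing sidecar degrades to default metadata with a warning and
    ``meta['metadata_missing'] = True``; a malformed header or a
    non-monotone time column raises :class:`TraceFormatError`.
    """
    path = Path(path)
    try:
        # round_trip parser: values written with 17 significant digits must
        # reload bit-identically
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TraceFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if tuple(table.columns) != _COLUMNS:
        raise TraceFormatError(
            f"{path}: line 1: expected header {','.join(_COLUMNS)}, "
            f"got {','.join(map(str, table.columns))}"
        )
    t = table["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise TraceFormatError(f"{path}: time_s column not strictly increasing")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = {**_DEFAULT_META, **json.load(fh)}
    else:
        warnings.warn(f"{sidecar} missing; using default metadata", stacklevel=2)
        meta = dict(_DEFAULT_META)
        meta["metadata_missing"] = True
    return CurrentTrace(
        t=t,
        v=table["voltage_mV"].to_numpy(dtype=float) * mV,
        i=table["current_pA"].to_numpy(dtype=float) * pA,
        meta=meta,
    )


CONFIG_SECTIONS = ("microdomain", "kinetics", "protocol", "noise", "grid",
                   "efret", "version")


def load_config(path: str | Path) -> dict:
    """Load a strict run-configuration document (JSON, known sections only)."""
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be an object")
    unknown = set(doc) - set(CONFIG_SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown config sections {sorted(unknown)}")
    return doc
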
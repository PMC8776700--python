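"""Respiratory trace container and CSV round-trip.

A :class:`RespiratoryTrace` holds the fiducial-marker (or surrogate) position
sampled uniformly in time in the three anatomical directions used throughout
the package: anterior-posterior (AP), cranial-caudal (CC) and left-right (LR),
in millimetres.  The sign convention is that the *larger* coordinate is
inspiration; end-expiration sits at the local minima (a per-direction sign
flag elsewhere in the package accommodates inverted tracking axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical direction order used for the position array columns.
DIRECTIONS = ("ap", "cc", "lr")

_CSV_COLUMNS = ("time_s", "ap_mm", "cc_mm", "lr_mm")

#: Relative tolerance on the constancy of the sampling interval.
TIME_UNIFORMITY_RTOL = 1e-6


class TraceValidationError(ValueError):
    """A trace violates its structural invariants."""


class TraceSchemaError(TraceValidationError):
    """A trace file does not match the expected CSV schema."""


@dataclass
class RespiratoryTrace:
    """Uniformly sampled 3-direction respiratory position signal.

    Parameters
    ----------
    time_s:
        Sample times in seconds, ascending, uniform to within
        :data:`TIME_UNIFORMITY_RTOL` relative tolerance.
    position_mm:
        Array of shape ``(n_samples, 3)`` with columns ordered as
        :data:`DIRECTIONS` (AP, CC, LR), millimetres.
    meta:
        Free-form identifier strings (patient, fraction, beam, trace_id...).
    """

    time_s: np.ndarray
    position_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise TraceValidationError("trace needs >= 2 samples")
        if self.position_mm.shape != (self.time_s.size, 3):
            raise TraceValidationError(
                f"position_mm shape {self.position_mm.shape} does not match "
                f"({self.time_s.size}, 3)"
            )
        if not np.all(np.isfinite(self.time_s)):
            raise TraceValidationError("non-finite sample times")
        if not np.all(np.isfinite(self.position_mm)):
            raise TraceValidationError("non-finite positions")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise TraceValidationError("sample times not strictly increasing")
        dt0 = (self.time_s[-1] - self.time_s[0]) / (self.time_s.size - 1)
        if np.max(np.abs(dt - dt0)) > TIME_UNIFORMITY_RTOL * dt0:
            raise TraceValidationError("sample times not uniformly spaced")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def dt_s(self) -> float:
        return float((self.time_s[-1] - self.time_s[0]) / (self.time_s.size - 1))

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.dt_s

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def trace_id(self) -> str:
        return str(self.meta.get("trace_id", "trace"))

    def direction(self, name: str) -> np.ndarray:
        """Return the 1-D position signal for direction ``name`` (ap/cc/lr)."""
        name = name.lower()
        if name not in DIRECTIONS:
            raise KeyError(f"unknown direction {name!r}; expected one of {DIRECTIONS}")
        return self.position_mm[:, DIRECTIONS.index(name)]


# -- CSV round trip -------------------------------------------------------

def write_trace_csv(trace: RespiratoryTrace, path: str | Path) -> Path:
    """Write a trace as ``time_s,ap_mm,cc_mm,lr_mm`` CSV (UTF-8, %.12g, so
    the time base stays uniform to 1e-6 relative even on long beams)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "ap_mm": trace.position_mm[:, 0],
            "cc_mm": trace.position_mm[:, 1],
            "lr_mm": trace.position_mm[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_trace_csv(path: str | Path, meta: dict | None = None) -> RespiratoryTrace:
    """Read a trace CSV written by :func:`write_trace_csv`.

    Raises :class:`TraceSchemaError` naming the first missing column or the
    line number of the first malformed row; non-uniform or non-monotone
    timestamps raise :class:`TraceValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceSchemaError(f"{path}: unreadable CSV: {exc}") from exc
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            raise TraceSchemaError(f"{path}: missing column {col!r}")
    values = {}
    for col in _CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise TraceSchemaError(
                f"{path}: malformed value in column {col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise TraceSchemaError(f"{path}: empty value in column {col!r} at line {line}")
        values[col] = coerced.to_numpy(dtype=float)
    full_meta = {"source": str(path)}
    if meta:
        full_meta.update(meta)
    return RespiratoryTrace(
        time_s=values["time_s"],
        position_mm=np.column_stack([values["ap_mm"], values["cc_mm"], values["lr_mm"]]),
        meta=full_meta,
    )
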
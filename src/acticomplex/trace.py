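"""Epoch-level activity traces and their CSV representation.

The trace is the pipeline's basic container: an evenly spaced series of
acceleration magnitudes (in gravitational units g), one value per fixed
epoch, with optional subject metadata attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a documented precondition."""


@dataclass
class ActivityTrace:
    """An evenly spaced epoch series of acceleration magnitudes.

    Parameters
    ----------
    values
        Magnitude per epoch.  Physical traces (read from file or produced
        by the rest/activity simulator) are nonnegative; canonical test
        signals (sine, noise, chaotic maps) may be signed.
    epoch_seconds
        Epoch length in seconds.
    start_time
        Timestamp of the first epoch, if known.
    subject_id, group, age, sex
        Optional subject metadata carried through to the feature table.
        ``group`` is ``"healthy"`` or ``"patient"`` when present.
    """

    values: np.ndarray
    epoch_seconds: float
    start_time: Optional[pd.Timestamp] = None
    subject_id: str = ""
    group: Optional[str] = None
    age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("values must be one-dimensional")
        if self.values.size < 1:
            raise ValidationError("values: a trace needs at least 1 epoch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if not (np.isfinite(self.epoch_seconds) and self.epoch_seconds > 0):
            raise ValidationError("epoch_seconds must be positive")
        if self.group is not None and self.group not in ("healthy", "patient"):
            raise ValidationError(
                f"group must be 'healthy' or 'patient', got {self.group!r}"
            )

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_hours(self) -> float:
        return self.n * self.epoch_seconds / 3600.0

    def with_values(self, values: np.ndarray, epoch_seconds: Optional[float] = None) -> "ActivityTrace":
        """A copy carrying the same metadata but new values."""
        return replace(
            self,
            values=values,
            epoch_seconds=self.epoch_seconds if epoch_seconds is None else epoch_seconds,
        )


#: column names of the epoch CSV dialect written and read by the pipeline
TRACE_COLUMNS = ("timestamp", "magnitude_g")


def read_trace_csv(
    path,
    subject_id: str = "",
    group: Optional[str] = None,
    age: Optional[float] = None,
    sex: Optional[str] = None,
) -> ActivityTrace:
    """Read an epoch CSV (columns ``timestamp``, ``magnitude_g``).

    Timestamps must be ISO-8601 and evenly spaced; gaps or irregular
    spacing are rejected rather than imputed, because the analysis
    assumes continuous recordings.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if len(df) < 2:
        raise ValidationError(f"{path}: a trace needs at least 2 epochs")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamp column: {exc}") from exc
    deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
    if deltas.size == 0 or np.any(deltas <= 0):
        raise ValidationError(f"{path}: timestamps must be strictly increasing")
    epoch = deltas[0]
    if not np.allclose(deltas, epoch, rtol=0, atol=1e-6):
        raise ValidationError(
            f"{path}: epochs are not evenly spaced (gap or irregular sampling); "
            "gap handling is not supported"
        )
    mags = pd.to_numeric(df["magnitude_g"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(mags)):
        raise ValidationError(f"{path}: magnitude_g contains non-numeric or non-finite values")
    if np.any(mags < 0):
        raise ValidationError(f"{path}: magnitude_g must be nonnegative")
    return ActivityTrace(
        values=mags,
        epoch_seconds=float(epoch),
        start_time=ts.iloc[0],
        subject_id=subject_id,
        group=group,
        age=age,
        sex=sex,
    )


def write_trace_csv(trace: ActivityTrace, path, header_comments: tuple[str, ...] = ()) -> None:
    """Write a trace in the same CSV dialect :func:`read_trace_csv` reads."""
    start = trace.start_time if trace.start_time is not None else pd.Timestamp("2000-01-03 00:00:00")
    ts = start + pd.to_timedelta(np.arange(trace.n) * trace.epoch_seconds, unit="s")
    df = pd.DataFrame(
        {"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"), "magnitude_g": trace.values}
    )
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
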
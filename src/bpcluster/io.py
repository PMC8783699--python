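"""Readers and writers for waveform records and per-cycle feature tables.

Waveform records are plain CSV with one column per channel (ECG, PPG, ABP)
sampled on a common clock; the column naming and the sampling rate come
from a small layout mapping because upstream exports of multi-channel
monitor data rarely agree on a convention.  Feature tables are CSV with a
fixed schema, one row per cardiac cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed column schema of a per-cycle feature table.
FEATURE_COLUMNS = (
    "record_id",
    "cycle_index",
    "ptt_s",
    "pir_ratio",
    "hr_bpm",
    "sbp_mmHg",
    "dbp_mmHg",
)

DEFAULT_LAYOUT: dict = {"ecg": "ecg", "ppg": "ppg", "abp": "abp", "sampling_rate_hz": 125.0}


class WaveformFormatError(ValueError):
    """Raised when a waveform file does not match the declared layout."""


class FeatureSchemaError(ValueError):
    """Raised when a feature-table file is missing required columns."""


@dataclass
class WaveformRecord:
    """Synchronized ECG/PPG/ABP samples on a common clock.

    Parameters
    ----------
    record_id : str
        Text label of the record.
    sampling_rate_hz : float
        Sampling rate shared by all three channels, samples/second.
    ecg, ppg : ndarray
        Channel samples in arbitrary amplitude/intensity units.
    abp : ndarray
        Arterial blood pressure samples in mmHg.
    n_dropped_rows : int
        Number of input rows discarded for non-numeric or missing values.
    """

    record_id: str
    sampling_rate_hz: float
    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if not (len(self.ecg) == len(self.ppg) == len(self.abp)):
            raise ValueError("ECG/PPG/ABP channels must have identical length")
        if len(self.ecg) < 2:
            raise ValueError("a waveform record needs at least 2 samples per channel")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.abp)):
            raise ValueError("ABP channel contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def read_waveform_record(
    path: str | Path,
    layout: Mapping | None = None,
    record_id: str | None = None,
) -> WaveformRecord:
    """Read a multi-channel waveform CSV into a :class:`WaveformRecord`.

    ``layout`` maps the roles ``ecg``/``ppg``/``abp`` to column names and
    supplies ``sampling_rate_hz``.  Rows containing missing or non-numeric
    entries in any mapped channel are dropped and counted.
    """
    layout = {**DEFAULT_LAYOUT, **(layout or {})}
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = {}
    for role in ("ecg", "ppg", "abp"):
        name = layout[role]
        if name not in frame.columns:
            raise WaveformFormatError(
                f"{path}: layout maps {role!r} to column {name!r}, "
                f"but file has columns {list(frame.columns)}"
            )
        cols[role] = pd.to_numeric(frame[name], errors="coerce")
    chans = pd.DataFrame(cols)
    keep = chans.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with missing/non-numeric values", path, n_dropped)
    chans = chans[keep]
    if len(chans) < 2:
        raise WaveformFormatError(f"{path}: fewer than 2 valid samples after filtering")
    return WaveformRecord(
        record_id=record_id or path.stem,
        sampling_rate_hz=float(layout["sampling_rate_hz"]),
        ecg=chans["ecg"].to_numpy(),
        ppg=chans["ppg"].to_numpy(),
        abp=chans["abp"].to_numpy(),
        n_dropped_rows=n_dropped,
    )


def write_waveform_record(record: WaveformRecord, path: str | Path) -> Path:
    """Write a record as CSV with columns ecg, ppg, abp (full float precision)."""
    path = Path(path)
    frame = pd.DataFrame({"ecg": record.ecg, "ppg": record.ppg, "abp": record.abp})
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


@dataclass
class RejectedRows:
    """Row-level report of feature rows rejected on load."""

    indices: list = field(default_factory=list)
    reasons: list = field(default_factory=list)

    def add(self, index: int, reason: str) -> None:
        self.indices.append(index)
        self.reasons.append(reason)

    def __len__(self) -> int:
        return len(self.indices)


def _validate_feature_frame(frame: pd.DataFrame, source: str) -> tuple[pd.DataFrame, RejectedRows]:
    missing = set(FEATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise FeatureSchemaError(f"{source}: missing feature columns {sorted(missing)}")
    report = RejectedRows()
    bad = frame["sbp_mmHg"] < frame["dbp_mmHg"]
    for i in frame.index[bad]:
        report.add(int(i), "sbp_mmHg < dbp_mmHg")
    frame = frame[~bad]
    dup = frame.duplicated(subset=["record_id", "cycle_index"], keep=False)
    if dup.any():
        raise FeatureSchemaError(
            f"{source}: duplicated (record_id, cycle_index) pairs at rows "
            f"{list(frame.index[dup])}"
        )
    if len(report):
        logger.warning("%s: rejected %d rows violating SBP >= DBP", source, len(report))
    return frame.reset_index(drop=True), report


def read_feature_table(
    path: str | Path, return_report: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, RejectedRows]:
    """Read a per-cycle feature table CSV, rejecting rows with SBP < DBP."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    frame, report = _validate_feature_frame(frame, str(path))
    if return_report:
        return frame, report
    return frame


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV with the fixed column schema first."""
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise FeatureSchemaError(f"feature table missing columns {sorted(missing)}")
    extra = [c for c in table.columns if c not in FEATURE_COLUMNS]
    ordered = table[list(FEATURE_COLUMNS) + extra]
    path = Path(path)
    ordered.to_csv(path, index=False, float_format="%.17g")
    return path
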
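"""Per-cardiac-cycle feature extraction from synchronized ECG/PPG/ABP.

The extraction stage segments the record into beat windows at ECG R-peaks
and computes, for each complete window ``[r_i, r_{i+1})``:

* **PTT** — time from the R-peak to the peak of the second derivative of
  the PPG (SDPPG) inside the window, in seconds;
* **PIR** — ratio of the PPG maximum (IH) to minimum (IL) in the window;
* **HR** — ``60 * fs / (r_{i+1} - r_i)``, beats per minute;
* **SBP/DBP** — maximum/minimum of the ABP channel in the window, mmHg.

Cycles failing any physiological gate are dropped and counted; one output
row per fully valid cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import FEATURE_COLUMNS, WaveformRecord

logger = logging.getLogger(__name__)


@dataclass
class ExtractionConfig:
    """Detector and gating parameters.

    refractory_s : minimum separation between R-peaks (s).
    smoothing_window_s : moving-average window applied to the PPG before
        the second derivative (s); 0 disables smoothing.
    min_hr_bpm / max_hr_bpm : physiologic heart-rate gates.
    min_ptt_s / max_ptt_s : physiologic transit-time gates.
    invert_pir : report IL/IH instead of IH/IL (some conventions invert
        the intensity ratio).
    ppg_dc_offset : constant added to the PPG before the ratio when a
        window's minimum is <= 0 (AC-coupled input); 0 disables and such
        windows are flagged invalid instead.
    """

    refractory_s: float = 0.25
    smoothing_window_s: float = 0.04
    min_hr_bpm: float = 30.0
    max_hr_bpm: float = 220.0
    min_ptt_s: float = 0.05
    max_ptt_s: float = 0.6
    invert_pir: bool = False
    ppg_dc_offset: float = 0.0

    def __post_init__(self) -> None:
        if min(self.refractory_s, self.min_hr_bpm, self.min_ptt_s) <= 0:
            raise ValueError("gates must be positive")
        if self.min_hr_bpm >= self.max_hr_bpm or self.min_ptt_s >= self.max_ptt_s:
            raise ValueError("min gate must be below max gate")


@dataclass
class BeatAnnotations:
    """Landmark indices produced during extraction (for inspection/plots)."""

    r_peaks: np.ndarray
    sdppg_peaks: list = field(default_factory=list)
    ppg_peaks: list = field(default_factory=list)
    ppg_valleys: list = field(default_factory=list)
    abp_cycle_bounds: list = field(default_factory=list)


def _odd_window(width_s: float, fs: float) -> int:
    w = int(round(width_s * fs))
    if w < 3:
        return 0
    return w + 1 if w % 2 == 0 else w


def detect_r_peaks(
    ecg: np.ndarray, sampling_rate_hz: float, config: ExtractionConfig | None = None
) -> np.ndarray:
    """Detect ECG R-peaks with a derivative-energy detector.

    Detrended signal -> first difference -> squaring -> moving-window
    integration; candidate peaks of the energy envelope above an adaptive
    threshold and separated by the refractory period are refined to the
    local maximum of the raw ECG.  Returns strictly increasing sample
    indices; empty array when nothing crosses the threshold.
    """
    config = config or ExtractionConfig()
    ecg = np.asarray(ecg, dtype=float)
    fs = float(sampling_rate_hz)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG signal")

    baseline_w = _odd_window(0.6, fs) or 3
    baseline = sps.convolve(ecg, np.ones(baseline_w) / baseline_w, mode="same")
    detr = ecg - baseline
    energy = np.gradient(detr) ** 2
    integ_w = _odd_window(0.12, fs) or 3
    envelope = sps.convolve(energy, np.ones(integ_w) / integ_w, mode="same")

    peak = envelope.max()
    if peak <= 0 or peak < 1e3 * np.finfo(float).tiny:
        return np.array([], dtype=int)
    threshold = max(0.2 * peak, 4.0 * np.median(envelope))
    distance = max(1, int(round(config.refractory_s * fs)))
    cand, _ = sps.find_peaks(envelope, height=threshold, distance=distance)
    if len(cand) == 0:
        return np.array([], dtype=int)

    # refine each envelope peak to the raw-ECG local maximum nearby
    half = max(1, integ_w // 2)
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(ecg), c + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)
    # refinement can merge neighbours; enforce the refractory spacing keeping
    # the larger raw peak
    keep: list[int] = []
    for idx in refined:
        if keep and idx - keep[-1] < distance:
            if ecg[idx] > ecg[keep[-1]]:
                keep[-1] = idx
        else:
            keep.append(idx)
    return np.array(keep, dtype=int)


def second_derivative_ppg(
    ppg: np.ndarray, sampling_rate_hz: float, config: ExtractionConfig | None = None
) -> np.ndarray:
    """Smoothed second central difference of the PPG, scaled by fs**2.

    Output has the input length; the two edge samples replicate their
    nearest interior value.
    """
    config = config or ExtractionConfig()
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < 5:
        raise ValueError("need at least 5 PPG samples for a second derivative")
    fs = float(sampling_rate_hz)
    w = _odd_window(config.smoothing_window_s, fs)
    if w:
        ppg = sps.convolve(ppg, np.ones(w) / w, mode="same")
    sd = np.empty_like(ppg)
    sd[1:-1] = (ppg[2:] - 2 * ppg[1:-1] + ppg[:-2]) * fs * fs
    sd[0], sd[-1] = sd[1], sd[-2]
    return sd


def beat_windows(r_peaks: np.ndarray) -> list[tuple[int, int]]:
    """Half-open windows [r_i, r_{i+1}) — one per completed cycle."""
    return [(int(r_peaks[i]), int(r_peaks[i + 1])) for i in range(len(r_peaks) - 1)]


def extract_ptt(
    r_peaks: np.ndarray,
    sdppg: np.ndarray,
    sampling_rate_hz: float,
    config: ExtractionConfig | None = None,
) -> np.ndarray:
    """PTT per cycle: R-peak to SDPPG argmax within the beat window (s).

    Values outside the [min_ptt_s, max_ptt_s] gate are NaN.
    """
    config = config or ExtractionConfig()
    fs = float(sampling_rate_hz)
    out = np.full(max(len(r_peaks) - 1, 0), np.nan)
    for i, (a, b) in enumerate(beat_windows(r_peaks)):
        if b <= a or b > len(sdppg):
            continue
        ptt = float(np.argmax(sdppg[a:b])) / fs
        if config.min_ptt_s <= ptt <= config.max_ptt_s:
            out[i] = ptt
    return out


def extract_pir(
    ppg: np.ndarray,
    windows: list[tuple[int, int]],
    config: ExtractionConfig | None = None,
) -> np.ndarray:
    """PIR per cycle: IH/IL = window max over window min of the PPG.

    Windows whose minimum is <= 0 are shifted by ``ppg_dc_offset`` when
    configured, else NaN (the intensity ratio is undefined).  With
    ``invert_pir`` the reciprocal IL/IH is reported.
    """
    config = config or ExtractionConfig()
    ppg = np.asarray(ppg, dtype=float)
    out = np.full(len(windows), np.nan)
    for i, (a, b) in enumerate(windows):
        if b <= a or b > len(ppg):
            continue
        seg = ppg[a:b]
        lo, hi = float(seg.min()), float(seg.max())
        if lo <= 0:
            if config.ppg_dc_offset > 0 and lo + config.ppg_dc_offset > 0:
                lo += config.ppg_dc_offset
                hi += config.ppg_dc_offset
            else:
                continue
        out[i] = lo / hi if config.invert_pir else hi / lo
    return out


def extract_hr(
    r_peaks: np.ndarray,
    sampling_rate_hz: float,
    config: ExtractionConfig | None = None,
) -> np.ndarray:
    """HR per cycle from consecutive R-R intervals, bpm; gated to NaN."""
    config = config or ExtractionConfig()
    if len(r_peaks) < 2:
        return np.array([])
    fs = float(sampling_rate_hz)
    rr = np.diff(np.asarray(r_peaks, dtype=float))
    hr = 60.0 * fs / rr
    hr[(hr < config.min_hr_bpm) | (hr > config.max_hr_bpm)] = np.nan
    return hr


def extract_sbp_dbp(
    abp: np.ndarray, windows: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (SBP, DBP) = (max, min) of the ABP inside each window."""
    abp = np.asarray(abp, dtype=float)
    sbp = np.full(len(windows), np.nan)
    dbp = np.full(len(windows), np.nan)
    for i, (a, b) in enumerate(windows):
        if b <= a or b > len(abp):
            continue
        seg = abp[a:b]
        sbp[i], dbp[i] = float(seg.max()), float(seg.min())
    return sbp, dbp


def build_feature_table(
    record: WaveformRecord,
    config: ExtractionConfig | None = None,
    return_annotations: bool = False,
):
    """Run the full extraction stage on one record.

    Returns a feature table with one row per cycle in which all five
    quantities pass their gates; dropped-cycle counts are logged.  With
    ``return_annotations`` also returns the landmark indices.
    """
    config = config or ExtractionConfig()
    fs = record.sampling_rate_hz
    r_peaks = detect_r_peaks(record.ecg, fs, config)
    windows = beat_windows(r_peaks)
    ann = BeatAnnotations(r_peaks=r_peaks, abp_cycle_bounds=windows)

    empty = pd.DataFrame(columns=list(FEATURE_COLUMNS))
    if len(windows) == 0:
        logger.warning("%s: no complete cardiac cycles detected", record.record_id)
        return (empty, ann) if return_annotations else empty

    sdppg = second_derivative_ppg(record.ppg, fs, config)
    ptt = extract_ptt(r_peaks, sdppg, fs, config)
    pir = extract_pir(record.ppg, windows, config)
    hr = extract_hr(r_peaks, fs, config)
    sbp, dbp = extract_sbp_dbp(record.abp, windows)

    valid = (
        ~np.isnan(ptt) & ~np.isnan(pir) & ~np.isnan(hr)
        & ~np.isnan(sbp) & ~np.isnan(dbp) & (sbp >= dbp)
    )
    n_drop = int((~valid).sum())
    if n_drop:
        logger.info(
            "%s: dropped %d/%d cycles failing gates", record.record_id, n_drop, len(windows)
        )
    table = pd.DataFrame(
        {
            "record_id": record.record_id,
            "cycle_index": np.arange(len(windows)),
            "ptt_s": ptt,
            "pir_ratio": pir,
            "hr_bpm": hr,
            "sbp_mmHg": sbp,
            "dbp_mmHg": dbp,
        }
    )[valid].reset_index(drop=True)
    if len(table) == 0:
        logger.warning("%s: zero valid cycles", record.record_id)
    if return_annotations:
        return table, ann
    return table


def build_feature_tables(records, config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Concatenate :func:`build_feature_table` over several records."""
    parts = [build_feature_table(r, config) for r in records]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=list(FEATURE_COLUMNS))
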
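"""Synthetic beat-synchronized ECG/PPG/ABP generator with exact ground truth.

Each cardiac cycle is built from minimal morphologies chosen so that the
landmarks the feature extractors consume are exact by construction:

* ECG — a narrow Gaussian spike on a flat baseline, its maximum exactly at
  the first sample of the beat window (the R-peak).
* PPG — a pulse synthesized by double-integrating a designed curvature
  profile: a Gaussian curvature bump centred exactly at the pulse onset
  (``round(PTT * fs)`` samples after the R-peak), a negative bump at the
  systolic peak and a weaker positive bump at the end of the decay.  The
  rise is steeper than the decay, so the dominant second-derivative (SDPPG)
  peak is the onset bump and the extracted PTT equals the drawn PTT to
  within half a sample.  The pulse is affinely normalized so its maximum
  (IH) and minimum (IL) realize the drawn intensity ratio PIR = IH/IL.
* ABP — the same pulse template normalized so max = drawn SBP and
  min = drawn DBP, in mmHg.

A population is a concatenation of several *regimes* — parameter clouds
with distinct (PTT, PIR, HR) means and regime-specific blood-pressure
response coefficients — which reproduces the multitrend, high-dispersion
feature structure that motivates clustering before regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FEATURE_COLUMNS, WaveformRecord

# Curvature-kernel widths in samples; the onset kernel is kept narrower so
# its SDPPG peak stays strictly dominant after extraction-side smoothing.
_ONSET_SIGMA = 2.0
_OTHER_SIGMA = 3.0


@dataclass
class RegimeSpec:
    """One parameter regime of the synthetic population.

    ``sbp_coeffs``/``dbp_coeffs`` define the regime's ground-truth pressure
    response ``BP = intercept + c_ptt*PTT + c_pir*PIR + c_hr*HR +
    c_inv_ptt/PTT + N(0, noise_sd_mmHg)``; keys: ``intercept``, ``ptt``,
    ``pir``, ``hr``, ``inv_ptt`` (missing keys default to 0).
    """

    regime_id: int
    hr_mean_bpm: float
    hr_sd: float
    ptt_mean_s: float
    ptt_sd: float
    pir_mean: float
    pir_sd: float
    sbp_coeffs: Mapping[str, float]
    dbp_coeffs: Mapping[str, float]
    noise_sd_mmHg: float = 3.0
    n_beats: int = 200

    def __post_init__(self) -> None:
        if self.hr_mean_bpm <= 0 or self.hr_sd < 0:
            raise ValueError("heart-rate parameters must be positive (sd >= 0)")
        if self.ptt_mean_s <= 0 or self.ptt_sd < 0:
            raise ValueError("PTT parameters must be positive (sd >= 0)")
        if self.pir_mean < 1.0 or self.pir_sd < 0:
            raise ValueError("pir_mean must be >= 1 (IH/IL convention)")
        if self.noise_sd_mmHg < 0:
            raise ValueError("noise_sd_mmHg must be non-negative")
        if self.n_beats < 1:
            raise ValueError("n_beats must be positive")
        if self.ptt_mean_s >= 60.0 / self.hr_mean_bpm:
            raise ValueError("ptt_mean_s must be shorter than the mean beat period")


@dataclass
class SyntheticDataset:
    """Generated records plus the per-beat ground-truth feature table."""

    records: list[WaveformRecord]
    truth: pd.DataFrame  # FEATURE_COLUMNS + regime_id
    seed: int


def _eval_bp(coeffs: Mapping[str, float], ptt: np.ndarray, pir: np.ndarray,
             hr: np.ndarray) -> np.ndarray:
    return (
        coeffs.get("intercept", 0.0)
        + coeffs.get("ptt", 0.0) * ptt
        + coeffs.get("pir", 0.0) * pir
        + coeffs.get("hr", 0.0) * hr
        + coeffs.get("inv_ptt", 0.0) / ptt
    )


def sample_truth_features(
    spec: RegimeSpec, rng: np.random.Generator | int
) -> pd.DataFrame:
    """Draw per-beat (PTT, PIR, HR, SBP, DBP) truth rows for one regime.

    Beats violating physiological constraints (PTT not fitting in the beat
    period, PIR < 1, SBP <= DBP) are redrawn.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = spec.n_beats
    out = np.empty((n, 5))
    filled = 0
    for _ in range(1000):  # resampling rounds; virtually always 1-2 suffice
        m = n - filled
        if m == 0:
            break
        hr = rng.normal(spec.hr_mean_bpm, spec.hr_sd, m)
        ptt = rng.normal(spec.ptt_mean_s, spec.ptt_sd, m)
        pir = rng.normal(spec.pir_mean, spec.pir_sd, m)
        ok = (hr > 20) & (ptt > 0.02) & (ptt < 0.55 * 60.0 / np.maximum(hr, 20)) & (pir >= 1.01)
        hr, ptt, pir = hr[ok], ptt[ok], pir[ok]
        sbp = _eval_bp(spec.sbp_coeffs, ptt, pir, hr) + rng.normal(0, spec.noise_sd_mmHg, len(hr))
        dbp = _eval_bp(spec.dbp_coeffs, ptt, pir, hr) + rng.normal(0, spec.noise_sd_mmHg, len(hr))
        ok = sbp > dbp
        block = np.column_stack([ptt[ok], pir[ok], hr[ok], sbp[ok], dbp[ok]])
        take = min(len(block), m)
        out[filled : filled + take] = block[:take]
        filled += take
    if filled < n:
        raise RuntimeError("could not satisfy regime constraints by resampling")
    frame = pd.DataFrame(out, columns=["ptt_s", "pir_ratio", "hr_bpm", "sbp_mmHg", "dbp_mmHg"])
    frame.insert(0, "cycle_index", np.arange(n))
    frame["regime_id"] = spec.regime_id
    return frame


def _gaussian_kernel(n: int, center: int, sigma: float) -> np.ndarray:
    j = np.arange(n)
    g = np.exp(-0.5 * ((j - center) / sigma) ** 2)
    return g / g.sum()


def _pulse(n: int, onset: int, rise: int, decay: int, lo: float, hi: float) -> np.ndarray:
    """Flat-rise-decay pulse with its curvature maximum exactly at ``onset``.

    Built by double integration of three curvature kernels (onset +, peak −,
    decay end +) and affinely normalized to [lo, hi]; the rise slope exceeds
    the decay slope so the onset curvature bump dominates.
    """
    top = onset + rise
    end = min(n - 4, top + decay)
    if end <= top + 4:
        end = top + 5
    s_r = 1.0 / rise
    s_d = 1.0 / (end - top)
    # the second central difference of cumsum(cumsum(c)) at j equals c[j+1],
    # so kernels sit one sample late for the SDPPG peak to land on the target
    curv = (
        s_r * _gaussian_kernel(n, onset + 1, _ONSET_SIGMA)
        - (s_r + s_d) * _gaussian_kernel(n, top + 1, _OTHER_SIGMA)
        + s_d * _gaussian_kernel(n, end + 1, _OTHER_SIGMA)
    )
    f = np.cumsum(np.cumsum(curv))
    # remove the linear residual of truncated kernel tails; leaves curvature
    # (and hence the SDPPG argmax) untouched
    f = f - np.linspace(f[0], f[-1], n)
    lo_f, hi_f = f.min(), f.max()
    return lo + (f - lo_f) * (hi - lo) / (hi_f - lo_f)


def generate_beat_train(
    spec: RegimeSpec,
    sampling_rate_hz: float = 125.0,
    seed: int | np.random.Generator = 0,
    record_id: str | None = None,
) -> tuple[WaveformRecord, pd.DataFrame]:
    """Generate one gapless record of ``spec.n_beats`` beats plus truth rows."""
    if sampling_rate_hz < 50:
        raise ValueError("sampling_rate_hz must be >= 50 to resolve the landmarks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = float(sampling_rate_hz)
    truth = sample_truth_features(spec, rng)

    periods = np.rint(fs * 60.0 / truth["hr_bpm"].to_numpy()).astype(int)
    if periods.min() < 30:
        raise ValueError(
            "beat period under 30 samples; raise sampling_rate_hz or lower hr_mean_bpm"
        )
    # baseline lead-in so the first R spike is not truncated at the edge
    pad = int(round(0.3 * fs))
    starts = pad + np.concatenate([[0], np.cumsum(periods)])
    total = int(starts[-1])
    ecg = np.zeros(total)
    ppg = np.full(total, 1.0)
    abp = np.full(total, float(truth["dbp_mmHg"].iat[0]))

    sigma_r = max(1.0, 0.008 * fs)
    half = int(np.ceil(4 * sigma_r))
    for i in range(len(periods)):
        n = periods[i]
        s = starts[i]
        # R-peak spike, maximum exactly at the window's first sample
        j0, j1 = max(0, s - half), min(total, s + half + 1)
        j = np.arange(j0, j1)
        ecg[j0:j1] += np.exp(-0.5 * ((j - s) / sigma_r) ** 2)

        ptt, pir = truth["ptt_s"].iat[i], truth["pir_ratio"].iat[i]
        sbp, dbp = truth["sbp_mmHg"].iat[i], truth["dbp_mmHg"].iat[i]
        rise = max(6, int(round(0.12 * n)))
        decay = max(10, int(round(0.35 * n)))
        onset = int(round(ptt * fs))
        clamped = min(max(onset, 8), n - rise - 10)
        if clamped != onset:  # drawn PTT does not fit this beat window;
            truth.loc[truth.index[i], "ptt_s"] = clamped / fs  # truth follows the waveform
        ppg[s : s + n] = _pulse(n, clamped, rise, decay, lo=1.0, hi=pir)
        abp_onset = max(6, int(round(0.05 * n)))
        abp[s : s + n] = _pulse(n, abp_onset, rise, decay, lo=dbp, hi=sbp)

    rid = record_id or f"regime{spec.regime_id}"
    truth.insert(0, "record_id", rid)
    record = WaveformRecord(record_id=rid, sampling_rate_hz=fs, ecg=ecg, ppg=ppg, abp=abp)
    return record, truth[list(FEATURE_COLUMNS) + ["regime_id"]]


def generate_population(
    specs: Sequence[RegimeSpec],
    sampling_rate_hz: float = 125.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate one record per regime and the concatenated truth table."""
    if len(specs) == 0:
        raise ValueError("need at least one regime spec")
    rng = np.random.default_rng(seed)
    records, tables = [], []
    for spec in specs:
        rec, truth = generate_beat_train(spec, sampling_rate_hz, rng)
        records.append(rec)
        tables.append(truth)
    truth = pd.concat(tables, ignore_index=True)
    return SyntheticDataset(records=records, truth=truth, seed=seed)


# Default study population. Regime centres sit at these offsets from the
# base point, in units of the within-regime SD per feature; the layout is
# oblique (no single feature separates the regimes) with >= 5.3 SD minimum
# pairwise Euclidean separation.
_REGIME_GEOMETRY = [
    # (ptt, pir, hr) offset/SD   (sbp_mean, dbp_mean)  response signs
    ((0.0, 0.0, 0.0), (135.0, 80.0), (+1, +1, +1)),
    ((3.5, 3.5, 2.0), (90.0, 48.0), (+1, -1, +1)),
    ((1.5, -3.0, 4.5), (185.0, 118.0), (-1, +1, -1)),
    ((-2.0, 3.0, 4.0), (175.0, 110.0), (+1, -1, +1)),
    ((5.0, -1.5, -2.5), (100.0, 55.0), (-1, +1, -1)),
]
_FEATURE_SD = (0.012, 0.07, 3.0)  # ptt (s), pir (ratio), hr (bpm)
_FEATURE_BASE = (0.22, 2.0, 85.0)
#: Within-regime SBP signal contributed by each feature (mmHg SD):
#: the 1/PTT term, the PIR term and the HR term respectively.
_SIGNAL_SD_MMHG = (11.0, 8.0, 7.0)
_DBP_RESPONSE_FACTOR = 0.9


def default_regimes(n_beats: int = 400, noise_sd_mmHg: float = 3.0) -> list[RegimeSpec]:
    """The five-regime study population.

    Regime centres are separated by >= 5 within-regime standard deviations
    in scaled (PTT, PIR, HR) space but arranged obliquely, so no single
    feature separates them; each regime carries its own pressure-response
    coefficients (alternating signs, normalized so each feature contributes
    a fixed within-regime signal SD) and regimes adjacent in feature space
    have strongly different mean pressures.  Together this realizes the
    multitrend, high-dispersion structure that a single global regressor
    fits poorly but cluster-wise regressors fit well.
    """
    ptt_sd, pir_sd, hr_sd = _FEATURE_SD
    specs = []
    for i, ((ox, oy, oz), (sbp_m, dbp_m), (g1, g2, g3)) in enumerate(
            _REGIME_GEOMETRY, start=1):
        ptt_m = _FEATURE_BASE[0] + ox * ptt_sd
        pir_m = _FEATURE_BASE[1] + oy * pir_sd
        hr_m = _FEATURE_BASE[2] + oz * hr_sd
        # coefficient sized so its term has the prescribed signal SD;
        # d(1/ptt) ~= ptt_sd / ptt_mean^2 to first order
        c_inv = g1 * _SIGNAL_SD_MMHG[0] / (ptt_sd / ptt_m**2)
        c_pir = g2 * _SIGNAL_SD_MMHG[1] / pir_sd
        c_hr = g3 * _SIGNAL_SD_MMHG[2] / hr_sd
        sbp_coeffs = {
            "intercept": sbp_m - c_inv / ptt_m - c_pir * pir_m - c_hr * hr_m,
            "inv_ptt": c_inv, "pir": c_pir, "hr": c_hr,
        }
        f = _DBP_RESPONSE_FACTOR
        dbp_coeffs = {
            "intercept": dbp_m - f * (c_inv / ptt_m + c_pir * pir_m + c_hr * hr_m),
            "inv_ptt": f * c_inv, "pir": f * c_pir, "hr": f * c_hr,
        }
        specs.append(
            RegimeSpec(
                regime_id=i,
                hr_mean_bpm=hr_m,
                hr_sd=hr_sd,
                ptt_mean_s=ptt_m,
                ptt_sd=ptt_sd,
                pir_mean=pir_m,
                pir_sd=pir_sd,
                sbp_coeffs=sbp_coeffs,
                dbp_coeffs=dbp_coeffs,
                noise_sd_mmHg=noise_sd_mmHg,
                n_beats=n_beats,
            )
        )
    return specs


def regimes_from_dict(entries: Sequence[Mapping]) -> list[RegimeSpec]:
    """Build regime specs from parsed configuration (e.g. a YAML document)."""
    return [RegimeSpec(**e) for e in entries]
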
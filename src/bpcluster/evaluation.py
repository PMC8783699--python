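"""Error metrics, weighted-total aggregation and device-standard grading.

Per-cluster MAE, RMSE and Pearson r are aggregated into totals by the
weighted arithmetic mean with the cluster sample counts as weights.  The
estimate quality is additionally graded against the British Hypertension
Society (BHS) cumulative-error bands and the AAMI mean-error/SD criterion,
and summarized by Bland-Altman limits of agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

#: BHS grade thresholds: cumulative % of absolute errors within 5/10/15 mmHg.
BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0), "C": (40.0, 65.0, 85.0)}

#: AAMI criterion: |mean error| <= 5 mmHg, error SD <= 8 mmHg, >= 85 subjects.
AAMI_LIMITS = {"mean_error": 5.0, "sd_error": 8.0, "min_subjects": 85}


def _pair(estimates, references) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape or e.size == 0:
        raise ValueError("estimates and references must be equal-length and non-empty")
    return e, r


def mae(estimates, references) -> float:
    """Mean absolute error, mmHg."""
    e, r = _pair(estimates, references)
    return float(np.mean(np.abs(r - e)))


def rmse(estimates, references) -> float:
    """Root mean squared error, mmHg."""
    e, r = _pair(estimates, references)
    return float(np.sqrt(np.mean((r - e) ** 2)))


def pearson_r(estimates, references) -> float:
    """Product-moment correlation between estimates and references."""
    e, r = _pair(estimates, references)
    if e.size < 2 or np.all(e == e[0]) or np.all(r == r[0]):
        raise ValueError("correlation needs >= 2 points and nonconstant vectors")
    return float(stats.pearsonr(e, r).statistic)


def weighted_total(values, counts) -> float:
    """Weighted arithmetic mean sum(v_i * n_i) / sum(n_i)."""
    v = np.asarray(values, dtype=float)
    n = np.asarray(counts, dtype=float)
    if v.shape != n.shape or v.size == 0:
        raise ValueError("values and counts must be equal-length and non-empty")
    if np.any(n <= 0):
        raise ValueError("counts must be positive")
    return float(np.dot(v, n) / n.sum())


def bhs_grade(estimates, references) -> tuple[float, float, float, str]:
    """Cumulative % of |error| <= 5/10/15 mmHg and the resulting BHS grade.

    A grade requires all three of its thresholds to hold; closed bounds
    (<=) on both the error and the percentage thresholds.
    """
    e, r = _pair(estimates, references)
    err = np.abs(e - r)
    pcts = tuple(float(100.0 * np.mean(err <= t)) for t in (5.0, 10.0, 15.0))
    grade = "D"
    for g in ("A", "B", "C"):
        if all(p >= t for p, t in zip(pcts, BHS_THRESHOLDS[g])):
            grade = g
            break
    return (*pcts, grade)


def aami_check(estimates, references, n_subjects: int) -> tuple[float, float, bool]:
    """Signed mean error, SD of error, and the AAMI pass decision."""
    e, r = _pair(estimates, references)
    diff = e - r
    me = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    ok = (
        abs(me) <= AAMI_LIMITS["mean_error"]
        and sd <= AAMI_LIMITS["sd_error"]
        and n_subjects >= AAMI_LIMITS["min_subjects"]
    )
    return me, sd, ok


def aami_check_summary(mean_error: float, sd_error: float, n_subjects: int) -> bool:
    """AAMI pass decision from already-computed summary statistics."""
    return (
        abs(mean_error) <= AAMI_LIMITS["mean_error"]
        and sd_error <= AAMI_LIMITS["sd_error"]
        and n_subjects >= AAMI_LIMITS["min_subjects"]
    )


def bland_altman(estimates, references) -> tuple[float, float, float]:
    """Bias and 1.96-SD limits of agreement of (estimate - reference)."""
    e, r = _pair(estimates, references)
    diff = e - r
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if diff.size > 1 else 0.0
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class ClusterMetrics:
    """Per-cluster error summary for one target (SBP or DBP)."""

    cluster: int
    n: int
    mae_mmHg: float
    rmse_mmHg: float
    r: float  # NaN when undefined (constant vectors within the cluster)


@dataclass
class TargetReport:
    """Per-cluster metrics plus weighted totals for one pressure target."""

    target: str
    clusters: list = field(default_factory=list)
    total_mae: float = np.nan
    total_rmse: float = np.nan          # weighted mean of per-cluster RMSE
    total_rmse_pooled: float = np.nan   # pooled over all squared errors
    total_r: float = np.nan             # weighted mean of per-cluster r
    bhs: tuple = ()
    aami: tuple = ()
    bland_altman: tuple = ()


@dataclass
class EvaluationReport:
    """Full evaluation: one :class:`TargetReport` per pressure target."""

    sbp: TargetReport
    dbp: TargetReport
    n_rows: int
    split: str = "test"

    def to_dict(self) -> dict:
        def tr(t: TargetReport) -> dict:
            return {
                "clusters": [vars(c) for c in t.clusters],
                "total_mae": t.total_mae,
                "total_rmse": t.total_rmse,
                "total_rmse_pooled": t.total_rmse_pooled,
                "total_r": t.total_r,
                "bhs": {"pct_le_5": t.bhs[0], "pct_le_10": t.bhs[1],
                        "pct_le_15": t.bhs[2], "grade": t.bhs[3]},
                "aami": {"mean_error": t.aami[0], "sd_error": t.aami[1],
                         "pass": bool(t.aami[2])},
                "bland_altman": {"bias": t.bland_altman[0],
                                 "lower": t.bland_altman[1],
                                 "upper": t.bland_altman[2]},
            }
        return {"split": self.split, "n_rows": self.n_rows,
                "sbp": tr(self.sbp), "dbp": tr(self.dbp)}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_table(self) -> pd.DataFrame:
        """Per-cluster + total rows in the usual comparison-table layout."""
        rows = []
        for cs, cd in zip(self.sbp.clusters, self.dbp.clusters):
            rows.append({"cluster": f"cluster{cs.cluster + 1}", "n": cs.n,
                         "sbp_mae": cs.mae_mmHg, "sbp_rmse": cs.rmse_mmHg, "sbp_r": cs.r,
                         "dbp_mae": cd.mae_mmHg, "dbp_rmse": cd.rmse_mmHg, "dbp_r": cd.r})
        rows.append({"cluster": "total", "n": self.n_rows,
                     "sbp_mae": self.sbp.total_mae, "sbp_rmse": self.sbp.total_rmse,
                     "sbp_r": self.sbp.total_r,
                     "dbp_mae": self.dbp.total_mae, "dbp_rmse": self.dbp.total_rmse,
                     "dbp_r": self.dbp.total_r})
        return pd.DataFrame(rows)


def _target_report(pred: np.ndarray, ref: np.ndarray, clusters: np.ndarray,
                   target: str, n_subjects: int) -> TargetReport:
    report = TargetReport(target=target)
    values_mae, values_rmse, values_r, counts = [], [], [], []
    for c in sorted(np.unique(clusters)):
        idx = clusters == c
        p, y = pred[idx], ref[idx]
        try:
            r = pearson_r(p, y)
        except ValueError:
            r = np.nan
        report.clusters.append(ClusterMetrics(
            cluster=int(c), n=int(idx.sum()),
            mae_mmHg=mae(p, y), rmse_mmHg=rmse(p, y), r=r,
        ))
        values_mae.append(mae(p, y))
        values_rmse.append(rmse(p, y))
        values_r.append(r)
        counts.append(int(idx.sum()))
    report.total_mae = weighted_total(values_mae, counts)
    report.total_rmse = weighted_total(values_rmse, counts)
    report.total_rmse_pooled = rmse(pred, ref)
    r_ok = ~np.isnan(values_r)
    if r_ok.any():
        report.total_r = weighted_total(np.array(values_r)[r_ok],
                                        np.array(counts)[r_ok])
    report.bhs = bhs_grade(pred, ref)
    report.aami = aami_check(pred, ref, n_subjects)
    report.bland_altman = bland_altman(pred, ref)
    return report


def build_report(
    predictions: pd.DataFrame,
    references: pd.DataFrame,
    n_subjects: int | None = None,
    split: str = "test",
) -> EvaluationReport:
    """Assemble the full report from routed predictions and references.

    ``predictions`` must carry ``cluster``, ``sbp_hat``, ``dbp_hat``;
    ``references`` the aligned ``sbp_mmHg``, ``dbp_mmHg``.  ``n_subjects``
    defaults to the row count (cycle-level grading) — pass the true
    subject count when it is known.
    """
    if len(predictions) != len(references) or len(predictions) == 0:
        raise ValueError("predictions and references must align and be non-empty")
    clusters = predictions["cluster"].to_numpy()
    n_subjects = len(predictions) if n_subjects is None else n_subjects
    sbp = _target_report(predictions["sbp_hat"].to_numpy(),
                         references["sbp_mmHg"].to_numpy(), clusters, "sbp", n_subjects)
    dbp = _target_report(predictions["dbp_hat"].to_numpy(),
                         references["dbp_mmHg"].to_numpy(), clusters, "dbp", n_subjects)
    return EvaluationReport(sbp=sbp, dbp=dbp, n_rows=len(predictions), split=split)
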
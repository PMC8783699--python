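"""Published MIMIC-II reference results used as validation inputs.

These values come from a published study of clustered cuff-less blood
pressure estimation on the Kaggle-hosted preprocessed MIMIC-II waveform
set (five k-means clusters of per-cycle PTT/PIR/HR features, one
regressor per cluster, totals by weighted arithmetic mean).  Reproducing
the raw-data numbers requires that external download; the tables are kept
here as *inputs* for validating the aggregation arithmetic and the
BHS/AAMI graders, not as outputs of this package.
"""

from __future__ import annotations

#: Per-cluster sample counts of the published five-cluster partition.
CLUSTER_COUNTS = (6282, 6276, 3355, 8300, 2390)

#: Published total sample count (sum of CLUSTER_COUNTS).
TOTAL_SAMPLES = 26603

#: Per-cluster MAE (mmHg) by learner family and target, with the printed
#: weighted totals.
PER_CLUSTER_MAE = {
    ("random_forest", "sbp"): ((3.407, 3.468, 3.521, 3.396, 2.434), 3.344),
    ("random_forest", "dbp"): ((3.250, 3.038, 2.813, 2.870, 2.677), 2.974),
    ("gradient_boosting", "sbp"): ((2.644, 2.781, 2.533, 2.610, 1.643), 2.561),
    ("gradient_boosting", "dbp"): ((2.486, 2.468, 2.003, 2.161, 1.504), 2.231),
    ("mlp", "sbp"): ((5.230, 5.340, 6.235, 7.261, 4.326), 5.937),
    ("mlp", "dbp"): ((4.896, 5.263, 6.094, 6.288, 4.160), 5.501),
}

#: Per-cluster Pearson r (gradient boosting only) with printed totals.
PER_CLUSTER_R = {
    ("gradient_boosting", "sbp"): ((0.96, 0.93, 0.76, 0.85, 0.85), 0.88),
    ("gradient_boosting", "dbp"): ((0.98, 0.96, 0.80, 0.95, 0.95), 0.94),
}

#: Published global (no clustering) totals for context: family ->
#: (sbp_mae, sbp_rmse, sbp_r, dbp_mae, dbp_rmse, dbp_r).
GLOBAL_RESULTS = {
    "random_forest": (7.426, 12.250, 0.65, 7.410, 12.110, 0.68),
    "gradient_boosting": (6.367, 10.395, 0.67, 6.276, 10.221, 0.71),
    "mlp": (9.422, 14.120, 0.59, 9.323, 14.099, 0.64),
}

#: Published BHS cumulative error percentages: target -> (<=5, <=10, <=15).
BHS_PERCENTAGES = {"dbp": (73.05, 90.12, 97.34), "sbp": (65.59, 86.54, 96.32)}

#: Published AAMI summary: target -> (mean error mmHg, SD mmHg, n subjects).
AAMI_SUMMARY = {"dbp": (2.811, 5.596, 942), "sbp": (3.987, 5.715, 942)}
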
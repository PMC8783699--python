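"""Cluster-wise regression ensembles mapping (PTT, PIR, HR) to SBP and DBP.

Three learner families are supported — gradient boosting, random forest
and a multilayer perceptron — as interchangeable backends.  The method's
own logic is the orchestration: one independently trained regressor pair
(SBP model, DBP model) per cluster, nearest-centroid routing of unseen
samples, and a global (no-clustering) fallback for clusters too small to
train on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .cluster import FEATURE_SPACE, ClusterModel, ScalingModel, assign_cluster

logger = logging.getLogger(__name__)

LEARNER_FAMILIES = ("gradient_boosting", "random_forest", "mlp")

_DEFAULT_HP: dict[str, dict] = {
    "gradient_boosting": {"n_estimators": 300, "max_depth": 3, "learning_rate": 0.1},
    "random_forest": {"n_estimators": 300, "max_depth": None},
    # batch 32 so small per-cluster training sets still get several
    # gradient updates per epoch
    "mlp": {"hidden_layer_sizes": (64, 32), "activation": "relu",
            "learning_rate_init": 1e-3, "max_iter": 500, "batch_size": 32},
}


@dataclass
class LearnerSpec:
    """A learner family plus hyperparameters and a seed."""

    family: str = "gradient_boosting"
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; "
                             f"choose from {LEARNER_FAMILIES}")

    def build(self):
        """Instantiate an unfitted sklearn regressor for this spec."""
        hp = {**_DEFAULT_HP[self.family], **dict(self.hyperparameters)}
        if self.family == "gradient_boosting":
            return GradientBoostingRegressor(random_state=self.seed, **hp)
        if self.family == "random_forest":
            return RandomForestRegressor(random_state=self.seed, **hp)
        # MLP needs standardized inputs and target to converge on
        # mmHg-scale targets with sub-second features
        net = MLPRegressor(random_state=self.seed, **hp)
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), net),
            transformer=StandardScaler(),
        )


@dataclass
class ClusterEnsemble:
    """One fitted (SBP, DBP) regressor pair per cluster + routing metadata."""

    cluster_model: ClusterModel
    scaler: ScalingModel
    spec: LearnerSpec
    models: dict  # cluster index -> (sbp_model, dbp_model)
    counts: dict  # cluster index -> training rows
    fallback_clusters: tuple = ()

    @property
    def n_training_rows(self) -> int:
        return int(sum(self.counts.values()))


def _xy(features: pd.DataFrame):
    x = features[list(FEATURE_SPACE)].to_numpy(dtype=float)
    return x, features["sbp_mmHg"].to_numpy(dtype=float), features["dbp_mmHg"].to_numpy(dtype=float)


def fit_global(features: pd.DataFrame, spec: LearnerSpec):
    """Fit one (SBP, DBP) regressor pair on the whole table."""
    if len(features) < 10:
        raise ValueError("need at least 10 rows to fit a regressor pair")
    x, sbp, dbp = _xy(features)
    m_sbp = spec.build().fit(x, sbp)
    m_dbp = spec.build().fit(x, dbp)
    return m_sbp, m_dbp


def fit_per_cluster(
    features: pd.DataFrame,
    cluster_model: ClusterModel,
    scaler: ScalingModel,
    spec: LearnerSpec,
    min_cluster_rows: int = 10,
) -> ClusterEnsemble:
    """Fit one regressor pair per cluster of the training rows.

    Rows are routed to clusters by nearest centroid.  Clusters with fewer
    than ``min_cluster_rows`` training rows share a single global-fit
    fallback pair (logged).
    """
    labels = assign_cluster(cluster_model, scaler, features)
    models: dict[int, tuple] = {}
    counts: dict[int, int] = {}
    fallback: list[int] = []
    global_pair = None
    for c in range(cluster_model.k):
        rows = features[labels == c]
        counts[c] = len(rows)
        if len(rows) >= min_cluster_rows:
            models[c] = fit_global(rows, spec)
        else:
            if global_pair is None:
                global_pair = fit_global(features, spec)
            models[c] = global_pair
            fallback.append(c)
            logger.warning(
                "cluster %d has %d rows (< %d); using global fallback model",
                c, len(rows), min_cluster_rows,
            )
    return ClusterEnsemble(
        cluster_model=cluster_model,
        scaler=scaler,
        spec=spec,
        models=models,
        counts=counts,
        fallback_clusters=tuple(fallback),
    )


def predict(ensemble: ClusterEnsemble, features: pd.DataFrame) -> pd.DataFrame:
    """Route each row to its nearest centroid and predict with that pair.

    Returns a frame with columns ``cluster``, ``sbp_hat``, ``dbp_hat``
    aligned to ``features`` (plus identifying columns when present).
    """
    labels = assign_cluster(ensemble.cluster_model, ensemble.scaler, features)
    x = features[list(FEATURE_SPACE)].to_numpy(dtype=float)
    sbp_hat = np.empty(len(features))
    dbp_hat = np.empty(len(features))
    for c in np.unique(labels):
        m_sbp, m_dbp = ensemble.models[int(c)]
        idx = labels == c
        sbp_hat[idx] = m_sbp.predict(x[idx])
        dbp_hat[idx] = m_dbp.predict(x[idx])
    if not (np.all(np.isfinite(sbp_hat)) and np.all(np.isfinite(dbp_hat))):
        raise RuntimeError("non-finite predictions")
    out = pd.DataFrame({"cluster": labels, "sbp_hat": sbp_hat, "dbp_hat": dbp_hat},
                       index=features.index)
    for col in ("record_id", "cycle_index"):
        if col in features.columns:
            out.insert(0, col, features[col])
    return out


def predict_global(pair: tuple, features: pd.DataFrame) -> pd.DataFrame:
    """Predict with a single global (SBP, DBP) pair; no routing."""
    x = features[list(FEATURE_SPACE)].to_numpy(dtype=float)
    return pd.DataFrame(
        {"sbp_hat": pair[0].predict(x), "dbp_hat": pair[1].predict(x)},
        index=features.index,
    )
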
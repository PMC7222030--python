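"""Blind application of a trained ensemble to an external cohort.

Every optimal CV1 model in the ensemble predicts the external subjects
from its own stored feature mask and weights; the per-subject arithmetic
mean over all ensemble members is the SVR score (on the training cohort's
EYO scale: higher = more advanced predicted disease stage).  Nothing is
refitted, recalibrated, or pooled across cohorts — the external features
must already be harmonized against the external cohort's own healthy
reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv_engine import EnsembleModel
from .datatypes import FeatureMatrix
from .errors import FeatureMismatchError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SVRScoreTable", "score_external"]


@dataclass
class SVRScoreTable:
    """Per-subject ensemble scores with provenance.

    ``table`` columns: ``id, score, score_sd, score_z`` — the ensemble-mean
    prediction (EYO-scale units), the across-model prediction SD, and the
    score z-scored within this cohort for standardized-coefficient
    regressions.
    """

    table: pd.DataFrame
    ensemble_ref: str
    cohort: str

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("id")["score"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ensemble_ref: str = "", cohort: str = "") -> "SVRScoreTable":
        return cls(pd.read_csv(path), ensemble_ref=ensemble_ref, cohort=cohort)


def score_external(ensemble: EnsembleModel, features: FeatureMatrix) -> SVRScoreTable:
    """Score an external cohort with a frozen ensemble (no refitting).

    Features absent from the ensemble's registry are dropped with a
    warning; registry features absent from the input are a hard error (the
    analysis assumes complete biomarker availability — no imputation).
    Input must carry harmonization provenance.
    """
    if not features.harmonized:
        raise ValidationError(
            "refusing to score unharmonized features: scale them to the "
            "external cohort's own healthy reference group first")
    registry = ensemble.feature_registry
    have = set(features.feature_names)
    missing = set(registry) - have
    if missing:
        raise FeatureMismatchError(
            f"external cohort lacks required features: {sorted(missing)[:8]}",
            missing=missing)
    extra = have - set(registry)
    if extra:
        logger.warning("dropping %d feature(s) unknown to the ensemble: %s",
                       len(extra), sorted(extra)[:5])
    aligned = features.values[registry]
    X = aligned.to_numpy(dtype=float)

    pred = ensemble.predict_matrix(X)  # (n_models, n_subjects)
    score = pred.mean(axis=0)
    spread = pred.std(axis=0, ddof=0)
    z_sd = score.std(ddof=1) if len(score) > 1 else 0.0
    score_z = (score - score.mean()) / z_sd if z_sd > 0 else np.zeros_like(score)

    table = pd.DataFrame({
        "id": aligned.index, "score": score, "score_sd": spread, "score_z": score_z,
    }).reset_index(drop=True)
    return SVRScoreTable(
        table=table,
        ensemble_ref=(f"{ensemble.training_cohort}:"
                      f"{''.join(ensemble.modalities)}:{len(ensemble)}models"),
        cohort=features.cohort,
    )
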
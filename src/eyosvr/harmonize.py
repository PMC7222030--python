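"""Reference-group scaling of biomarker features.

Each cohort's features are standardized and variance-normalized against
that cohort's own healthy reference group (non-carrier siblings in the
ADAD-like cohort; cognitively normal amyloid-negative subjects in the
MCI-like cohort).  Because the two cohorts measure the same biology through
different instruments, z-scoring to the cohort-internal healthy reference
puts both on a common "SDs from healthy" scale — this is what lets a model
trained in one cohort be applied blindly to the other.

Scaling is fitted once per cohort, before any cross-validation; reference
statistics are treated as fixed inputs downstream.  No statistic from one
cohort ever enters the other's scaler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix
from .errors import FeatureMismatchError, HarmonizationError

__all__ = ["ScalingParams", "fit_reference_scaler", "apply_scaler"]


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature reference mean/SD plus provenance of the reference group."""

    mean: pd.Series            # feature -> reference mean (raw units)
    sd: pd.Series              # feature -> reference SD (raw units)
    cohort: str                # cohort the reference group belongs to
    reference_label: str       # how the reference group was defined
    n_reference: int
    ddof: int = 1              # 1 = sample SD (default), 0 = population SD

    @property
    def feature_names(self) -> list[str]:
        return list(self.mean.index)

    def ref(self) -> str:
        return f"{self.cohort}:{self.reference_label}(n={self.n_reference})"

    def to_json(self, path) -> None:
        payload = {
            "cohort": self.cohort,
            "reference_label": self.reference_label,
            "n_reference": self.n_reference,
            "ddof": self.ddof,
            "features": {
                name: {"mean": float(self.mean[name]), "sd": float(self.sd[name])}
                for name in self.feature_names
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScalingParams":
        with open(path) as fh:
            payload = json.load(fh)
        feats = payload["features"]
        names = list(feats)
        return cls(
            mean=pd.Series({n: feats[n]["mean"] for n in names}),
            sd=pd.Series({n: feats[n]["sd"] for n in names}),
            cohort=payload["cohort"],
            reference_label=payload["reference_label"],
            n_reference=payload["n_reference"],
            ddof=payload.get("ddof", 1),
        )


def fit_reference_scaler(features: FeatureMatrix, reference_ids: Iterable,
                         reference_label: str = "reference",
                         ddof: int = 1) -> ScalingParams:
    """Compute per-feature mean and SD from the healthy reference subjects.

    Parameters
    ----------
    features
        Raw-scale feature matrix of the whole cohort.
    reference_ids
        Subject ids forming the healthy reference group; must all be
        present in ``features`` and number at least two.
    ddof
        Delta degrees of freedom for the SD (1 = sample SD).
    """
    ref_ids = list(reference_ids)
    if not ref_ids:
        raise HarmonizationError("reference group is empty")
    unknown = set(ref_ids) - set(features.subject_ids)
    if unknown:
        raise HarmonizationError(
            f"reference ids not in feature matrix: {sorted(unknown)[:5]}")
    if len(ref_ids) < 2:
        raise HarmonizationError("need at least 2 reference subjects per feature")

    block = features.values.loc[ref_ids]
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=ddof)
    degenerate = sd.index[~(sd > 0)].tolist()
    if degenerate:
        raise HarmonizationError(
            f"zero reference SD for feature(s) {degenerate[:5]}: cannot scale")
    return ScalingParams(mean=mean, sd=sd, cohort=features.cohort,
                         reference_label=reference_label,
                         n_reference=len(ref_ids), ddof=ddof)


def apply_scaler(features: FeatureMatrix, params: ScalingParams) -> FeatureMatrix:
    """Return ``(value - reference mean) / reference SD`` feature-wise.

    Feature registries must match exactly (order-insensitive); the output
    keeps the input's column order, modality tags, and is flagged
    harmonized with the scaler's provenance attached.
    """
    have = set(features.feature_names)
    want = set(params.feature_names)
    if have != want:
        raise FeatureMismatchError(
            "scaler/feature registry mismatch: "
            f"missing={sorted(want - have)} extra={sorted(have - want)}",
            missing=want - have, extra=have - want,
        )
    cols = features.values.columns
    scaled = (features.values - params.mean[cols]) / params.sd[cols]
    return replace(features, values=scaled, harmonized=True, scaler_ref=params.ref())
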
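"""Core in-memory containers shared across pipeline stages.

Tabular data is held in pandas objects with fixed column conventions:

* cohort table — one row per subject with columns ``id, cohort, group, age,
  sex, education, eyo, abeta_status`` (``eyo`` is NaN outside the
  mutation-carrier cohort, ``abeta_status`` outside the MCI cohort).
* feature matrix — subjects x features, wrapped in :class:`FeatureMatrix`
  so that modality tags and harmonization provenance travel with the data.
* longitudinal cognition — long format with columns ``id, years, mem, adas``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FeatureMismatchError, ValidationError

#: Recognised biomarker modalities: amyloid-PET (A), FDG-PET (F),
#: gray-matter structure (G), CSF analytes (C).
MODALITIES = ("A", "F", "G", "C")

COHORT_COLUMNS = [
    "id", "cohort", "group", "age", "sex", "education", "eyo", "abeta_status",
]
COGNITION_COLUMNS = ["id", "years", "mem", "adas"]


def modality_of(feature_name: str) -> str:
    """Return the modality tag encoded in a feature name (``A__precuneus`` -> ``A``)."""
    tag, sep, rest = feature_name.partition("__")
    if sep != "__" or tag not in MODALITIES or not rest:
        raise ValidationError(
            f"feature name {feature_name!r} must look like '<modality>__<name>' "
            f"with modality in {MODALITIES}"
        )
    return tag


@dataclass
class FeatureMatrix:
    """Subjects x named biomarker features, each tagged with a modality.

    Parameters
    ----------
    values
        DataFrame indexed by subject id; columns are feature names of the
        form ``<modality>__<region-or-analyte>``.
    cohort
        Free-text identifier of the cohort the rows belong to.
    harmonized
        True once the matrix has been reference-scaled.  Stages that require
        harmonized input (training, scoring) refuse matrices where this flag
        is False.
    scaler_ref
        Provenance string identifying the scaler that produced the values.
    """

    values: pd.DataFrame
    cohort: str = ""
    harmonized: bool = False
    scaler_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate subject ids in feature matrix: {dupes[:5]}")
        for name in self.values.columns:
            modality_of(name)  # raises on malformed names

    # -- registry ----------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    def modalities(self) -> set[str]:
        return {modality_of(c) for c in self.values.columns}

    def feature_modalities(self) -> pd.Series:
        return pd.Series({c: modality_of(c) for c in self.values.columns})

    # -- views -------------------------------------------------------------
    def restrict_modalities(self, modalities: Iterable[str]) -> "FeatureMatrix":
        """Return a view containing only features of the given modalities."""
        wanted = set(modalities)
        unknown = wanted - set(MODALITIES)
        if unknown:
            raise ValidationError(f"unknown modalities requested: {sorted(unknown)}")
        cols = [c for c in self.values.columns if modality_of(c) in wanted]
        if not cols:
            raise ValidationError(f"no features for modalities {sorted(wanted)}")
        return replace(self, values=self.values[cols])

    def subset_subjects(self, ids: Iterable) -> "FeatureMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise ValidationError(f"unknown subject ids: {sorted(missing)[:5]}")
        return replace(self, values=self.values.loc[ids])

    def align_features(self, names: Iterable[str]) -> "FeatureMatrix":
        """Reorder columns to ``names``, failing loudly on any mismatch."""
        names = list(names)
        have, want = set(self.values.columns), set(names)
        if have != want:
            raise FeatureMismatchError(
                "feature registries differ: "
                f"missing={sorted(want - have)} extra={sorted(have - want)}",
                missing=want - have, extra=have - want,
            )
        return replace(self, values=self.values[names])

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class CohortBundle:
    """Everything the generator knows about one synthetic cohort.

    ``truth`` carries the latent quantities (disease burden, true cognitive
    slopes) used to build the data.  It exists for testing and calibration
    only; the training and scoring interfaces accept a cohort table and a
    feature matrix, so the ground truth cannot leak into model fitting.
    """

    cohort: pd.DataFrame
    features: FeatureMatrix
    cognition: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_cols = [c for c in COHORT_COLUMNS if c not in self.cohort.columns]
        if missing_cols:
            raise ValidationError(f"cohort table lacks columns {missing_cols}")
        ids = set(self.cohort["id"])
        feat_ids = set(self.features.subject_ids)
        if feat_ids - ids:
            raise ValidationError("feature matrix contains subjects absent from cohort table")
        if self.cognition is not None:
            if set(self.cognition["id"]) - ids:
                raise ValidationError("cognition rows reference unknown subjects")

    def write(self, outdir) -> None:
        """Write the bundle as plain CSV files (cohort/features/cognition/truth)."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "cohort.csv", index=False)
        self.features.values.rename_axis("id").to_csv(out / "features.csv")
        if self.cognition is not None:
            self.cognition.to_csv(out / "cognition.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "truth.csv", index=False)
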
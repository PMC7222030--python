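"""Does the transferred SVR score predict cognition and cognitive decline?

Two-step procedure, stratified by amyloid status:

1. Subject-specific annual change slopes are estimated by ordinary least
   squares per subject per follow-up window (baseline to year 1, 2, 3, 4),
   using only subjects with complete annual visits through that window.
   Covariates play no role at this stage.
2. The slope (or baseline score) is regressed on the SVR score with age,
   sex, and education as covariates; outcome and score are z-scored first
   so the score coefficient is standardized.  Optionally baseline
   cognition joins the covariates to control for baseline severity.

The reported effect-size for the score term is the partial R-squared
t^2 / (t^2 + df); a semi-partial variant is available by switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .transfer import SVRScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeTable", "RegressionResult", "fit_subject_slopes",
    "baseline_values", "regress_outcome", "stratified_validation",
]

MEASURES = ("mem", "adas")


# ---------------------------------------------------------------------------
# step 1: subject-specific slopes
# ---------------------------------------------------------------------------

@dataclass
class SlopeTable:
    """Per-subject annual change estimates per follow-up window.

    ``table`` is long format: ``id, measure, window, slope, n_visits``.
    A window-k slope exists only for subjects with complete annual visits
    at years 0..k (at least two points by construction).
    """

    table: pd.DataFrame
    windows: tuple

    def get(self, measure: str, window: int) -> pd.Series:
        sub = self.table[(self.table["measure"] == measure)
                         & (self.table["window"] == window)]
        return sub.set_index("id")["slope"]


def fit_subject_slopes(cognition: pd.DataFrame,
                       windows: Sequence[int] = (1, 2, 3, 4),
                       measures: Sequence[str] = MEASURES) -> SlopeTable:
    """OLS slope of each cognitive measure against years-from-baseline,
    per subject per window, requiring complete annual follow-up.

    Slopes are computed in closed form from the centered-time inner
    product, which for a per-subject simple regression is exact OLS.
    """
    dup = cognition.duplicated(subset=["id", "years"])
    if dup.any():
        bad = cognition.loc[dup, "id"].unique()[:5]
        raise ValidationError(f"duplicate visit times for subject(s) {list(bad)}")
    rows = []
    for measure in measures:
        wide = cognition.pivot(index="id", columns="years", values=measure)
        for k in windows:
            needed = [float(t) for t in range(k + 1)]
            missing_cols = [t for t in needed if t not in wide.columns]
            if missing_cols:
                continue  # no subject can have this window
            block = wide[needed].dropna()
            if block.empty:
                continue
            t = np.array(needed)
            w = t - t.mean()
            slopes = block.to_numpy() @ w / (w @ w)
            for sid, s in zip(block.index, slopes):
                rows.append((sid, measure, k, float(s), k + 1))
    table = pd.DataFrame(rows, columns=["id", "measure", "window", "slope", "n_visits"])
    return SlopeTable(table=table, windows=tuple(windows))


def baseline_values(cognition: pd.DataFrame,
                    measures: Sequence[str] = MEASURES) -> pd.DataFrame:
    """Baseline (year 0) value of each measure, indexed by subject id."""
    base = cognition[cognition["years"] == 0.0]
    return base.set_index("id")[list(measures)]


# ---------------------------------------------------------------------------
# step 2: covariate-adjusted regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Standardized effect of the SVR score on one outcome in one stratum."""

    beta: float          # standardized score coefficient
    t: float
    df: int              # residual degrees of freedom
    p: float
    partial_r2: float
    n: int
    covariates: tuple
    stratum: str = ""
    outcome: str = ""
    window: Union[int, str] = ""
    baseline_adjusted: bool = False

    def as_row(self) -> dict:
        return {
            "stratum": self.stratum, "outcome": self.outcome,
            "window": self.window, "n": self.n, "beta": self.beta,
            "t": self.t, "df": self.df, "p": self.p,
            "partial_r2": self.partial_r2,
            "baseline_adjusted": self.baseline_adjusted,
        }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def _name_collinear(design: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on the columns before them."""
    bad, kept = [], []
    for col in design.columns:
        if kept:
            A = design[kept].to_numpy()
            b = design[col].to_numpy()
            resid = b - A @ np.linalg.lstsq(A, b, rcond=None)[0]
            if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(b)):
                bad.append(col)
                continue
        kept.append(col)
    return bad


def regress_outcome(outcome: pd.Series, score: pd.Series,
                    covariates: Optional[pd.DataFrame] = None,
                    extra_adjusters: Optional[pd.DataFrame] = None,
                    r2_kind: str = "partial") -> RegressionResult:
    """Standardized linear regression of an outcome on the SVR score.

    All inputs are pandas objects indexed by subject id; only complete
    cases across every input are used.  Outcome and score are z-scored so
    ``beta`` is standardized; covariates enter raw (the score term's t and
    partial R-squared are invariant to their scaling).
    """
    parts = [outcome.rename("__outcome"), score.rename("__score")]
    if covariates is not None:
        parts.append(covariates)
    if extra_adjusters is not None:
        parts.append(extra_adjusters)
    data = pd.concat(parts, axis=1, join="inner").dropna()
    n = len(data)
    n_params = data.shape[1] + 1  # + intercept
    if n <= n_params + 1:
        raise ValidationError(f"too few complete cases (n={n}) for {n_params} parameters")

    y = _zscore(data["__outcome"].to_numpy(dtype=float))
    design = pd.DataFrame({"const": 1.0, "score": _zscore(data["__score"].to_numpy(dtype=float))},
                          index=data.index)
    for col in data.columns:
        if col not in ("__outcome", "__score"):
            design[col] = data[col].astype(float)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValidationError(
            f"rank-deficient design; collinear columns: {_name_collinear(design)}")

    fit = sm.OLS(y, design.to_numpy()).fit()
    beta, t, p = fit.params[1], fit.tvalues[1], fit.pvalues[1]
    df = int(fit.df_resid)
    if r2_kind == "partial":
        r2 = t ** 2 / (t ** 2 + df)
    elif r2_kind == "semipartial":
        r2 = t ** 2 * (1.0 - fit.rsquared) / df
    else:
        raise ValidationError(f"unknown r2_kind {r2_kind!r}")
    covs = tuple(c for c in design.columns if c not in ("const", "score"))
    return RegressionResult(beta=float(beta), t=float(t), df=df, p=float(p),
                            partial_r2=float(r2), n=n, covariates=covs)


# ---------------------------------------------------------------------------
# the stratified validation table
# ---------------------------------------------------------------------------

def stratified_validation(scores: Union[SVRScoreTable, pd.Series],
                          cognition: pd.DataFrame, cohort: pd.DataFrame,
                          windows: Sequence[int] = (1, 2, 3, 4),
                          measures: Sequence[str] = MEASURES,
                          covariate_cols: Sequence[str] = ("age", "sex", "education"),
                          include_baseline_adjusted: bool = True,
                          r2_kind: str = "partial") -> pd.DataFrame:
    """Score -> cognition regressions for each amyloid stratum, outcome,
    and target (baseline + each follow-up window).

    Returns one row per regression; primary rows (2 strata x 2 outcomes x
    (1 + len(windows)) targets) have ``baseline_adjusted == False``, and a
    second pass re-runs the slope regressions with baseline cognition as an
    additional covariate.
    """
    score = scores.scores if isinstance(scores, SVRScoreTable) else scores
    meta = cohort.set_index("id")
    slopes = fit_subject_slopes(cognition, windows, measures)
    base = baseline_values(cognition, measures)
    rows = []
    for stratum in ("pos", "neg"):
        ids = meta.index[(meta["abeta_status"] == stratum)
                         & (meta["group"] == "MCI")]
        if len(ids) == 0:
            logger.info("stratum %s empty: skipped", stratum)
            continue
        covs = meta.loc[ids, list(covariate_cols)]
        s = score.reindex(ids).dropna()
        for measure in measures:
            targets = [("baseline", base[measure].reindex(ids))]
            targets += [(k, slopes.get(measure, k).reindex(ids).dropna())
                        for k in windows]
            for window, outcome in targets:
                passes = [(False, None)]
                if include_baseline_adjusted and window != "baseline":
                    passes.append((True, base[[measure]].rename(
                        columns={measure: f"baseline_{measure}"})))
                for adjusted, extra in passes:
                    try:
                        res = regress_outcome(outcome, s, covs, extra, r2_kind)
                    except ValidationError as exc:
                        logger.info("skipping %s/%s/%s: %s",
                                    stratum, measure, window, exc)
                        continue
                    res.stratum, res.outcome, res.window = stratum, measure, window
                    res.baseline_adjusted = adjusted
                    rows.append(res.as_row())
    return pd.DataFrame(rows)
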
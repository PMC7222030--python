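"""Risk enrichment and trial sample-size estimation.

At-risk subjects are the amyloid-positive MCI subjects whose SVR score
falls strictly above the within-stratum median.  For each selection
strategy (none, or score-based selection from the best single-, two-,
three-, and four-modality ensembles) and follow-up window, the group-level
time effect on cognition is estimated with a random-intercept linear mixed
model (time + age + sex + education as fixed effects, REML), and the
required per-arm sample size for a hypothetical intervention shrinking the
mean annual change by 10-40% is computed from two-sided two-sample t-test
power at alpha 0.05 / power 0.8.

The effect size is d = fraction * |mean annual change| / SD of the
subject-level annual changes observed in the analyzed group; required N is
the smallest integer per arm whose noncentral-t power reaches the target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ConvergenceError, ValidationError
from .outcome_models import MEASURES, fit_subject_slopes
from .transfer import SVRScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelResult", "select_at_risk", "fit_time_effect",
    "power_two_sample_t", "required_n_per_arm", "percent_reduction",
    "enrichment_table",
]


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_at_risk(scores: Union[SVRScoreTable, pd.Series],
                   rule: str = "above_median") -> set:
    """Subjects predicted to decline fastest: score strictly above the
    median of the provided scores.

    The caller controls the stratum by what it passes in (by default the
    amyloid-positive subjects only).  If all scores are identical the
    selection is empty and a warning is logged.
    """
    s = scores.scores if isinstance(scores, SVRScoreTable) else scores
    if len(s) < 2:
        raise ValidationError("need at least 2 scored subjects to select from")
    if rule != "above_median":
        raise ValidationError(f"unknown selection rule {rule!r}")
    med = float(s.median())
    chosen = set(s.index[s > med])
    if not chosen:
        logger.warning("selection empty: all %d scores equal the median %.4f",
                       len(s), med)
    else:
        logger.info("selected %d/%d subjects above score median %.3f",
                    len(chosen), len(s), med)
    return chosen


# ---------------------------------------------------------------------------
# mixed-model time effect
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Fixed effect of time from a random-intercept linear mixed model."""

    beta_time: float   # cognition units per year
    se: float
    t: float
    p: float
    n_subjects: int
    n_obs: int
    selection: str = ""
    outcome: str = ""
    window: Union[int, str] = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta_time):
            raise ValidationError("non-finite time effect")
        if self.n_subjects < 2:
            raise ValidationError("mixed model needs >= 2 subjects")


def fit_time_effect(cognition: pd.DataFrame, covariates: pd.DataFrame,
                    measure: str = "mem") -> MixedModelResult:
    """Random-intercept mixed model of one cognitive measure on time.

    Fixed effects: years from baseline plus age, sex, and education;
    random intercept per subject; REML.  Falls back from the default
    optimizer to Powell before raising a convergence error.
    """
    data = cognition.merge(covariates.rename_axis("id").reset_index(), on="id")
    data = data.dropna(subset=[measure, "years", "age", "sex", "education"])
    n_subj = data["id"].nunique()
    if n_subj < 2 or (data.groupby("id").size() >= 2).sum() < 2:
        raise ValidationError("need >= 2 visits for >= 2 subjects")
    model = smf.mixedlm(f"{measure} ~ years + age + sex + education",
                        data=data, groups=data["id"])
    fit, errors = None, []
    for method in (["lbfgs"], ["powell"], ["cg"]):
        try:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=True, method=method, maxiter=500)
            if np.isfinite(cand.params["years"]) and np.isfinite(cand.bse["years"]):
                fit = cand
                break
            errors.append(f"{method[0]}: non-finite estimate")
        except Exception as exc:  # statsmodels raises plain LinAlgError etc.
            errors.append(f"{method[0]}: {exc}")
    if fit is None:
        raise ConvergenceError("mixed model did not converge; " + "; ".join(errors))
    beta = float(fit.params["years"])
    se = float(fit.bse["years"])
    return MixedModelResult(
        beta_time=beta, se=se, t=beta / se if se > 0 else np.inf,
        p=float(fit.pvalues["years"]), n_subjects=n_subj, n_obs=len(data),
        outcome=measure)


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

def power_two_sample_t(n_per_arm: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t test at effect size d,
    from the noncentral t distribution."""
    if n_per_arm < 2:
        return 0.0
    df = 2 * (n_per_arm - 1)
    nc = abs(d) * math.sqrt(n_per_arm / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    val = float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    if not math.isfinite(val):
        # scipy's noncentral t loses accuracy at extreme noncentrality,
        # where power is 1 to machine precision; use the normal limit
        val = float(stats.norm.sf(tcrit - nc) + stats.norm.cdf(-tcrit - nc))
    return val


def required_n_per_arm(mean_change: float, sd_change: float, fraction: float,
                       alpha: float = 0.05, power: float = 0.8) -> float:
    """Smallest integer N per arm detecting a fractional intervention effect.

    The detectable difference is ``fraction * |mean_change|`` of annual
    cognitive change against the observed between-subject SD of change, so
    d = fraction * |mean_change| / sd_change; returns ``math.inf`` when the
    effect is exactly zero.
    """
    if sd_change <= 0:
        raise ValidationError("sd_change must be > 0")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    if not 0.0 < alpha < 1.0 or not alpha < power < 1.0:
        raise ValidationError("need 0 < alpha < power < 1")
    d = fraction * abs(mean_change) / sd_change
    if d == 0.0:
        return math.inf
    # normal-approximation start, then walk to the smallest sufficient n
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = max(2, int(math.floor(2.0 * ((za + zb) / d) ** 2)) - 2)
    while power_two_sample_t(n, d, alpha) < power:
        n += 1
    while n > 2 and power_two_sample_t(n - 1, d, alpha) >= power:
        n -= 1
    return n


def percent_reduction(n_none: float, n_selected: float) -> Union[int, float]:
    """Percent reduction of required N relative to no selection (rounded);
    negative when selection hurts."""
    if n_none <= 0 or n_selected <= 0:
        raise ValidationError("sample sizes must be > 0")
    if math.isinf(n_none) or math.isinf(n_selected):
        return math.nan
    return int(round(100.0 * (1.0 - n_selected / n_none)))


# ---------------------------------------------------------------------------
# the full enrichment grid
# ---------------------------------------------------------------------------

def enrichment_table(scores_by_strategy: Mapping[str, Optional[Union[SVRScoreTable, pd.Series]]],
                     cognition: pd.DataFrame, cohort: pd.DataFrame,
                     windows: Sequence[int] = (1, 2, 3, 4),
                     fractions: Sequence[float] = (0.10, 0.20, 0.30, 0.40),
                     measures: Sequence[str] = MEASURES,
                     alpha: float = 0.05, power: float = 0.8,
                     stratum: str = "pos",
                     fit_mixed: bool = True) -> pd.DataFrame:
    """Required N per arm by selection strategy x window x intervention
    fraction, with percent reduction versus no selection.

    ``scores_by_strategy`` maps a strategy label to its score table (or
    None for the mandatory "none" strategy, which uses every subject of the
    amyloid stratum).  Score medians are computed within the stratum.
    Mixed-model time effects are refit per (strategy, window, measure)
    unless ``fit_mixed`` is False (sample sizes derive from subject-level
    slopes either way).
    """
    meta = cohort.set_index("id")
    stratum_ids = meta.index[(meta["group"] == "MCI")
                             & (meta["abeta_status"] == stratum)]
    covs = meta.loc[stratum_ids, ["age", "sex", "education"]]
    slopes = fit_subject_slopes(cognition, windows, measures)

    strategies = dict(scores_by_strategy)
    strategies.setdefault("none", None)
    selections: dict[str, set] = {}
    for label, sc in strategies.items():
        if sc is None:
            selections[label] = set(stratum_ids)
        else:
            s = (sc.scores if isinstance(sc, SVRScoreTable) else sc)
            selections[label] = select_at_risk(s.reindex(stratum_ids).dropna())

    rows = []
    for label, selected in selections.items():
        if label != "none" and not selected:
            for measure in measures:
                for k in windows:
                    for f in fractions:
                        rows.append({"strategy": label, "outcome": measure,
                                     "window": k, "fraction": f,
                                     "available": False})
            continue
        for measure in measures:
            for k in windows:
                sl = slopes.get(measure, k)
                sl = sl[sl.index.isin(selected)]
                if len(sl) < 2:
                    logger.info("no complete follow-up for %s/%s/y%s", label, measure, k)
                    continue
                mean_change = float(sl.mean())
                sd_change = float(sl.std(ddof=1))
                mm = None
                if fit_mixed:
                    sub = cognition[cognition["id"].isin(sl.index)
                                    & (cognition["years"] <= k)]
                    mm = fit_time_effect(sub, covs, measure)
                    mm.selection, mm.window = label, k
                for f in fractions:
                    n_req = required_n_per_arm(mean_change, sd_change, f,
                                               alpha, power)
                    rows.append({
                        "strategy": label, "outcome": measure, "window": k,
                        "fraction": f, "available": True,
                        "n_selected": len(sl),
                        "mean_change": mean_change, "sd_change": sd_change,
                        "beta_time": mm.beta_time if mm else np.nan,
                        "t_time": mm.t if mm else np.nan,
                        "p_time": mm.p if mm else np.nan,
                        "n_required_per_arm": n_req,
                    })
    grid = pd.DataFrame(rows)
    # percent reduction vs the matching no-selection cell
    none_n = grid[grid["strategy"] == "none"].set_index(
        ["outcome", "window", "fraction"])["n_required_per_arm"]

    def _reduction(row):
        if not row.get("available", False) or row["strategy"] == "none":
            return np.nan
        key = (row["outcome"], row["window"], row["fraction"])
        if key not in none_n.index:
            return np.nan
        return percent_reduction(none_n.loc[key], row["n_required_per_arm"])

    grid["pct_reduction"] = grid.apply(_reduction, axis=1)
    return grid
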
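"""Synthetic ADAD-like and sporadic-MCI-like cohorts.

The real training data (autosomal-dominant Alzheimer's disease mutation
carriers with an estimated-years-to-onset, EYO, timeline) and validation
data (amnestic MCI with longitudinal cognition) are controlled-access, so
this module generates cohorts with the statistical structure the analysis
assumes:

* each biomarker feature follows a logistic (sigmoid) trajectory along a
  disease-time axis — EYO for mutation carriers, a latent burden expressed
  on the same axis for sporadic subjects — the simplest monotone saturating
  form consistent with the amyloid-cascade literature;
* healthy reference subjects sit at the pre-disease asymptote of every
  trajectory, with the same subject-offset and measurement noise;
* the two cohorts measure the same biology through different instruments:
  a per-modality affine offset/scale (PiB- vs AV45-like amyloid tracers,
  different CSF immunoassays) is applied to the sporadic cohort's raw
  values, which is exactly what reference-group harmonization must undo;
* amyloid positivity in the sporadic cohort is defined by thresholding the
  raw-scale global amyloid composite at an AV45-like SUVR cutoff (1.11),
  with burden sampling calibrated by rejection so the requested stratum
  sizes come out exactly;
* each MCI subject's cognition declines linearly with a true annual slope
  tied to latent burden in the amyloid-positive stratum and unlinked in the
  amyloid-negative stratum, observed at annual visits with measurement
  noise.

Ground truth (burden, true slopes) is stored on the returned bundle for
testing; the training and scoring interfaces accept only the cohort table
and feature matrix, so the truth cannot leak into model fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .datatypes import MODALITIES, CohortBundle, FeatureMatrix
from .errors import ConfigurationError, GenerationError, ValidationError

__all__ = [
    "TrajectoryParams",
    "CohortSpec",
    "default_trajectories",
    "generate_adad_cohort",
    "generate_sporadic_cohort",
    "generate_linear_benchmark",
]


# ---------------------------------------------------------------------------
# trajectory model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryParams:
    """Sigmoid trajectory of one biomarker feature along disease time.

    The feature's expected raw value at disease time ``t`` (EYO years for
    carriers, latent-burden years for sporadic subjects) is::

        healthy + direction * asymptote * expit(steepness * (t - midpoint))

    so ``healthy`` is the pre-disease level, ``asymptote`` the total change
    magnitude (raw units), ``midpoint`` the disease time of half-maximal
    change, and ``direction`` +1 for accumulation (amyloid, tau) or -1 for
    loss (glucose metabolism, cortical thickness, CSF Abeta42).  Individual
    values add a subject-level random offset (SD ``offset_sd``) and
    measurement noise (SD ``noise_sd``).
    """

    name: str
    modality: str
    healthy: float
    asymptote: float
    midpoint: float
    steepness: float
    direction: int
    noise_sd: float
    offset_sd: float

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r} for {self.name}")
        values = (self.healthy, self.asymptote, self.midpoint, self.steepness,
                  self.noise_sd, self.offset_sd)
        if not all(math.isfinite(v) for v in values):
            raise ValidationError(f"non-finite trajectory parameter for {self.name}")
        if self.steepness <= 0:
            raise ValidationError(f"steepness must be > 0 for {self.name}")
        if self.noise_sd < 0 or self.offset_sd < 0:
            raise ValidationError(f"noise SDs must be >= 0 for {self.name}")
        if self.direction not in (-1, 1):
            raise ValidationError(f"direction must be +1 or -1 for {self.name}")

    @property
    def feature_name(self) -> str:
        return f"{self.modality}__{self.name}"

    def mean_at(self, t: np.ndarray) -> np.ndarray:
        """Expected raw value at disease time ``t`` (no noise, no offset)."""
        t = np.asarray(t, dtype=float)
        return self.healthy + self.direction * self.asymptote * expit(
            self.steepness * (t - self.midpoint)
        )


_ROI_BASENAMES = [
    "precuneus", "posterior_cingulate", "inferior_parietal", "superior_parietal",
    "lateral_occipital", "middle_temporal", "inferior_temporal", "fusiform",
    "entorhinal", "parahippocampal", "hippocampus", "superior_frontal",
    "rostral_middle_frontal", "caudal_middle_frontal", "supramarginal",
]


def default_trajectories(seed: int = 161803) -> list[TrajectoryParams]:
    """The default feature registry: 30 ROIs per imaging modality + 3 CSF analytes.

    Per-ROI parameters are jittered around modality-level anchors with a
    fixed registry seed, so the registry itself is a constant of the
    package, independent of the cohort seed.  Anchors encode the canonical
    ordering of biomarker change: amyloid-PET turns early (midpoints around
    -15 EYO years), CSF p-tau/t-tau intermediate, FDG-PET hypometabolism and
    gray-matter loss late (midpoints around -5 to 0).
    """
    rng = np.random.default_rng(seed)
    rois = [f"{hemi}_{base}" for base in _ROI_BASENAMES for hemi in ("lh", "rh")]
    out: list[TrajectoryParams] = []
    for roi in rois:  # amyloid-PET SUVR, accumulation, early
        out.append(TrajectoryParams(
            name=roi, modality="A",
            healthy=rng.normal(1.02, 0.04), asymptote=rng.uniform(0.5, 0.9),
            midpoint=rng.uniform(-18.0, -12.0), steepness=rng.uniform(0.15, 0.25),
            direction=+1, noise_sd=0.08, offset_sd=0.06,
        ))
    for roi in rois:  # FDG-PET SUVR, hypometabolism, late
        out.append(TrajectoryParams(
            name=roi, modality="F",
            healthy=rng.normal(1.30, 0.05), asymptote=rng.uniform(0.15, 0.30),
            midpoint=rng.uniform(-8.0, -2.0), steepness=rng.uniform(0.20, 0.35),
            direction=-1, noise_sd=0.07, offset_sd=0.05,
        ))
    for roi in rois:  # gray-matter thickness/volume, atrophy, late
        out.append(TrajectoryParams(
            name=roi, modality="G",
            healthy=rng.normal(2.50, 0.15), asymptote=rng.uniform(0.25, 0.45),
            midpoint=rng.uniform(-8.0, 0.0), steepness=rng.uniform(0.20, 0.35),
            direction=-1, noise_sd=0.12, offset_sd=0.08,
        ))
    out.append(TrajectoryParams(
        name="abeta42", modality="C", healthy=210.0, asymptote=90.0,
        midpoint=-18.0, steepness=0.20, direction=-1, noise_sd=25.0, offset_sd=20.0,
    ))
    out.append(TrajectoryParams(
        name="ptau181", modality="C", healthy=25.0, asymptote=35.0,
        midpoint=-12.0, steepness=0.22, direction=+1, noise_sd=6.0, offset_sd=5.0,
    ))
    out.append(TrajectoryParams(
        name="ttau", modality="C", healthy=60.0, asymptote=45.0,
        midpoint=-8.0, steepness=0.22, direction=+1, noise_sd=12.0, offset_sd=10.0,
    ))
    return out


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort.

    Use :meth:`adad_default` / :meth:`sporadic_default` for specs whose
    counts and covariate distributions match the published baseline tables
    of the DIAN-like and ADNI-like samples; individual fields can then be
    overridden with :func:`dataclasses.replace`.
    """

    # counts
    n_carriers: int = 121
    n_mci_pos: int = 216
    n_mci_neg: int = 175
    n_reference: int = 54
    # training-cohort disease clock
    eyo_mean: float = -7.10
    eyo_sd: float = 11.23
    eyo_bounds: tuple[float, float] = (-30.0, 15.0)
    # covariates (per-group tuples: carriers/MCI+, then reference or MCI-)
    age_mean: float = 38.66
    age_sd: float = 9.98
    female_prop: float = 0.595
    edu_mean: float = 14.27
    edu_sd: float = 3.02
    # instrument differences vs the training cohort (per-modality affine)
    cohort_offset: dict = field(default_factory=lambda: {m: 0.0 for m in MODALITIES})
    cohort_scale: dict = field(default_factory=lambda: {m: 1.0 for m in MODALITIES})
    # sporadic-cohort latent burden and amyloid stratification
    amyloid_cutoff: float = 1.11
    burden_mean: float = -22.0
    burden_sd: float = 12.0
    # cognition model (memory composite 'mem', global cognition 'adas')
    slope_link: float = 0.006        # mem units/yr lost per burden-year past threshold
    slope_link_adas: float = 0.06    # adas points/yr gained per burden-year
    slope_link_neg: float = 0.0      # link in the amyloid-negative stratum
    slope_noise_sd: float = 0.04
    adas_slope_noise_sd: float = 0.40
    cog_noise_sd: float = 0.15       # per-visit measurement noise, mem
    adas_noise_sd: float = 1.80
    baseline_link_mem: float = 0.055
    baseline_link_adas: float = 0.55
    followup_years: tuple[int, ...] = (0, 1, 2, 3, 4)
    dropout_rate: float = 0.0        # per-visit probability of dropping out (monotone)
    modalities: tuple[str, ...] = MODALITIES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_carriers", "n_mci_pos", "n_mci_neg", "n_reference"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not set(self.followup_years) <= {0, 1, 2, 3, 4}:
            raise ValidationError("followup_years must be a subset of {0,1,2,3,4}")
        if 0 not in self.followup_years or len(self.followup_years) < 2:
            raise ValidationError("followup must include baseline and >=1 later visit")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ConfigurationError(f"unknown modalities {sorted(unknown)}")

    @classmethod
    def adad_default(cls, seed: int = 0, **overrides) -> "CohortSpec":
        return cls(seed=seed, **overrides)

    @classmethod
    def sporadic_default(cls, seed: int = 0, **overrides) -> "CohortSpec":
        base = dict(
            n_reference=49,
            age_mean=72.74, age_sd=6.69, female_prop=0.458,
            edu_mean=16.00, edu_sd=2.79,
            # AV45-like amyloid scaling vs PiB; Elecsys-like CSF vs xMap
            cohort_offset={"A": 0.12, "F": 0.05, "G": -0.05, "C": 0.0},
            cohort_scale={"A": 0.85, "F": 0.95, "G": 1.00, "C": 1.40},
        )
        base.update(overrides)
        return cls(seed=seed, **base)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _check_modalities(spec: CohortSpec, trajectories: Sequence[TrajectoryParams]) -> list[TrajectoryParams]:
    traj = [t for t in trajectories if t.modality in spec.modalities]
    present = {t.modality for t in traj}
    missing = set(spec.modalities) - present
    if missing:
        raise ConfigurationError(
            f"no trajectory features for requested modalities {sorted(missing)}"
        )
    names = [t.feature_name for t in traj]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate feature names in trajectory list")
    return traj


def _raw_features(rng: np.random.Generator, t: np.ndarray,
                  traj: Sequence[TrajectoryParams], at_healthy: bool = False) -> np.ndarray:
    """Raw-scale feature matrix for disease times ``t`` (or at healthy levels)."""
    n = len(t)
    cols = []
    for tp in traj:
        mean = np.full(n, tp.healthy) if at_healthy else tp.mean_at(t)
        offset = rng.normal(0.0, tp.offset_sd, size=n) if tp.offset_sd > 0 else 0.0
        noise = rng.normal(0.0, tp.noise_sd, size=n) if tp.noise_sd > 0 else 0.0
        cols.append(mean + offset + noise)
    return np.column_stack(cols)


def _apply_instrument(X: np.ndarray, traj: Sequence[TrajectoryParams],
                      spec: CohortSpec) -> np.ndarray:
    scale = np.array([spec.cohort_scale.get(t.modality, 1.0) for t in traj])
    offset = np.array([spec.cohort_offset.get(t.modality, 0.0) for t in traj])
    return X * scale + offset


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Sample a truncated normal whose *truncated* mean/SD equal the targets.

    Truncation shrinks the variance of the parent normal, so the parent
    (mu, sigma) is solved numerically such that the distribution actually
    sampled has the requested moments.
    """
    from scipy.optimize import fsolve

    def moments(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol, _, ok, _ = fsolve(moments, [mean, math.log(sd)], full_output=True)
    mu, sigma = sol[0], math.exp(sol[1])
    if ok != 1 or not (math.isfinite(mu) and math.isfinite(sigma)):
        raise GenerationError(
            f"cannot match mean={mean}, sd={sd} inside bounds ({lo}, {hi})")
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _covariates(rng, n, age_mean, age_sd, female_prop, edu_mean, edu_sd):
    age = rng.normal(age_mean, age_sd, size=n)
    sex = (rng.random(n) < female_prop).astype(int)  # 1 = female
    edu = np.clip(rng.normal(edu_mean, edu_sd, size=n), 6.0, 24.0)
    return age, sex, edu


# ---------------------------------------------------------------------------
# ADAD-like training cohort
# ---------------------------------------------------------------------------

def generate_adad_cohort(spec: CohortSpec,
                         trajectories: Optional[Sequence[TrajectoryParams]] = None
                         ) -> CohortBundle:
    """Generate a mutation-carrier training cohort with an EYO disease clock.

    Carriers draw EYO from a truncated normal targeting the spec's
    mean/SD; every feature is its sigmoid trajectory evaluated at the
    carrier's EYO plus subject offset and noise.  Non-carrier reference
    subjects sit at the healthy asymptote of every trajectory.
    """
    traj = _check_modalities(spec, trajectories if trajectories is not None
                             else default_trajectories())
    rng = np.random.default_rng(spec.seed)

    n_mc, n_nc = spec.n_carriers, spec.n_reference
    eyo_mc = _truncated_normal(rng, spec.eyo_mean, spec.eyo_sd,
                               *spec.eyo_bounds, size=n_mc)
    eyo_nc = _truncated_normal(rng, -9.35, 10.94, *spec.eyo_bounds, size=n_nc)

    X_mc = _apply_instrument(_raw_features(rng, eyo_mc, traj), traj, spec)
    X_nc = _apply_instrument(
        _raw_features(rng, eyo_nc, traj, at_healthy=True), traj, spec)

    age_mc, sex_mc, edu_mc = _covariates(
        rng, n_mc, spec.age_mean, spec.age_sd, spec.female_prop,
        spec.edu_mean, spec.edu_sd)
    age_nc, sex_nc, edu_nc = _covariates(rng, n_nc, 38.87, 10.48, 0.648, 15.50, 2.23)

    ids = [f"DIAN_{i:04d}" for i in range(1, n_mc + n_nc + 1)]
    cohort = pd.DataFrame({
        "id": ids,
        "cohort": "adad",
        "group": ["MC"] * n_mc + ["NC"] * n_nc,
        "age": np.concatenate([age_mc, age_nc]),
        "sex": np.concatenate([sex_mc, sex_nc]),
        "education": np.concatenate([edu_mc, edu_nc]),
        "eyo": np.concatenate([eyo_mc, eyo_nc]),
        "abeta_status": pd.NA,
    })
    values = pd.DataFrame(np.vstack([X_mc, X_nc]), index=ids,
                          columns=[t.feature_name for t in traj])
    truth = pd.DataFrame({"id": ids,
                          "burden": np.concatenate([eyo_mc, eyo_nc]),
                          "is_carrier": [True] * n_mc + [False] * n_nc})
    return CohortBundle(
        cohort=cohort,
        features=FeatureMatrix(values, cohort="adad", harmonized=False),
        truth=truth,
        meta={"kind": "adad", "seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# sporadic-MCI-like validation cohort
# ---------------------------------------------------------------------------

def burden_at_cutoff(spec: CohortSpec, traj: Sequence[TrajectoryParams]) -> float:
    """Disease time where the noiseless instrument-scale global amyloid
    composite crosses the positivity cutoff."""
    a_traj = [t for t in traj if t.modality == "A"]
    if not a_traj:
        raise ConfigurationError("no amyloid (A) features: cannot stratify by cutoff")
    scale = spec.cohort_scale.get("A", 1.0)
    offset = spec.cohort_offset.get("A", 0.0)

    def composite(b):
        return float(np.mean([t.mean_at(np.array([b]))[0] for t in a_traj])) * scale + offset

    lo, hi = -80.0, 50.0
    if not composite(lo) < spec.amyloid_cutoff < composite(hi):
        raise GenerationError(
            f"amyloid cutoff {spec.amyloid_cutoff} outside the achievable composite "
            f"range [{composite(lo):.3f}, {composite(hi):.3f}]: the "
            f"{'positive' if composite(hi) <= spec.amyloid_cutoff else 'negative'} "
            "stratum would be empty"
        )
    return brentq(lambda b: composite(b) - spec.amyloid_cutoff, lo, hi, xtol=1e-8)


def generate_sporadic_cohort(spec: Optional[CohortSpec] = None,
                             trajectories: Optional[Sequence[TrajectoryParams]] = None
                             ) -> CohortBundle:
    """Generate an MCI-like validation cohort with longitudinal cognition.

    Subjects carry a latent disease burden on the same axis as the training
    cohort's EYO; features follow the shared trajectory family evaluated at
    the burden and are then put through the cohort's instrument transform
    (per-modality offset/scale).  Amyloid status comes from thresholding the
    realized raw-scale global amyloid composite at the cutoff; burden
    candidates are rejection-sampled until both strata reach the requested
    sizes exactly.  Cognition is linear in time per subject with a true
    slope tied to burden in the amyloid-positive stratum only.
    """
    if spec is None:
        spec = CohortSpec.sporadic_default()
    traj = _check_modalities(spec, trajectories if trajectories is not None
                             else default_trajectories())
    rng = np.random.default_rng(spec.seed)
    a_cols = np.array([t.modality == "A" for t in traj])
    b_star = burden_at_cutoff(spec, traj)

    # rejection-sample burden until both strata are exactly filled
    need_pos, need_neg = spec.n_mci_pos, spec.n_mci_neg
    pos_b, pos_X, neg_b, neg_X = [], [], [], []
    batch = max(2 * (need_pos + need_neg), 256)
    for _ in range(1000):
        if len(pos_b) >= need_pos and len(neg_b) >= need_neg:
            break
        b = rng.normal(spec.burden_mean, spec.burden_sd, size=batch)
        X = _apply_instrument(_raw_features(rng, b, traj), traj, spec)
        composite = X[:, a_cols].mean(axis=1)
        is_pos = composite > spec.amyloid_cutoff
        pos_b.extend(b[is_pos]); pos_X.extend(X[is_pos])
        neg_b.extend(b[~is_pos]); neg_X.extend(X[~is_pos])
    for stratum, got, need in (("amyloid-positive", len(pos_b), need_pos),
                               ("amyloid-negative", len(neg_b), need_neg)):
        if got < need:
            raise GenerationError(
                f"could not fill the {stratum} stratum ({got}/{need}): "
                "burden distribution and cutoff are incompatible")
    burden = np.concatenate([np.asarray(pos_b[:need_pos]), np.asarray(neg_b[:need_neg])])
    X_mci = np.vstack([np.asarray(pos_X[:need_pos]), np.asarray(neg_X[:need_neg])])
    status = np.array(["pos"] * need_pos + ["neg"] * need_neg)
    n_mci = need_pos + need_neg

    # healthy reference subgroup (cognitively normal, amyloid-negative)
    n_cn = spec.n_reference
    X_cn = _apply_instrument(
        _raw_features(rng, np.zeros(n_cn), traj, at_healthy=True), traj, spec)

    # covariates per stratum
    age_p, sex_p, edu_p = _covariates(rng, need_pos, spec.age_mean, spec.age_sd,
                                      spec.female_prop, spec.edu_mean, spec.edu_sd)
    age_n, sex_n, edu_n = _covariates(rng, need_neg, 70.16, 7.76, 0.463, 16.47, 2.47)
    age_c, sex_c, edu_c = _covariates(rng, n_cn, 65.76, 2.69, 0.531, 17.14, 2.27)

    ids_mci = [f"ADNI_{i:04d}" for i in range(1, n_mci + 1)]
    ids_cn = [f"ADNI_{i:04d}" for i in range(n_mci + 1, n_mci + n_cn + 1)]
    cohort = pd.DataFrame({
        "id": ids_mci + ids_cn,
        "cohort": "sporadic",
        "group": ["MCI"] * n_mci + ["CN"] * n_cn,
        "age": np.concatenate([age_p, age_n, age_c]),
        "sex": np.concatenate([sex_p, sex_n, sex_c]),
        "education": np.concatenate([edu_p, edu_n, edu_c]),
        "eyo": np.nan,
        "abeta_status": list(status) + ["neg"] * n_cn,
    })
    values = pd.DataFrame(np.vstack([X_mci, X_cn]), index=ids_mci + ids_cn,
                          columns=[t.feature_name for t in traj])

    # --- cognition: linear subject trajectories over annual visits --------
    u = burden - b_star                      # burden-years past the amyloid threshold
    pos = status == "pos"
    link = np.where(pos, spec.slope_link, spec.slope_link_neg)
    link_adas = np.where(pos, spec.slope_link_adas, spec.slope_link_neg * 10.0)
    mem_slope = -link * u + rng.normal(0.0, spec.slope_noise_sd, n_mci)
    adas_slope = link_adas * u + rng.normal(0.0, spec.adas_slope_noise_sd, n_mci)
    mem0 = 0.62 - spec.baseline_link_mem * np.maximum(u, 0.0) \
        + rng.normal(0.0, 0.45, n_mci)
    adas0 = 12.2 + spec.baseline_link_adas * np.maximum(u, 0.0) \
        + rng.normal(0.0, 4.8, n_mci)

    years = np.array(sorted(spec.followup_years), dtype=float)
    rows = []
    for i, sid in enumerate(ids_mci):
        visit_years = years
        if spec.dropout_rate > 0:
            keep = rng.random(len(years)) >= spec.dropout_rate
            keep[0] = True
            first_gone = np.argmin(keep) if not keep.all() else len(years)
            visit_years = years[:max(first_gone, 1)] if not keep.all() else years
        for t in visit_years:
            rows.append((
                sid, float(t),
                mem0[i] + mem_slope[i] * t + rng.normal(0.0, spec.cog_noise_sd),
                adas0[i] + adas_slope[i] * t + rng.normal(0.0, spec.adas_noise_sd),
            ))
    cognition = pd.DataFrame(rows, columns=["id", "years", "mem", "adas"])

    truth = pd.DataFrame({
        "id": ids_mci, "burden": burden, "excess_burden": u,
        "mem_slope_true": mem_slope, "adas_slope_true": adas_slope,
        "mem_baseline_true": mem0, "adas_baseline_true": adas0,
    })
    return CohortBundle(
        cohort=cohort,
        features=FeatureMatrix(values, cohort="sporadic", harmonized=False),
        cognition=cognition,
        truth=truth,
        meta={"kind": "sporadic", "seed": spec.seed, "burden_at_cutoff": b_star},
    )


# ---------------------------------------------------------------------------
# linear benchmark for cross-validation calibration
# ---------------------------------------------------------------------------

def generate_linear_benchmark(n_subjects: int = 150, n_features: int = 90,
                              signal_r2: float = 0.55, n_informative: int = 30,
                              loading: float = 0.5, seed: int = 0) -> CohortBundle:
    """A carrier-only cohort whose EYO is linearly predictable from the
    features with a known population R-squared.

    Mirrors the correlation structure of multimodal biomarker panels: a
    single latent disease factor drives both the target and the
    ``n_informative`` informative features (each a sign-flipped noisy copy
    with squared loading ``loading``); the remaining features are pure
    noise.  The latent-factor variance share is chosen so the best linear
    predictor of the target from the features explains exactly
    ``signal_r2`` of its variance, giving the cross-validation engine a
    known recoverable ceiling.  Features arrive standard-normal and are
    flagged harmonized.
    """
    if not 0.0 < signal_r2 < 1.0:
        raise ValidationError("signal_r2 must be in (0, 1)")
    if n_informative > n_features:
        raise ValidationError("n_informative cannot exceed n_features")
    if not 0.0 < loading < 1.0:
        raise ValidationError("loading must be in (0, 1)")
    # best linear predictor from k noisy factor copies recovers a fraction
    # k*lam / (k*lam + 1 - lam) of the factor variance; invert that so the
    # attainable R^2 equals signal_r2
    recover = n_informative * loading / (n_informative * loading + 1.0 - loading)
    latent_r2 = signal_r2 / recover
    if latent_r2 >= 1.0:
        raise ValidationError(
            f"signal_r2={signal_r2} not attainable with {n_informative} "
            f"features at loading {loading}")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_subjects)
    X = rng.standard_normal((n_subjects, n_features))
    idx = rng.choice(n_features, size=n_informative, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_informative)
    X[:, idx] = (math.sqrt(loading) * np.outer(g, signs)
                 + math.sqrt(1.0 - loading) * X[:, idx])
    y = (math.sqrt(latent_r2) * g
         + math.sqrt(1.0 - latent_r2) * rng.standard_normal(n_subjects))

    per = max(1, n_features // len(MODALITIES))
    names = [f"{MODALITIES[min(j // per, 3)]}__sim{j:03d}" for j in range(n_features)]
    ids = [f"SIM_{i:04d}" for i in range(1, n_subjects + 1)]
    cohort = pd.DataFrame({
        "id": ids, "cohort": "benchmark", "group": "MC",
        "age": 40.0, "sex": 0, "education": 14.0, "eyo": y, "abeta_status": pd.NA,
    })
    values = pd.DataFrame(X, index=ids, columns=names)
    informative = np.zeros(n_features, dtype=bool)
    informative[idx] = True
    truth = pd.DataFrame({"id": ids, "latent_factor": g})
    return CohortBundle(
        cohort=cohort,
        features=FeatureMatrix(values, cohort="benchmark", harmonized=True,
                               scaler_ref="synthetic-standard-normal"),
        truth=truth,
        meta={"kind": "linear-benchmark", "seed": seed, "signal_r2": signal_r2,
              "informative_features": [names[j] for j in np.where(informative)[0]]},
    )
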
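"""Repeated nested double cross-validation for SVR-based EYO prediction.

The training cohort is repeatedly permuted and split into outer (CV2)
folds; within each outer training pool, inner (CV1) folds drive univariate
Spearman-filter feature selection and SVR hyperparameter tuning.  For each
inner fold the grid point with minimum held-out mean squared error is
retained as that fold's optimal model; the bank of all optimal CV1 models
forms the transferable ensemble.  Unbiased performance is read exclusively
on outer test folds, each predicted by the unweighted mean of its own inner
optimal models.

With the default bookkeeping (10 outer permutations x 10 outer folds x 10
inner permutations x 10 inner folds) the ensemble holds 10,000 models; all
four counts are configurable and are typically scaled down for tests.

Every fitted model records the exact subject ids it touched, and a leakage
audit asserting fold-disjointness runs automatically after every nested
run.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR, LinearSVR

from .datatypes import MODALITIES, FeatureMatrix
from .errors import LeakageError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig", "CVAssignment", "SVRModelSpec", "EnsembleModel",
    "CVPerformance", "build_cv_assignment", "select_features",
    "tune_and_select", "run_nested_cv", "modality_sweep", "audit_ensemble",
    "pooled_performance",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_c_grid() -> tuple[float, ...]:
    return tuple(float(2.0 ** k) for k in range(-6, 5))


@dataclass(frozen=True)
class CVConfig:
    """Knobs of the nested CV procedure.

    The kernel and hyperparameter grid are declared defaults, not inferred:
    a linear kernel keeps model weights interpretable for the
    feature-selection-probability analysis and is the standard choice at
    n ~ 120 subjects with ~100 features.
    """

    k_outer: int = 10
    k_inner: int = 10
    n_outer_perms: int = 10
    n_inner_perms: int = 10
    feature_fraction: float = 0.35
    kernel: str = "linear"
    c_grid: tuple[float, ...] = field(default_factory=_default_c_grid)
    epsilon_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    solver_tol: float = 1e-3
    solver_max_iter: int = 2000
    train_group: str = "MC"
    target: str = "eyo"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValidationError("feature_fraction must be in (0, 1]")
        if min(self.k_outer, self.k_inner, self.n_outer_perms,
               self.n_inner_perms) < 1:
            raise ValidationError("fold/permutation counts must be >= 1")
        if not self.c_grid or not self.epsilon_grid:
            raise ValidationError("hyperparameter grids must be non-empty")

    @property
    def n_models(self) -> int:
        return (self.n_outer_perms * self.k_outer
                * self.n_inner_perms * self.k_inner)


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

@dataclass
class CVAssignment:
    """Deterministic fold bookkeeping for the full repeated nested design.

    ``outer[p2]`` is a list of ``k_outer`` id-arrays partitioning all
    subjects; ``inner[(p2, k2, p1)]`` is a list of ``k_inner`` id-arrays
    partitioning exactly the subjects outside outer fold ``k2``.
    """

    subject_ids: tuple
    k_outer: int
    k_inner: int
    n_outer_perms: int
    n_inner_perms: int
    seed: int
    outer: dict = field(default_factory=dict)
    inner: dict = field(default_factory=dict)

    @property
    def n_model_slots(self) -> int:
        return (self.n_outer_perms * self.k_outer
                * self.n_inner_perms * self.k_inner)

    def validate(self) -> None:
        """Re-check the partition invariants (raises on violation)."""
        all_ids = set(self.subject_ids)
        for p2, folds in self.outer.items():
            flat = list(itertools.chain.from_iterable(folds))
            if len(flat) != len(all_ids) or set(flat) != all_ids:
                raise ValidationError(f"outer folds of permutation {p2} do not partition subjects")
            sizes = [len(f) for f in folds]
            if max(sizes) - min(sizes) > 1:
                raise ValidationError(f"outer fold sizes differ by more than 1 in permutation {p2}")
        for (p2, k2, p1), folds in self.inner.items():
            pool = all_ids - set(self.outer[p2][k2])
            flat = list(itertools.chain.from_iterable(folds))
            if len(flat) != len(pool) or set(flat) != pool:
                raise ValidationError(
                    f"inner folds at (perm {p2}, fold {k2}, inner perm {p1}) "
                    "do not partition the training pool")
            sizes = [len(f) for f in folds]
            if max(sizes) - min(sizes) > 1:
                raise ValidationError(
                    f"inner fold sizes differ by more than 1 at ({p2},{k2},{p1})")


def _partition(rng: np.random.Generator, ids: np.ndarray, k: int) -> list[np.ndarray]:
    perm = rng.permutation(ids)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def build_cv_assignment(subject_ids: Iterable, k_outer: int = 10,
                        k_inner: int = 10, n_outer_perms: int = 10,
                        n_inner_perms: int = 10, seed: int = 0) -> CVAssignment:
    """Build the full deterministic fold assignment.

    Random streams are derived per (permutation, fold) by counter from the
    master seed, so re-running any subset of the design reproduces
    identical folds.
    """
    ids = np.asarray(list(subject_ids))
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate subject ids")
    n = len(ids)
    if n < k_outer:
        raise ValidationError(f"cannot split {n} subjects into {k_outer} outer folds")
    max_outer_fold = math.ceil(n / k_outer)
    if n - max_outer_fold < k_inner:
        raise ValidationError(
            f"training pool of {n - max_outer_fold} cannot hold {k_inner} inner folds")

    asn = CVAssignment(subject_ids=tuple(ids), k_outer=k_outer, k_inner=k_inner,
                       n_outer_perms=n_outer_perms, n_inner_perms=n_inner_perms,
                       seed=seed)
    for p2 in range(n_outer_perms):
        rng = np.random.default_rng([seed, 101, p2])
        asn.outer[p2] = _partition(rng, ids, k_outer)
        for k2 in range(k_outer):
            pool = np.array(sorted(set(ids) - set(asn.outer[p2][k2])))
            for p1 in range(n_inner_perms):
                rng_in = np.random.default_rng([seed, 202, p2, k2, p1])
                asn.inner[(p2, k2, p1)] = _partition(rng_in, pool, k_inner)
    asn.validate()
    return asn


# ---------------------------------------------------------------------------
# Spearman filter feature selection
# ---------------------------------------------------------------------------

def spearman_abs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Spearman rho| of each column of X with y; columns with undefined
    rho (constant feature) get 0."""
    n = len(y)
    rx = rankdata(X, axis=0)
    ry = rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=0) * (ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rx * ry[:, None]).sum(axis=0) / denom, 0.0)
    return np.abs(rho)


def select_features(X: np.ndarray, y: np.ndarray, names: Sequence[str],
                    fraction: float = 0.35) -> np.ndarray:
    """Boolean mask retaining the ceil(fraction * p) features with largest
    |Spearman correlation| with the target.

    Ties in |rho| break lexicographically by feature name; a constant
    feature (undefined rho) counts as |rho| = 0 and additionally sorts
    after any feature whose rho is defined.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must be in (0, 1]")
    if len(y) < 2:
        raise ValidationError("need >= 2 subjects for feature selection")
    p = X.shape[1]
    abs_rho = spearman_abs(X, y)
    constant = X.std(axis=0) == 0
    if constant.any():
        logger.warning("constant feature(s) treated as |rho|=0: %s",
                       [names[j] for j in np.where(constant)[0][:5]])
    k = math.ceil(fraction * p)
    order = sorted(range(p), key=lambda j: (-abs_rho[j], bool(constant[j]), names[j]))
    mask = np.zeros(p, dtype=bool)
    mask[order[:k]] = True
    return mask


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class SVRModelSpec:
    """One optimal CV1 model: selected features + fitted SVR + bookkeeping."""

    coords: tuple  # (outer perm, outer fold, inner perm, inner fold)
    mask: np.ndarray  # boolean over the feature registry
    weights: Optional[np.ndarray]  # linear kernel only
    intercept: float
    kernel: str
    C: float
    epsilon: float
    cv1_mse: float
    train_ids: tuple
    inner_test_ids: tuple
    estimator: object = None  # retained for non-linear kernels

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = X[:, self.mask]
        if self.kernel == "linear":
            return Xs @ self.weights + self.intercept
        return self.estimator.predict(Xs)


@dataclass
class EnsembleModel:
    """The bank of optimal CV1 models plus the registry they index into."""

    models: list
    feature_registry: list
    modalities: tuple
    training_cohort: str
    scaler_ref: Optional[str]
    config: CVConfig
    assignment: Optional[CVAssignment] = None

    def __post_init__(self) -> None:
        expected = self.config.n_models
        if len(self.models) != expected:
            raise ValidationError(
                f"ensemble holds {len(self.models)} models, expected {expected}")

    def __len__(self) -> int:
        return len(self.models)

    def selection_profile(self) -> pd.Series:
        """Feature -> fraction of optimal CV1 models retaining it."""
        counts = np.zeros(len(self.feature_registry))
        for m in self.models:
            counts += m.mask
        return pd.Series(counts / len(self.models), index=self.feature_registry,
                         name="selection_probability")

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n_models, n_subjects) prediction matrix."""
        return np.vstack([m.predict(X) for m in self.models])

    # -- persistence (linear kernel only; flat text formats) ---------------
    def save(self, outdir) -> None:
        if self.config.kernel != "linear":
            raise NotImplementedError("persistence is implemented for linear kernels")
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "feature_registry": self.feature_registry,
            "modalities": list(self.modalities),
            "training_cohort": self.training_cohort,
            "scaler_ref": self.scaler_ref,
            "config": {
                "k_outer": self.config.k_outer, "k_inner": self.config.k_inner,
                "n_outer_perms": self.config.n_outer_perms,
                "n_inner_perms": self.config.n_inner_perms,
                "feature_fraction": self.config.feature_fraction,
                "kernel": self.config.kernel,
                "c_grid": list(self.config.c_grid),
                "epsilon_grid": list(self.config.epsilon_grid),
                "train_group": self.config.train_group,
                "target": self.config.target,
                "seed": self.config.seed,
            },
            "n_models": len(self.models),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        meta_rows, weight_rows = [], []
        for i, m in enumerate(self.models):
            meta_rows.append((i, *m.coords, m.C, m.epsilon, m.intercept, m.cv1_mse))
            for j, w in zip(np.where(m.mask)[0], m.weights):
                weight_rows.append((i, self.feature_registry[j], w))
        pd.DataFrame(meta_rows, columns=["model", "p2", "k2", "p1", "k1",
                                         "C", "epsilon", "intercept", "cv1_mse"]
                     ).to_csv(out / "models_meta.csv", index=False)
        pd.DataFrame(weight_rows, columns=["model", "feature", "weight"]
                     ).to_csv(out / "weights.csv", index=False)

    @classmethod
    def load(cls, indir) -> "EnsembleModel":
        src = pathlib.Path(indir)
        manifest = json.loads((src / "manifest.json").read_text())
        cfg = CVConfig(**{**manifest["config"],
                          "c_grid": tuple(manifest["config"]["c_grid"]),
                          "epsilon_grid": tuple(manifest["config"]["epsilon_grid"])})
        registry = manifest["feature_registry"]
        index = {f: j for j, f in enumerate(registry)}
        meta = pd.read_csv(src / "models_meta.csv")
        weights = pd.read_csv(src / "weights.csv")
        by_model = dict(tuple(weights.groupby("model")))
        models = []
        for row in meta.itertuples(index=False):
            wrows = by_model[row.model]
            mask = np.zeros(len(registry), dtype=bool)
            idx = np.array([index[f] for f in wrows.feature])
            mask[idx] = True
            # predict() slices X by boolean mask (ascending registry index),
            # so the weights must be re-sorted to that order
            w = wrows.weight.to_numpy()[np.argsort(idx)]
            models.append(SVRModelSpec(
                coords=(row.p2, row.k2, row.p1, row.k1), mask=mask, weights=w,
                intercept=row.intercept, kernel=cfg.kernel, C=row.C,
                epsilon=row.epsilon, cv1_mse=row.cv1_mse,
                train_ids=(), inner_test_ids=()))
        return cls(models=models, feature_registry=registry,
                   modalities=tuple(manifest["modalities"]),
                   training_cohort=manifest["training_cohort"],
                   scaler_ref=manifest["scaler_ref"], config=cfg)


@dataclass
class CVPerformance:
    """Held-out (CV2) predictions pooled over outer permutations."""

    predictions: pd.DataFrame  # columns: perm, fold, id, actual, predicted
    r: float
    p_value: float
    r2: float
    mse: float

    @property
    def n(self) -> int:
        return self.predictions["id"].nunique()


def pooled_performance(predictions: pd.DataFrame) -> CVPerformance:
    actual = predictions["actual"].to_numpy()
    pred = predictions["predicted"].to_numpy()
    r, p = pearsonr(actual, pred)
    return CVPerformance(predictions=predictions, r=float(r), p_value=float(p),
                         r2=float(r) ** 2, mse=float(np.mean((actual - pred) ** 2)))


# ---------------------------------------------------------------------------
# inner-loop tuning
# ---------------------------------------------------------------------------

def _fit_svr(X: np.ndarray, y: np.ndarray, config: CVConfig, C: float,
             epsilon: float):
    """Fit one SVR at a grid point; returns (weights, intercept, estimator).

    The linear kernel is solved with liblinear (epsilon-insensitive loss),
    which is orders of magnitude faster than the kernelized solver at large
    C.  liblinear regularizes the intercept, so the target is centered
    before fitting and the mean folded back into the returned intercept.
    Non-linear kernels fall back to the kernelized solver and return the
    fitted estimator instead of flat weights.
    """
    if config.kernel == "linear":
        y_mean = float(np.mean(y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            est = LinearSVR(C=C, epsilon=epsilon, tol=config.solver_tol,
                            max_iter=config.solver_max_iter,
                            random_state=0).fit(X, y - y_mean)
        return est.coef_.copy(), float(np.atleast_1d(est.intercept_)[0]) + y_mean, None
    est = SVR(kernel=config.kernel, C=C, epsilon=epsilon,
              tol=config.solver_tol).fit(X, y)
    return None, 0.0, est


def tune_and_select(X_pool: np.ndarray, y_pool: np.ndarray,
                    pool_ids: Sequence, inner_folds: Sequence[np.ndarray],
                    config: CVConfig, registry: Sequence[str],
                    coords_prefix: tuple = ()) -> list[SVRModelSpec]:
    """One inner CV1 cycle: per inner fold, select features and tune the SVR
    on the fold's training portion, score on the held-out inner fold, and
    keep the grid point with minimum held-out MSE (ties: smaller C, then
    smaller epsilon).

    Feature selection runs once per inner fold, before tuning, on that
    fold's training subjects only.
    """
    if np.allclose(y_pool, y_pool[0]):
        raise ValidationError("degenerate training target: all values equal")
    id_pos = {sid: i for i, sid in enumerate(pool_ids)}
    out = []
    for k1, test_ids in enumerate(inner_folds):
        test_idx = np.array([id_pos[s] for s in test_ids])
        train_sel = np.ones(len(pool_ids), dtype=bool)
        train_sel[test_idx] = False
        X_tr, y_tr = X_pool[train_sel], y_pool[train_sel]
        X_te, y_te = X_pool[test_idx], y_pool[test_idx]
        train_ids = tuple(np.asarray(pool_ids)[train_sel])

        mask = select_features(X_tr, y_tr, registry, config.feature_fraction)
        best = None
        for C in sorted(config.c_grid):
            for eps in sorted(config.epsilon_grid):
                w, b, est = _fit_svr(X_tr[:, mask], y_tr, config, C, eps)
                pred = (X_te[:, mask] @ w + b) if est is None else est.predict(X_te[:, mask])
                mse = float(np.mean((pred - y_te) ** 2))
                if best is None or mse < best[0]:
                    best = (mse, C, eps, w, b, est)
        mse, C, eps, w, b, keep = best
        out.append(SVRModelSpec(
            coords=(*coords_prefix, k1), mask=mask, weights=w, intercept=b,
            kernel=config.kernel, C=C, epsilon=eps, cv1_mse=mse,
            train_ids=train_ids, inner_test_ids=tuple(test_ids), estimator=keep))
    return out


# ---------------------------------------------------------------------------
# the full nested procedure
# ---------------------------------------------------------------------------

def audit_ensemble(models: Sequence[SVRModelSpec],
                   assignment: CVAssignment) -> int:
    """Count fold-disjointness violations: a model whose training ids
    intersect its inner test fold or its outer test fold.  Returns 0 on a
    clean ensemble; callers raise on anything else."""
    violations = 0
    for m in models:
        p2, k2, _, _ = m.coords
        outer_test = set(assignment.outer[p2][k2])
        train = set(m.train_ids)
        if train & set(m.inner_test_ids) or train & outer_test:
            violations += 1
    return violations


@dataclass
class NestedCVResult:
    ensemble: EnsembleModel
    performance: CVPerformance
    selection_profile: pd.Series


def run_nested_cv(cohort: pd.DataFrame, features: FeatureMatrix,
                  modalities: Iterable[str] = MODALITIES,
                  config: Optional[CVConfig] = None,
                  assignment: Optional[CVAssignment] = None) -> NestedCVResult:
    """Execute the repeated nested double CV on harmonized features.

    Subjects are the cohort rows of ``config.train_group`` with a finite
    target.  Each outer test fold is predicted by the unweighted mean of
    the optimal CV1 models trained inside that fold's training pool;
    performance is pooled over all outer permutations.  A leakage audit
    runs before returning and aborts on any violation.
    """
    config = config or CVConfig()
    feats = features.restrict_modalities(modalities)
    if not feats.harmonized:
        raise ValidationError("run_nested_cv requires reference-harmonized features")

    rows = cohort[cohort["group"] == config.train_group]
    rows = rows[np.isfinite(rows[config.target].astype(float))]
    ids = rows["id"].tolist()
    if not ids:
        raise ValidationError(
            f"no trainable subjects (group={config.train_group!r}, "
            f"target={config.target!r})")
    y = rows.set_index("id")[config.target].astype(float)
    feats = feats.subset_subjects(ids)
    X = feats.to_array()
    registry = feats.feature_names
    y_vec = y.loc[ids].to_numpy()
    id_pos = {sid: i for i, sid in enumerate(ids)}

    if assignment is None:
        assignment = build_cv_assignment(
            ids, config.k_outer, config.k_inner,
            config.n_outer_perms, config.n_inner_perms, config.seed)

    all_models: list[SVRModelSpec] = []
    pred_rows = []
    for p2 in range(config.n_outer_perms):
        for k2 in range(config.k_outer):
            test_ids = assignment.outer[p2][k2]
            test_idx = np.array([id_pos[s] for s in test_ids])
            pool_ids = np.array(sorted(set(ids) - set(test_ids)))
            pool_idx = np.array([id_pos[s] for s in pool_ids])
            X_pool, y_pool = X[pool_idx], y_vec[pool_idx]
            fold_models: list[SVRModelSpec] = []
            for p1 in range(config.n_inner_perms):
                fold_models.extend(tune_and_select(
                    X_pool, y_pool, pool_ids,
                    assignment.inner[(p2, k2, p1)], config, registry,
                    coords_prefix=(p2, k2, p1)))
            all_models.extend(fold_models)
            # CV2 prediction: unweighted mean over this fold's optimal CV1 models
            preds = np.mean([m.predict(X[test_idx]) for m in fold_models], axis=0)
            for sid, a, pr in zip(test_ids, y_vec[test_idx], preds):
                pred_rows.append((p2, k2, sid, a, pr))

    violations = audit_ensemble(all_models, assignment)
    if violations:
        bad = next(m.coords for m in all_models
                   if set(m.train_ids) & (set(m.inner_test_ids)
                                          | set(assignment.outer[m.coords[0]][m.coords[1]])))
        raise LeakageError(f"{violations} leakage violation(s); first at CV coordinate {bad}")

    predictions = pd.DataFrame(pred_rows,
                               columns=["perm", "fold", "id", "actual", "predicted"])
    ensemble = EnsembleModel(models=all_models, feature_registry=registry,
                             modalities=tuple(sorted(set(modalities))),
                             training_cohort=feats.cohort,
                             scaler_ref=feats.scaler_ref, config=config,
                             assignment=assignment)
    return NestedCVResult(ensemble=ensemble,
                          performance=pooled_performance(predictions),
                          selection_profile=ensemble.selection_profile())


def modality_sweep(cohort: pd.DataFrame, features: FeatureMatrix,
                   config: Optional[CVConfig] = None,
                   subsets: Optional[Sequence[str]] = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Run the nested CV for every non-empty modality subset (15 for four
    modalities) on identical folds, so subset comparisons are paired.

    Returns a performance table (one row per subset, ordered by descending
    R^2 within each subset size) and a dict subset -> NestedCVResult.
    """
    config = config or CVConfig()
    if subsets is None:
        present = sorted(features.modalities(), key=MODALITIES.index)
        subsets = ["".join(c) for r in range(1, len(present) + 1)
                   for c in itertools.combinations(present, r)]
    rows_tr = cohort[cohort["group"] == config.train_group]
    rows_tr = rows_tr[np.isfinite(rows_tr[config.target].astype(float))]
    assignment = build_cv_assignment(
        rows_tr["id"].tolist(), config.k_outer, config.k_inner,
        config.n_outer_perms, config.n_inner_perms, config.seed)

    results, rows = {}, []
    for subset in subsets:
        res = run_nested_cv(cohort, features, tuple(subset), config, assignment)
        results[subset] = res
        rows.append({
            "modalities": subset, "n_modalities": len(subset),
            "n_features": int(np.sum([m in set(subset) for m in
                                      features.feature_modalities()])),
            "r": res.performance.r, "r2": res.performance.r2,
            "mse": res.performance.mse, "n_models": len(res.ensemble),
        })
    table = pd.DataFrame(rows).sort_values(
        ["n_modalities", "r2"], ascending=[True, False]).reset_index(drop=True)
    return table, results
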
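import numpy as np
import pytest
from scipy.stats import spearmanr

from eyosvr.cv_engine import (
    CVConfig,
    EnsembleModel,
    audit_ensemble,
    build_cv_assignment,
    run_nested_cv,
    select_features,
    tune_and_select,
)
from eyosvr.errors import ValidationError
from eyosvr.synthetic_data import generate_linear_benchmark

SMALL = CVConfig(k_outer=5, k_inner=5, n_outer_perms=1, n_inner_perms=1, seed=0)


class TestAssignment:
    def test_exact_division(self):
        ids = [f"s{i}" for i in range(100)]
        asn = build_cv_assignment(ids, k_outer=10, k_inner=10, n_outer_perms=1,
                                  n_inner_perms=1, seed=1)
        folds = asn.outer[0]
        assert all(len(f) == 10 for f in folds)
        assert set(np.concatenate(folds)) == set(ids)

    def test_model_slot_bookkeeping(self):
        ids = [f"s{i}" for i in range(100)]
        asn = build_cv_assignment(ids, 10, 10, 10, 10, seed=0)
        assert asn.n_model_slots == 10_000

    def test_infeasible_partition(self):
        with pytest.raises(ValidationError):
            build_cv_assignment([f"s{i}" for i in range(9)], k_outer=10)

    def test_duplicate_ids(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_cv_assignment(["a", "a", "b"] + [f"s{i}" for i in range(20)],
                                k_outer=5, k_inner=5)

    def test_inner_folds_partition_training_pool(self):
        ids = [f"s{i}" for i in range(47)]  # uneven fold sizes
        asn = build_cv_assignment(ids, 5, 4, 2, 2, seed=3)
        asn.validate()  # raises if any invariant broken
        for (p2, k2, p1), folds in asn.inner.items():
            pool = set(ids) - set(asn.outer[p2][k2])
            assert set(np.concatenate(folds)) == pool

    def test_determinism(self):
        ids = [f"s{i}" for i in range(40)]
        a1 = build_cv_assignment(ids, 5, 5, 2, 2, seed=9)
        a2 = build_cv_assignment(ids, 5, 5, 2, 2, seed=9)
        for p2 in a1.outer:
            for f1, f2 in zip(a1.outer[p2], a2.outer[p2]):
                assert (f1 == f2).all()


class TestFeatureSelection:
    def test_fraction_rounding(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        mask = select_features(X, y, [f"f{i:02d}" for i in range(20)], 0.35)
        assert mask.sum() == 7  # ceil(0.35 * 20)

    def test_monotone_feature_always_selected(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(50)
        X = rng.standard_normal((50, 10))
        X[:, 3] = np.exp(y)  # strictly monotone in y -> |rho| = 1
        mask = select_features(X, y, [f"f{i}" for i in range(10)], 0.1)
        assert mask[3] and mask.sum() == 1

    def test_matches_independent_rank_oracle(self):
        """Selection equals a brute-force scipy.spearmanr ranking."""
        rng = np.random.default_rng(2)
        for trial in range(5):
            X = rng.standard_normal((40, 15))
            y = rng.standard_normal(40)
            names = [f"f{i:02d}" for i in range(15)]
            mask = select_features(X, y, names, 0.4)
            oracle = sorted(
                range(15),
                key=lambda j: (-abs(spearmanr(X[:, j], y).statistic), names[j]))
            expect = set(oracle[:6])  # ceil(0.4*15)
            assert set(np.where(mask)[0]) == expect

    def test_constant_feature_never_beats_defined_rho(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        X[:, 0] = 7.0  # constant -> undefined rho
        y = rng.standard_normal(30)
        mask = select_features(X, y, ["aaa", "bbb", "ccc", "ddd"], 0.75)
        assert not mask[0]


class TestTuneAndSelect:
    def _pool(self, n=60, p=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        w = rng.normal(size=p)
        y = X @ w
        ids = np.array([f"s{i}" for i in range(n)])
        folds = [ids[k::4] for k in range(4)]
        return X, y, ids, folds

    def test_single_grid_point_trivially_optimal(self):
        X, y, ids, folds = self._pool()
        cfg = CVConfig(c_grid=(1.0,), epsilon_grid=(0.1,), k_inner=4,
                       feature_fraction=1.0)
        models = tune_and_select(X, y, ids, folds, cfg, [f"f{i}" for i in range(12)])
        assert all(m.C == 1.0 and m.epsilon == 0.1 for m in models)

    def test_noiseless_linear_target_is_realizable(self):
        """With a tight-tube grid point and full features, the linear SVR
        reproduces an exactly linear target to near machine tolerance."""
        X, y, ids, folds = self._pool()
        cfg = CVConfig(c_grid=(100.0,), epsilon_grid=(1e-4,),
                       feature_fraction=1.0, k_inner=4,
                       solver_tol=1e-7, solver_max_iter=200_000)
        models = tune_and_select(X, y, ids, folds, cfg, [f"f{i}" for i in range(12)])
        assert min(m.cv1_mse for m in models) <= 1e-6

    def test_degenerate_target_errors(self):
        X, y, ids, folds = self._pool()
        with pytest.raises(ValidationError, match="degenerate"):
            tune_and_select(X, np.ones_like(y), ids, folds,
                            CVConfig(k_inner=4), [f"f{i}" for i in range(12)])

    def test_optimal_mse_matches_external_refit_oracle(self):
        """Refitting the winning grid point outside the engine on the same
        folds reproduces the stored CV1 MSE exactly."""
        from eyosvr.cv_engine import _fit_svr, select_features as sf

        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=50)
        ids = np.array([f"s{i}" for i in range(50)])
        folds = [ids[k::5] for k in range(5)]
        cfg = CVConfig(k_inner=5, feature_fraction=0.5)
        models = tune_and_select(X, y, ids, folds, cfg, [f"f{i}" for i in range(10)])
        pos = {s: i for i, s in enumerate(ids)}
        for m in models:
            te = np.array([pos[s] for s in m.inner_test_ids])
            tr = np.array([pos[s] for s in m.train_ids])
            mask = sf(X[tr], y[tr], [f"f{i}" for i in range(10)], 0.5)
            assert (mask == m.mask).all()
            w, b, _ = _fit_svr(X[tr][:, mask], y[tr], cfg, m.C, m.epsilon)
            mse = np.mean((X[te][:, mask] @ w + b - y[te]) ** 2)
            assert mse == pytest.approx(m.cv1_mse, rel=1e-10)


class TestNestedCV:
    def test_requires_harmonized_features(self):
        b = generate_linear_benchmark(n_subjects=60, n_features=20, n_informative=8, seed=0)
        b.features.harmonized = False
        with pytest.raises(ValidationError, match="harmonized"):
            run_nested_cv(b.cohort, b.features, config=SMALL)

    def test_each_subject_predicted_once_per_permutation(self):
        b = generate_linear_benchmark(n_subjects=60, n_features=20, n_informative=8, seed=1)
        cfg = CVConfig(k_outer=5, k_inner=5, n_outer_perms=2, n_inner_perms=1,
                       seed=4)
        res = run_nested_cv(b.cohort, b.features, config=cfg)
        counts = res.performance.predictions.groupby(["perm", "id"]).size()
        assert (counts == 1).all()
        assert res.performance.predictions.groupby("perm").size().eq(60).all()

    def test_ensemble_size_and_audit_clean(self):
        b = generate_linear_benchmark(n_subjects=60, n_features=20, n_informative=8, seed=2)
        cfg = CVConfig(k_outer=5, k_inner=5, n_outer_perms=2, n_inner_perms=2,
                       seed=5)
        res = run_nested_cv(b.cohort, b.features, config=cfg)
        assert len(res.ensemble) == 2 * 5 * 2 * 5
        assert audit_ensemble(res.ensemble.models, res.ensemble.assignment) == 0

    def test_selection_profile_ranks_signal_over_noise(self):
        b = generate_linear_benchmark(n_subjects=100, n_features=30,
                                      n_informative=8, seed=3)
        res = run_nested_cv(b.cohort, b.features, config=SMALL)
        prof = res.selection_profile
        assert prof.between(0, 1).all()
        informative = b.meta["informative_features"]
        noise = [f for f in prof.index if f not in informative]
        assert prof[informative].max() > prof[noise].min()
        assert prof[informative].mean() > prof[noise].mean()

    def test_r2_is_squared_pooled_r(self):
        b = generate_linear_benchmark(n_subjects=60, n_features=20, n_informative=8, seed=6)
        res = run_nested_cv(b.cohort, b.features, config=SMALL)
        assert res.performance.r2 == pytest.approx(res.performance.r ** 2)

    def test_persistence_roundtrip_predictions(self, tmp_path):
        b = generate_linear_benchmark(n_subjects=60, n_features=20, n_informative=8, seed=7)
        res = run_nested_cv(b.cohort, b.features, config=SMALL)
        res.ensemble.save(tmp_path / "ens")
        back = EnsembleModel.load(tmp_path / "ens")
        X = b.features.to_array()
        assert np.allclose(back.predict_matrix(X),
                           res.ensemble.predict_matrix(X), atol=1e-12)
        assert back.feature_registry == res.ensemble.feature_registry


class TestFilterThresholdRobustness:
    def test_fraction_in_quarter_to_half_band_barely_moves_r2(self):
        """Shifting the Spearman-filter threshold between 25% and 45%
        changes CV2 R-squared by less than 0.1 on the factor benchmark."""
        b = generate_linear_benchmark(seed=12)
        r2 = {}
        for frac in (0.25, 0.35, 0.45):
            cfg = CVConfig(k_outer=10, k_inner=5, n_outer_perms=1,
                           n_inner_perms=1, feature_fraction=frac, seed=13)
            r2[frac] = run_nested_cv(b.cohort, b.features,
                                     config=cfg).performance.r2
        assert abs(r2[0.25] - r2[0.35]) < 0.1
        assert abs(r2[0.45] - r2[0.35]) < 0.1


class TestModalitySweep:
    def test_subset_enumeration_and_consistency(self):
        from eyosvr.cv_engine import modality_sweep

        b = generate_linear_benchmark(n_subjects=80, n_features=24, n_informative=8, seed=8)
        cfg = CVConfig(k_outer=4, k_inner=4, n_outer_perms=1, n_inner_perms=1,
                       seed=11)
        table, results = modality_sweep(b.cohort, b.features, cfg)
        assert len(table) == 15  # 2^4 - 1
        # single-modality rows equal a direct nested run on the same folds
        direct = run_nested_cv(b.cohort, b.features, ("A",), cfg)
        row = table.set_index("modalities").loc["A"]
        assert row["r"] == pytest.approx(direct.performance.r)
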
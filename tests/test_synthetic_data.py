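import dataclasses

import numpy as np
import pandas as pd
import pytest

from eyosvr.errors import ConfigurationError, GenerationError, ValidationError
from eyosvr.synthetic_data import (
    CohortSpec,
    TrajectoryParams,
    default_trajectories,
    generate_adad_cohort,
    generate_linear_benchmark,
    generate_sporadic_cohort,
)


def noiseless(trajs, **overrides):
    return [dataclasses.replace(t, noise_sd=0.0, offset_sd=0.0, **overrides)
            for t in trajs]


class TestTrajectoryParams:
    def test_rejects_invalid_parameters(self):
        ok = dict(name="x", modality="A", healthy=1.0, asymptote=0.5,
                  midpoint=-10.0, steepness=0.2, direction=1,
                  noise_sd=0.1, offset_sd=0.1)
        TrajectoryParams(**ok)
        with pytest.raises(ValidationError):
            TrajectoryParams(**{**ok, "steepness": 0.0})
        with pytest.raises(ValidationError):
            TrajectoryParams(**{**ok, "noise_sd": -0.1})
        with pytest.raises(ValidationError):
            TrajectoryParams(**{**ok, "midpoint": float("nan")})
        with pytest.raises(ValidationError):
            TrajectoryParams(**{**ok, "modality": "X"})

    def test_default_registry_shape(self):
        trajs = default_trajectories()
        tags = pd.Series([t.modality for t in trajs]).value_counts()
        assert tags["A"] == tags["F"] == tags["G"] == 30
        assert tags["C"] == 3
        names = [t.feature_name for t in trajs]
        assert len(names) == len(set(names))


class TestAdadCohort:
    def test_carrier_eyo_matches_published_moments(self):
        """Carrier EYO sample mean/SD within 2 SE of the -7.10 (11.23) targets."""
        spec = CohortSpec.adad_default(seed=5)
        mc = generate_adad_cohort(spec).cohort.query("group == 'MC'")
        assert len(mc) == 121
        se_mean = 11.23 / np.sqrt(121)
        se_sd = 11.23 / np.sqrt(2 * 121)
        assert abs(mc.eyo.mean() - (-7.10)) < 2 * se_mean
        assert abs(mc.eyo.std() - 11.23) < 2 * se_sd

    def test_noiseless_step_limit(self):
        """With no noise and huge steepness, carriers are a step function of
        EYO at the midpoint and reference subjects sit exactly at healthy."""
        trajs = noiseless(default_trajectories()[:5], steepness=50.0, direction=1)
        spec = CohortSpec.adad_default(seed=2, modalities=("A",))
        bundle = generate_adad_cohort(spec, trajs)
        cohort = bundle.cohort.set_index("id")
        for tp in trajs:
            col = bundle.features.values[tp.feature_name]
            nc = col[cohort.group == "NC"]
            assert np.allclose(nc, tp.healthy)
            mc = col[cohort.group == "MC"]
            eyo = cohort.loc[mc.index, "eyo"]
            far_before = mc[eyo < tp.midpoint - 1]
            far_after = mc[eyo > tp.midpoint + 1]
            assert np.allclose(far_before, tp.healthy, atol=1e-6)
            assert np.allclose(far_after, tp.healthy + tp.asymptote, atol=1e-6)

    def test_determinism_and_seed_sensitivity(self):
        spec = CohortSpec.adad_default(seed=7)
        b1 = generate_adad_cohort(spec)
        b2 = generate_adad_cohort(spec)
        assert b1.features.values.equals(b2.features.values)
        assert b1.cohort.equals(b2.cohort)
        b3 = generate_adad_cohort(CohortSpec.adad_default(seed=8))
        assert not b1.features.values.equals(b3.features.values)

    def test_missing_modality_is_configuration_error(self):
        only_imaging = [t for t in default_trajectories() if t.modality != "C"]
        with pytest.raises(ConfigurationError, match="C"):
            generate_adad_cohort(CohortSpec.adad_default(seed=0), only_imaging)


class TestSporadicCohort:
    def test_stratum_sizes_exact(self, sporadic_bundle):
        counts = sporadic_bundle.cohort.groupby(["group", "abeta_status"]).size()
        assert counts[("MCI", "pos")] == 216
        assert counts[("MCI", "neg")] == 175
        assert counts[("CN", "neg")] == 49

    def test_status_consistent_with_composite_cutoff(self, sporadic_bundle):
        feats = sporadic_bundle.features
        a_cols = [c for c in feats.feature_names if c.startswith("A__")]
        composite = feats.values[a_cols].mean(axis=1)
        meta = sporadic_bundle.cohort.set_index("id")
        mci = meta[meta.group == "MCI"]
        assert ((composite[mci.index] > 1.11) == (mci.abeta_status == "pos")).all()

    def test_null_link_gives_zero_slopes(self):
        spec = CohortSpec.sporadic_default(
            seed=3, n_mci_pos=40, n_mci_neg=30, n_reference=10,
            slope_link=0.0, slope_link_adas=0.0, slope_noise_sd=0.0,
            adas_slope_noise_sd=0.0)
        bundle = generate_sporadic_cohort(spec)
        assert np.allclose(bundle.truth.mem_slope_true, 0.0)
        assert np.allclose(bundle.truth.adas_slope_true, 0.0)

    def test_noiseless_cognition_recovers_true_slope(self):
        spec = CohortSpec.sporadic_default(
            seed=4, n_mci_pos=30, n_mci_neg=20, n_reference=10,
            cog_noise_sd=0.0, adas_noise_sd=0.0)
        bundle = generate_sporadic_cohort(spec)
        truth = bundle.truth.set_index("id")
        for sid, visits in bundle.cognition.groupby("id"):
            slope = np.polyfit(visits.years, visits.mem, 1)[0]
            assert slope == pytest.approx(truth.loc[sid, "mem_slope_true"], abs=1e-9)

    def test_impossible_cutoff_names_stratum(self):
        spec = CohortSpec.sporadic_default(seed=0, amyloid_cutoff=99.0)
        with pytest.raises(GenerationError, match="positive"):
            generate_sporadic_cohort(spec)

    def test_dropout_shrinks_followup(self):
        spec = CohortSpec.sporadic_default(
            seed=9, n_mci_pos=60, n_mci_neg=40, n_reference=10,
            dropout_rate=0.15)
        cog = generate_sporadic_cohort(spec).cognition
        n_by_year = cog.groupby("years")["id"].nunique()
        assert (n_by_year.diff().dropna() <= 0).all()
        assert n_by_year[4.0] < n_by_year[0.0]


class TestCrossCohortStructure:
    def test_reference_groups_share_law_before_instrument_transform(self):
        """Healthy reference distributions are identical across cohorts before
        the per-modality instrument transform and differ after — the property
        harmonization must undo."""
        trajs = default_trajectories()
        identity = {m: 0.0 for m in "AFGC"}
        ones = {m: 1.0 for m in "AFGC"}
        ad = generate_adad_cohort(CohortSpec.adad_default(
            seed=21, n_reference=400), trajs)
        sp_same = generate_sporadic_cohort(CohortSpec.sporadic_default(
            seed=22, n_reference=400, cohort_offset=identity, cohort_scale=ones,
            n_mci_pos=5, n_mci_neg=5), trajs)
        sp_shift = generate_sporadic_cohort(CohortSpec.sporadic_default(
            seed=22, n_reference=400, n_mci_pos=5, n_mci_neg=5), trajs)
        from scipy.stats import ks_2samp
        ad_ref = ad.features.values.loc[ad.cohort.query("group=='NC'").id]
        for sp, expect_same in ((sp_same, True), (sp_shift, False)):
            ref = sp.features.values.loc[sp.cohort.query("group=='CN'").id]
            col = "A__lh_precuneus"
            p = ks_2samp(ad_ref[col], ref[col]).pvalue
            assert (p > 0.01) == expect_same

    def test_truth_not_reachable_from_training_interface(self, sporadic_bundle):
        """Ground truth lives only on the bundle, not on the tables the
        training/scoring interfaces accept."""
        assert "burden" not in sporadic_bundle.cohort.columns
        assert not any("slope" in c for c in sporadic_bundle.cohort.columns)
        assert "burden" not in sporadic_bundle.features.values.columns


class TestLinearBenchmark:
    def test_population_r2_calibration(self):
        """At large n the best linear predictor explains ~ the requested share."""
        b = generate_linear_benchmark(n_subjects=20000, seed=0)
        X = b.features.to_array()
        y = b.cohort.eyo.to_numpy()
        beta, *_ = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)
        fitted = (X - X.mean(0)) @ beta
        r2 = 1 - np.var(y - y.mean() - fitted) / np.var(y)
        assert r2 == pytest.approx(0.55, abs=0.03)

    def test_flags_and_shapes(self):
        b = generate_linear_benchmark(seed=1)
        assert b.features.harmonized
        assert b.features.values.shape == (150, 90)
        assert set(b.meta["informative_features"]) <= set(b.features.feature_names)
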
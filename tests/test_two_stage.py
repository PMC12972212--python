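import numpy as np
import pandas as pd
import pytest

from betaclock import (
    ClockConfig,
    CohortSizeError,
    DegenerateDataError,
    SimConfig,
    TwoStageModel,
    optimize_cutoff,
    predict_single_stage,
    predict_two_stage,
    simulate_dataset,
    train_cohort_models,
    train_sex_specific,
    train_stage1,
    train_two_stage,
)
from betaclock.simulate import simulate_like

from conftest import make_dataset, quiet


class TestTrainStage1:
    def test_selects_the_informative_sites(self, linear_cohort):
        ds, truth, _ = linear_cohort
        ref = train_stage1(ds)
        assert set(ref.site_ids) == set(truth.informative_sites)

    def test_sample_order_invariance(self, linear_cohort):
        ds, _, _ = linear_cohort
        rng = np.random.default_rng(0)
        shuffled = ds.subset_samples(rng.permutation(ds.sample_ids))
        a, b = train_stage1(ds), train_stage1(shuffled)
        assert a.site_ids == b.site_ids
        # summation order inside tied-age windows differs, hence the atol
        np.testing.assert_allclose(a.mu, b.mu, atol=1e-12)
        np.testing.assert_allclose(a.sigma, b.sigma, atol=1e-12)

    def test_identical_ages_are_degenerate(self):
        rng = np.random.default_rng(1)
        beta = rng.uniform(0.2, 0.8, (50, 5))
        ds = make_dataset(beta, ages=[40] * 50)
        with pytest.raises(DegenerateDataError), quiet():
            train_stage1(ds)


class TestCohortModels:
    def test_piecewise_cohorts_get_different_trends(self):
        ds, truth = simulate_dataset(
            SimConfig(n_samples=1200, curve_family="piecewise",
                      changepoint_age=25, noise_scale=0.02, seed=21)
        )
        with quiet():
            junior, senior = train_cohort_models(ds, 25)
        shared = set(junior.site_ids) & set(senior.site_ids)
        assert shared, "cohorts should share at least one informative site"
        site = sorted(shared)[0]
        ji, si = junior.site_ids.index(site), senior.site_ids.index(site)
        grid = junior.age_grid
        jr_slope = np.diff(junior.mu[ji][(grid >= 5) & (grid <= 25)]).mean()
        sr_slope = np.diff(senior.mu[si][(grid >= 30) & (grid <= 95)]).mean()
        assert abs(jr_slope) > 2 * abs(sr_slope)

    def test_cutoff_below_youngest_age_fails(self, linear_cohort):
        ds, _, _ = linear_cohort
        with pytest.raises(CohortSizeError, match="junior"):
            train_cohort_models(ds, int(ds.ages.min()) - 1)

    def test_undersized_cohort_rejected(self, linear_cohort):
        ds, _, _ = linear_cohort
        young = ds.subset_samples(ds.ages <= 50)
        with pytest.raises(CohortSizeError), quiet():
            train_cohort_models(young, 48, ClockConfig(min_cohort_size=30))


class TestPredictTwoStage:
    def test_routing_boundary_is_inclusive_for_junior(self, linear_cohort):
        ds, truth, _ = linear_cohort
        with quiet():
            model, _ = train_two_stage(ds, cutoff=25)
        # noise-free samples at exact integer ages -> exact stage-1 estimates
        cfg0 = SimConfig(
            n_samples=1, n_sites=40, n_informative=16,
            curve_family="linear", noise_scale=0.0, seed=42,
        )
        _, truth0 = simulate_dataset(cfg0)
        grid = truth0.true_mean_grid(np.array([25.0, 26.0]))
        betas = pd.DataFrame(grid.to_numpy().T, index=["at25", "at26"],
                             columns=grid.index)
        from betaclock import MethylationDataset

        pred = predict_two_stage(model, MethylationDataset(beta=betas))
        assert pred.loc["at25", "stage1_age"] == 25
        assert pred.loc["at25", "cohort"] == "junior"
        assert pred.loc["at26", "stage1_age"] == 26
        assert pred.loc["at26", "cohort"] == "senior"

    def test_every_sample_routed_to_exactly_one_cohort(
        self, trained_linear_model, linear_cohort
    ):
        _, _, test = linear_cohort
        pred = predict_two_stage(trained_linear_model, test)
        assert set(pred["cohort"]) <= {"junior", "senior"}
        junior = pred["stage1_age"] <= trained_linear_model.routing_threshold
        assert (pred.loc[junior, "cohort"] == "junior").all()
        assert (pred.loc[~junior, "cohort"] == "senior").all()

    def test_degenerate_model_reproduces_stage1(
        self, trained_linear_model, linear_cohort
    ):
        _, _, test = linear_cohort
        m = trained_linear_model
        degenerate = TwoStageModel(
            stage1=m.stage1, junior=m.stage1, senior=m.stage1,
            cutoff_age=m.cutoff_age, routing_threshold=m.routing_threshold,
            config=m.config,
        )
        pred = predict_two_stage(degenerate, test)
        np.testing.assert_array_equal(
            pred["final_age"].to_numpy(), pred["stage1_age"].to_numpy()
        )

    def test_no_overlap_recorded_as_failed_without_stopping_others(
        self, trained_linear_model, linear_cohort
    ):
        _, _, test = linear_cohort
        beta = test.beta.copy()
        beta.iloc[0, :] = np.nan
        from betaclock import MethylationDataset

        broken = MethylationDataset(beta=beta, ages=test.ages, sex=test.sex)
        with pytest.warns(UserWarning, match="could not be predicted"):
            pred = predict_two_stage(trained_linear_model, broken)
        assert pred.iloc[0]["cohort"] == "failed"
        assert np.isnan(pred.iloc[0]["final_age"])
        assert pred.iloc[1:]["final_age"].notna().all()

    def test_noise_free_piecewise_junior_sample_recovered(self):
        ds, truth = simulate_dataset(
            SimConfig(n_samples=800, n_sites=30, n_informative=16,
                      curve_family="piecewise", noise_scale=0.0, seed=30)
        )
        with quiet():
            model, _ = train_two_stage(ds, cutoff=25)
        test = simulate_like(truth, 50, seed=31)
        pred = predict_two_stage(model, test)
        young = test.ages == 10
        if young.any():
            assert (pred.loc[young[young].index, "final_age"] == 10).all()


class TestOptimizeCutoff:
    def test_identical_metrics_tie_breaks_to_smallest_cutoff(self):
        # noise-free linear data: every cutoff predicts exactly -> MBE 0 ties
        ds, truth = simulate_dataset(
            SimConfig(n_samples=600, n_sites=25, n_informative=16,
                      curve_family="linear", noise_scale=0.0, seed=33)
        )
        val = simulate_like(truth, 120, seed=34)
        with quiet():
            scan = optimize_cutoff(ds, val, range(20, 26))
        mbes = scan.table.dropna()["mbe"].round(12)
        if mbes.nunique() == 1:
            assert scan.selected_cutoff == scan.table["cutoff"].min()
        else:  # still must be the |MBE| argmin
            best = scan.table.loc[scan.table["mbe"].abs().idxmin(), "cutoff"]
            assert scan.selected_cutoff == best

    def test_single_candidate_returned_with_metrics(self, linear_cohort):
        ds, truth, _ = linear_cohort
        val = simulate_like(truth, 100, seed=35)
        with quiet():
            scan = optimize_cutoff(ds, val, [25])
        assert scan.selected_cutoff == 25
        assert scan.table.shape[0] == 1
        assert np.isfinite(scan.table[["mae", "rmse", "mbe"]]).all().all()

    def test_infeasible_candidates_skipped_with_warning(self, linear_cohort):
        ds, truth, _ = linear_cohort
        val = simulate_like(truth, 60, seed=36)
        lo = int(ds.ages.min())
        with pytest.warns(UserWarning, match="skipped"):
            scan = optimize_cutoff(ds, val, [lo - 1, 25])
        assert scan.selected_cutoff == 25
        assert scan.table["mae"].isna().sum() == 1


class TestSexSpecific:
    def test_without_sex_effect_both_models_use_informative_sites(self):
        ds, truth = simulate_dataset(
            SimConfig(n_samples=900, n_sites=30, n_informative=16,
                      curve_family="linear", noise_scale=0.02,
                      sex_effect_size=0.0, seed=40)
        )
        with quiet():
            models = train_sex_specific(ds, cutoff=25)
        informative = set(truth.informative_sites)
        for sex in ("male", "female"):
            assert set(models[sex].stage1.site_ids) <= informative
            assert models[sex].sex_label == sex

    def test_matching_sex_model_recovers_noise_free_ages(self):
        ds, truth = simulate_dataset(
            SimConfig(n_samples=900, n_sites=25, n_informative=16,
                      curve_family="linear", noise_scale=0.0, seed=41)
        )
        with quiet():
            models = train_sex_specific(ds, cutoff=25)
        test = simulate_like(truth, 60, seed=42)
        for sex in ("male", "female"):
            sub = test.subset_samples(test.sex == sex)
            pred = predict_two_stage(models[sex], sub)
            lo = ds.ages[ds.sex == sex].min()
            hi = ds.ages[ds.sex == sex].max()
            in_range = (sub.ages >= lo) & (sub.ages <= hi)
            assert (
                pred.loc[in_range[in_range].index, "final_age"]
                == sub.ages[in_range]
            ).all()

    def test_all_unknown_sex_is_an_error(self, linear_cohort):
        ds, _, _ = linear_cohort
        from betaclock import MethylationDataset

        unknown = MethylationDataset(
            beta=ds.beta, ages=ds.ages, sex=pd.Series("unknown", index=ds.beta.index)
        )
        with pytest.raises(CohortSizeError), quiet():
            train_sex_specific(unknown)


def test_senior_trained_reference_does_not_collapse_to_age_zero():
    """A sample looking younger than a restricted reference's range lands at
    the range boundary, not at the far end of the constant-extrapolated tie."""
    rng = np.random.default_rng(50)
    ages = rng.integers(30, 91, 300).astype(float)
    beta = np.clip(0.2 + 0.005 * ages + rng.normal(0, 0.02, 300), 0, 1)
    ds = make_dataset(beta[:, None], ages=ages)
    ref = train_stage1(ds, ClockConfig(n_sites=1))
    young_looking = make_dataset([[0.05]], ages=[20])
    pred = predict_single_stage(ref, young_looking)
    assert pred["age"].iloc[0] == 30
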
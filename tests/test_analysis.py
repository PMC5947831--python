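"""Analysis stages: AUC, cross-validation, transfer, age effects, partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import marshniche as mn
from marshniche.analysis import (
    age_effect_at_optimum,
    compute_auc,
    cross_validate,
    fit_species_model,
    hierarchical_partition,
    niche_surface,
    predict_transfer,
    _kde_mode,
)
from marshniche.simulate import SimulationConfig, generate_survey
from tests.conftest import flat_profile, make_dataset, small_sim_config


def brute_force_auc(scores, labels):
    """Pairwise concordance: P(score_pos > score_neg) with ties counting 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestComputeAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.1], [1, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
            ([0.8, 0.6, 0.4], [1, 0, 1], 0.5),  # 2 pos-neg pairs: one win, one loss
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert compute_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.9], [1, 1])

    def test_equals_brute_force_concordance_exactly(self):
        rng = np.random.default_rng(12)
        for n in (5, 12, 30):
            for _ in range(10):
                labels = rng.integers(0, 2, n)
                if labels.min() == labels.max():
                    labels[0] = 1 - labels[0]
                # coarse scores force ties
                scores = rng.integers(0, 4, n) / 4.0
                assert compute_auc(scores, labels) == brute_force_auc(scores, labels)


class TestCrossValidation:
    def _separable_dataset(self, n=80):
        rng = np.random.default_rng(3)
        rth = rng.uniform(0, 1, n)
        pres = (rth > 0.5).astype(int)
        return make_dataset(rth, redox=rng.normal(size=n) * 50, presence={"SpA": pres})

    def test_perfectly_separable_species_approaches_auc_one(self):
        ds = self._separable_dataset()
        res = cross_validate(ds, "SpA", n_runs=50, seed=1)
        assert res.mean_auc > 0.97
        assert np.all((res.auc_per_run >= 0) & (res.auc_per_run <= 1))
        assert res.mean_auc == pytest.approx(res.auc_per_run.mean())

    def test_permuted_labels_give_null_auc(self):
        # a single fixed permutation carries finite-sample chance association,
        # so the null calibration averages several independent permutations
        rng = np.random.default_rng(4)
        n = 150
        rth = rng.uniform(0, 1, n)
        labels = (rth > 0.5).astype(int)
        means = []
        for rep in range(4):
            pres = rng.permutation(labels)
            ds = make_dataset(rth, redox=rng.normal(size=n) * 50, presence={"SpA": pres})
            means.append(cross_validate(ds, "SpA", n_runs=30, seed=rep).mean_auc)
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) <= max(3 * se, 0.04)

    def test_too_rare_species_flagged_not_aborted(self):
        ds = make_dataset(np.linspace(0, 1, 40), presence={"SpA": [1] + [0] * 39})
        res = cross_validate(ds, "SpA", n_runs=10, seed=0)
        assert res.flagged
        assert np.isnan(res.mean_auc)

    def test_fewer_runs_only_widen_scatter(self):
        ds = self._separable_dataset()
        r100 = cross_validate(ds, "SpA", n_runs=100, seed=5)
        r25 = cross_validate(ds, "SpA", n_runs=25, seed=6)
        se = r100.auc_per_run.std() / np.sqrt(25)
        assert abs(r25.mean_auc - r100.mean_auc) <= max(4 * se, 0.02)


class TestTransfer:
    def _fit_and_data(self):
        rng = np.random.default_rng(8)
        n = 120
        rth = rng.uniform(0, 1, n)
        p = norm.cdf(1.0 - ((rth - 0.3) / 0.3) ** 2)
        pres = (rng.uniform(size=n) < p).astype(int)
        ds = make_dataset(rth, redox=rng.normal(size=n) * 30, presence={"SpA": pres})
        fit = fit_species_model(ds, "SpA")
        return fit, ds

    def test_identity_transfer_matches_in_sample_mean(self):
        fit, ds = self._fit_and_data()
        X = ds.quadrats[["rth", "redox", "region"]]
        in_sample = fit.predict_probability(X).mean()
        tr = predict_transfer(fit, ds, "SpA", n_draws=4000, seed=1)
        assert tr.median == pytest.approx(in_sample, abs=0.02)
        assert tr.ci_low <= tr.median <= tr.ci_high

    def test_draw_median_converges_to_analytic_mean(self):
        fit, ds = self._fit_and_data()
        sub = make_dataset([0.1, 0.5], redox=[0.0, 10.0])
        sub.quadrats[:]  # tiny 2-quadrat target
        tr = predict_transfer(fit, sub, "SpA", n_draws=100_000, seed=2)
        analytic = fit.predict_probability(sub.quadrats[["rth", "redox", "region"]]).mean()
        se = tr.per_draw_mean.std() / np.sqrt(len(tr.per_draw_mean))
        assert abs(tr.per_draw_mean.mean() - analytic) <= 3 * se

    def test_lower_target_class_favours_low_marsh_species(self):
        # low-marsh species + MR quadrats placed lower -> transfer-predicted
        # MR mean exceeds the NAT mean
        rng = np.random.default_rng(9)
        n = 150
        rth_nat = rng.uniform(0.2, 1.2, n)
        p = norm.cdf(1.5 - ((rth_nat - 0.1) / 0.4) ** 2)
        pres = (rng.uniform(size=n) < p).astype(int)
        nat = make_dataset(rth_nat, presence={"SpA": pres})
        fit = fit_species_model(nat, "SpA")
        rth_mr = rng.uniform(-0.4, 0.6, n)
        mr = make_dataset(rth_mr, age_class=["MR"] * n)
        tr_mr = predict_transfer(fit, mr, "SpA", n_draws=500, seed=3)
        tr_nat = predict_transfer(fit, nat, "SpA", n_draws=500, seed=3)
        assert tr_mr.median > tr_nat.median

    def test_mixed_age_class_dataset_rejected(self):
        fit, ds = self._fit_and_data()
        mixed = make_dataset([0.1, 0.2], age_class=["NAT", "MR"])
        with pytest.raises(ValueError):
            predict_transfer(fit, mixed, "SpA")


class TestAgeEffects:
    def test_point_mass_draws_give_degenerate_mode(self):
        assert _kde_mode(np.full(200, 0.37)) == pytest.approx(0.37)

    def test_exchangeable_classes_have_overlapping_intervals(self):
        prof = flat_profile("Spar", max_latent=0.5, rth_breadth=1.0,
                            rth_optimum=0.5, redox_breadth=400.0)
        cfg = small_sim_config(seed=13, quadrats=60, profiles=[prof])
        ds = generate_survey(cfg)
        fit = fit_species_model(ds, "Spar", include_age=True)
        effs = age_effect_at_optimum(fit, ds, "Spar", n_draws=400, seed=1)
        by = {e.age_class: e for e in effs}
        for a, b in [("MR", "NAT"), ("AR", "NAT"), ("MR", "AR")]:
            assert by[a].ci_low <= by[b].ci_high and by[b].ci_low <= by[a].ci_high

    def test_mode_inside_interval_and_probabilities_valid(self, default_survey):
        fit = fit_species_model(default_survey, "Pucc", include_age=True)
        for e in age_effect_at_optimum(fit, default_survey, "Pucc", n_draws=300, seed=2):
            assert 0 < e.ci_low <= e.mode <= e.ci_high < 1


class TestHierarchicalPartition:
    def test_contributions_sum_to_total_gof(self, small_survey):
        res = hierarchical_partition(small_survey, "Pucc")
        assert sum(res.contributions.values()) == pytest.approx(res.total_gof, abs=1e-6)

    def test_order_invariance(self, small_survey):
        a = hierarchical_partition(small_survey, "Sali", predictors=("rth", "redox", "age_class"))
        b = hierarchical_partition(small_survey, "Sali", predictors=("age_class", "rth", "redox"))
        for k in a.contributions:
            assert a.contributions[k] == pytest.approx(b.contributions[k], abs=1e-9)

    def test_cloned_predictor_contributions_equal(self):
        rng = np.random.default_rng(21)
        n = 120
        rth = rng.uniform(0, 1, n)
        pres = (rng.uniform(size=n) < norm.cdf(2 * (rth - 0.5))).astype(int)
        ds = make_dataset(rth, presence={"SpA": pres})
        ds.quadrats["rth_clone"] = ds.quadrats["rth"]
        res = hierarchical_partition(ds, "SpA", predictors=("rth", "rth_clone"))
        a, b = res.contributions["rth"], res.contributions["rth_clone"]
        assert a == pytest.approx(b, rel=0.02, abs=0.05)

    def test_single_predictor_contribution_equals_full_gain(self):
        rng = np.random.default_rng(22)
        n = 100
        rth = rng.uniform(0, 1, n)
        pres = (rng.uniform(size=n) < norm.cdf(2 * (rth - 0.5))).astype(int)
        ds = make_dataset(rth, presence={"SpA": pres})
        res = hierarchical_partition(ds, "SpA", predictors=("rth",))
        assert res.contributions["rth"] == pytest.approx(res.total_gof)

    def test_age_dominates_when_environment_uninformative(self):
        prof = flat_profile("Spar", max_latent=1.0,
                            age_shifts={"MR": -2.0, "AR": -1.0, "NAT": 0.0})
        cfg = small_sim_config(seed=17, quadrats=60, profiles=[prof])
        ds = generate_survey(cfg)
        res = hierarchical_partition(ds, "Spar")
        c = res.contributions
        assert c["age_class"] == max(c.values())


class TestNicheSurface:
    def test_unimodal_species_argmax_recovers_generative_optimum(self):
        prof = mn.default_config().species_profiles[4]  # Pucc: opt (0.65, 150)
        cfg = small_sim_config(seed=23, quadrats=170, profiles=[prof])
        ds = generate_survey(cfg).subset(age_class="NAT")  # ~500 NAT quadrats
        fit = fit_species_model(ds, "Pucc")
        # grid cells at half the generative niche breadth per axis: the
        # resolution at which the optimum is actually identifiable
        rth_grid = np.arange(-0.3, 1.45, prof.rth_breadth / 2)
        redox_grid = np.arange(-270.0, 451.0, prof.redox_breadth / 2)
        surf = niche_surface(fit, rth_grid, redox_grid, region="Essex")
        rth_hat, redox_hat = surf.argmax_available()
        assert abs(rth_hat - prof.rth_optimum) <= prof.rth_breadth / 2 + 1e-9
        assert abs(redox_hat - prof.redox_optimum) <= prof.redox_breadth / 2 + 1e-9

    def test_observed_points_never_masked(self):
        rng = np.random.default_rng(5)
        rth = rng.uniform(0, 1, 40)
        redox = rng.uniform(-100, 100, 40)
        pres = rng.integers(0, 2, 40)
        pres[0], pres[1] = 0, 1
        ds = make_dataset(rth, redox=redox, presence={"SpA": pres})
        fit = fit_species_model(ds, "SpA")
        surf = niche_surface(fit, np.sort(rth[:10]), np.sort(redox[:10]), region="Essex")
        for r, x in zip(rth[:10], redox[:10]):
            i = np.argmin(np.abs(surf.redox_grid - x))
            j = np.argmin(np.abs(surf.rth_grid - r))
            if surf.redox_grid[i] == x and surf.rth_grid[j] == r:
                assert surf.available[i, j]

    def test_collinear_observations_mask_off_line_cells(self):
        rth = np.linspace(0, 1, 12)
        redox = 100 * rth  # perfectly collinear environment
        pres = (rth > 0.5).astype(int)
        ds = make_dataset(rth, redox=redox, presence={"SpA": pres})
        fit = fit_species_model(ds, "SpA")
        surf = niche_surface(fit, np.linspace(0, 1, 7), np.linspace(0, 100, 7), region="Essex")
        # off-line cells masked; on-line observed cells available
        off = surf.available[0, -1]  # redox 0 at rth 1: far off the line
        assert not off
        assert surf.available.sum() >= 1

    def test_empty_grid_rejected(self):
        ds = make_dataset([0.1, 0.9], presence={"SpA": [0, 1]})
        fit = fit_species_model(ds, "SpA")
        with pytest.raises(ValueError):
            niche_surface(fit, [], [0.0], region="Essex")
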
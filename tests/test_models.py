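"""Robust t-noise model fits: support constraints, recovery, reductions."""

import numpy as np
import pytest

from robustchange.inference import hdi
from robustchange.models import (
    DegenerateDataError,
    ModelError,
    ModelSpec,
    fit_multi_group,
    fit_regression,
    fit_single_group,
    fit_two_group,
)


class TestSingleGroup:
    def test_hdi_covers_true_mean_across_seeds(self, fast_spec):
        hits = 0
        for seed in range(20):
            y = np.random.default_rng(seed).normal(0.5, 1.0, 200)
            spec = fast_spec(chains=2, draws_per_chain=600, warmup=250, seed=seed)
            post = fit_single_group(y, spec)
            h = hdi(post.stacked("mu"), 0.95)
            hits += h.lower <= 0.5 <= h.upper
        assert hits >= 18

    def test_nu_floor_is_respected_by_every_draw(self, rng, fast_spec):
        y = rng.standard_t(3, 100)
        post = fit_single_group(y, fast_spec(nu_floor=2.0, draws_per_chain=300, warmup=150))
        assert post.stacked("nu").min() >= 2.0

    def test_sigma_draws_always_positive(self, rng, fast_spec):
        y = rng.normal(0, 0.01, 50)
        post = fit_single_group(y, fast_spec(draws_per_chain=300, warmup=150))
        assert (post.stacked("sigma") > 0).all()

    def test_identical_seed_reproduces_identical_draws(self, rng, fast_spec):
        y = rng.normal(1, 2, 80)
        a = fit_single_group(y, fast_spec(draws_per_chain=200, warmup=100))
        b = fit_single_group(y, fast_spec(draws_per_chain=200, warmup=100))
        for name in a.names():
            assert np.array_equal(a.params[name], b.params[name])

    def test_zero_variance_data_rejected_with_variable_name(self, fast_spec):
        with pytest.raises(DegenerateDataError, match="handwash"):
            fit_single_group(np.ones(30), fast_spec(), variable="handwash")

    def test_tiny_sample_rejected(self, fast_spec):
        with pytest.raises(ModelError, match="at least 5"):
            fit_single_group([1.0, 2.0], fast_spec())

    def test_diffuse_data_posterior_sd_near_prior_scale(self, rng, fast_spec):
        # n=5 with enormous spread: the explicit mu prior should dominate
        y = rng.normal(0, 1e6, 5)
        post = fit_single_group(
            y, fast_spec(mu_prior=(0.0, 10.0), draws_per_chain=2000, warmup=500)
        )
        sd = post.stacked("mu").std()
        assert 1.0 < sd < 100.0


class TestTwoGroup:
    def test_identical_groups_difference_contains_zero(self, rng, fast_spec):
        y = rng.normal(0.3, 1.0, 120)
        post = fit_two_group(y, y, fast_spec("two_group", draws_per_chain=500, warmup=200))
        diff = post.stacked("mu2") - post.stacked("mu1")
        h = hdi(diff)
        assert h.lower < 0 < h.upper

    def test_unit_shift_recovered(self, rng, fast_spec):
        y1 = rng.normal(0, 1, 500)
        y2 = rng.normal(1, 1, 500)
        post = fit_two_group(y1, y2, fast_spec("two_group", draws_per_chain=600, warmup=250))
        med = np.median(post.stacked("mu2") - post.stacked("mu1"))
        assert 0.8 <= med <= 1.2

    def test_swapping_groups_negates_the_difference(self, rng, fast_spec):
        y1 = rng.normal(0, 1, 200)
        y2 = rng.normal(0.7, 1.3, 200)
        spec = fast_spec("two_group", draws_per_chain=600, warmup=250)
        a = fit_two_group(y1, y2, spec)
        b = fit_two_group(y2, y1, spec)
        d1 = np.median(a.stacked("mu2") - a.stacked("mu1"))
        d2 = np.median(b.stacked("mu2") - b.stacked("mu1"))
        assert d1 == pytest.approx(-d2, abs=0.05)

    def test_group_specific_scales_are_estimated(self, rng, fast_spec):
        y1 = rng.normal(0, 1, 400)
        y2 = rng.normal(0, 3, 400)
        post = fit_two_group(y1, y2, fast_spec("two_group", draws_per_chain=500, warmup=250))
        assert np.median(post.stacked("sigma1")) == pytest.approx(1.0, abs=0.25)
        assert np.median(post.stacked("sigma2")) == pytest.approx(3.0, abs=0.6)


class TestMultiGroup:
    def test_null_groups_deflections_contain_zero(self, rng, fast_spec):
        groups = {g: rng.normal(0, 1, 150) for g in ("a", "b", "c")}
        post = fit_multi_group(groups, fast_spec("multi_group", draws_per_chain=500, warmup=250))
        for g in groups:
            h = hdi(post.stacked(f"beta[{g}]"))
            assert h.lower < 0 < h.upper

    def test_cell_means_recovered_within_tolerance(self, rng, fast_spec):
        truth = {"a": 0.0, "b": 0.0, "c": 1.0}
        groups = {g: rng.normal(m, 1.0, 300) for g, m in truth.items()}
        post = fit_multi_group(groups, fast_spec("multi_group", draws_per_chain=600, warmup=250))
        for g, m in truth.items():
            assert np.median(post.stacked(f"mu[{g}]")) == pytest.approx(m, abs=0.15)

    def test_deflections_sum_to_zero_at_every_draw(self, rng, fast_spec):
        groups = {g: rng.normal(i, 1, 80) for i, g in enumerate("abcd")}
        post = fit_multi_group(groups, fast_spec("multi_group", draws_per_chain=300, warmup=150))
        total = sum(post.params[f"beta[{g}]"] for g in groups)
        assert np.abs(total).max() < 1e-10

    def test_cell_means_equal_grand_mean_plus_deflection(self, rng, fast_spec):
        groups = {g: rng.normal(i, 1, 60) for i, g in enumerate("abc")}
        post = fit_multi_group(groups, fast_spec("multi_group", draws_per_chain=300, warmup=150))
        for g in groups:
            recon = post.params["beta0"] + post.params[f"beta[{g}]"]
            assert np.allclose(recon, post.params[f"mu[{g}]"])

    def test_matches_single_group_fits_on_large_balanced_groups(self, rng, fast_spec):
        groups = {g: rng.normal(m, 1.0, 700) for g, m in (("a", 0.0), ("b", 0.6))}
        multi = fit_multi_group(groups, fast_spec("multi_group", draws_per_chain=800, warmup=300))
        for g, y in groups.items():
            single = fit_single_group(y, fast_spec(draws_per_chain=800, warmup=300))
            m_multi = np.median(multi.stacked(f"mu[{g}]"))
            m_single = np.median(single.stacked("mu"))
            # generous 3x Monte-Carlo error bound at this chain length
            assert m_multi == pytest.approx(m_single, abs=0.05)

    def test_six_member_group_still_fits(self, rng, fast_spec):
        groups = {"SP": rng.normal(0, 1, 6), "HC": rng.normal(0, 1, 300)}
        post = fit_multi_group(groups, fast_spec("multi_group", draws_per_chain=300, warmup=150))
        assert np.isfinite(post.stacked("mu[SP]")).all()

    def test_single_member_group_rejected_by_name(self, rng, fast_spec):
        groups = {"ok": rng.normal(0, 1, 50), "tiny": np.array([1.0])}
        with pytest.raises(ModelError, match="tiny"):
            fit_multi_group(groups, fast_spec("multi_group"))


class TestRegression:
    def test_slope_recovered(self, rng, fast_spec):
        x = rng.normal(0, 1, 500)
        y = 2.0 * x + rng.normal(0, 0.5, 500)
        post = fit_regression(y, x, fast_spec("regression", draws_per_chain=600, warmup=250),
                              names=["x"])
        assert 1.8 <= np.median(post.stacked("b[x]")) <= 2.2

    def test_intercept_only_matches_single_group(self, rng, fast_spec):
        y = rng.normal(0.4, 1.0, 400)
        reg = fit_regression(y, np.empty((400, 0)),
                             fast_spec("regression", draws_per_chain=800, warmup=300), names=[])
        single = fit_single_group(y, fast_spec(draws_per_chain=800, warmup=300))
        assert np.median(reg.stacked("intercept")) == pytest.approx(
            np.median(single.stacked("mu")), abs=0.05
        )

    def test_negative_binary_effect_has_mass_below_zero(self, rng, fast_spec):
        x = (rng.random(2000) < 0.5).astype(float)
        y = -0.3 * x + rng.normal(0, 1, 2000)
        post = fit_regression(y, x, fast_spec("regression", draws_per_chain=600, warmup=250),
                              names=["relationship"])
        frac_below = np.mean(post.stacked("b[relationship]") < 0)
        assert frac_below >= 0.95

    def test_collinear_design_rejected_with_column_names(self, rng, fast_spec):
        x1 = rng.normal(0, 1, 100)
        X = np.column_stack([x1, 2 * x1])
        with pytest.raises(ModelError, match="collinear"):
            fit_regression(rng.normal(0, 1, 100), X, fast_spec("regression"),
                           names=["age", "age_doubled"])


class TestSpecValidation:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec(model_kind="bogus")
        with pytest.raises(ModelError):
            ModelSpec(chains=1)
        with pytest.raises(ModelError):
            ModelSpec(nu_rate=0)
        with pytest.raises(ModelError):
            ModelSpec(sigma_prior_single=(2.0, 1.0))
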
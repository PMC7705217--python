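"""HDI, effect sizes, ROPE decisions, posterior fractions, MD-vs-HC contrast."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from robustchange.inference import (
    EffectSizePosterior,
    HDInterval,
    InferenceError,
    RopeSpec,
    contrast_md_vs_hc,
    effect_size_single,
    effect_size_two,
    hdi,
    posterior_fractions,
    rope_decision,
)
from robustchange.models import ModelSpec, PosteriorSamples


def effect_from_hdi(lo, hi, n=4000):
    """Draws spread uniformly so their 95% HDI is ~[lo, hi]; for verdict tests."""
    pad = (hi - lo) * 0.025
    draws = np.linspace(lo - pad, hi + pad, n).reshape(2, -1)
    return EffectSizePosterior(draws, float(np.median(draws)), HDInterval(lo, hi))


class TestHDI:
    def test_point_mass_collapses_to_point(self):
        h = hdi(np.full(100, 3.25))
        assert (h.lower, h.upper) == (3.25, 3.25)

    def test_standard_normal_endpoints_match_analytic_quantiles(self, rng):
        draws = rng.standard_normal(1_000_000)
        h = hdi(draws, 0.95)
        assert h.lower == pytest.approx(-1.959964, abs=0.05)
        assert h.upper == pytest.approx(+1.959964, abs=0.05)

    def test_full_mass_returns_min_max(self, rng):
        draws = rng.normal(size=500)
        h = hdi(draws, 1.0)
        assert (h.lower, h.upper) == (draws.min(), draws.max())

    def test_width_grows_with_mass(self, rng):
        draws = rng.standard_normal(20_000)
        widths = [hdi(draws, m).width for m in (0.5, 0.8, 0.95, 1.0)]
        assert widths == sorted(widths)

    def test_skewed_sample_hdi_is_narrower_than_central_interval(self, rng):
        draws = rng.exponential(size=200_000)
        h = hdi(draws, 0.95)
        central = np.quantile(draws, [0.025, 0.975])
        assert h.width < central[1] - central[0]
        assert h.lower == pytest.approx(0.0, abs=0.01)

    def test_rejects_empty_and_nan(self):
        with pytest.raises(InferenceError):
            hdi([])
        with pytest.raises(InferenceError):
            hdi([1.0, np.nan, 2.0])

    def test_matches_arviz_on_gaussian_mixture(self, rng):
        az = pytest.importorskip("arviz")
        draws = np.concatenate([rng.normal(0, 1, 60_000), rng.normal(0.5, 1.2, 40_000)])
        ours = hdi(draws, 0.95)
        theirs = az.hdi(draws, hdi_prob=0.95)
        assert ours.lower == pytest.approx(theirs[0], abs=0.02)
        assert ours.upper == pytest.approx(theirs[1], abs=0.02)


class TestEffectSizes:
    def test_point_mass_reproduces_printed_depression_row(self):
        # posterior medians mu=2.34, sigma=5.87 print delta 0.40
        eff = effect_size_single(np.full((2, 50), 2.34), np.full((2, 50), 5.87))
        assert eff.median == pytest.approx(0.40, abs=0.015)

    def test_zero_mu_gives_zero_delta(self, rng):
        eff = effect_size_single(np.zeros((2, 100)), rng.uniform(1, 3, (2, 100)))
        assert np.all(eff.delta_draws == 0)

    def test_correlated_draws_match_elementwise_ratio_oracle(self, rng):
        mu = rng.normal(1, 0.2, (4, 500))
        sigma = np.abs(mu) + rng.uniform(0.5, 1.5, (4, 500))
        eff = effect_size_single(mu, sigma)
        brute = np.median([m / s for m, s in zip(mu.ravel(), sigma.ravel())])
        assert eff.median == pytest.approx(brute, abs=1e-12)

    def test_two_group_unit_case(self):
        shape = (2, 10)
        eff = effect_size_two(
            np.zeros(shape), np.ones(shape), np.ones(shape), np.ones(shape)
        )
        assert np.allclose(eff.delta_draws, 1.0)

    def test_two_group_root_mean_variance_denominator(self):
        shape = (2, 10)
        eff = effect_size_two(
            np.zeros(shape), np.full(shape, 5.0), np.full(shape, 3.0), np.full(shape, 4.0)
        )
        assert np.allclose(eff.delta_draws, 5.0 / np.sqrt(12.5))

    def test_swapping_groups_negates_delta(self, rng):
        m1, m2 = rng.normal(size=(2, 200)), rng.normal(1, 1, (2, 200))
        s1, s2 = rng.uniform(1, 2, (2, 200)), rng.uniform(1, 2, (2, 200))
        a = effect_size_two(m1, m2, s1, s2)
        b = effect_size_two(m2, m1, s2, s1)
        assert np.allclose(a.delta_draws, -b.delta_draws)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InferenceError):
            effect_size_single(np.zeros((2, 10)), np.ones((2, 11)))


class TestRopeDecision:
    @pytest.mark.parametrize(
        "lo,hi,verdict",
        [
            (-0.9, -0.5, "accept_alternative"),  # disjoint left
            (-0.5, 0.0, "inconclusive"),         # overlaps left bound
            (-0.15, 0.1, "accept_null"),         # contained
            (-0.6, 0.7, "inconclusive"),         # contains the ROPE
            (0.1, 0.5, "inconclusive"),          # overlaps right bound
            (0.31, 0.48, "accept_alternative"),  # disjoint right
        ],
    )
    def test_verdicts_on_all_qualitative_configurations(self, lo, hi, verdict):
        assert rope_decision(effect_from_hdi(lo, hi)).verdict == verdict

    def test_boundary_touching_hdi_counts_as_contained(self):
        # closed-ROPE reading: an HDI of [-0.20, 0.01] still accepts the null
        assert rope_decision(effect_from_hdi(-0.20, 0.01)).verdict == "accept_null"

    def test_verdict_invariant_to_joint_affine_rescaling(self, rng):
        draws = rng.normal(0.1, 0.1, (2, 4000))
        eff = lambda d: EffectSizePosterior(d, float(np.median(d)), hdi(d))
        base = rope_decision(eff(draws), RopeSpec(-0.2, 0.2))
        scaled = rope_decision(eff(draws * 7.5), RopeSpec(-1.5, 1.5))
        assert base.verdict == scaled.verdict

    def test_constructed_mass_placement_is_reported_exactly(self):
        rope = RopeSpec(-0.2, 0.2)
        draws = np.concatenate(
            [np.full(250, -1.0), np.full(500, 0.0), np.full(250, 1.0)]
        ).reshape(2, -1)
        above0, below, inside, above = posterior_fractions(draws, rope)
        assert (below, inside, above) == (25.0, 50.0, 25.0)
        assert above0 == 25.0

    def test_in_rope_percentage_reproduced_from_known_placement(self):
        rope = RopeSpec(-0.2, 0.2)
        n = 1000
        k = 598
        draws = np.concatenate([np.zeros(k), np.full(n - k, 2.0)])
        _, _, inside, _ = posterior_fractions(draws, rope)
        assert inside == pytest.approx(59.8)

    def test_all_positive_point_mass_fractions(self):
        above0, below, inside, above = posterior_fractions(np.full(100, 0.5), RopeSpec())
        assert (above0, below, inside, above) == (100.0, 0.0, 0.0, 100.0)

    def test_symmetric_draws_split_mass_around_zero(self, rng):
        d = rng.standard_normal(200_000)
        above0, *_ = posterior_fractions(d, RopeSpec())
        assert above0 == pytest.approx(50.0, abs=1.0)

    @given(st.floats(-0.5, 0.5), st.floats(0.05, 0.5))
    def test_rope_fractions_always_sum_to_100(self, center, spread):
        rng = np.random.default_rng(7)
        d = rng.normal(center, spread, 5000)
        _, below, inside, above = posterior_fractions(d, RopeSpec())
        assert below + inside + above == pytest.approx(100.0, abs=1e-9)


def fake_multigroup_posterior(mu_by_group, sigma_by_group, n=6000):
    rng = np.random.default_rng(11)
    params = {}
    for g, m in mu_by_group.items():
        params[f"mu[{g}]"] = rng.normal(m, 0.02, (2, n // 2))
        params[f"sigma[{g}]"] = np.abs(rng.normal(sigma_by_group[g], 0.02, (2, n // 2)))
    spec = ModelSpec(model_kind="multi_group", chains=2, draws_per_chain=n // 2)
    return PosteriorSamples(params, spec, group_labels=tuple(mu_by_group))


class TestContrast:
    def test_identical_groups_contain_zero(self):
        mus = {g: 0.5 for g in ("GAD", "DP", "HC")}
        sig = {g: 1.0 for g in ("GAD", "DP", "HC")}
        post = fake_multigroup_posterior(mus, sig)
        eff, dec, raw = contrast_md_vs_hc(post, ["GAD", "DP"], "HC")
        assert hdi(raw).lower < 0 < hdi(raw).upper
        assert dec.verdict == "accept_null"

    def test_unit_separation_recovers_delta_one(self):
        mus = {"GAD": 1.0, "DP": 1.0, "ED": 1.0, "HC": 0.0}
        sig = {g: 1.0 for g in mus}
        post = fake_multigroup_posterior(mus, sig)
        eff, dec, _ = contrast_md_vs_hc(post, ["GAD", "DP", "ED"], "HC")
        assert eff.median == pytest.approx(1.0, abs=0.1)
        assert dec.verdict == "accept_alternative"

    def test_weighted_equals_unweighted_under_balance(self):
        mus = {"GAD": 0.8, "DP": 0.4, "HC": 0.0}
        sig = {g: 1.0 for g in mus}
        post = fake_multigroup_posterior(mus, sig)
        eq, *_ = contrast_md_vs_hc(post, ["GAD", "DP"], "HC")
        wt, *_ = contrast_md_vs_hc(post, ["GAD", "DP"], "HC", weights={"GAD": 5, "DP": 5})
        assert eq.median == pytest.approx(wt.median, abs=1e-12)

    def test_unknown_group_rejected(self):
        post = fake_multigroup_posterior({"GAD": 0, "HC": 0}, {"GAD": 1, "HC": 1})
        with pytest.raises(InferenceError, match="XX"):
            contrast_md_vs_hc(post, ["XX"], "HC")
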
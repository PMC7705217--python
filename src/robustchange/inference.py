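"""Posterior decision layer: HDIs, standardized effect sizes, and ROPE verdicts.

The analysis reports, for every parameter of interest, the posterior median,
the 95% highest-density interval (HDI, the narrowest interval holding the
stated posterior mass), and a three-way hypothesis decision against a region
of practical equivalence (ROPE) on the effect-size scale:

* accept the null when the HDI lies completely within the ROPE,
* accept the alternative when the HDI lies completely outside it,
* otherwise the result is inconclusive.

ROPE bounds default to -0.2 < delta < 0.2 and containment is evaluated on
the closed interval, so an HDI endpoint that exactly touches a ROPE bound
still counts as inside.  Alongside the verdict, the fractions of posterior
mass above zero and below/inside/above the ROPE are reported, which lets
trends be read off even when the decision is inconclusive.

Effect sizes are ``delta = mu / sigma`` for a single group and
``delta = (mu2 - mu1) / sqrt((sigma1^2 + sigma2^2) / 2)`` for two groups,
propagated per draw (the summary is the median of per-draw ratios, not the
ratio of medians).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import PosteriorSamples

__all__ = [
    "HDInterval",
    "RopeSpec",
    "RopeDecision",
    "EffectSizePosterior",
    "InferenceError",
    "hdi",
    "effect_size_single",
    "effect_size_two",
    "rope_decision",
    "posterior_fractions",
    "contrast_md_vs_hc",
]


class InferenceError(ValueError):
    """Invalid posterior input to the decision layer."""


@dataclass(frozen=True)
class HDInterval:
    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.mass <= 1):
            raise InferenceError("mass must be in (0, 1]")
        if self.lower > self.upper:
            raise InferenceError("HDI lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class RopeSpec:
    """Region of practical equivalence on the effect-size scale."""

    lower: float = -0.2
    upper: float = 0.2

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise InferenceError("ROPE lower bound must be < upper bound")


@dataclass(frozen=True)
class RopeDecision:
    hdi: HDInterval
    rope: RopeSpec
    verdict: str  # accept_null | accept_alternative | inconclusive
    pct_above_zero: float
    pct_below_rope: float
    pct_in_rope: float
    pct_above_rope: float


@dataclass
class EffectSizePosterior:
    """Per-draw standardized effect with its median and HDI summary."""

    delta_draws: np.ndarray  # (chains, draws)
    median: float
    hdi: HDInterval

    def stacked(self) -> np.ndarray:
        return self.delta_draws.reshape(-1)


def hdi(draws, mass: float = 0.95) -> HDInterval:
    """Narrowest contiguous interval over sorted draws containing >= mass of them.

    With ``mass = 1`` this is simply [min, max].
    """
    x = np.asarray(draws, dtype=float).reshape(-1)
    if x.size < 2:
        raise InferenceError("HDI requires at least 2 draws")
    if not np.isfinite(x).all():
        raise InferenceError("HDI input contains non-finite draws")
    if not (0 < mass <= 1):
        raise InferenceError("mass must be in (0, 1]")
    x = np.sort(x)
    n = x.size
    k = int(np.ceil(mass * n))
    if k >= n:
        return HDInterval(float(x[0]), float(x[-1]), mass)
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HDInterval(float(x[i]), float(x[i + k - 1]), mass)


def _summarize(delta: np.ndarray, mass: float) -> EffectSizePosterior:
    return EffectSizePosterior(delta, float(np.median(delta)), hdi(delta, mass))


def effect_size_single(mu_draws, sigma_draws, mass: float = 0.95) -> EffectSizePosterior:
    """Per-draw delta = mu / sigma for a single-group change model."""
    mu = np.atleast_2d(np.asarray(mu_draws, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma_draws, dtype=float))
    if mu.shape != sigma.shape:
        raise InferenceError(f"shape mismatch: mu {mu.shape} vs sigma {sigma.shape}")
    if (sigma <= 0).any():
        raise InferenceError("sigma draws must be positive")
    return _summarize(mu / sigma, mass)


def effect_size_two(mu1, mu2, sigma1, sigma2, mass: float = 0.95) -> EffectSizePosterior:
    """Per-draw delta = (mu2 - mu1) / sqrt((sigma1^2 + sigma2^2) / 2)."""
    arrs = [np.atleast_2d(np.asarray(a, dtype=float)) for a in (mu1, mu2, sigma1, sigma2)]
    if len({a.shape for a in arrs}) != 1:
        raise InferenceError("all draw arrays must share one shape")
    m1, m2, s1, s2 = arrs
    if (s1 <= 0).any() or (s2 <= 0).any():
        raise InferenceError("sigma draws must be positive")
    delta = (m2 - m1) / np.sqrt((s1**2 + s2**2) / 2.0)
    return _summarize(delta, mass)


def posterior_fractions(delta_draws, rope: RopeSpec = RopeSpec(), reference: float = 0.0):
    """Percentages of posterior mass above `reference` and below/in/above the ROPE.

    'In' uses the closed interval [lower, upper]; the three ROPE fractions
    sum to 100 exactly (up to float rounding).
    """
    d = np.asarray(delta_draws, dtype=float).reshape(-1)
    if d.size == 0:
        raise InferenceError("empty draw array")
    pct_above_zero = float(np.mean(d > reference) * 100.0)
    pct_below = float(np.mean(d < rope.lower) * 100.0)
    pct_above = float(np.mean(d > rope.upper) * 100.0)
    pct_in = float(np.mean((d >= rope.lower) & (d <= rope.upper)) * 100.0)
    return pct_above_zero, pct_below, pct_in, pct_above


def rope_decision(delta: EffectSizePosterior, rope: RopeSpec = RopeSpec()) -> RopeDecision:
    """Three-way verdict comparing the delta HDI against the (closed) ROPE."""
    h = delta.hdi
    if h.lower >= rope.lower and h.upper <= rope.upper:
        verdict = "accept_null"
    elif h.upper < rope.lower or h.lower > rope.upper:
        verdict = "accept_alternative"
    else:
        verdict = "inconclusive"
    above0, below, inside, above = posterior_fractions(delta.delta_draws, rope)
    return RopeDecision(h, rope, verdict, above0, below, inside, above)


def contrast_md_vs_hc(
    posterior: PosteriorSamples,
    md_groups: list[str],
    hc_group: str = "HC",
    rope: RopeSpec = RopeSpec(),
    mass: float = 0.95,
    weights: dict[str, float] | None = None,
) -> tuple[EffectSizePosterior, RopeDecision, np.ndarray]:
    """Pooled mental-disorder groups vs healthy controls, per draw.

    ``mu_MD`` is the (by default unweighted; pass per-group ``weights`` for
    an n-weighted version) mean of the disorder-group cell means, and
    ``sigma_MD`` the root-mean of the disorder-group variances (matching
    weights).  The standardized contrast then runs through the two-group
    effect size and ROPE machinery.

    Returns (effect-size posterior, decision, raw mu_MD - mu_HC draws).
    """
    if not md_groups:
        raise InferenceError("md_groups must be non-empty")
    for g in list(md_groups) + [hc_group]:
        if f"mu[{g}]" not in posterior.params:
            raise InferenceError(f"unknown group label {g!r} in posterior")
    if weights is None:
        w = np.full(len(md_groups), 1.0 / len(md_groups))
    else:
        w = np.array([weights[g] for g in md_groups], dtype=float)
        w = w / w.sum()

    mu_md = sum(wi * posterior.params[f"mu[{g}]"] for wi, g in zip(w, md_groups))
    var_md = sum(wi * posterior.params[f"sigma[{g}]"] ** 2 for wi, g in zip(w, md_groups))
    mu_hc = posterior.params[f"mu[{hc_group}]"]
    sig_hc = posterior.params[f"sigma[{hc_group}]"]

    effect = effect_size_two(mu_hc, mu_md, sig_hc, np.sqrt(var_md), mass)
    # convention: contrast = MD minus HC
    decision = rope_decision(effect, rope)
    return effect, decision, mu_md - mu_hc
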
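"""MCMC convergence assessment and the remediation policy for heavy-tail fits.

Effective sample size follows the classic formula ``N / (1 + 2 * sum(rho_k))``
with the autocorrelation sum truncated by Geyer's initial-positive-sequence
rule, combined across chains through the between/within variance estimate
(so chains stuck in different places yield small ESS).  The potential scale
reduction factor (PSRF, Gelman-Rubin) uses the split-chain variant: each
chain is halved before comparing between- and within-chain variance, which
also flags trends inside a single chain.

A fit passes the convergence gate when every parameter of interest reaches
the ESS target (default 10,000) and stays below the PSRF threshold (default
1.05).  Failing fits of t-noise models are typically over-compensating for
outliers: the normality parameter nu piles up near zero and drags mu and
sigma toward zero with it.  The remediation policy therefore escalates a
floor on nu (none -> 1 -> 2) and refits once per escalation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import PosteriorSamples

__all__ = [
    "ParameterDiagnostics",
    "DiagnosticsReport",
    "DiagnosticsError",
    "effective_sample_size",
    "gelman_rubin",
    "lag1_autocorrelation",
    "chain_overlap",
    "diagnose",
    "convergence_gate",
    "GateDecision",
]

#: Escalating floors applied to nu when a fit fails the gate.
NU_FLOOR_LADDER = (1.0, 2.0)


class DiagnosticsError(ValueError):
    """Invalid diagnostics input."""


def _as_chains(draws) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise DiagnosticsError("expected a chains x draws array")
    return arr


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT (standard for ESS)."""
    n = x.size
    xc = x - x.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conj(f), size)[:n].real / n
    return acov


def effective_sample_size(draws) -> float:
    """Autocorrelation-adjusted count of independent-equivalent draws.

    Chains are combined through the pooled variance estimate (within-chain
    variance plus a between-chain term), so disagreement between chains
    deflates the ESS.  A constant chain has no information and returns 0.
    """
    chains = _as_chains(draws)
    m, n = chains.shape
    if n < 10:
        raise DiagnosticsError("need at least 10 draws per chain")

    acovs = np.stack([_autocov(c) for c in chains])
    w = acovs[:, 0].mean()  # mean within-chain variance (biased)
    if w <= 0:
        return 0.0
    if m > 1:
        b_over_n = chains.mean(axis=1).var(ddof=1)
        var_plus = w * (n - 1) / n + b_over_n
    else:
        var_plus = w * (n - 1) / n

    rho = 1.0 - (w - acovs.mean(axis=0)) / var_plus  # rho[0] == ~1
    # Geyer initial positive sequence: sum lag pairs until a pair goes negative
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        k += 2
    ess = m * n / tau
    return float(max(ess, 0.0))


def gelman_rubin(draws) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half; the PSRF is
    ``sqrt(((n-1)/n * W + B/n) / W)`` over the resulting 2m half-chains.
    Values near 1 indicate the chains sample one stationary distribution.
    """
    chains = _as_chains(draws)
    m, n = chains.shape
    if m < 2:
        raise DiagnosticsError("PSRF requires at least 2 chains")
    half = n // 2
    if half < 2:
        raise DiagnosticsError("chains too short to split")
    split = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0  # degenerate constant chains: no spread to compare
    b_over_n = split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b_over_n
    return float(np.sqrt(var_plus / w))


def lag1_autocorrelation(draws) -> float:
    """Mean over chains of the lag-1 autocorrelation."""
    chains = _as_chains(draws)
    vals = []
    for c in chains:
        v = c.var()
        if v <= 0:
            vals.append(0.0)
            continue
        xc = c - c.mean()
        vals.append(float(np.dot(xc[:-1], xc[1:]) / (c.size * v)))
    return float(np.mean(vals))


def chain_overlap(draws, bins: int = 50) -> float:
    """Mean pairwise histogram overlap between chains (1 = identical densities).

    A mechanized stand-in for visually comparing per-chain density plots;
    reported but not used as a gate.
    """
    chains = _as_chains(draws)
    m = chains.shape[0]
    if m < 2:
        return 1.0
    lo, hi = chains.min(), chains.max()
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    hists = [np.histogram(c, bins=edges, density=False)[0] / c.size for c in chains]
    overlaps = [
        np.minimum(hists[i], hists[j]).sum()
        for i in range(m)
        for j in range(i + 1, m)
    ]
    return float(np.mean(overlaps))


@dataclass
class ParameterDiagnostics:
    ess: float
    psrf: float
    lag1_autocorr: float
    overlap: float


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence summary for one fit."""

    per_parameter: dict[str, ParameterDiagnostics]
    ess_target: float = 10_000.0
    psrf_threshold: float = 1.05
    parameters_of_interest: tuple[str, ...] = ()
    notes: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        poi = self.parameters_of_interest or tuple(self.per_parameter)
        for name in poi:
            d = self.per_parameter[name]
            if d.ess < self.ess_target or d.psrf > self.psrf_threshold:
                return False
        return True

    def worst(self) -> dict[str, float]:
        poi = self.parameters_of_interest or tuple(self.per_parameter)
        return {
            "min_ess": min(self.per_parameter[p].ess for p in poi),
            "max_psrf": max(self.per_parameter[p].psrf for p in poi),
        }


def _interest_set(posterior: PosteriorSamples) -> tuple[str, ...]:
    """Location/scale/coefficient parameters; nu is inspected but not gated."""
    return tuple(
        nm
        for nm in posterior.names()
        if nm != "nu"
    )


def diagnose(
    posterior: PosteriorSamples,
    ess_target: float = 10_000.0,
    psrf_threshold: float = 1.05,
) -> DiagnosticsReport:
    """Compute ESS, split-chain PSRF, lag-1 autocorrelation and chain overlap."""
    per = {}
    notes = []
    for nm, arr in posterior.params.items():
        if np.allclose(arr, arr.reshape(-1)[0]):
            per[nm] = ParameterDiagnostics(0.0, 1.0, 1.0, 1.0)
            notes.append(f"{nm}: degenerate (constant) chain")
            continue
        per[nm] = ParameterDiagnostics(
            ess=effective_sample_size(arr),
            psrf=gelman_rubin(arr),
            lag1_autocorr=lag1_autocorrelation(arr),
            overlap=chain_overlap(arr),
        )
    return DiagnosticsReport(per, ess_target, psrf_threshold, _interest_set(posterior), notes)


@dataclass(frozen=True)
class GateDecision:
    action: str  # "pass" | "remediate" | "fail"
    nu_floor: float | None = None
    report: DiagnosticsReport | None = None


def convergence_gate(report: DiagnosticsReport, current_floor: float | None = None) -> GateDecision:
    """Pass a converged fit, else escalate the nu floor (none -> 1 -> 2).

    After the ladder is exhausted the decision is a hard failure carrying the
    report; the caller refits once per escalation step.  The gate is
    idempotent on passing reports.
    """
    if report.converged:
        return GateDecision("pass", current_floor, report)
    for floor in NU_FLOOR_LADDER:
        if current_floor is None or floor > current_floor:
            return GateDecision("remediate", floor, report)
    return GateDecision("fail", current_floor, report)
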
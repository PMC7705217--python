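"""Seeded synthetic cohorts with the statistical structure the change analysis assumes.

The generator emulates an 11-group clinical survey with two assessments per
participant (a retrospective pre-pandemic baseline T0 and a during-outbreak
measurement T1): bounded questionnaire sum scores, heavy-tailed individual
change drawn from a location-scale Student-t, group-specific spread, and the
sociodemographic covariates the regression stage consumes (age, gender,
relationship status).

Ground truth is explicit: for every (group, variable) pair the configuration
carries the true mean change ``mu_true``, spread ``sigma_true`` (raw score
units) and normality parameter ``nu_true``, so the implied standardized
effect ``delta_true = mu_true / sigma_true`` is known exactly and downstream
estimation can be validated by recovery.

One cohort seed expands into independent per-(group, variable) substreams, so
adding a variable to the configuration does not perturb existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "DEFAULT_GROUP_SIZES",
    "CohortConfig",
    "CohortTable",
    "CohortError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Diagnostic group labels: ten self-identified mental-disorder groups
#: (generalized anxiety, panic/agoraphobia, illness anxiety, social anxiety,
#: depression, OCD, body dysmorphic, eating, schizophrenia-spectrum, other)
#: plus healthy controls.
GROUPS = ("GAD", "PA", "IA", "SAD", "DP", "OCD", "BDD", "ED", "SP", "other", "HC")

#: Default per-group sample sizes of the surveyed cohort.
DEFAULT_GROUP_SIZES = {
    "GAD": 135,
    "PA": 83,
    "IA": 30,
    "SAD": 86,
    "DP": 586,
    "OCD": 47,
    "BDD": 16,
    "ED": 62,
    "SP": 6,
    "other": 156,
    "HC": 1026,
}

#: Default true change for the psychosocial-stress sum score (0-20 range):
#: location/spread per group in raw score units, heavy-tail parameter 30
#: (nearly normal individual change).  The depression group's (1.55, 3.10)
#: corresponds to a standardized change of 0.50.
DEFAULT_STRESS_CHANGE = {
    ("GAD", "stress"): (1.58, 2.98, 30.0),
    ("PA", "stress"): (1.49, 2.68, 30.0),
    ("IA", "stress"): (1.24, 2.69, 30.0),
    ("SAD", "stress"): (1.03, 2.73, 30.0),
    ("DP", "stress"): (1.55, 3.10, 30.0),
    ("OCD", "stress"): (0.92, 2.79, 30.0),
    ("BDD", "stress"): (1.64, 2.62, 30.0),
    ("ED", "stress"): (1.38, 2.75, 30.0),
    ("SP", "stress"): (1.35, 2.62, 30.0),
    ("other", "stress"): (0.83, 2.43, 30.0),
    ("HC", "stress"): (1.56, 2.66, 30.0),
}

_COVARIATE_DEFAULTS = {
    # age: mean/SD of the surveyed sample, truncated at the age-18 inclusion
    # criterion; gender/relationship as marginal proportions (female, in a
    # relationship).
    "age_mean": 33.2,
    "age_sd": 12.7,
    "age_min": 18.0,
    "p_female": 0.81,
    "p_relationship": 0.64,
}


class CohortError(ValueError):
    """Invalid cohort configuration or cohort file."""


@dataclass
class CohortConfig:
    """Ground-truth specification for one synthetic cohort.

    ``variables`` lists (name, score_min, score_max) triples; ``true_change``
    maps (group, variable) to (mu_true, sigma_true, nu_true); ``baseline``
    maps variable to (location, spread) of the truncated-normal T0 model.
    ``clamp`` disables/enables clamping-and-rounding to the integer score
    grid — disable it for calibration studies, because clamping biases
    effect-size recovery near the range edges.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    variables: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("stress", 0, 20)]
    )
    true_change: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_CHANGE)
    )
    baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"stress": (8.0, 4.0)}
    )
    covariates: dict[str, float] = field(default_factory=lambda: dict(_COVARIATE_DEFAULTS))
    clamp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        var_names = {v[0] for v in self.variables}
        for g, n in self.group_sizes.items():
            if n < 1:
                raise CohortError(f"group {g}: size must be >= 1, got {n}")
        for name, lo, hi in self.variables:
            if lo >= hi:
                raise CohortError(f"variable {name}: score_min must be < score_max")
        for (g, v), (mu, sigma, nu) in self.true_change.items():
            if g not in self.group_sizes:
                raise CohortError(f"true_change references unknown group {g!r}")
            if v not in var_names:
                raise CohortError(f"true_change references unknown variable {v!r}")
            if sigma <= 0:
                raise CohortError(f"({g}, {v}): sigma_true must be > 0")
            if nu <= 0:
                raise CohortError(f"({g}, {v}): nu_true must be > 0")
        for v in self.baseline:
            if v not in var_names:
                raise CohortError(f"baseline references unknown variable {v!r}")

    def delta_true(self, group: str, variable: str) -> float:
        """True standardized change mu_true / sigma_true."""
        mu, sigma, _ = self.true_change[(group, variable)]
        return mu / sigma


@dataclass
class CohortTable:
    """Per-participant cohort records backed by a pandas DataFrame.

    Columns: ``participant_id``, ``group``, per variable ``<var>_t0``,
    ``<var>_t1``, ``<var>_diff`` (exactly t1 - t0), and covariates ``age``,
    ``gender``, ``relationship``.
    """

    data: pd.DataFrame
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        required = ["participant_id", "group"]
        for v in self.variables:
            required += [f"{v}_t0", f"{v}_t1"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise CohortError(f"cohort table missing column(s): {', '.join(missing)}")
        for v in self.variables:
            diff_col = f"{v}_diff"
            expected = self.data[f"{v}_t1"] - self.data[f"{v}_t0"]
            if diff_col not in self.data.columns:
                self.data[diff_col] = expected
            elif not np.allclose(self.data[diff_col], expected):
                raise CohortError(f"{diff_col} is not t1 - t0")

    def __len__(self) -> int:
        return len(self.data)

    def group_sizes(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()

    def diffs(self, variable: str, group: str | None = None) -> np.ndarray:
        """Change scores t1 - t0 for one variable, optionally one group."""
        df = self.data if group is None else self.data[self.data["group"] == group]
        if f"{variable}_diff" not in df.columns:
            raise CohortError(f"unknown variable {variable!r}")
        return df[f"{variable}_diff"].to_numpy(dtype=float)

    def diffs_by_group(self, variable: str) -> dict[str, np.ndarray]:
        return {
            g: self.diffs(variable, g)
            for g in self.data["group"].unique()
        }


def _substream(seed: int, group: str, variable: str) -> np.random.Generator:
    """Independent, platform-stable RNG stream per (group, variable)."""
    key = (
        zlib.crc32(group.encode()) & 0x7FFFFFFF,
        zlib.crc32(variable.encode()) & 0x7FFFFFFF,
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a cohort under the configured ground truth; deterministic given seed.

    T0 comes from a truncated normal on the score range; individual change is
    location-scale Student-t(nu_true, mu_true, sigma_true); T1 = T0 + change.
    With ``clamp`` on, both time points are clamped to the range and rounded
    to the integer grid before the difference is formed.
    """
    groups = list(config.group_sizes)
    n_total = sum(config.group_sizes.values())

    frame: dict[str, object] = {
        "participant_id": np.arange(1, n_total + 1),
        "group": np.repeat(groups, [config.group_sizes[g] for g in groups]),
    }

    for name, lo, hi in config.variables:
        b_loc, b_spread = config.baseline.get(name, ((lo + hi) / 2.0, (hi - lo) / 5.0))
        t0_all, t1_all = [], []
        for g in groups:
            n = config.group_sizes[g]
            rng = _substream(config.seed, g, name)
            a, b = (lo - b_loc) / b_spread, (hi - b_loc) / b_spread
            t0 = stats.truncnorm.rvs(a, b, loc=b_loc, scale=b_spread, size=n, random_state=rng)
            if (g, name) in config.true_change:
                mu, sigma, nu = config.true_change[(g, name)]
            else:
                mu, sigma, nu = 0.0, max((hi - lo) / 10.0, 1e-6), 30.0
            change = mu + sigma * rng.standard_t(nu, size=n)
            t1 = t0 + change
            if config.clamp:
                t0 = np.rint(np.clip(t0, lo, hi))
                t1 = np.rint(np.clip(t1, lo, hi))
            t0_all.append(t0)
            t1_all.append(t1)
        frame[f"{name}_t0"] = np.concatenate(t0_all)
        frame[f"{name}_t1"] = np.concatenate(t1_all)
        frame[f"{name}_diff"] = frame[f"{name}_t1"] - frame[f"{name}_t0"]

    cov_rng = _substream(config.seed, "__covariates__", "")
    cov = config.covariates
    a = (cov["age_min"] - cov["age_mean"]) / cov["age_sd"]
    frame["age"] = np.round(
        stats.truncnorm.rvs(
            a, np.inf, loc=cov["age_mean"], scale=cov["age_sd"], size=n_total,
            random_state=cov_rng,
        ),
        1,
    )
    frame["gender"] = np.where(
        cov_rng.random(n_total) < cov["p_female"], "female", "male"
    )
    frame["relationship"] = (cov_rng.random(n_total) < cov["p_relationship"]).astype(int)

    df = pd.DataFrame(frame)
    return CohortTable(df, tuple(v[0] for v in config.variables))


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV (diff columns included for auditability)."""
    table.data.to_csv(path, index=False)


def read_cohort(path: str | Path, variables: list[str] | None = None) -> CohortTable:
    """Read a cohort CSV back; validates schema and the diff = t1 - t0 identity.

    ``variables`` defaults to every ``<var>_t0`` / ``<var>_t1`` column pair
    found in the file.
    """
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise CohortError(f"{path}: missing required column 'group'")
    if "participant_id" not in df.columns:
        raise CohortError(f"{path}: missing required column 'participant_id'")

    if variables is None:
        variables = sorted(
            c[: -len("_t0")]
            for c in df.columns
            if c.endswith("_t0") and f"{c[:-3]}_t1" in df.columns
        )
        if not variables:
            raise CohortError(f"{path}: no <var>_t0/<var>_t1 column pairs found")

    for v in variables:
        for col in (f"{v}_t0", f"{v}_t1"):
            if col not in df.columns:
                raise CohortError(f"{path}: missing required column '{col}'")
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna() & df[col].notna()
            if bad.any() or df[col].isna().any():
                row = int(np.argmax((bad | df[col].isna()).to_numpy()))
                raise CohortError(f"{path}: non-numeric score in '{col}' at row {row}")
            df[col] = numeric

    unknown = set(df["group"].unique()) - set(GROUPS)
    if unknown:
        row = int(np.argmax(df["group"].isin(unknown).to_numpy()))
        raise CohortError(
            f"{path}: unknown group label(s) {sorted(unknown)} (first at row {row})"
        )

    return CohortTable(df, tuple(variables))
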
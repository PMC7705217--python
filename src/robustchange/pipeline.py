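"""Config-driven orchestration of the full change analysis.

One run takes a cohort (read from CSV or simulated under explicit ground
truth), computes T1 - T0 difference scores, fits the requested robust
models per variable, applies the convergence gate with its nu-floor
remediation ladder, turns posteriors into effect sizes and ROPE verdicts,
and emits report tables with the column layout

    label, mu, sigma, HDI_mu LL, HDI_mu UL, delta, HDI_delta LL,
    HDI_delta UL, % delta > 0, % < ROPE, % in ROPE, % > ROPE, verdict

rounded to two decimals (decisions are always made on unrounded values).
Every variable is analyzed independently — no multiplicity adjustment is
applied, by design: each questionnaire is treated as its own estimation
problem, and readers should weigh the set of per-variable verdicts
accordingly.

Identical config + seed reproduces byte-identical reports; the manifest
records the config, per-fit seeds and package version so every output is
traceable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptives import difference_scores, frequency_table, round_half_up
from .diagnostics import convergence_gate, diagnose
from .inference import (
    RopeSpec,
    contrast_md_vs_hc,
    effect_size_single,
    hdi,
    posterior_fractions,
    rope_decision,
)
from .models import (
    ModelSpec,
    fit_multi_group,
    fit_regression,
    fit_single_group,
)
from .synthetic import CohortConfig, CohortTable, generate_cohort, read_cohort, write_cohort

__all__ = [
    "PlanEntry",
    "RunConfig",
    "PipelineError",
    "ReportRow",
    "VariableResult",
    "run_pipeline",
    "render_reports",
    "load_config",
]

logger = logging.getLogger("robustchange")

REPORT_COLUMNS = [
    "label",
    "mu",
    "sigma",
    "hdi_mu_ll",
    "hdi_mu_ul",
    "delta",
    "hdi_delta_ll",
    "hdi_delta_ul",
    "pct_delta_gt_0",
    "pct_below_rope",
    "pct_in_rope",
    "pct_above_rope",
    "verdict",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and offending input."""


@dataclass
class PlanEntry:
    """One analysis: a variable and how to model it.

    kind "by_group" fits the ANOVA-like multi-group model and reports one
    row per group plus a pooled disorder-groups vs healthy-controls contrast;
    kind "pooled" fits a single-group model to all difference scores (used
    for instruments administered to one diagnostic group only).
    """

    variable: str
    kind: str = "by_group"
    groups: list[str] | None = None
    rope: tuple[float, float] = (-0.2, 0.2)
    hdi_mass: float = 0.95
    hc_group: str = "HC"

    def __post_init__(self) -> None:
        if self.kind not in ("by_group", "pooled"):
            raise PipelineError(f"plan for {self.variable!r}: unknown kind {self.kind!r}")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    input_path: str | None = None
    simulate: CohortConfig | None = None
    plan: list[PlanEntry] = field(default_factory=lambda: [PlanEntry("stress")])
    regression: dict | None = None  # {"variable": ..., "covariates": [...]}
    chains: int = 4
    draws_per_chain: int = 12500
    warmup: int = 1000
    ess_target: float = 10_000.0
    psrf_threshold: float = 1.05
    out_dir: str = "run_output"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise PipelineError("config must give exactly one of input_path or simulate")


@dataclass
class ReportRow:
    label: str
    mu: float
    sigma: float | None
    hdi_mu_ll: float
    hdi_mu_ul: float
    delta: float
    hdi_delta_ll: float
    hdi_delta_ul: float
    pct_delta_gt_0: float
    pct_below_rope: float
    pct_in_rope: float
    pct_above_rope: float
    verdict: str


@dataclass
class VariableResult:
    variable: str
    rows: list[ReportRow]
    diagnostics: dict
    nu_floor_used: float | None


def _fit_seed(seed: int, *parts: str) -> int:
    return zlib.crc32(("|".join(map(str, parts)) + f"|{seed}").encode()) & 0x7FFFFFFF


def _spec(config: RunConfig, kind: str, seed: int, nu_floor: float | None) -> ModelSpec:
    return ModelSpec(
        model_kind=kind,
        nu_floor=nu_floor,
        chains=config.chains,
        draws_per_chain=config.draws_per_chain,
        warmup=config.warmup,
        seed=seed,
    )


def _fit_with_gate(fit_fn, config: RunConfig, kind: str, seed: int, label: str):
    """Fit, diagnose, and walk the nu-floor remediation ladder if needed."""
    floor: float | None = None
    while True:
        post = fit_fn(_spec(config, kind, seed, floor))
        report = diagnose(post, config.ess_target, config.psrf_threshold)
        decision = convergence_gate(report, floor)
        if decision.action == "pass":
            return post, report, floor
        if decision.action == "remediate":
            logger.info(
                "%s: non-convergent (min ESS %.0f, max PSRF %.3f); refitting with nu >= %g",
                label, report.worst()["min_ess"], report.worst()["max_psrf"], decision.nu_floor,
            )
            floor = decision.nu_floor
            continue
        raise PipelineError(
            f"stage fit[{label}]: non-convergent after nu-floor ladder; "
            f"worst diagnostics {report.worst()}"
        )


def _single_group_rows(diffs, config: RunConfig, entry: PlanEntry, label: str) -> tuple[ReportRow, dict, float | None]:
    post, report, floor = _fit_with_gate(
        lambda spec: fit_single_group(diffs, spec, variable=entry.variable),
        config, "single_group", _fit_seed(config.seed, entry.variable, label), label,
    )
    rope = RopeSpec(*entry.rope)
    eff = effect_size_single(post.params["mu"], post.params["sigma"], entry.hdi_mass)
    dec = rope_decision(eff, rope)
    h_mu = hdi(post.stacked("mu"), entry.hdi_mass)
    row = ReportRow(
        label,
        float(np.median(post.stacked("mu"))),
        float(np.median(post.stacked("sigma"))),
        h_mu.lower, h_mu.upper,
        eff.median, eff.hdi.lower, eff.hdi.upper,
        dec.pct_above_zero, dec.pct_below_rope, dec.pct_in_rope, dec.pct_above_rope,
        dec.verdict,
    )
    return row, _report_dict(report), floor


def _by_group_rows(cohort: CohortTable, config: RunConfig, entry: PlanEntry) -> VariableResult:
    groups = entry.groups or [g for g in cohort.data["group"].unique()]
    diffs = {g: cohort.diffs(entry.variable, g) for g in groups}
    for g, d in diffs.items():
        if d.size < 2:
            raise PipelineError(f"stage fit[{entry.variable}]: group {g!r} has n={d.size} < 2")
    label = f"{entry.variable}/by_group"
    post, report, floor = _fit_with_gate(
        lambda spec: fit_multi_group(diffs, spec),
        config, "multi_group", _fit_seed(config.seed, entry.variable, "by_group"), label,
    )
    rope = RopeSpec(*entry.rope)
    rows = []
    for g in groups:
        mu_d, sig_d = post.params[f"mu[{g}]"], post.params[f"sigma[{g}]"]
        eff = effect_size_single(mu_d, sig_d, entry.hdi_mass)
        dec = rope_decision(eff, rope)
        h_mu = hdi(mu_d, entry.hdi_mass)
        rows.append(
            ReportRow(
                g,
                float(np.median(mu_d)), float(np.median(sig_d)),
                h_mu.lower, h_mu.upper,
                eff.median, eff.hdi.lower, eff.hdi.upper,
                dec.pct_above_zero, dec.pct_below_rope, dec.pct_in_rope, dec.pct_above_rope,
                dec.verdict,
            )
        )
    md = [g for g in groups if g != entry.hc_group]
    if entry.hc_group in groups and md:
        eff, dec, raw = contrast_md_vs_hc(post, md, entry.hc_group, rope, entry.hdi_mass)
        h_mu = hdi(raw, entry.hdi_mass)
        rows.append(
            ReportRow(
                f"Contrast MD vs. {entry.hc_group}",
                float(np.median(raw)), None,
                h_mu.lower, h_mu.upper,
                eff.median, eff.hdi.lower, eff.hdi.upper,
                dec.pct_above_zero, dec.pct_below_rope, dec.pct_in_rope, dec.pct_above_rope,
                dec.verdict,
            )
        )
    return VariableResult(entry.variable, rows, _report_dict(report), floor)


def _regression_result(cohort: CohortTable, config: RunConfig, reg: dict) -> VariableResult:
    variable = reg.get("variable", "stress")
    covariates = reg.get("covariates", ["age", "gender", "relationship"])
    y = difference_scores(cohort.data, variable)
    cols = []
    for cov in covariates:
        if cov not in cohort.data.columns:
            raise PipelineError(f"stage regression: missing covariate column {cov!r}")
        col = cohort.data[cov]
        if col.dtype == object:
            col = (col == col.iloc[0]).astype(float)  # binary indicator vs first level
        col = col.to_numpy(dtype=float)
        if cov == "age":
            col = col - col.mean()
        cols.append(col)
    X = np.column_stack(cols)
    label = f"{variable}~{'+'.join(covariates)}"
    post, report, floor = _fit_with_gate(
        lambda spec: fit_regression(y, X, spec, names=list(covariates)),
        config, "regression", _fit_seed(config.seed, variable, "regression"), label,
    )
    rows = []
    rope = RopeSpec()
    for cov in covariates:
        b = post.params[f"b[{cov}]"]
        h = hdi(b, 0.95)
        above0, below, inside, above = posterior_fractions(b, rope)
        rows.append(
            ReportRow(
                f"b[{cov}]",
                float(np.median(b)), None, h.lower, h.upper,
                float("nan"), float("nan"), float("nan"),
                above0, below, inside, above, "",
            )
        )
    return VariableResult(f"regression_{variable}", rows, _report_dict(report), floor)


def _report_dict(report) -> dict:
    return {
        "converged": report.converged,
        "ess_target": report.ess_target,
        "psrf_threshold": report.psrf_threshold,
        "per_parameter": {
            nm: dataclasses.asdict(d) for nm, d in report.per_parameter.items()
        },
        "notes": report.notes,
    }


def render_reports(results: list[VariableResult], out_dir: str | Path) -> list[Path]:
    """Write one CSV per analyzed variable with 2-decimal rounded values."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for res in results:
        rows = []
        for r in res.rows:
            d = dataclasses.asdict(r)
            for k, v in d.items():
                if isinstance(v, float):
                    d[k] = "" if not np.isfinite(v) else f"{round_half_up(v):.2f}"
                elif v is None:
                    d[k] = ""
            rows.append(d)
        df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        path = out_dir / f"report_{res.variable}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)

    if config.simulate is not None:
        logger.info("stage simulate: generating cohort (seed %d)", config.simulate.seed)
        cohort = generate_cohort(config.simulate)
        write_cohort(cohort, out / "cohort.csv")
    else:
        logger.info("stage load: reading %s", config.input_path)
        try:
            cohort = read_cohort(config.input_path)
        except Exception as e:
            raise PipelineError(f"stage load: {e}") from e

    freq = frequency_table(cohort.data, "group", denominator_definition="final sample")
    freq.rows.to_csv(out / "group_frequencies.csv", index=False)

    results: list[VariableResult] = []
    for entry in config.plan:
        if f"{entry.variable}_t0" not in cohort.data.columns:
            raise PipelineError(f"stage plan: variable {entry.variable!r} not in cohort")
        logger.info("stage fit: %s (%s)", entry.variable, entry.kind)
        try:
            if entry.kind == "by_group":
                results.append(_by_group_rows(cohort, config, entry))
            else:
                diffs = cohort.diffs(entry.variable)
                row, diag, floor = _single_group_rows(diffs, config, entry, entry.variable)
                results.append(VariableResult(entry.variable, [row], diag, floor))
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage fit[{entry.variable}]: {e}") from e

    if config.regression is not None:
        logger.info("stage regression")
        results.append(_regression_result(cohort, config, config.regression))

    report_paths = render_reports(results, out / "reports")

    diagnostics = {r.variable: r.diagnostics | {"nu_floor_used": r.nu_floor_used} for r in results}
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "chains": config.chains,
        "draws_per_chain": config.draws_per_chain,
        "warmup": config.warmup,
        "ess_target": config.ess_target,
        "input": config.input_path or "simulated",
        "plan": [dataclasses.asdict(e) for e in config.plan],
        "reports": [p.name for p in report_paths],
    }
    if config.simulate is not None:
        manifest["simulate_seed"] = config.simulate.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("run complete: %s", out)
    return out


def _setup_logging(out: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file.

    Top-level keys mirror RunConfig fields; a `simulate:` block maps onto
    CohortConfig (group_sizes, variables, true_change keyed "group/variable",
    baseline, clamp, seed), and `plan:` is a list of PlanEntry mappings.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulate" in raw:
        s = raw["simulate"] or {}
        kwargs = {}
        if "group_sizes" in s:
            kwargs["group_sizes"] = {str(k): int(v) for k, v in s["group_sizes"].items()}
        if "variables" in s:
            kwargs["variables"] = [tuple(v) for v in s["variables"]]
        if "true_change" in s:
            kwargs["true_change"] = {
                tuple(k.split("/")): tuple(v) for k, v in s["true_change"].items()
            }
        if "baseline" in s:
            kwargs["baseline"] = {k: tuple(v) for k, v in s["baseline"].items()}
        for key in ("clamp", "seed"):
            if key in s:
                kwargs[key] = s[key]
        sim = CohortConfig(**kwargs)

    plan = [
        PlanEntry(
            variable=p["variable"],
            kind=p.get("kind", "by_group"),
            groups=p.get("groups"),
            rope=tuple(p.get("rope", (-0.2, 0.2))),
            hdi_mass=float(p.get("hdi_mass", 0.95)),
        )
        for p in raw.get("plan", [{"variable": "stress"}])
    ]

    return RunConfig(
        input_path=raw.get("input_path"),
        simulate=sim,
        plan=plan,
        regression=raw.get("regression"),
        chains=int(raw.get("chains", 4)),
        draws_per_chain=int(raw.get("draws_per_chain", 5000)),
        warmup=int(raw.get("warmup", 1000)),
        ess_target=float(raw.get("ess_target", 10_000)),
        psrf_threshold=float(raw.get("psrf_threshold", 1.05)),
        out_dir=raw.get("out_dir", "run_output"),
        seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"),
    )
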
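"""End-to-end run orchestration: simulate/load -> QC -> summarize -> associate.

A run is driven by a :class:`RunConfig` (usually parsed from YAML), analyses
each population separately — populations are never pooled — and writes a
report bundle: per-population descriptive summaries, a population
comparison, a characteristics comparison, the full OR grid
(predictor x outcome x population) and a manifest that reconstructs the run
(canonical config hash, seed, library versions).  A failed model fit leaves
an explicitly marked empty cell with the failure reason instead of aborting
the grid.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationResult,
    OUTCOME_COLUMNS,
    complete_case,
    compare_populations,
    fit_univariable_binary,
    fit_univariable_ordinal,
    impute_cohort,
    pool_rubin,
    summarize_cohort,
)
from .cohort import CHARACTERISTIC_COLUMNS, Cohort, read_cohort
from .errors import ThrombocharError, ValidationError
from .synthetic import CohortSimConfig, inject_missingness, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PopulationSpec:
    """One population: either a cohort CSV path or a simulation config."""

    name: str
    cohort_path: str | None = None
    simulate: CohortSimConfig | None = None
    missing_rates: dict = field(default_factory=dict)
    missing_mechanism: str = "MCAR"

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.simulate is None):
            raise ValidationError(
                f"population {self.name!r}: give exactly one of cohort_path/simulate"
            )


@dataclass
class RunConfig:
    populations: list[PopulationSpec]
    predictors: list[str] = field(default_factory=lambda: list(CHARACTERISTIC_COLUMNS))
    outcomes: list[str] = field(default_factory=lambda: ["mrs", "fps", "etici"])
    impute: bool = True
    m_imputations: int = 5
    informers: list[str] | None = None
    seed: int = 0
    out_dir: str = "thrombochar_run"

    def __post_init__(self) -> None:
        if len(self.populations) < 1:
            raise ValidationError("at least one population required")
        unknown = [p for p in self.predictors if p not in CHARACTERISTIC_COLUMNS]
        if unknown:
            raise ValidationError(f"unknown predictors: {unknown}")
        unknown = [o for o in self.outcomes if o not in OUTCOME_COLUMNS]
        if unknown:
            raise ValidationError(f"unknown outcomes: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pops = []
        for p in raw.pop("populations"):
            sim = p.pop("simulate", None)
            if sim is not None:
                sim = CohortSimConfig(**sim)
            pops.append(PopulationSpec(simulate=sim, **p))
        return cls(populations=pops, **raw)


@dataclass
class ReportBundle:
    summaries: dict[str, pd.DataFrame]
    comparison: pd.DataFrame | None
    characteristics_comparison: pd.DataFrame | None
    or_grid: pd.DataFrame
    manifest: dict
    cohorts: dict[str, Cohort]


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_population(spec: PopulationSpec, seed_offset: int) -> Cohort:
    if spec.cohort_path is not None:
        cohort = read_cohort(spec.cohort_path)
    else:
        cohort = simulate_cohort(spec.simulate)
    if spec.missing_rates:
        cohort = inject_missingness(
            cohort, spec.missing_rates, mechanism=spec.missing_mechanism,
            seed=seed_offset,
        )
    return cohort


def _fit_cell(cohort, predictor, outcome, config: RunConfig, seed: int) -> AssociationResult:
    outcome_col = OUTCOME_COLUMNS[outcome]
    has_missing = cohort.df[[predictor, outcome_col]].isna().any().any()
    if config.impute and has_missing:
        completed = impute_cohort(
            cohort, m=config.m_imputations, informers=config.informers, seed=seed
        )
        fits = []
        for comp in completed:
            if outcome == "mrs":
                fits.append(fit_univariable_ordinal(comp, predictor))
            else:
                fits.append(fit_univariable_binary(comp, predictor, outcome))
        return pool_rubin(fits)
    cc = complete_case(cohort, [predictor, outcome_col])
    if outcome == "mrs":
        return fit_univariable_ordinal(cc, predictor)
    return fit_univariable_binary(cc, predictor, outcome)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute a full configured run and write all artifacts to out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("thrombochar")
    root.addHandler(handler)
    failures: list[dict] = []
    try:
        cohorts: dict[str, Cohort] = {}
        for i, spec in enumerate(config.populations):
            cohorts[spec.name] = _load_population(spec, seed_offset=config.seed + 7919 * (i + 1))
            logger.info("population %s: %d records", spec.name, len(cohorts[spec.name]))

        summaries = {}
        for name, cohort in cohorts.items():
            df = summarize_cohort(cohort)
            summaries[name] = df
            df.to_csv(out_dir / f"summary_{name}.csv", index=False)

        comparison = characteristics_comparison = None
        if len(cohorts) >= 2:
            names = list(cohorts)
            comparison = compare_populations(cohorts[names[0]], cohorts[names[1]])
            comparison.to_csv(out_dir / "comparison.csv", index=False)
            characteristics_comparison = comparison[
                comparison["variable"].isin(CHARACTERISTIC_COLUMNS)
            ].reset_index(drop=True)
            characteristics_comparison.to_csv(out_dir / "characteristics.csv", index=False)

        rows = []
        for pop_i, (name, cohort) in enumerate(cohorts.items()):
            for predictor in config.predictors:
                for outcome in config.outcomes:
                    cell_seed = config.seed + 104729 * (pop_i + 1)
                    base = {
                        "population": name, "predictor": predictor, "outcome": outcome,
                    }
                    try:
                        res = _fit_cell(cohort, predictor, outcome, config, cell_seed)
                        rows.append({
                            **base,
                            "scaling": res.scaling, "model": res.model,
                            "adjusted": res.adjusted, "or": res.or_,
                            "ci_low": res.ci_low, "ci_high": res.ci_high,
                            "p_value": res.p_value, "n_used": res.n_used,
                            "pooled": res.pooled, "status": "ok", "reason": "",
                        })
                    except ThrombocharError as exc:
                        logger.warning("cell %s failed: %s", base, exc)
                        failures.append({**base, "reason": str(exc)})
                        rows.append({
                            **base, "scaling": "", "model": "", "adjusted": "",
                            "or": "", "ci_low": "", "ci_high": "", "p_value": "",
                            "n_used": "", "pooled": "", "status": "failed",
                            "reason": str(exc),
                        })
        or_grid = pd.DataFrame(rows)
        or_grid.to_csv(out_dir / "or_grid.csv", index=False)

        import scipy
        import statsmodels

        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "populations": {
                name: {"n": len(c), "provenance": c.provenance}
                for name, c in cohorts.items()
            },
            "predictors": config.predictors,
            "outcomes": config.outcomes,
            "impute": config.impute,
            "m_imputations": config.m_imputations,
            "failures": failures,
            "versions": {
                "thrombochar": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return ReportBundle(
            summaries=summaries,
            comparison=comparison,
            characteristics_comparison=characteristics_comparison,
            or_grid=or_grid,
            manifest=manifest,
            cohorts=cohorts,
        )
    finally:
        root.removeHandler(handler)
        handler.close()
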
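"""Cohort I/O and end-to-end orchestration.

The cohort interchange format is a plain UTF-8 CSV with one row per woman:
``age_years``, ``bmi``, the 23 risk-factor flag columns of
:mod:`obcmi.core` and the 15 outcome indicator columns of
:mod:`obcmi.outcomes`, booleans encoded 0/1.  Reads are validated
(missing columns, non-binary flag values and out-of-range ages are
reported with their row/column); writes round-trip exactly.

:func:`run_pipeline` executes one reproducible analysis run: obtain a
cohort (from file or the synthetic generator), score it under one or both
systems, evaluate both composite outcomes, and write a deterministic
report bundle (scored cohort, odds-ratio table, cutoff table, NNH table at
the configured cutoffs, cumulative score frequencies, summary JSON and a
run manifest).  All tables are computed before anything is written, so a
failing stage leaves no partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import evaluation
from .core import (
    FLAG_FIELDS,
    RiskFactorProfile,
    ScoringSystem,
    get_system,
    score_cohort,
)
from .outcomes import CFM_INDICATORS, SMM_INDICATORS, OutcomeRecord
from .simulate import SimulationConfig, SyntheticCohort, generate_cohort

__all__ = [
    "Cohort",
    "RunConfig",
    "PipelineResult",
    "SchemaError",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_pipeline",
]

logger = logging.getLogger("obcmi")

PROFILE_COLUMNS: tuple[str, ...] = ("age_years", "bmi", *FLAG_FIELDS)
OUTCOME_COLUMNS: tuple[str, ...] = (*SMM_INDICATORS, *CFM_INDICATORS)
ALL_COLUMNS: tuple[str, ...] = (*PROFILE_COLUMNS, *OUTCOME_COLUMNS)
_FLAG_COLUMNS = (*FLAG_FIELDS, *OUTCOME_COLUMNS)


class SchemaError(ValueError):
    """A cohort file does not match the expected schema."""


@dataclass(frozen=True)
class Cohort:
    """Profiles and outcomes for one cohort, row-aligned."""

    profiles: tuple[RiskFactorProfile, ...]
    outcomes: tuple[OutcomeRecord, ...]

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.outcomes):
            raise ValueError("profiles and outcomes must have equal length")

    def __len__(self) -> int:
        return len(self.profiles)

    @classmethod
    def from_synthetic(cls, synthetic: SyntheticCohort) -> "Cohort":
        return cls(profiles=synthetic.profiles, outcomes=synthetic.outcomes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for profile, outcome in zip(self.profiles, self.outcomes):
            row: dict[str, object] = {
                "age_years": profile.age_years,
                "bmi": profile.bmi,
            }
            for f in FLAG_FIELDS:
                row[f] = int(getattr(profile, f))
            for f in OUTCOME_COLUMNS:
                row[f] = int(getattr(outcome, f))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(ALL_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        missing = sorted(set(ALL_COLUMNS) - set(df.columns))
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        unknown = sorted(set(df.columns) - set(ALL_COLUMNS))
        if unknown:
            warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)

        for col in _FLAG_COLUMNS:
            values = pd.to_numeric(df[col], errors="coerce")
            bad = values.index[~values.isin([0, 1])]
            if len(bad):
                raise SchemaError(
                    f"column '{col}' must be 0/1; offending rows: {list(bad[:5])}"
                )

        profiles, outcomes = [], []
        for idx, row in df.iterrows():
            try:
                profiles.append(
                    RiskFactorProfile(
                        age_years=int(row["age_years"]),
                        bmi=float(row["bmi"]),
                        **{f: bool(int(row[f])) for f in FLAG_FIELDS},
                    )
                )
                outcomes.append(
                    OutcomeRecord(**{f: bool(int(row[f])) for f in OUTCOME_COLUMNS})
                )
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"row {idx}: {exc}") from exc
        return cls(profiles=tuple(profiles), outcomes=tuple(outcomes))

    def smm(self) -> np.ndarray:
        return np.array([o.smm for o in self.outcomes], dtype=bool)

    def cfm(self) -> np.ndarray:
        return np.array([o.cfm for o in self.outcomes], dtype=bool)


def read_cohort_csv(path) -> Cohort:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path)
    cohort = Cohort.from_frame(df)
    logger.info("read %d records from %s", len(cohort), path)
    return cohort


def write_cohort_csv(cohort: Cohort | SyntheticCohort, path) -> None:
    """Write a cohort CSV that round-trips through :func:`read_cohort_csv`."""
    if isinstance(cohort, SyntheticCohort):
        cohort = Cohort.from_synthetic(cohort)
    cohort.to_frame().to_csv(path, index=False)
    logger.info("wrote %d records to %s", len(cohort), path)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """One reproducible analysis run.

    Exactly one of ``input_csv`` (an existing cohort file) or ``simulation``
    (generator settings) supplies the cohort.  ``cutoffs`` are the score
    thresholds for the NNH table; the default {3, 4, 5} brackets the
    recommended high-risk flag at score >= 4.
    """

    model_config = ConfigDict(frozen=True)

    input_csv: Path | None = None
    simulation: SimulationConfig | None = None
    systems: tuple[Literal["validated", "modified"], ...] = ("validated", "modified")
    outcomes: tuple[Literal["smm", "cfm"], ...] = ("smm", "cfm")
    cutoffs: tuple[int, ...] = (3, 4, 5)
    out_dir: Path = Path("obcmi_run")
    precision: int = Field(default=1, ge=0, le=6)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_csv or simulation")
        if not self.systems:
            raise ValueError("select at least one scoring system")
        return self


@dataclass(frozen=True)
class PipelineResult:
    """In-memory report bundle plus the paths that were written."""

    cohort: Cohort
    scores: dict[str, np.ndarray]
    or_table: pd.DataFrame
    cutoff_tables: pd.DataFrame
    nnh_table: pd.DataFrame
    cumulative: pd.DataFrame
    summary: dict
    manifest: dict
    paths: dict[str, Path]


def _config_digest(config: RunConfig) -> str:
    payload = config.model_dump(mode="json", exclude={"out_dir"})
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode("utf-8")
    ).hexdigest()


def _outcome_vector(cohort: Cohort, outcome: str) -> np.ndarray:
    return cohort.smm() if outcome == "smm" else cohort.cfm()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Score, evaluate, and report one cohort; see the module docstring."""
    if config.simulation is not None:
        synthetic = generate_cohort(config.simulation)
        cohort = Cohort.from_synthetic(synthetic)
        logger.info("simulated cohort of %d records", len(cohort))
    else:
        cohort = read_cohort_csv(config.input_csv)

    systems: dict[str, ScoringSystem] = {name: get_system(name) for name in config.systems}
    scores = {
        name: np.array([s.value for s in score_cohort(cohort.profiles, system)])
        for name, system in systems.items()
    }
    logger.info("scored %d records under %s", len(cohort), list(scores))

    p = config.precision
    or_rows, cutoff_frames, nnh_rows, cum_frames, summary_models = [], [], [], [], {}
    for sys_name, s in scores.items():
        cum = evaluation.cumulative_frequency(s)
        cum.insert(0, "system", sys_name)
        cum_frames.append(cum)
        for outcome in config.outcomes:
            y = _outcome_vector(cohort, outcome)
            if y.all() or not y.any():
                raise ValueError(
                    f"outcome '{outcome}' has a single class; evaluation is undefined"
                )
            fit = evaluation.fit_per_unit_logistic(s, y)
            roc = evaluation.roc_auc(s, y)
            comparison = evaluation.wilcoxon_rank_sum(s[y], s[~y])
            or_rows.append(
                {
                    "system": sys_name,
                    "outcome": outcome,
                    "n": fit.n,
                    "events": int(y.sum()),
                    "incidence_pct": evaluation.round_percent(100 * y.mean(), p),
                    "or_per_unit": round(fit.or_per_unit, 2),
                    "or_ci_low": round(fit.ci_low, 2),
                    "or_ci_high": round(fit.ci_high, 2),
                    "wald_p": round(fit.wald_p, 4),
                    "auc": round(roc.auc, 2),
                    "auc_ci_low": round(roc.auc_ci_low, 2),
                    "auc_ci_high": round(roc.auc_ci_high, 2),
                    "rank_sum_p": round(comparison.rank_sum_p, 4),
                }
            )
            summary_models[f"{sys_name}_{outcome}"] = {
                "or_per_unit": fit.or_per_unit,
                "auc": roc.auc,
                "median_with_outcome": comparison.group_a.median,
                "median_without_outcome": comparison.group_b.median,
            }

            table = evaluation.cutoff_table_frame(
                evaluation.cutoff_table(s, y), precision=p
            )
            table.insert(0, "outcome", outcome)
            table.insert(0, "system", sys_name)
            cutoff_frames.append(table)

            for cut in config.cutoffs:
                below = s < cut
                if below.sum() == 0 or below.all():
                    continue
                stats_row = evaluation.two_by_two_stats(
                    int(below.sum()),
                    int(y[below].sum()),
                    int((~below).sum()),
                    int(y[~below].sum()),
                    cutoff=float(cut),
                )
                nnh_rows.append(
                    {
                        "system": sys_name,
                        "outcome": outcome,
                        "cutoff": cut,
                        "n_below": int(below.sum()),
                        "events_below": int(y[below].sum()),
                        "n_above": int((~below).sum()),
                        "events_above": int(y[~below].sum()),
                        "risk_below_pct": evaluation.round_percent(
                            100 - stats_row.npv, p
                        ),
                        "risk_above_pct": evaluation.round_percent(stats_row.ppv, p),
                        "rd_pct": evaluation.round_percent(stats_row.rd, p),
                        "rr": evaluation.round_percent(stats_row.rr, p),
                        "rr_ci_low": evaluation.round_percent(stats_row.rr_ci_low, p),
                        "rr_ci_high": evaluation.round_percent(stats_row.rr_ci_high, p),
                        "nnh": evaluation.round_percent(stats_row.nnh, p),
                        "nnh_whole": stats_row.nnh_whole,
                    }
                )

    if len(scores) == 2 and len(cohort) > 1:
        s1, s2 = (scores[name] for name in config.systems)
        for outcome in config.outcomes:
            y = _outcome_vector(cohort, outcome)
            summary_models[f"auc_comparison_p_{outcome}"] = evaluation.compare_auc_paired(
                s1, s2, y
            )

    or_table = pd.DataFrame(or_rows)
    cutoff_tables = pd.concat(cutoff_frames, ignore_index=True)
    nnh_table = pd.DataFrame(nnh_rows)
    cumulative = pd.concat(cum_frames, ignore_index=True)

    try:
        pkg_version = _pkg_version("obcmi")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "package_version": pkg_version,
        "config": config.model_dump(mode="json", exclude={"out_dir"}),
        "config_sha256": _config_digest(config),
        "n_records": len(cohort),
        "seed": config.simulation.seed if config.simulation else None,
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scored = cohort.to_frame()
    for name, s in scores.items():
        scored[f"obcmi_{name}"] = s
    paths = {
        "scored_cohort": out / "scored_cohort.csv",
        "or_table": out / "or_table.csv",
        "cutoff_table": out / "cutoff_table.csv",
        "nnh_table": out / "nnh_table.csv",
        "cumulative_frequency": out / "cumulative_frequency.csv",
        "summary": out / "summary.json",
        "manifest": out / "manifest.json",
    }
    scored.to_csv(paths["scored_cohort"], index=False)
    or_table.to_csv(paths["or_table"], index=False)
    cutoff_tables.to_csv(paths["cutoff_table"], index=False)
    nnh_table.to_csv(paths["nnh_table"], index=False)
    cumulative.to_csv(paths["cumulative_frequency"], index=False)
    paths["summary"].write_text(json.dumps(summary_models, indent=2, sort_keys=True))
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote report bundle to %s", out)

    return PipelineResult(
        cohort=cohort,
        scores=scores,
        or_table=or_table,
        cutoff_tables=cutoff_tables,
        nnh_table=nnh_table,
        cumulative=cumulative,
        summary=summary_models,
        manifest=manifest,
        paths=paths,
    )
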
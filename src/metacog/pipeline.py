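"""End-to-end orchestration: simulate/load -> preprocess -> metrics -> inference.

A run is fully determined by its configuration and seed: the same
(config, seed) pair reproduces every output table byte for byte.  Each
stage logs one line with its input/output row counts.  Outputs land in
one directory per run: ``manifest.json``, ``trials.csv`` (simulate
mode), ``trials_filtered.csv``, ``exclusion.json``, ``subjects.csv``,
``results.csv`` and ``results.json``.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    InferenceResult,
    ancova_group_effect,
    bayes_factor_t,
    mixed_anova_confidence,
    one_way_anova,
    two_sample_t,
)
from .observer_sim import CohortSpec, ObserverParams, simulate_cohort, write_cohort_csv
from .preprocessing import (
    ExclusionReport,
    bin_cohort_confidence,
    detect_outlier_subjects,
    exclude_trials,
)
from .sdt_metrics import summarise_cohort

log = logging.getLogger("metacog")

__all__ = ["RunConfig", "RunReport", "run", "analyze_trials", "read_trial_table", "load_config"]

#: Measures compared across all groups with a one-way ANOVA.
ANOVA_MEASURES = [
    "auroc2",
    "accuracy",
    "mean_orientation_deg",
    "median_rt_ms",
    "dprime",
    "criterion",
    "median_confidence",
]

_SCHEMA = {
    "subject_id": "str",
    "group": "str",
    "block": "int",
    "variance_condition": "float",
    "mean_orientation_deg": "float",
    "stimulus_direction": "cat",
    "response": "cat",
    "rt_ms": "float",
    "confidence": "float",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_mode: str = "simulate"  # "simulate" | "table"
    cohort: CohortSpec | None = None
    input_path: str | None = None
    column_map: Mapping[str, str] | None = None
    n_bins: int = 6
    rt_bounds_ms: tuple[float, float] = (100.0, 1500.0)
    drop_first_block: bool = True
    outlier_rule: str = "lower_fence_1p5"  # or "none"
    bayes_r_scale: float = 1.0
    output_dir: str = "metacog_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in ("simulate", "table"):
            raise ValueError("input_mode must be 'simulate' or 'table'")
        if self.input_mode == "table" and not self.input_path:
            raise ValueError("table mode requires input_path")
        if self.input_mode == "simulate" and self.input_path:
            raise ValueError("exactly one of cohort/input_path may be active")
        if not self.rt_bounds_ms[0] < self.rt_bounds_ms[1]:
            raise ValueError("rt lower bound must be below upper bound")
        if self.outlier_rule not in ("lower_fence_1p5", "none"):
            raise ValueError("outlier_rule must be 'lower_fence_1p5' or 'none'")
        if self.input_mode == "simulate" and self.cohort is None:
            self.cohort = CohortSpec(seed=self.seed)


@dataclass
class RunReport:
    """Manifest of a completed run; every referenced file exists."""

    config: dict
    seed: int
    version: str
    n_subjects: int
    n_trials_simulated: int | None
    exclusion: dict
    files: dict
    timestamp: str | None = None


def load_config(path, seed: int | None = None, output_dir: str | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML/JSON config file.

    Per-group observer parameters live under ``cohort.groups`` as
    mappings of :class:`ObserverParams` field overrides.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, seed=seed, output_dir=output_dir)


def config_from_dict(raw: dict, seed: int | None = None, output_dir: str | None = None) -> RunConfig:
    raw = dict(raw)
    cohort_raw = raw.pop("cohort", None)
    if seed is not None:
        raw["seed"] = seed
    if output_dir is not None:
        raw["output_dir"] = output_dir
    cohort = None
    if cohort_raw is not None:
        cohort_raw = dict(cohort_raw)
        groups = cohort_raw.pop("groups", None)
        if groups is not None:
            cohort_raw["group_params"] = {
                g: ObserverParams(**(overrides or {})) for g, overrides in groups.items()
            }
        cohort_raw.setdefault("seed", raw.get("seed", 0))
        if "variance_conditions" in cohort_raw:
            cohort_raw["variance_conditions"] = tuple(cohort_raw["variance_conditions"])
        cohort = CohortSpec(**cohort_raw)
    if "rt_bounds_ms" in raw:
        raw["rt_bounds_ms"] = tuple(raw["rt_bounds_ms"])
    return RunConfig(cohort=cohort, **raw)


def read_trial_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial table CSV into the canonical schema.

    ``column_map`` maps source column names to canonical ones (how an
    external source-data file is adapted without hard-coded guesses).
    Ambiguous or out-of-range files are rejected with row numbers rather
    than silently coerced.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing columns {missing}")
    problems = []
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad_conf = df.index[(conf < 0) | (conf > 1)]
    problems += [f"row {i + 2}: confidence out of [0,1]" for i in bad_conf[:10]]
    bad_resp = df.index[~df["response"].isin(["left", "right", "missing"]) & df["response"].notna()]
    problems += [f"row {i + 2}: unknown response" for i in bad_resp[:10]]
    bad_stim = df.index[~df["stimulus_direction"].isin(["left", "right"])]
    problems += [f"row {i + 2}: unknown stimulus_direction" for i in bad_stim[:10]]
    if problems:
        raise ValueError(f"invalid trial table {path}: " + "; ".join(problems))
    if "correct" not in df.columns:
        df["correct"] = (df["response"] == df["stimulus_direction"]).astype("Float64")
        df.loc[~df["response"].isin(["left", "right"]), "correct"] = pd.NA
    if "confidence_bin" not in df.columns:
        df["confidence_bin"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


def _auroc2_frame(subjects: pd.DataFrame) -> pd.DataFrame:
    return subjects.dropna(subset=["auroc2"])


def _inference_stage(subjects: pd.DataFrame, config: RunConfig) -> list[InferenceResult]:
    results: list[InferenceResult] = []
    groups = list(pd.unique(subjects["group"]))
    if len(groups) < 2:
        log.info("inference: single group, no between-group statistics")
        return results

    for measure in ANOVA_MEASURES:
        sub = subjects.dropna(subset=[measure])
        if sub.groupby("group").size().min() < 2 or sub["group"].nunique() < 2:
            continue
        results.append(
            one_way_anova(sub[measure], sub["group"], name=f"anova_{measure}")
        )

    auroc = _auroc2_frame(subjects)
    by_group = {g: auroc.loc[auroc["group"] == g, "auroc2"].to_numpy() for g in groups}
    for ga, gb in itertools.combinations(groups, 2):
        if len(by_group[ga]) < 2 or len(by_group[gb]) < 2:
            continue
        results.append(two_sample_t(by_group[ga], by_group[gb], name=f"ttest_auroc2_{ga}_vs_{gb}"))
        results.append(
            bayes_factor_t(
                by_group[ga],
                by_group[gb],
                r_scale=config.bayes_r_scale,
                name=f"bayes_auroc2_{ga}_vs_{gb}",
            )
        )

    covs = subjects.dropna(subset=["auroc2", "dprime", "criterion", "mean_orientation_deg"])
    if covs["group"].nunique() >= 2 and len(covs) > covs["group"].nunique() + 4:
        results.append(
            ancova_group_effect(
                covs["auroc2"],
                covs["group"],
                covs[["dprime", "criterion", "mean_orientation_deg"]],
                name="ancova_auroc2_dprime_c_orientation",
            )
        )

    conf_cells = subjects.dropna(subset=["median_confidence_correct", "median_confidence_error"])
    long = conf_cells.melt(
        id_vars=["subject_id", "group"],
        value_vars=["median_confidence_correct", "median_confidence_error"],
        var_name="correctness",
        value_name="value",
    )
    long["correctness"] = long["correctness"].str.replace("median_confidence_", "", regex=False)
    for ga, gb in itertools.combinations(groups, 2):
        pair = long[long["group"].isin([ga, gb])]
        if pair.groupby("group")["subject_id"].nunique().min() < 2:
            continue
        results.extend(
            mixed_anova_confidence(pair, name_prefix=f"mixed_confidence_{ga}_vs_{gb}")
        )
    return results


def analyze_trials(trials: pd.DataFrame, config: RunConfig):
    """Preprocess, summarise and test a trial table.

    Returns ``(filtered_trials, exclusion_report, subjects, results)``.
    """
    filtered, report = exclude_trials(
        trials, rt_bounds_ms=config.rt_bounds_ms, drop_first_block=config.drop_first_block
    )
    log.info("exclude_trials: %d -> %d rows", report.n_trials_in, report.n_trials_out)
    filtered = bin_cohort_confidence(filtered, n_bins=config.n_bins)
    subjects = summarise_cohort(filtered, n_bins=config.n_bins)
    log.info("summarise: %d subjects", len(subjects))

    if config.outlier_rule == "lower_fence_1p5" and len(subjects) >= 4:
        flagged = detect_outlier_subjects(
            dict(zip(subjects["subject_id"], subjects["accuracy"]))
        )
        if flagged:
            log.info("outlier exclusion: %s", flagged)
            report.excluded_subjects += [
                {"subject_id": s, "reason": "accuracy below lower Tukey fence"} for s in flagged
            ]
            subjects = subjects[~subjects["subject_id"].isin(flagged)].reset_index(drop=True)
            filtered = filtered[~filtered["subject_id"].isin(flagged)]
    for _, row in subjects[subjects["auroc2"].isna()].iterrows():
        report.excluded_subjects.append(
            {"subject_id": row["subject_id"], "reason": "type-II ROC undefined (no error or no correct trials)"}
        )

    results = _inference_stage(subjects, config)
    log.info("inference: %d comparisons", len(results))
    return filtered, report, subjects, results


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all outputs to ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    if config.input_mode == "simulate":
        cohort = config.cohort
        trials = simulate_cohort(cohort)
        log.info("simulate: %d trials, %d subjects", len(trials), trials["subject_id"].nunique())
        write_cohort_csv(trials, out / "trials.csv")
        files["trials"] = "trials.csv"
        n_sim = len(trials)
    else:
        trials = read_trial_table(config.input_path, column_map=config.column_map)
        log.info("read_trial_table: %d rows from %s", len(trials), config.input_path)
        n_sim = None

    filtered, report, subjects, results = analyze_trials(trials, config)

    write_cohort_csv(filtered, out / "trials_filtered.csv")
    subjects.to_csv(out / "subjects.csv", index=False, na_rep="")
    results_df = pd.DataFrame([r.to_dict() for r in results])
    results_df.to_csv(out / "results.csv", index=False, na_rep="")
    (out / "results.json").write_text(json.dumps([r.to_dict() for r in results], indent=2))
    (out / "exclusion.json").write_text(json.dumps(report.to_dict(), indent=2))
    files.update(
        trials_filtered="trials_filtered.csv",
        subjects="subjects.csv",
        results_csv="results.csv",
        results_json="results.json",
        exclusion="exclusion.json",
    )

    cfg_echo = dataclasses.asdict(config)
    if cfg_echo.get("cohort") is not None:
        cfg_echo["cohort"]["group_params"] = {
            g: dataclasses.asdict(p) for g, p in config.cohort.group_params.items()
        }
    manifest = RunReport(
        config=_jsonable(cfg_echo),
        seed=config.seed,
        version=__version__,
        n_subjects=len(subjects),
        n_trials_simulated=n_sim,
        exclusion=report.to_dict(),
        files=files,
    )
    (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    files["manifest"] = "manifest.json"
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
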
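"""Pipeline orchestration: simulate -> clean -> cohort -> outcomes -> fit -> report.

A single YAML config drives all stages; every run writes a manifest listing
the seed, config hash, stage timings, and each output file with its row
count and content hash.  Identical config + seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import cohort as cohort_mod
from . import models, outcomes, registry
from .synthetic_data import SimulationConfig, generate_population

logger = logging.getLogger("opioidcohort")

STAGES = ["simulate", "clean", "cohort", "outcomes", "fit", "report"]
#: upstream artifacts each stage requires (file names in the output directory)
STAGE_INPUTS = {
    "simulate": [],
    "clean": ["fills.csv"],
    "cohort": ["fills_clean.csv", "claims.csv", "spans.csv", "deaths.csv", "demographics.csv"],
    "outcomes": ["fills_clean.csv", "cohort.csv", "index_events.csv", "claims.csv", "spans.csv", "deaths.csv"],
    "fit": ["cohort.csv", "chronic.csv", "survival.csv", "secondary.csv"],
    "report": ["cohort.csv", "chronic.csv", "survival.csv"],
}
STAGE_FOR_INPUT = {
    "fills.csv": "simulate",
    "spans.csv": "simulate",
    "claims.csv": "simulate",
    "deaths.csv": "simulate",
    "demographics.csv": "simulate",
    "fills_clean.csv": "clean",
    "index_events.csv": "cohort",
    "cohort.csv": "cohort",
    "chronic.csv": "outcomes",
    "survival.csv": "outcomes",
    "secondary.csv": "outcomes",
}


class StageDependencyError(RuntimeError):
    pass


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if len(out) and isinstance(out[col].iloc[0], list):
            out[col] = [";".join(v) for v in out[col]]
        elif pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.6g")


def _file_entry(path: Path) -> dict:
    data = path.read_bytes()
    rows = max(data.count(b"\n") - 1, 0) if path.suffix == ".csv" else None
    return {"rows": rows, "sha256": hashlib.sha256(data).hexdigest()}


def _read_dates(path: Path, date_cols: list[str], list_cols: list[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "prescriber_id": str}, keep_default_na=False)
    for col in date_cols:
        df[col] = pd.to_datetime(df[col])
    for col in list_cols:
        df[col] = [[c for c in str(v).split(";") if c] for v in df[col]]
    for col in df.columns:
        if df[col].dtype == object and df[col].isin(["True", "False"]).all() and len(df):
            df[col] = df[col] == "True"
    return df


def run_pipeline(
    config: SimulationConfig | str | Path | dict | None = None,
    outdir: str | Path = "run",
    stages: list[str] | str = "all",
    seed: int | None = None,
    random_effect: bool = False,
    frailty_min_patients: int = 200,
) -> dict:
    """Execute the requested stages and return the run manifest (also written
    as ``manifest.json``).  ``stages`` is ``"all"`` or an ordered subset of
    simulate/clean/cohort/outcomes/fit/report; a missing upstream artifact
    raises :class:`StageDependencyError` naming the stage to run first."""
    if config is None:
        cfg = SimulationConfig()
    elif isinstance(config, SimulationConfig):
        cfg = config
    elif isinstance(config, dict):
        cfg = SimulationConfig.from_dict(config)
    else:
        cfg = SimulationConfig.from_yaml(config)
    if seed is not None:
        cfg = cfg.replace(seed=seed)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = STAGES if stages == "all" else [s for s in STAGES if s in stages]
    if not requested:
        raise ValueError(f"no valid stages in {stages!r}")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
        "files": {},
    }
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _write_csv(df, path)
        written[name] = path

    def require(stage: str) -> None:
        for name in STAGE_INPUTS[stage]:
            if not (outdir / name).exists():
                raise StageDependencyError(
                    f"stage '{stage}' needs {name}; run stage '{STAGE_FOR_INPUT[name]}' first"
                )

    for stage in requested:
        require(stage)
        t0 = time.perf_counter()
        logger.info("running stage: %s", stage)

        if stage == "simulate":
            tables, gt = generate_population(cfg)
            for name, df in [
                ("fills.csv", tables.fills),
                ("spans.csv", tables.spans),
                ("claims.csv", tables.claims),
                ("deaths.csv", tables.deaths),
                ("demographics.csv", tables.demographics),
                ("ground_truth.csv", gt.frame),
            ]:
                emit(name, df)

        elif stage == "clean":
            fills = _read_dates(outdir / "fills.csv", ["fill_date"])
            kept, log = registry.clean_fills(fills)
            emit("fills_clean.csv", kept)
            emit("removal_log.csv", log)

        elif stage == "cohort":
            fills = _read_dates(outdir / "fills_clean.csv", ["fill_date"])
            claims = _read_dates(outdir / "claims.csv", ["service_date"], list_cols=["diagnosis_codes"])
            spans = _read_dates(outdir / "spans.csv", ["start_date", "end_date"])
            deaths = _read_dates(outdir / "deaths.csv", ["death_date"], list_cols=["multiple_causes"])
            demographics = _read_dates(outdir / "demographics.csv", [])
            code_set = registry.load_code_set()
            index_events = cohort_mod.find_index_events(fills, claims, code_set)
            kept, excluded = cohort_mod.apply_enrollment_filter(index_events, spans, deaths)
            cohort = cohort_mod.categorize(kept, demographics, spans, registry.load_mme_table())
            emit("index_events.csv", kept)
            emit("exclusions.csv", excluded)
            emit("cohort.csv", cohort)

        elif stage == "outcomes":
            fills = _read_dates(outdir / "fills_clean.csv", ["fill_date"])
            index_events = _read_dates(outdir / "index_events.csv", ["fill_date", "index_date"])
            claims = _read_dates(outdir / "claims.csv", ["service_date"], list_cols=["diagnosis_codes"])
            spans = _read_dates(outdir / "spans.csv", ["start_date", "end_date"])
            deaths = _read_dates(outdir / "deaths.csv", ["death_date"], list_cols=["multiple_causes"])
            code_set = registry.load_code_set()
            chronic = outcomes.classify_chronic(fills, index_events)
            od = outcomes.detect_overdoses(claims, deaths, code_set, index_events)
            survival = outcomes.compute_survival(
                index_events, spans, od, deaths, study_end=cfg.study_end
            )
            secondary = outcomes.secondary_outcomes(fills, index_events, registry.load_mme_table())
            emit("chronic.csv", chronic)
            emit("overdose_events.csv", od)
            emit("survival.csv", survival)
            emit("secondary.csv", secondary)

        elif stage == "fit":
            cohort = _read_dates(outdir / "cohort.csv", ["index_date"])
            chronic = _read_dates(outdir / "chronic.csv", [])
            survival = _read_dates(outdir / "survival.csv", [])
            secondary = _read_dates(outdir / "secondary.csv", [])
            reports = {
                "model_chronic": models.fit_chronic_logistic(cohort, chronic, random_effect=random_effect),
                "model_cox": models.fit_overdose_cox(cohort, survival),
                "model_zinb": models.fit_cumulative_zinb(cohort, secondary),
            }
            try:
                reports["model_switch"] = models.fit_switch_logistic(cohort, secondary)
            except ValueError as exc:
                logger.warning("switch model skipped: %s", exc)
            try:
                sub_log, sub_cox = models.run_combination_subgroup(cohort, chronic, survival)
                reports["subgroup_chronic"] = sub_log
                reports["subgroup_cox"] = sub_cox
            except ValueError as exc:
                logger.warning("subgroup models skipped: %s", exc)
            for name, rep in reports.items():
                (outdir / f"{name}.json").write_text(rep.to_json())
                (outdir / f"{name}.txt").write_text(rep.to_text() + "\n")
                written[f"{name}.json"] = outdir / f"{name}.json"
                written[f"{name}.txt"] = outdir / f"{name}.txt"

        elif stage == "report":
            cohort = _read_dates(outdir / "cohort.csv", ["index_date"])
            chronic = _read_dates(outdir / "chronic.csv", [])
            survival = _read_dates(outdir / "survival.csv", [])
            t1, t2, t3 = render_tables(cohort, chronic, survival)
            emit("table1.csv", t1)
            emit("table2.csv", t2)
            emit("table3.csv", t3)
            (outdir / "table1.txt").write_text(t1.to_string(index=False, float_format="%.2f") + "\n")
            written["table1.txt"] = outdir / "table1.txt"

        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

    for name, path in sorted(written.items()):
        manifest["files"][name] = _file_entry(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_tables(
    cohort: pd.DataFrame, chronic: pd.DataFrame, survival: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Render the balance table and the two outcome tables.

    Returns (balance, chronic-use counts, overdose counts): per covariate
    level, patient counts and within-group percentages by index drug with
    standardized differences; then outcome/no-outcome counts with the row
    percentage of each level experiencing the outcome."""
    balance = models.balance_table(cohort)

    def outcome_counts(flag: pd.Series, label: str) -> pd.DataFrame:
        df = cohort.copy()
        df["_y"] = flag.to_numpy()
        rows = []
        for cov in [c for c in models.DEFAULT_COVARIATES if c in df.columns]:
            for level in models._ordered_levels(df, cov):
                sub = df[df[cov].astype(str) == level]
                n_yes = int(sub["_y"].sum())
                n_no = int(len(sub) - n_yes)
                rows.append(
                    {
                        "covariate": cov,
                        "level": level,
                        f"no_{label}": n_no,
                        label: n_yes,
                        "row_pct": 100.0 * n_yes / len(sub) if len(sub) else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    chronic_flag = (
        cohort[["patient_id"]]
        .merge(chronic[["patient_id", "chronic_primary"]], on="patient_id", how="left")["chronic_primary"]
        .fillna(False)
        .astype(bool)
    )
    event_flag = (
        cohort[["patient_id"]]
        .merge(survival[["patient_id", "event"]], on="patient_id", how="left")["event"]
        .fillna(False)
        .astype(bool)
    )
    return balance, outcome_counts(chronic_flag, "chronic_use"), outcome_counts(event_flag, "overdose")
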
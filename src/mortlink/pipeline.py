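"""End-to-end orchestration: simulate → link → compose → benchmark → survive.

Each stage reads the previous stage's tables, writes headered
comma-delimited outputs with ISO-8601 dates, and records row counts and
SHA-256 hashes in a run manifest, so a rerun with the same configuration
and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import benchmark as bm
from . import composite as cp
from . import linkage as lk
from . import survival as sv
from .config import config_to_dict
from .simulate import SimulatedData, SimulationConfig, simulate_all

__all__ = ["run_pipeline", "run_study", "validate_against_table",
           "RunManifest", "StudyResult"]

log = logging.getLogger("mortlink")

_DATE_COLS = ("birth_date", "advanced_diagnosis_date", "last_activity_date",
              "true_death_date", "death_date", "gold_death_date")


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict        # stage -> {file: {rows, sha256}}
    versions: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def write_table(df: pd.DataFrame, path: Path) -> dict:
    out = df.copy()
    for col in out.columns:
        if col in _DATE_COLS:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return {"rows": len(out), "sha256": digest}


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in df.columns:
        if col in _DATE_COLS:
            df[col] = pd.to_datetime(df[col])
    return df


@dataclasses.dataclass
class StudyResult:
    """In-memory result of one simulated study run end to end."""

    data: SimulatedData
    calls: pd.DataFrame                  # per-patient gold vital-status calls
    linked: dict                         # source_id -> linked assertions
    versions: list                       # composite DatasetVersions, in order
    reports: list                        # one ValidationReport per version

    def report_frame(self) -> pd.DataFrame:
        return bm.report_table(self.reports)


def run_study(config: SimulationConfig) -> StudyResult:
    """Simulate, link, compose and benchmark one study without touching disk."""
    data = simulate_all(config)
    linked = {sid: lk.link_source(data.cohort, records)
              for sid, records in data.sources.items()}
    calls = lk.classify_gold_matches(
        data.cohort, data.gold, lk.match_records(data.cohort, data.gold))
    versions = cp.build_dataset_versions(
        data.cohort, linked, recency_days=config.abs_recency_days,
        reference_date=pd.Timestamp(config.study_cutoff))
    reports = [bm.validation_report(v.label, v.composite, calls)
               for v in versions]
    return StudyResult(data=data, calls=calls, linked=linked,
                       versions=versions, reports=reports)


def run_pipeline(config: SimulationConfig, outdir,
                 version_subset=None,
                 horizons=(182, 365, 730)) -> RunManifest:
    """Run the whole study and write every stage's outputs to ``outdir``.

    ``version_subset`` optionally restricts the benchmark and survival
    stages to a subset of the five composite version labels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    # --- simulate ---------------------------------------------------------
    data: SimulatedData = simulate_all(config)
    stage = {"cohort.csv": write_table(data.cohort, outdir / "cohort.csv")}
    for sid, df in data.sources.items():
        stage[f"source_{sid}.csv"] = write_table(
            df, outdir / f"source_{sid}.csv")
    stage["gold.csv"] = write_table(data.gold, outdir / "gold.csv")
    stages["simulate"] = stage
    log.info("simulate: cohort=%d deaths=%d sources=%s gold=%d",
             len(data.cohort), int(data.cohort["true_death_date"].notna().sum()),
             {k: len(v) for k, v in data.sources.items()}, len(data.gold))

    # --- link -------------------------------------------------------------
    stage = {}
    linked: dict[str, pd.DataFrame] = {}
    for sid, records in data.sources.items():
        matches = lk.match_records(data.cohort, records)
        audit = records[["record_id", "source_id", "death_date"]].merge(
            matches, on="record_id")
        stage[f"matches_{sid}.csv"] = write_table(
            audit, outdir / f"matches_{sid}.csv")
        linked[sid] = audit[audit["patient_id"].notna()][
            ["patient_id", "source_id", "death_date"]]
        log.info("link %s: %d records, %d matched", sid, len(records),
                 int(matches["patient_id"].notna().sum()))
    gold_matches = lk.match_records(data.cohort, data.gold)
    calls = lk.classify_gold_matches(data.cohort, data.gold, gold_matches)
    stage["vital_status.csv"] = write_table(calls, outdir / "vital_status.csv")
    frac = lk.match_class_fractions(calls)
    log.info("gold classification fractions: %s",
             {k: round(v, 3) for k, v in frac.items()})
    stages["link"] = stage

    # --- compose ----------------------------------------------------------
    versions = cp.build_dataset_versions(
        data.cohort, linked, recency_days=config.abs_recency_days,
        reference_date=pd.Timestamp(config.study_cutoff))
    if version_subset is not None:
        versions = [v for v in versions if v.label in set(version_subset)]
    stage = {}
    for v in versions:
        stage[f"composite_{v.label}.csv"] = write_table(
            v.composite, outdir / f"composite_{v.label}.csv")
        log.info("compose %s: %d deaths (%d removed implausible)", v.label,
                 int(v.composite["death_date"].notna().sum()),
                 int(v.composite["resolution"].eq("removed_implausible").sum()))
    stages["compose"] = stage

    # --- benchmark --------------------------------------------------------
    reports = [bm.validation_report(v.label, v.composite, calls)
               for v in versions]
    report_df = bm.report_table(reports)
    stage = {"report.csv": write_table(report_df, outdir / "report.csv")}
    final = versions[-1]
    summary = bm.per_practice_sensitivity(final.composite, calls, data.cohort)
    practice_df = summary.sensitivities.rename("sensitivity").reset_index()
    stage["practice_summary.csv"] = write_table(
        practice_df, outdir / "practice_summary.csv")
    stages["benchmark"] = stage

    # --- survive ----------------------------------------------------------
    stage = {}
    curves = {}
    for v in versions:
        inputs = sv.make_survival_inputs(data.cohort, v.composite,
                                         config.study_cutoff)
        curve = sv.km_estimate(inputs)
        curves[v.label] = curve
        km_df = pd.DataFrame({"time_days": curve.event_times,
                              "at_risk": curve.at_risk,
                              "survival": curve.survival})
        stage[f"km_{v.label}.csv"] = write_table(
            km_df, outdir / f"km_{v.label}.csv")
    gold_curve = sv.km_estimate(
        sv.gold_survival_inputs(data.cohort, calls, config.study_cutoff))
    comparison = sv.compare_curves(curves, gold_curve, horizons=horizons)
    stage["survival_comparison.csv"] = write_table(
        comparison, outdir / "survival_comparison.csv")
    stages["survive"] = stage

    manifest = RunManifest(config=config_to_dict(config), seed=config.seed,
                           stages=stages, versions=[v.label for v in versions])
    manifest.to_json(outdir / "manifest.json")
    return manifest


def validate_against_table(report: pd.DataFrame, expected: pd.DataFrame,
                           tolerance: float = 0.0015) -> list:
    """Cell-by-cell comparison of a benchmark report against expected rows.

    ``expected`` must carry a ``version`` column plus any metric columns
    to check (on the proportion scale); ``tolerance`` is the absolute
    allowance per cell.  Returns a list of (version, column, got,
    expected) tuples for the non-passing cells; empty means pass.
    """
    metric_cols = [c for c in expected.columns if c != "version"]
    missing = set(metric_cols) - set(report.columns)
    if missing or "version" not in report.columns:
        raise lk.SchemaError(
            f"report is missing columns: {sorted(missing) or ['version']}")
    failures = []
    got = report.set_index("version")
    for _, row in expected.iterrows():
        if row["version"] not in got.index:
            raise lk.SchemaError(f"report has no row {row['version']!r}")
        for col in metric_cols:
            g = got.loc[row["version"], col]
            if abs(g - row[col]) > tolerance:
                failures.append((row["version"], col, float(g),
                                 float(row[col])))
    return failures
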
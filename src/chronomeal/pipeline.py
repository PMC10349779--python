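"""End-to-end orchestration: inputs (or simulation) -> derived
per-participant table -> descriptive and association reports.

Stage order mirrors the study design: recall reconciliation, actigraphy
validity filtering, weekly meal-timing exposures, marker derivation,
then the stratified regression layer with multiplicity control.  Every
exclusion is counted and reported in the run report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import associations as assoc
from . import chrono_metrics as chrono
from . import markers
from . import recall_io
from . import sleep_metrics as sleep
from .config import PipelineConfig
from .errors import PipelineError
from .synthetic import emit_dual_entries, generate_cohort, write_cohort
from .timeaxis import format_clock

log = logging.getLogger("chronomeal")

EXPOSURES = ("eating_window", "caloric_midpoint", "eating_jetlag", "msp_to_first", "last_to_msp")
BODYCOMP_OUTCOMES = ("bmi", "fat_pct", "lean_mass_index", "vat_g", "waist_cm")
CARDIO_OUTCOMES = (
    "mean_bp",
    "triglycerides",
    "total_chol",
    "hdl",
    "ldl",
    "homa_ir",
    "risk_z",
)
CLOCK_COLUMNS = (
    "caloric_midpoint",
    "eating_midpoint_working",
    "eating_midpoint_nonworking",
    "midsleep_week",
    "midsleep_working",
    "midsleep_nonworking",
)


@dataclass
class RunReport:
    """Accounting of one pipeline run (mirrors a participant flow chart)."""

    counts: dict = dc_field(default_factory=dict)
    exclusions: list = dc_field(default_factory=list)
    outputs: dict = dc_field(default_factory=dict)
    config: dict = dc_field(default_factory=dict)
    software_version: str = ""
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def derive_participant_table(
    events: pd.DataFrame,
    nights: pd.DataFrame,
    participants: pd.DataFrame,
    conventions,
) -> tuple[pd.DataFrame, RunReport]:
    """Inputs -> one derived row per participant, plus exclusion accounting."""
    report = RunReport()
    report.counts["enrolled"] = int(participants["participant_id"].nunique())

    # dual-entry reconciliation
    clean, failures = recall_io.reconcile_events_table(events, conventions.cv_threshold_pct)
    for f in failures:
        report.exclusions.append({**f, "stage": "recall_reconciliation"})
    report.counts["recall_days_reconciled"] = int(
        clean.groupby(["participant_id", "date"], observed=True).ngroups
    )
    report.counts["recall_days_failed"] = len(failures)

    # actigraphy validity + weekly sleep variables
    weights = (conventions.week_weight_working, conventions.week_weight_nonworking)
    sleep_weekly = sleep.weekly_sleep_table(nights, weights)
    invalid = sleep_weekly[~sleep_weekly["valid_actigraphy"]]
    for _, row in invalid.iterrows():
        report.exclusions.append(
            {
                "participant_id": row["participant_id"],
                "stage": "actigraphy_validity",
                "reason": row["invalid_reason"],
            }
        )
    report.counts["valid_actigraphy"] = int(sleep_weekly["valid_actigraphy"].sum())

    # weekly meal-timing exposures
    daily = chrono.daily_metrics_table(clean)
    weekly = chrono.weekly_chrono_table(daily, sleep_weekly, weights)
    breakfast = chrono.breakfast_status_table(
        clean,
        cutoff_h=conventions.breakfast_cutoff_h,
        min_kcal=conventions.breakfast_min_kcal,
    )

    # markers
    panel = markers.derive_panel(
        participants,
        bp_variable=conventions.risk_bp_variable,
        restandardize_risk=conventions.restandardize_risk_score,
    )

    derived = (
        panel.merge(weekly, on="participant_id", how="left")
        .merge(
            sleep_weekly.drop(columns=["midsleep_week", "midsleep_week_axis"]),
            on="participant_id",
            how="left",
        )
        .merge(breakfast, on="participant_id", how="left")
    )
    derived = derived[derived["valid_actigraphy"].fillna(False)].reset_index(drop=True)
    report.counts["analyzed"] = len(derived)
    report.counts["excluded"] = report.counts["enrolled"] - report.counts["analyzed"]
    return derived, report


def descriptive_table(derived: pd.DataFrame, conventions) -> pd.DataFrame:
    """Sex-stratified descriptive report.

    Per variable and stratum: n, then mean (SD) when a Shapiro-Wilk test
    does not reject normality at the configured alpha, else median
    (IQR).  The sex-comparison p-value comes from a one-way ANOVA, on
    log10 values for the skewed biomarkers.
    """
    variables = [
        ("age_yr", False),
        ("height_cm", False),
        ("weight_kg", False),
        ("bmi", False),
        ("fat_pct", False),
        ("lean_mass_index", False),
        ("vat_g", False),
        ("waist_cm", False),
        ("sbp", False),
        ("dbp", False),
        ("mean_bp", False),
        ("triglycerides", True),
        ("total_chol", True),
        ("hdl", True),
        ("ldl", True),
        ("glucose", True),
        ("insulin", True),
        ("homa_ir", True),
        ("risk_z", False),
        ("midsleep_week", False),
        ("sleep_duration_week", False),
        ("social_jetlag_abs", False),
        ("eating_window", False),
        ("caloric_midpoint", False),
        ("eating_jetlag_abs", False),
        ("msp_to_first", False),
        ("last_to_msp", False),
    ]
    strata = {
        "all": derived,
        "men": derived[derived["sex"] == "man"],
        "women": derived[derived["sex"] == "woman"],
    }
    rows = []
    for var, log_for_anova in variables:
        if var not in derived.columns:
            continue
        row: dict = {"variable": var}
        for name, sub in strata.items():
            x = sub[var].dropna().to_numpy(dtype=float)
            if x.size == 0:
                log.warning("descriptive table: empty stratum %s for %s", name, var)
                continue
            normal = True
            if x.size >= 3 and np.std(x) > 0:
                normal = stats.shapiro(x).pvalue >= conventions.shapiro_alpha
            if normal:
                center, spread = float(np.mean(x)), float(np.std(x, ddof=1))
                summary = f"{center:.2f} ({spread:.2f})"
            else:
                q1, center, q3 = np.percentile(x, [25, 50, 75])
                spread = float(q3 - q1)
                summary = f"{center:.2f} ({q1:.2f}, {q3:.2f})"
            row[f"n_{name}"] = int(x.size)
            row[f"center_{name}"] = float(center)
            row[f"spread_{name}"] = float(spread)
            row[f"normal_{name}"] = bool(normal)
            row[f"summary_{name}"] = summary
        vals = derived[var].astype(float)
        if log_for_anova:
            vals = np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), np.nan)
        try:
            _, p_sex = assoc.sex_comparison_anova(vals, derived["sex"].to_numpy())
        except Exception:
            p_sex = np.nan
        row["p_sex"] = p_sex
        rows.append(row)
    return pd.DataFrame(rows)


def _format_clock_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in CLOCK_COLUMNS:
        if col in out.columns:
            out[f"{col}_hhmm"] = [
                format_clock(v) if np.isfinite(v) else "" for v in out[col].astype(float)
            ]
    return out


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> RunReport:
    """Execute all stages and write every output table under
    ``config.output_dir``."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    conv = config.conventions

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            if seed is not None:
                sim_cfg = sim_cfg.model_copy(update={"seed": seed})
            cohort = generate_cohort(sim_cfg)
            dual = emit_dual_entries(cohort, sim_cfg) if config.dual_entries else None
            write_cohort(cohort, outdir / "data", dual)
            events = dual if dual is not None else cohort.recall_events
            nights = cohort.sleep_nights
            participants = cohort.participants.drop(
                columns=[c for c in cohort.participants.columns if c.startswith("true_")]
            )
            used_seed = sim_cfg.seed
        else:
            for name, path in (
                ("recalls", config.recalls_path),
                ("sleep", config.sleep_path),
                ("participants", config.participants_path),
            ):
                if not Path(path).exists():
                    raise PipelineError("inputs", f"{name} file not found: {path}")
            events = recall_io.read_recall_table(
                config.recalls_path,
                rollover_hour=conv.rollover_hour,
                caloric_threshold_kcal=conv.caloric_threshold_kcal,
            )
            nights = sleep.read_sleep_table(config.sleep_path)
            participants = pd.read_csv(config.participants_path)
            participants["participant_id"] = participants["participant_id"].astype(str)
            used_seed = seed

        stage = "derive"
        derived, report = derive_participant_table(events, nights, participants, conv)

        stage = "descriptives"
        table1 = descriptive_table(derived, conv)

        stage = "associations"
        analysis = assoc.transform_outcomes(derived)
        tables = {}
        for label, outcomes in (
            ("body_composition", BODYCOMP_OUTCOMES),
            ("cardiometabolic", CARDIO_OUTCOMES),
        ):
            outcome_list = [o for o in outcomes if o in analysis.columns]
            for kind, adjusted in (("simple", False), ("adjusted", True)):
                tables[f"{label}_{kind}"] = assoc.association_table(
                    analysis,
                    exposures=list(EXPOSURES),
                    outcomes=outcome_list,
                    adjusted=adjusted,
                    multiplicity=conv.multiplicity,
                )

        stage = "outputs"
        paths = {"derived": outdir / "derived_participants.csv", "table1": outdir / "table1_descriptives.csv"}
        _format_clock_columns(derived).to_csv(paths["derived"], index=False, float_format="%.6f")
        table1.to_csv(paths["table1"], index=False, float_format="%.6g")
        for name, table in tables.items():
            paths[f"assoc_{name}_long"] = outdir / f"associations_{name}_long.csv"
            table.to_csv(paths[f"assoc_{name}_long"], index=False, float_format="%.6g")
            paths[f"assoc_{name}_wide"] = outdir / f"associations_{name}_wide.csv"
            assoc.table_to_wide(table).to_csv(
                paths[f"assoc_{name}_wide"], index=False, float_format="%.6g"
            )
        report.outputs = {k: str(v) for k, v in paths.items()}
        report.config = json.loads(config.model_dump_json())
        report.software_version = pkg_version("chronomeal")
        report.seed = used_seed
        report.to_json(outdir / "run_report.json")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
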
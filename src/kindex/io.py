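"""CSV formats, the analysis pipeline, and report rendering.

The on-disk formats are deliberately plain: UTF-8 comma-separated CSV with
"." decimals (a locale option normalizes ","-decimal files on read), one
wide interview table following a documented column dictionary, one wide
response table per battery instrument (columns = item ids), and JSON for
configuration and result bundles.

``run_validation_pipeline`` ties the stages together in the order of the
original analysis: KINDEX scoring -> battery scoring -> z-composites ->
normality gate -> nonparametric correlations and group comparisons ->
reliability -> descriptive tables, and renders Markdown analogues of the
published table layouts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import composites as comp
from . import stats
from .instruments import InstrumentSchema, default_schemas
from .scoring import (
    INDICATOR_NAMES,
    KindexInterview,
    ScoringConfig,
    score_cohort,
)
from .simulate import SyntheticCohort, score_battery

logger = logging.getLogger("kindex")

__all__ = [
    "INTERVIEW_BOOL_COLUMNS",
    "INTERVIEW_INT_COLUMNS",
    "INTERVIEW_STR_COLUMNS",
    "RowIssue",
    "InterviewTable",
    "PipelineConfig",
    "ReportBundle",
    "read_interviews",
    "write_interviews",
    "read_battery",
    "write_battery",
    "write_cohort",
    "interviews_from_frame",
    "analyze_cohort",
    "run_validation_pipeline",
]

INTERVIEW_BOOL_COLUMNS: tuple[str, ...] = (
    "mother_foreign_born", "father_foreign_born", "cohabiting_with_father",
    "financial_worry", "pregnancy_planned", "physical_symptoms",
    "complications", "medical_risk", "childhood_physical_abuse",
    "childhood_sexual_abuse", "ipv_increase_8w", "ipv_vociferous_8w",
    "ipv_physical_8w", "ipv_ever", "smoke_mother", "alcohol_mother",
    "drugs_mother", "smoke_father", "alcohol_father", "drugs_father",
    "psych_diagnosis_ever", "psych_inpatient_ever", "psychotropic_ever",
    "sought_help_ever",
)
INTERVIEW_INT_COLUMNS: tuple[str, ...] = (
    "age_years", "gestational_week", "rooms", "persons", "joy_mother",
    "worries_mother", "joy_father", "worries_father",
    "pss4_1", "pss4_2", "pss4_3", "pss4_4",
)
INTERVIEW_STR_COLUMNS: tuple[str, ...] = (
    "interview_unit", "interviewer_profession", "support_wish",
)
MANDATORY_COLUMNS: tuple[str, ...] = (
    ("respondent_id",) + INTERVIEW_INT_COLUMNS + INTERVIEW_BOOL_COLUMNS
    + ("interview_unit", "interviewer_profession")
)


@dataclass(frozen=True)
class RowIssue:
    respondent_id: str
    reason: str


@dataclass(frozen=True)
class InterviewTable:
    records: tuple[KindexInterview, ...]
    issues: tuple[RowIssue, ...]

    def frame(self) -> pd.DataFrame:
        from .scoring import interviews_to_frame

        return interviews_to_frame(list(self.records))


def _to_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    if s in ("", "na", "nan", "none"):
        return None
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _to_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "na", "nan", "none"):
        return None
    f = float(value)
    if f != int(f):
        raise ValueError(f"expected an integer, got {value!r}")
    return int(f)


def interviews_from_frame(frame: pd.DataFrame) -> InterviewTable:
    """Typed records from a wide interview frame; row-level problems are
    collected as issues (the row is rejected), never silently dropped."""
    df = frame.reset_index() if frame.index.name == "respondent_id" else frame
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interview table lacks mandatory columns: {missing}")
    records: list[KindexInterview] = []
    issues: list[RowIssue] = []
    for _, row in df.iterrows():
        rid = str(row["respondent_id"])
        try:
            ints = {c: _to_int(row[c]) for c in INTERVIEW_INT_COLUMNS}
            bools = {c: _to_bool(row[c]) for c in INTERVIEW_BOOL_COLUMNS}
            for c in ("rooms", "persons"):
                if ints[c] is not None and ints[c] < 1:
                    raise ValueError(f"{c} must be a positive integer")
            rec = KindexInterview(
                respondent_id=rid,
                pss4_items=tuple(ints.pop(f"pss4_{i}") for i in range(1, 5)),
                interview_unit=(
                    None if pd.isna(row["interview_unit"])
                    else str(row["interview_unit"])
                ),
                interviewer_profession=(
                    None if pd.isna(row["interviewer_profession"])
                    else str(row["interviewer_profession"])
                ),
                support_wish=(
                    "" if "support_wish" not in row or pd.isna(row["support_wish"])
                    else str(row["support_wish"])
                ),
                **ints, **bools,
            )
        except (ValueError, TypeError) as exc:
            issues.append(RowIssue(rid, str(exc)))
            logger.warning("rejected interview row %s: %s", rid, exc)
            continue
        records.append(rec)
    return InterviewTable(tuple(records), tuple(issues))


def read_interviews(path, *, decimal: str = ".") -> InterviewTable:
    """Read a wide interview CSV into typed records.

    A missing mandatory column is a hard error listing the columns; invalid
    rows are rejected individually with reasons in ``issues``.
    """
    df = pd.read_csv(path, decimal=decimal)
    return interviews_from_frame(df)


def write_interviews(frame_or_records, path) -> None:
    """Write interviews (wide frame or records) as UTF-8 CSV."""
    if not isinstance(frame_or_records, pd.DataFrame):
        from .scoring import interviews_to_frame

        frame_or_records = interviews_to_frame(list(frame_or_records))
    frame_or_records.to_csv(path, encoding="utf-8")


def read_battery(path, instrument_id: str, *, decimal: str = ".") -> pd.DataFrame:
    """Read one instrument's wide response CSV (respondent_id + item columns)."""
    df = pd.read_csv(path, decimal=decimal)
    if "respondent_id" not in df.columns:
        raise ValueError(
            f"battery file for {instrument_id!r} lacks a respondent_id column"
        )
    return df.set_index("respondent_id")


def write_battery(battery: Mapping[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write one CSV per instrument into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, frame in battery.items():
        p = outdir / f"battery_{sid}.csv"
        frame.to_csv(p, encoding="utf-8")
        paths[sid] = p
    return paths


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Persist a synthetic cohort: interview CSV, battery CSVs, and a
    ground-truth JSON with the latent values and generator configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    interviews_path = outdir / "interviews.csv"
    cohort.interviews.to_csv(interviews_path, encoding="utf-8")
    battery_paths = write_battery(cohort.battery, outdir)
    truth = {
        "latent_adversity": {
            rid: float(v) for rid, v in cohort.latent.items()
        },
        "config": _jsonable(dataclasses.asdict(cohort.config)),
    }
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2), encoding="utf-8")
    return {"interviews": interviews_path, "battery": battery_paths,
            "ground_truth": truth_path}


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end analysis needs, in one document."""

    interviews_path: Optional[str] = None
    battery_dir: Optional[str] = None
    output_dir: Optional[str] = None
    alpha: float = 0.05
    sided: str = "two-sided"
    sd_ddof: int = 1  # 1 = sample SD for z-transforms, 0 = population SD
    housing_comparator: str = "le"
    referral_threshold: int = 2
    decimal: str = "."
    seed: int = 0

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(
            housing_comparator=self.housing_comparator,
            referral_threshold=self.referral_threshold,
        )


@dataclass
class ReportBundle:
    """All result tables of one pipeline run plus the exact options used."""

    options: dict
    profiles: pd.DataFrame
    battery_totals: pd.DataFrame
    composites: pd.DataFrame
    score_summary: pd.DataFrame
    descriptives: pd.DataFrame
    correlations: list
    normality: list
    reliability: stats.ReliabilityResult
    item_comparisons: dict[str, pd.DataFrame]
    unit_comparison: Optional[stats.GroupComparison]
    profession_comparison: Optional[stats.GroupComparison]
    n_tests: int
    issues: tuple = ()

    def to_markdown(self) -> str:
        lines = ["# KINDEX validation report", ""]
        lines += ["## Options", "", "```json",
                  json.dumps(_jsonable(self.options), indent=2), "```", ""]
        lines += ["## Risk-factor descriptives", "",
                  _md_table(self.descriptives.reset_index()), ""]
        lines += ["## Validation-scale distributions", "",
                  _md_table(self.score_summary.reset_index()), ""]
        corr = pd.DataFrame(
            [{"pair": " ~ ".join(c.pair), "rho": c.rho, "n": c.n, "p": c.p}
             for c in self.correlations]
        )
        lines += ["## Rank correlations (risk sum score vs global criteria)",
                  "", _md_table(corr), ""]
        for name, table in self.item_comparisons.items():
            lines += [f"## Criterion comparison by indicator: {name}", "",
                      _md_table(table.reset_index()), ""]
        norm_df = pd.DataFrame([dataclasses.asdict(r) for r in self.normality])
        lines += ["## Normality gate (Lilliefors-corrected K-S)", "",
                  _md_table(norm_df), ""]
        rel = self.reliability
        lines += [
            "## Reliability of the binary indicators", "",
            f"Cronbach's alpha = {rel.alpha:.3f} on {rel.n_items_retained} "
            f"items (of {rel.n_items_input}; "
            f"{len(rel.excluded_items)} excluded for zero variation: "
            f"{', '.join(i for i, _ in rel.excluded_items) or 'none'}), "
            f"n = {rel.n_respondents}.", "",
        ]
        lines += [
            f"_{self.n_tests} significance tests were performed; no "
            f"multiple-testing correction was applied._", "",
        ]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(outdir / "risk_profiles.csv")
        self.battery_totals.to_csv(outdir / "battery_totals.csv")
        self.composites.to_csv(outdir / "composites.csv")
        self.score_summary.to_csv(outdir / "score_summary.csv")
        self.descriptives.to_csv(outdir / "descriptives.csv")
        results = {
            "options": _jsonable(self.options),
            "correlations": [_jsonable(c) for c in self.correlations],
            "normality": [_jsonable(r) for r in self.normality],
            "reliability": _jsonable(self.reliability),
            "unit_comparison": _jsonable(self.unit_comparison),
            "profession_comparison": _jsonable(self.profession_comparison),
            "n_tests": self.n_tests,
            "row_issues": [_jsonable(i) for i in self.issues],
        }
        (outdir / "results.json").write_text(
            json.dumps(results, indent=2), encoding="utf-8"
        )
        (outdir / "report.md").write_text(self.to_markdown(), encoding="utf-8")


def _md_table(df: pd.DataFrame) -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = [
        "| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, sep] + rows)


def _summarize_scores(frame: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in frame.columns:
        s = frame[col].astype("float64").dropna()
        rows.append({
            "scale": col, "n": int(len(s)), "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)), "median": float(s.median()),
            "min": float(s.min()), "max": float(s.max()),
        })
    return pd.DataFrame(rows).set_index("scale")


def analyze_cohort(
    interviews: pd.DataFrame,
    battery: Mapping[str, pd.DataFrame],
    *,
    config: Optional[PipelineConfig] = None,
    schemas: Optional[Mapping[str, InstrumentSchema]] = None,
    issues: Sequence[RowIssue] = (),
) -> ReportBundle:
    """Run the full concurrent-validity analysis on an in-memory cohort.

    Stages: KINDEX scoring -> battery scoring -> z-composites -> normality
    gate -> Spearman correlations -> item-criterion Mann-Whitney tables ->
    reliability with zero-variance exclusion -> descriptives -> unit
    (Kruskal-Wallis) and interviewer-profession (t-test) comparisons.
    A stage failure is re-raised with the stage name attached.
    """
    cfg = config or PipelineConfig()
    if len(interviews) == 0:
        raise ValueError("empty cohort: nothing to analyze")
    schemas = dict(schemas or default_schemas())
    n_tests = 0

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    profiles = stage("kindex_scoring",
                     lambda: score_cohort(interviews, cfg.scoring_config()))
    totals = stage("battery_scoring", lambda: score_battery(battery, schemas))
    composite_frame, z_params = stage(
        "composites", lambda: comp.build_composites(totals, ddof=cfg.sd_ddof)
    )

    analysis = pd.DataFrame({
        "kindex_sum": profiles["sum_score"].astype("float64"),
    }).join(composite_frame, how="left")

    normality = []
    for col in ("kindex_sum", "global_stress", "global_psychopathology",
                "global_trauma_load"):
        normality.append(stage(
            "normality_gate",
            lambda c=col: stats.ks_normality(
                analysis[c], variable=c, alpha=cfg.alpha
            ),
        ))
    n_tests += len(normality)

    correlations = stage("correlations", lambda: stats.spearman_matrix(analysis))
    n_tests += len(correlations)

    criteria_psych = totals[
        ["scl_somatization", "pds_severity", "hscl_depression", "hscl_anxiety"]
    ].reindex(profiles.index)
    criteria_abuse = totals[
        ["cfv_physical", "cfv_witnessed", "cfv_verbal_emotional",
         "cfv_neglect", "cfv_sexual", "cfv_total"]
    ].reindex(profiles.index)
    item_comparisons: dict[str, pd.DataFrame] = {}
    for indicator, criteria in (
        ("psychiatric_diagnosis_ever", criteria_psych),
        ("childhood_physical_abuse", criteria_abuse),
    ):
        item_comparisons[indicator] = stage(
            "item_criterion",
            lambda i=indicator, c=criteria: stats.item_criterion_comparison(
                profiles[i], c, sided=cfg.sided
            ),
        )
        n_tests += item_comparisons[indicator].shape[0]

    indicator_matrix = profiles[list(INDICATOR_NAMES)].astype("float64")
    reliability = stage("reliability",
                        lambda: stats.cronbach_alpha(indicator_matrix))

    desc = stage("descriptives", lambda: stats.descriptives(
        profiles, list(INDICATOR_NAMES),
        rating_columns=["joy_mother", "worries_mother", "joy_father",
                        "worries_father"],
        ratings=interviews,
    ))

    unit_cmp = None
    if interviews["interview_unit"].nunique() >= 2:
        groups = [
            analysis.loc[interviews["interview_unit"] == u, "kindex_sum"]
            for u in sorted(interviews["interview_unit"].dropna().unique())
        ]
        unit_cmp = stage("unit_comparison", lambda: stats.kruskal_wallis(groups))
        n_tests += 1
    prof_cmp = None
    professions = interviews["interviewer_profession"].dropna().unique()
    if len(professions) == 2:
        a, b = sorted(professions)
        prof_cmp = stage("profession_comparison", lambda: stats.student_t(
            analysis.loc[interviews["interviewer_profession"] == a, "kindex_sum"],
            analysis.loc[interviews["interviewer_profession"] == b, "kindex_sum"],
        ))
        n_tests += 1

    summary_frame = pd.concat([totals, composite_frame], axis=1)
    options = dataclasses.asdict(cfg)
    options["z_params"] = z_params
    return ReportBundle(
        options=options,
        profiles=profiles,
        battery_totals=totals,
        composites=composite_frame,
        score_summary=_summarize_scores(summary_frame),
        descriptives=desc,
        correlations=correlations,
        normality=normality,
        reliability=reliability,
        item_comparisons=item_comparisons,
        unit_comparison=unit_cmp,
        profession_comparison=prof_cmp,
        n_tests=n_tests,
        issues=tuple(issues),
    )


def run_validation_pipeline(config: PipelineConfig) -> ReportBundle:
    """Load the cohort from disk, run :func:`analyze_cohort`, and write the
    report bundle (CSV tables, JSON results, Markdown report, run log)."""
    if config.interviews_path is None or config.battery_dir is None:
        raise ValueError("config must provide interviews_path and battery_dir")
    table = read_interviews(config.interviews_path, decimal=config.decimal)
    if not table.records:
        raise ValueError("no valid interview rows loaded")
    frame = table.frame()
    battery_dir = Path(config.battery_dir)
    battery = {}
    for sid in ("pss14", "esi", "hscl25", "scl90r_somatization",
                "pds_events", "pds_symptoms", "cfv"):
        path = battery_dir / f"battery_{sid}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing battery file {path}")
        battery[sid] = read_battery(path, sid, decimal=config.decimal)
    bundle = analyze_cohort(frame, battery, config=config, issues=table.issues)
    if config.output_dir is not None:
        bundle.write(config.output_dir)
        logger.info("report bundle written to %s", config.output_dir)
    return bundle
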
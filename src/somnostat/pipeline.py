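"""End-to-end pipeline: simulate/load -> stage -> summarize -> analyze.

One seeded, logged run produces per-subject stage sequences, arousal
summaries, group descriptives, the per-group objective-by-subjective
correlation matrix, the global canonical-correlation test and the
interaction regressions, plus a JSON manifest sufficient to reproduce
the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sct

from . import __version__
from .arousal import summarize_arousal
from .io import read_recording, write_stage_sequence
from .questionnaires import GROUPS, QuestionnaireRecord, Subject, ValidationError
from .simulate import SimulationConfig, simulate_cohort, synthesize_recording
from .staging import StagingSettings, stage_recording
from .stats import (
    FitFailure,
    cca_pillai_bootstrap,
    fit_linear_interaction_model,
    fit_proportional_odds,
    kruskal_wallis,
    spearman_with_p,
    variable_blocks,
)

__all__ = ["PipelineConfig", "run_pipeline", "read_subject_table"]

log = logging.getLogger("somnostat.pipeline")

_METRIC_ROWS = [
    ("age", "Age"),
    ("vas_pre", "VAS (pre)"),
    ("vas_post", "VAS (post)"),
    ("d_vas", "dVAS (post-pre)"),
    ("d_kss", "dKSS (post-pre)"),
    ("d_sss", "dSSS (post-pre)"),
    ("ssd", "SSD (minutes)"),
    ("ssq", "SSQ"),
    ("ess", "ESS"),
]
_ORDINAL_ROWS = [
    ("kss_pre", "KSS (pre)"),
    ("kss_post", "KSS (post)"),
    ("sss_pre", "SSS (pre)"),
    ("sss_post", "SSS (post)"),
]
_VIGILANCE_ROWS = [
    ("prop_0", "Proportion stage 0"),
    ("prop_a", "Proportion stage A"),
    ("prop_b", "Proportion stage B"),
    ("prop_c", "Proportion stage C"),
    ("mvv", "MVV"),
    ("ass", "ASS"),
]
_CORR_SUBJECTIVE = [
    "sss_pre", "kss_pre", "vas_pre", "sss_post", "kss_post", "vas_post",
    "d_sss", "d_kss", "d_vas", "asleep", "ess", "ssq",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    mode: str = "simulate"  # 'simulate' | 'files'
    output_dir: str = "somnostat_output"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    staging: StagingSettings = field(default_factory=StagingSettings)
    stage_from_signals: bool = False  # simulate mode: re-stage synthesized EEG
    subject_table: str | None = None  # files mode
    eeg_dir: str | None = None  # files mode, optional
    metric_dvs: tuple[str, ...] = ("vas_pre", "vas_post", "d_vas", "ess")
    ordinal_dvs: tuple[str, ...] = ("kss_pre", "sss_pre", "asleep")
    objective_measures: tuple[str, ...] = ("mvv", "ass")
    cca_replications: int = 9999
    write_sequences: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"input mode must be simulate or files, got {self.mode!r}")
        if self.mode == "files" and not self.subject_table:
            raise ValueError("files mode needs a subject_table path")


def read_subject_table(path) -> list[Subject]:
    """Read a one-row-per-subject delimited table with raw item columns.

    Required columns: id, age, gender, bmi, bdi, ess_item1..8, kss_pre,
    kss_post, sss_pre, sss_post, vas_pre, vas_post, asleep,
    rest_item1..8, ssd.  Validation failures name the offending row.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    required = (
        ["id", "age", "gender", "bmi", "bdi", "kss_pre", "kss_post", "sss_pre",
         "sss_post", "vas_pre", "vas_post", "asleep", "ssd"]
        + [f"ess_item{i}" for i in range(1, 9)]
        + [f"rest_item{i}" for i in range(1, 9)]
    )
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    subjects = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=2):  # 1 header line
        try:
            if row[required].isna().any():
                bad = [c for c in required if pd.isna(row[c])]
                raise ValidationError(f"missing values in {bad}")
            record = QuestionnaireRecord(
                ess_items=tuple(int(row[f"ess_item{i}"]) for i in range(1, 9)),
                kss_pre=int(row["kss_pre"]),
                kss_post=int(row["kss_post"]),
                sss_pre=int(row["sss_pre"]),
                sss_post=int(row["sss_post"]),
                vas_pre=float(row["vas_pre"]),
                vas_post=float(row["vas_post"]),
                asleep=int(row["asleep"]),
                restedness_items=tuple(
                    int(row[f"rest_item{i}"]) for i in range(1, 9)
                ),
                ssd=float(row["ssd"]),
            )
            subjects.append(
                Subject(
                    id=str(row["id"]),
                    age=float(row["age"]),
                    gender=str(row["gender"]),
                    bmi=float(row["bmi"]),
                    bdi=float(row["bdi"]),
                    questionnaire=record,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {pos}: {exc}") from exc
    return subjects


def _descriptives(df: pd.DataFrame, rows, kind: str) -> pd.DataFrame:
    out = []
    for col, label in rows:
        entry: dict = {"variable": label}
        for g in GROUPS:
            values = df.loc[df.group == g, col]
            if values.empty:
                continue
            if kind == "metric":
                entry[f"{g}_mean"] = values.mean()
                entry[f"{g}_sd"] = values.std(ddof=1)
            else:
                q1, med, q3 = values.quantile([0.25, 0.5, 0.75])
                entry[f"{g}_median"] = med
                entry[f"{g}_iqr"] = f"{q1:g} - {q3:g}"
        present = df.group.unique()
        if len(present) >= 2:
            entry["p_kruskal_wallis"] = kruskal_wallis(df[col], df.group).p
        out.append(entry)
    return pd.DataFrame(out)


def _categorical_descriptives(df: pd.DataFrame) -> pd.DataFrame:
    out = []
    for col, labels in (
        ("gender", {"female": "female", "male": "male"}),
        ("asleep", {1: "definitely", 2: "possibly", 3: "probably not",
                    4: "surely not"}),
    ):
        table = pd.crosstab(df[col], df.group)
        p = np.nan
        if table.shape[1] >= 2 and table.values.sum() > 0:
            p = sct.chi2_contingency(table.values)[1]
        for level, label in labels.items():
            entry = {"variable": col, "level": label}
            for g in GROUPS:
                n = int(table.loc[level, g]) if (
                    level in table.index and g in table.columns
                ) else 0
                total = int(table[g].sum()) if g in table.columns else 0
                entry[f"{g}_n"] = n
                entry[f"{g}_pct"] = 100.0 * n / total if total else np.nan
            entry["p_chi2"] = p
            out.append(entry)
    return pd.DataFrame(out)


def _group_correlations(df: pd.DataFrame, objectives) -> pd.DataFrame:
    """Per-group Spearman correlations of each objective measure with the
    subjective battery (the two objective blocks computed independently)."""
    out = []
    for obj in objectives:
        for subj_var in _CORR_SUBJECTIVE:
            entry = {"objective": obj, "subjective": subj_var}
            for g in GROUPS:
                sub = df[df.group == g]
                if len(sub) < 4 or sub[obj].nunique() < 2 or sub[subj_var].nunique() < 2:
                    entry[g] = np.nan
                else:
                    entry[g] = spearman_with_p(sub[obj], sub[subj_var]).statistic
            out.append(entry)
    return pd.DataFrame(out)


def _interaction_tables(df, config: PipelineConfig):
    metric_rows, ordinal_rows, failures = [], [], []
    for obj in config.objective_measures:
        for dv in config.metric_dvs:
            try:
                res = fit_linear_interaction_model(df, dv, obj)
            except FitFailure as exc:
                failures.append({"dv": dv, "objective": obj, "error": str(exc)})
                continue
            for term, row in res.anova.iterrows():
                if term == "Residual":
                    continue
                metric_rows.append(
                    {"dv": dv, "objective": obj, "term": term,
                     "F": row["F"], "p": row["PR(>F)"]}
                )
        for dv in config.ordinal_dvs:
            try:
                fit = fit_proportional_odds(df, dv, obj)
            except (FitFailure, ValueError) as exc:
                failures.append({"dv": dv, "objective": obj, "error": str(exc)})
                continue
            for term, row in fit.lr_tests.iterrows():
                ordinal_rows.append(
                    {"dv": dv, "objective": obj, "term": term,
                     "lr_chi2": row["lr_chi2"], "p": row["p"]}
                )
    return pd.DataFrame(metric_rows), pd.DataFrame(ordinal_rows), failures


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full chain and write the report bundle.

    Returns a dict of the written artifact paths plus headline results.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_dir = out / "stage_sequences"

    sequences: dict[str, object] = {}
    if config.mode == "simulate":
        log.info("simulating cohort (seed=%d)", config.seed)
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort, truth = simulate_cohort(sim)
        subjects = list(cohort.subjects)
        sequences = {s.id: seq for s, seq in zip(subjects, truth.sequences)}
        if config.stage_from_signals:
            log.info("synthesizing and re-staging %d recordings", len(subjects))
            for i, subject in enumerate(subjects):
                rec = synthesize_recording(
                    truth.sequences[i], sim, subject.recording_seed
                )
                staged = stage_recording(rec, config.staging)
                sequences[subject.id] = staged
                subjects[i] = dataclasses.replace(
                    subject, arousal=summarize_arousal(staged)
                )
    else:
        log.info("reading subject table %s", config.subject_table)
        subjects = read_subject_table(config.subject_table)
        if config.eeg_dir:
            for i, subject in enumerate(subjects):
                base = Path(config.eeg_dir) / subject.id
                path = next(
                    (p for p in (base.with_suffix(".tsv"), base.with_suffix(".edf"))
                     if p.exists()),
                    None,
                )
                if path is None:
                    raise FileNotFoundError(f"no recording found for {subject.id}")
                rec = read_recording(path)
                staged = stage_recording(rec, config.staging)
                sequences[subject.id] = staged
                subjects[i] = dataclasses.replace(
                    subject, arousal=summarize_arousal(staged)
                )

    df = pd.DataFrame([s.to_row() for s in subjects])
    df.to_csv(out / "subjects.csv", index=False)
    if config.write_sequences and sequences:
        stage_dir.mkdir(exist_ok=True)
        for sid, seq in sequences.items():
            write_stage_sequence(seq, stage_dir / f"{sid}.tsv")

    results: dict = {"n_subjects": len(df)}
    _descriptives(df, _METRIC_ROWS, "metric").to_csv(
        out / "descriptives_metric.csv", index=False
    )
    _descriptives(df, _ORDINAL_ROWS, "ordinal").to_csv(
        out / "descriptives_ordinal.csv", index=False
    )
    _categorical_descriptives(df).to_csv(
        out / "descriptives_categorical.csv", index=False
    )

    have_arousal = "mvv" in df.columns
    if have_arousal:
        _descriptives(df, _VIGILANCE_ROWS, "metric").to_csv(
            out / "vigilance_distribution.csv", index=False
        )
        _group_correlations(df, config.objective_measures).to_csv(
            out / "correlations_by_group.csv", index=False
        )
        x, y = variable_blocks(df)
        # constant columns (a stage no one reached in a small cohort) carry
        # no association information; drop them rather than abort the run
        for name, block in (("subjective", x), ("objective", y)):
            dropped = np.flatnonzero(block.std(axis=0) == 0)
            if dropped.size:
                log.warning("dropping constant %s column(s) %s", name, dropped)
        x = x[:, x.std(axis=0) > 0]
        y = y[:, y.std(axis=0) > 0]
        if x.shape[0] <= x.shape[1] + y.shape[1] or not (x.size and y.size):
            log.warning("too few subjects for the canonical correlation test")
            results["cca"] = {"skipped": "n too small for the variable count"}
        else:
            cca_seed = int(
                np.random.SeedSequence([config.seed, 9151]).generate_state(1)[0]
            )
            cca = cca_pillai_bootstrap(
                x, y, replications=config.cca_replications, seed=cca_seed
            )
            results["cca"] = {
                "pillai_trace": cca.statistic,
                "p": cca.p,
                "canonical_correlations": cca.extra["canonical_correlations"],
            }
            with open(out / "cca.json", "w") as fh:
                json.dump(results["cca"], fh, indent=1)
        metric_tab, ordinal_tab, failures = _interaction_tables(df, config)
        metric_tab.to_csv(out / "interaction_tests_metric.csv", index=False)
        ordinal_tab.to_csv(out / "interaction_tests_ordinal.csv", index=False)
        results["fit_failures"] = failures

    manifest = {
        "somnostat_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "versions": _library_versions(),
        "note": "p-values are uncorrected for multiple comparisons",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["output_dir"] = str(out)
    log.info("pipeline complete: %s", out)
    return results


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def _library_versions() -> dict:
    import pandas
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }
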
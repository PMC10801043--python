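"""End-to-end pipeline: ingest -> score -> metrics -> statistics -> report.

``run_pipeline`` reads (or synthesizes) a cohort, scores the questionnaires,
computes per-trial polar recall errors and motion analytics, runs the
within-subject statistics, and assembles a :class:`StudyReport` of delimited
tables mirroring the study's reporting layout:

* per-condition SUS and ITC-SOPI-NE summaries with paired t / Wilcoxon tests,
* the landmark x condition recall-error table with its mixed-model ANOVA,
* the phase x condition mean-v_t table with its mixed-model ANOVA,
* per-condition encoding/recall durations and Jaccard similarities,
* a solution-comparison table (SUS, ITC-NE) including optional baseline rows,
* raw-density grids of the motion-pad tilt per condition.

The report is deterministic: same inputs, config and seed give byte-identical
output files.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import AdapterError, DegenerateVarianceError, InputError, ModelError
from . import motion_analytics as ma
from . import questionnaire_scoring as qs
from . import spatial_memory_metrics as smm
from .group_statistics import lmm_anova, paired_t, wilcoxon_signed_rank
from .session_io import (
    CONDITIONS,
    QuestionnaireResponse,
    SessionLog,
    read_cohort,
    validate_session,
)
from .synthetic_cohort import CohortConfig, generate_cohort

#: published reference values of the earlier CAVE prototype, shown alongside
#: the computed rows of the solution-comparison table
DEFAULT_BASELINES = {"CAVE prototype": {"sus_mean": 60.0, "sus_sd": 15.05,
                                        "itc_ne_mean": 1.23, "itc_ne_sd": 0.31}}

_FLOAT_FMT = "%.10g"


@dataclass
class StudyReport:
    """All output tables of one pipeline run, plus the stage log."""

    sus_scores: pd.DataFrame
    sus_tests: pd.DataFrame
    itc_ne_scores: pd.DataFrame
    itc_ne_tests: pd.DataFrame
    error_table: pd.DataFrame
    error_anova: pd.DataFrame
    correct_recall: pd.DataFrame
    vt_table: pd.DataFrame
    vt_anova: pd.DataFrame
    jaccard_summary: pd.DataFrame
    jaccard_tests: pd.DataFrame
    duration_summary: pd.DataFrame
    duration_tests: pd.DataFrame
    comparison_table: pd.DataFrame
    density_grids: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "sus_scores": self.sus_scores,
            "sus_tests": self.sus_tests,
            "itc_ne_scores": self.itc_ne_scores,
            "itc_ne_tests": self.itc_ne_tests,
            "error_table": self.error_table,
            "error_anova": self.error_anova,
            "correct_recall": self.correct_recall,
            "vt_table": self.vt_table,
            "vt_anova": self.vt_anova,
            "jaccard_summary": self.jaccard_summary,
            "jaccard_tests": self.jaccard_tests,
            "duration_summary": self.duration_summary,
            "duration_tests": self.duration_tests,
            "comparison_table": self.comparison_table,
        }
        for cond, grid in self.density_grids.items():
            out[f"density_grid_{cond}"] = grid.to_frame()
        return out

    def write(self, out_dir) -> None:
        """Write every table as CSV plus a text summary; atomic per run.

        Files land in a staging directory first and are moved into place only
        after everything has been written, so a failed run leaves no partial
        output in ``out_dir``.
        """
        out = Path(out_dir)
        staging = out.parent / (out.name + ".partial")
        if staging.exists():
            shutil.rmtree(staging)
        staging.mkdir(parents=True)
        try:
            for name, df in self.tables().items():
                df.to_csv(staging / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
            (staging / "summary.txt").write_text(self.summary_text(), encoding="utf-8")
            (staging / "pipeline.log").write_text("\n".join(self.log) + "\n", encoding="utf-8")
        except Exception:
            shutil.rmtree(staging, ignore_errors=True)
            raise
        out.mkdir(parents=True, exist_ok=True)
        for f in staging.iterdir():
            shutil.move(str(f), out / f.name)
        staging.rmdir()

    def summary_text(self) -> str:
        lines = ["navassess study report", "======================", ""]

        def fmt_tests(df: pd.DataFrame) -> list[str]:
            out = []
            for _, r in df.iterrows():
                extra = f", {int(r['tied_pairs'])} tied pair(s)" if r["tied_pairs"] else ""
                dfs = "" if pd.isna(r["df"]) else f", df={r['df']:.0f}"
                out.append(
                    f"  {r['method']}: statistic={r['statistic']:.3f}{dfs}, "
                    f"p={r['p']:.4f} (n={int(r['n_pairs'])} pairs{extra})"
                )
            return out

        for title, scores, tests in (
            ("SUS (0-100)", self.sus_scores, self.sus_tests),
            ("ITC-SOPI negative effects (1-5)", self.itc_ne_scores, self.itc_ne_tests),
        ):
            lines.append(title)
            for _, r in scores.iterrows():
                band = f" [{r['band']}]" if "band" in scores.columns else ""
                lines.append(
                    f"  {r['condition']}: mean={r['mean']:.2f} (SD {r['sd']:.2f}), "
                    f"n={int(r['n'])}{band}"
                )
            lines += fmt_tests(tests) + [""]

        lines.append("Recall error by landmark x condition (virtual units / degrees)")
        for _, r in self.error_table.iterrows():
            lines.append(
                f"  {r['landmark']:>11s} x {r['condition']:<14s} "
                f"r={r['mean_r']:.2f} (SD {r['sd_r']:.2f})  "
                f"theta={r['mean_theta']:.2f} (SD {r['sd_theta']:.2f})  n={int(r['n_trials'])}"
            )
        for _, r in self.error_anova.iterrows():
            lines.append(
                f"  ANOVA[{r['metric']}] {r['term']}: F({int(r['num_df'])},{r['den_df']:.0f})"
                f"={r['F']:.2f}, p={r['p']:.3f}"
            )
        lines.append("")
        lines.append("Mean v_t by phase x condition")
        for _, r in self.vt_table.iterrows():
            lines.append(
                f"  {r['phase']:>8s} x {r['condition']:<14s} "
                f"v_t={r['mean_vt']:.3f} (SD {r['sd_vt']:.3f})  n={int(r['n'])}"
            )
        for _, r in self.vt_anova.iterrows():
            lines.append(
                f"  ANOVA {r['term']}: F({int(r['num_df'])},{r['den_df']:.1f})"
                f"={r['F']:.2f}, p={r['p']:.3f}"
            )
        lines.append("")
        lines.append("Encoding/recall Jaccard similarity of v_t distributions")
        for _, r in self.jaccard_summary.iterrows():
            lines.append(
                f"  {r['condition']}: mean={r['mean']:.3f} (SD {r['sd']:.3f}), n={int(r['n'])}"
            )
        lines += fmt_tests(self.jaccard_tests) if len(self.jaccard_tests) else []
        lines.append("")
        lines.append("Phase durations (minutes)")
        for _, r in self.duration_summary.iterrows():
            lines.append(
                f"  {r['phase']:>8s} {r['condition']:<14s} "
                f"mean={r['mean']:.2f} (SD {r['sd']:.2f}), n={int(r['n'])}"
            )
        lines.append("")
        lines.append("Solution comparison")
        for _, r in self.comparison_table.iterrows():
            lines.append(
                f"  {r['solution']:<28s} SUS {r['sus_mean']:.2f} ({r['sus_sd']:.2f})   "
                f"ITC-NE {r['itc_ne_mean']:.2f} ({r['itc_ne_sd']:.2f})"
            )
        lines.append("")
        return "\n".join(lines)


def _paired_frame(df: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    """Align one value per participant across the two conditions."""
    wide = df.pivot_table(index="participant_id", columns="condition", values=value, aggfunc="mean")
    wide = wide.dropna(subset=[c for c in CONDITIONS if c in wide.columns])
    if not all(c in wide.columns for c in CONDITIONS):
        return np.array([]), np.array([])
    return wide["immersive"].to_numpy(), wide["semi_immersive"].to_numpy()


def _paired_tests(x: np.ndarray, y: np.ndarray, log: list) -> pd.DataFrame:
    cols = ["method", "statistic", "df", "p", "n_pairs", "tied_pairs"]
    rows = []
    if x.size >= 2:
        try:
            r = paired_t(x, y)
            rows.append([r.method, r.statistic, r.df, r.p, r.n_pairs, r.tied_pairs])
        except DegenerateVarianceError as exc:
            log.append(f"paired_t skipped: {exc}")
        try:
            r = wilcoxon_signed_rank(x, y)
            rows.append([r.method, r.statistic, r.df, r.p, r.n_pairs, r.tied_pairs])
        except InputError as exc:
            log.append(f"wilcoxon skipped: {exc}")
    else:
        log.append(f"paired tests skipped: only {x.size} complete pair(s)")
    return pd.DataFrame(rows, columns=cols)


def _try_anova(data, response, fixed, grouping, log, label) -> pd.DataFrame:
    cols = ["term", "F", "num_df", "den_df", "p"]
    try:
        tab = lmm_anova(data, response=response, fixed=fixed, grouping=grouping)
        log.append(
            f"anova[{label}]: n_obs={tab.n_obs} n_participants={tab.n_groups} "
            f"tau2={tab.tau2:.4g} sigma2={tab.sigma2:.4g} singular={tab.singular}"
        )
        return tab.table
    except (ModelError, InputError) as exc:
        log.append(f"anova[{label}] skipped: {exc}")
        return pd.DataFrame(columns=cols)


def build_report(
    sessions: list[SessionLog],
    questionnaires: list[QuestionnaireResponse],
    jaccard_bin_width: float = ma.JACCARD_BIN_WIDTH,
    jaccard_variant: str = "weighted",
    angle_direction: str = "encoding_to_recall",
    correct_radius: float = smm.CORRECT_RADIUS,
    baselines: dict | None = None,
) -> StudyReport:
    """Assemble the full study report from an in-memory cohort."""
    log: list[str] = []
    log.append(f"ingest: {len(sessions)} sessions, {len(questionnaires)} questionnaire responses")
    n_violations = sum(len(validate_session(s)) for s in sessions)
    log.append(f"validate: {n_violations} structural violations across sessions")
    by_pid = sorted({s.participant_id for s in sessions})
    for pid in by_pid:
        conds = sorted(s.condition for s in sessions if s.participant_id == pid)
        if len(conds) < len(CONDITIONS):
            log.append(f"dropout: participant {pid} has only {conds}")

    # --- questionnaire scoring -------------------------------------------
    score_rows = []
    for q in questionnaires:
        if q.instrument == "SUS":
            s = qs.score_sus(q.items)
            score_rows.append(
                {"participant_id": q.participant_id, "condition": q.condition,
                 "instrument": "SUS", "score": s.value, "band": s.band}
            )
        elif q.instrument == "ITC_SOPI_NE":
            s = qs.score_itc_ne(q.items)
            score_rows.append(
                {"participant_id": q.participant_id, "condition": q.condition,
                 "instrument": "ITC_SOPI_NE", "score": s.value, "band": ""}
            )
    scores = pd.DataFrame(
        score_rows, columns=["participant_id", "condition", "instrument", "score", "band"]
    )

    def instrument_tables(instrument: str, with_band: bool):
        sub = scores[scores["instrument"] == instrument]
        rows = []
        for cond in CONDITIONS:
            vals = sub.loc[sub["condition"] == cond, "score"].to_numpy(dtype=float)
            row = {
                "condition": cond,
                "n": vals.size,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan,
            }
            if with_band:
                row["band"] = qs.sus_band(row["mean"]) if vals.size else ""
            rows.append(row)
        summary = pd.DataFrame(rows)
        x, y = _paired_frame(sub, "score")
        tests = _paired_tests(x, y, log)
        log.append(f"score[{instrument}]: {len(sub)} responses, {x.size} complete pairs")
        return summary, tests

    sus_scores, sus_tests = instrument_tables("SUS", with_band=True)
    itc_scores, itc_tests = instrument_tables("ITC_SOPI_NE", with_band=False)

    # --- spatial memory metrics ------------------------------------------
    all_trials = [t for s in sessions for t in s.trials]
    trial_df = smm.trials_to_frame(all_trials, direction=angle_direction, radius=correct_radius)
    log.append(f"metrics: {len(trial_df)} trials across {len(sessions)} sessions")
    error_table = smm.summarize_errors(trial_df)
    err_anova = pd.concat(
        [
            _anova_frame_with_metric(
                _try_anova(trial_df, "r", ("landmark", "condition"), "participant_id", log, "r"),
                "r",
            ),
            _anova_frame_with_metric(
                _try_anova(
                    trial_df.dropna(subset=["theta_deg"]),
                    "theta_deg", ("landmark", "condition"), "participant_id", log, "theta",
                ),
                "theta",
            ),
        ],
        ignore_index=True,
    )
    correct = (
        trial_df.groupby("condition", sort=True)["correct"]
        .agg(n_trials="size", n_correct="sum")
        .reset_index()
    )
    correct["fraction_correct"] = correct["n_correct"] / correct["n_trials"]

    # --- motion analytics -------------------------------------------------
    vt_rows, jac_rows, dur_rows = [], [], []
    grids: dict[str, dict] = {}
    for s in sessions:
        mags = {}
        for phase, trace in (("encoding", s.encoding_trace), ("recall", s.recall_trace)):
            if trace is None or len(trace) == 0:
                continue
            mag = ma.magnitude_series(trace)
            mags[phase] = mag
            vt_rows.append(
                {"participant_id": s.participant_id, "condition": s.condition,
                 "phase": phase, "mean_vt": float(np.mean(mag.v))}
            )
            if len(trace) >= 2:
                dur_rows.append(
                    {"participant_id": s.participant_id, "condition": s.condition,
                     "phase": phase, "minutes": ma.phase_duration(trace)}
                )
            grid = grids.setdefault(s.condition, {})
            g = ma.density_grid(trace)
            for cell, cnt in g.cells.items():
                grid[cell] = grid.get(cell, 0) + cnt
        if "encoding" in mags and "recall" in mags:
            jac_rows.append(
                {"participant_id": s.participant_id, "condition": s.condition,
                 "jaccard": ma.jaccard_similarity(
                     mags["encoding"], mags["recall"],
                     bin_width=jaccard_bin_width, variant=jaccard_variant,
                 )}
            )
    vt_long = pd.DataFrame(vt_rows, columns=["participant_id", "condition", "phase", "mean_vt"])
    jac_long = pd.DataFrame(jac_rows, columns=["participant_id", "condition", "jaccard"])
    dur_long = pd.DataFrame(dur_rows, columns=["participant_id", "condition", "phase", "minutes"])
    log.append(
        f"motion: {len(vt_long)} phase traces, {len(jac_long)} encoding/recall Jaccard pairs"
    )

    vt_table = (
        vt_long.groupby(["phase", "condition"], sort=True)["mean_vt"]
        .agg(n="size", mean_vt="mean", sd_vt=lambda v: v.std(ddof=1))
        .reset_index()[["phase", "condition", "mean_vt", "sd_vt", "n"]]
        if len(vt_long)
        else pd.DataFrame(columns=["phase", "condition", "mean_vt", "sd_vt", "n"])
    )
    vt_anova = _try_anova(vt_long, "mean_vt", ("phase", "condition"), "participant_id", log, "vt")

    jac_summary = (
        jac_long.groupby("condition", sort=True)["jaccard"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()[["condition", "mean", "sd", "n"]]
        if len(jac_long)
        else pd.DataFrame(columns=["condition", "mean", "sd", "n"])
    )
    jx, jy = _paired_frame(jac_long, "jaccard") if len(jac_long) else (np.array([]), np.array([]))
    jac_tests = _paired_tests(jx, jy, log)

    dur_summary = (
        dur_long.groupby(["phase", "condition"], sort=True)["minutes"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()[["phase", "condition", "mean", "sd", "n"]]
        if len(dur_long)
        else pd.DataFrame(columns=["phase", "condition", "mean", "sd", "n"])
    )
    dur_test_rows = []
    for phase in ("encoding", "recall"):
        sub = dur_long[dur_long["phase"] == phase]
        dx, dy = _paired_frame(sub, "minutes") if len(sub) else (np.array([]), np.array([]))
        t = _paired_tests(dx, dy, log)
        t.insert(0, "phase", phase)
        dur_test_rows.append(t)
    dur_tests = pd.concat(dur_test_rows, ignore_index=True) if dur_test_rows else pd.DataFrame()

    # --- comparison table --------------------------------------------------
    comp_rows = []
    for name, vals in (baselines if baselines is not None else DEFAULT_BASELINES).items():
        comp_rows.append({"solution": name, **vals, "source": "reference"})
    for cond in CONDITIONS:
        srow = sus_scores[sus_scores["condition"] == cond].iloc[0]
        irow = itc_scores[itc_scores["condition"] == cond].iloc[0]
        comp_rows.append(
            {"solution": f"this study ({cond})", "sus_mean": srow["mean"], "sus_sd": srow["sd"],
             "itc_ne_mean": irow["mean"], "itc_ne_sd": irow["sd"], "source": "computed"}
        )
    comparison = pd.DataFrame(
        comp_rows, columns=["solution", "sus_mean", "sus_sd", "itc_ne_mean", "itc_ne_sd", "source"]
    )

    density = {
        cond: ma.DensityGrid(bin_width=ma.DENSITY_BIN_WIDTH, cells=cells)
        for cond, cells in sorted(grids.items())
    }
    log.append("report: assembled all tables")
    return StudyReport(
        sus_scores=sus_scores,
        sus_tests=sus_tests,
        itc_ne_scores=itc_scores,
        itc_ne_tests=itc_tests,
        error_table=error_table,
        error_anova=err_anova,
        correct_recall=correct,
        vt_table=vt_table,
        vt_anova=vt_anova,
        jaccard_summary=jac_summary,
        jaccard_tests=jac_tests,
        duration_summary=dur_summary,
        duration_tests=dur_tests,
        comparison_table=comparison,
        density_grids=density,
        log=log,
    )


def _anova_frame_with_metric(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    df = df.copy()
    df.insert(0, "metric", metric)
    return df


def run_pipeline(
    input_dir=None,
    synthetic: bool = False,
    config: CohortConfig | None = None,
    seed: int | None = None,
    out_dir=None,
    **report_kwargs,
) -> StudyReport:
    """Run the full pipeline and (optionally) write the report tables.

    Either ``input_dir`` (a directory in the documented log format) or
    ``synthetic=True`` must be given; with ``synthetic`` the cohort comes
    from :func:`generate_cohort` under ``config`` (study defaults if None)
    and ``seed``.
    """
    if synthetic:
        cfg = config if config is not None else CohortConfig()
        sessions, questionnaires = generate_cohort(cfg, seed=seed)
        source = f"synthetic cohort (seed={cfg.seed if seed is None else seed})"
        report_kwargs.setdefault("correct_radius", cfg.correct_radius)
    elif input_dir is not None:
        sessions, questionnaires = read_cohort(input_dir)
        source = f"log directory {input_dir}"
    else:
        raise InputError("run_pipeline needs input_dir or synthetic=True")
    report = build_report(sessions, questionnaires, **report_kwargs)
    report.log.insert(0, f"source: {source}")
    if out_dir is not None:
        report.write(out_dir)
        report.log.append(f"wrote report to {out_dir}")
    return report


def import_deposited(path) -> tuple[list[SessionLog], list[QuestionnaireResponse]]:
    """Best-effort adapter for an unpacked external data deposit.

    If the directory already follows the package's documented log format it is
    read directly; otherwise an :class:`AdapterError` lists the files found so
    a mapping can be written against the actual archive layout.
    """
    root = Path(path)
    if not root.is_dir():
        raise AdapterError(f"{root} is not a directory")
    if (root / "sessions.csv").exists():
        return read_cohort(root)
    found = sorted(str(p.relative_to(root)) for p in root.rglob("*") if p.is_file())
    raise AdapterError(
        "unrecognized deposit layout; no sessions.csv found. Files present: "
        + (", ".join(found[:50]) if found else "(none)")
    )
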
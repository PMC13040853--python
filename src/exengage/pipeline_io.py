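"""File formats, trial configuration, and the end-to-end trial analysis.

All on-disk formats are delimited text:

* skeleton streams — long format, one row per joint per frame, header
  ``time_s, joint, x_m, y_m, z_m, confidence`` (confidence 0 or an absent
  row marks a missing marker);
* session logs — ``session_index, condition, exercise, attempted, quality,
  prescribed, best_time_s, fun_rating, helpful_rating, phase``;
* agreement tables — ``video_id, manual, system[, rater2]``.

:func:`run_trial` chains detection -> scoring -> design -> statistics ->
agreement into one reproducible report; (config, inputs, seed) fully
determine every reported number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import sced_stats as ss
from .engagement import CONDITIONS, ExerciseOutcome, SessionRecord, summarize_session
from .errors import ConfigurationError, OrderingError, SchemaError
from .kinematics import (
    JOINT_INDEX,
    JOINT_NAMES,
    ExerciseDefinition,
    SkeletonSequence,
    default_exercises,
    detect_attempts,
    assess_quality,
    time_hold,
)
from .sced_design import enumerate_schedules, select_best_alone

SKELETON_COLUMNS = ["time_s", "joint", "x_m", "y_m", "z_m", "confidence"]
SESSION_COLUMNS = ["session_index", "condition", "exercise", "attempted",
                   "quality", "prescribed", "best_time_s", "fun_rating",
                   "helpful_rating", "phase"]

#: Outcome scales for the visual summaries: adherence/fidelity proportions
#: (upper bound generous since both may exceed 1), smiley ratings 1-5.
OUTCOME_SCALES = {"adherence": (0.0, 1.25), "fidelity": (0.0, 1.25),
                  "fun": (1.0, 5.0), "helpful": (1.0, 5.0)}


# --------------------------------------------------------------------------
# Skeleton streams
# --------------------------------------------------------------------------

def write_skeleton(seq: SkeletonSequence, path) -> None:
    rows = []
    for i, t in enumerate(seq.times):
        for j, name in enumerate(JOINT_NAMES):
            if seq.missing[i, j]:
                rows.append((t, name, 0.0, 0.0, 0.0, 0))
            else:
                x, y, z = seq.xyz[i, j]
                rows.append((t, name, x, y, z, 1))
    pd.DataFrame(rows, columns=SKELETON_COLUMNS).to_csv(path, index=False)


def read_skeleton(path) -> SkeletonSequence:
    """Read a long-format skeleton file into a validated sequence.

    Unknown joint names raise :class:`SchemaError` with the offending line;
    non-monotonic frame times raise :class:`OrderingError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(SKELETON_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    bad = ~df["joint"].isin(JOINT_NAMES)
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(
            f"{path}: unknown joint {df.loc[row, 'joint']!r} at line {row + 2}")
    times = df["time_s"].drop_duplicates().to_numpy()
    if np.any(np.diff(times) <= 0):
        raise OrderingError(f"{path}: frame times are not strictly increasing")

    n = len(times)
    xyz = np.full((n, len(JOINT_NAMES), 3), np.nan)
    missing = np.ones((n, len(JOINT_NAMES)), dtype=bool)
    t_index = {t: i for i, t in enumerate(times)}
    ji = df["joint"].map(JOINT_INDEX).to_numpy()
    ti = df["time_s"].map(t_index).to_numpy()
    ok = df["confidence"].to_numpy() > 0
    xyz[ti[ok], ji[ok]] = df.loc[ok, ["x_m", "y_m", "z_m"]].to_numpy()
    missing[ti[ok], ji[ok]] = False
    return SkeletonSequence(times=times, xyz=xyz, missing=missing)


# --------------------------------------------------------------------------
# Session logs and agreement tables
# --------------------------------------------------------------------------

def write_sessions(records: list[SessionRecord], path) -> None:
    rows = []
    for r in records:
        if r.exercises:
            for name, o in r.exercises.items():
                rows.append((r.session_index, r.condition, name, o.attempted,
                             o.quality, o.prescribed,
                             o.quality if o.mode == "timed" else "",
                             r.fun_rating, r.helpful_rating, r.phase))
        else:
            rows.append((r.session_index, r.condition, "_session",
                         r.adherence, r.fidelity, 1.0, "",
                         r.fun_rating, r.helpful_rating, r.phase))
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_sessions(path) -> list[SessionRecord]:
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, grp in df.groupby("session_index", sort=True):
        cond = grp["condition"].iloc[0]
        if cond not in CONDITIONS:
            raise SchemaError(f"{path}: unknown condition {cond!r}")
        fun = grp["fun_rating"].iloc[0]
        helpful = grp["helpful_rating"].iloc[0]
        phase = grp["phase"].iloc[0] if "phase" in grp else "comparison"
        rec = SessionRecord(
            session_index=int(idx), condition=cond,
            fun_rating=None if pd.isna(fun) else int(fun),
            helpful_rating=None if pd.isna(helpful) else int(helpful),
            phase=str(phase))
        if set(grp["exercise"]) == {"_session"}:
            rec.adherence = float(grp["attempted"].iloc[0])
            rec.fidelity = float(grp["quality"].iloc[0])
        else:
            adh, fid = [], []
            for _, row in grp.iterrows():
                o = ExerciseOutcome(row["exercise"], float(row["attempted"]),
                                    float(row["quality"]), float(row["prescribed"]))
                rec.exercises[o.name] = o
                adh.append(o.attempted / o.prescribed)
                fid.append(o.quality / o.prescribed)
            rec.adherence = sum(adh) / len(adh)
            rec.fidelity = sum(fid) / len(fid)
        records.append(rec)
    return records


def write_agreement_table(table: agr.AgreementTable, path) -> None:
    data = {"video_id": table.video_id, "manual": table.manual,
            "system": table.system}
    if table.rater2 is not None:
        data["rater2"] = table.rater2
    pd.DataFrame(data).to_csv(path, index=False)


def read_agreement_table(path) -> agr.AgreementTable:
    df = pd.read_csv(path)
    if not {"video_id", "manual", "system"} <= set(df.columns):
        raise SchemaError(f"{path}: need columns video_id, manual, system")
    return agr.AgreementTable(
        video_id=df["video_id"].astype(str).tolist(),
        manual=df["manual"].to_numpy(float),
        system=df["system"].to_numpy(float),
        rater2=df["rater2"].to_numpy(float) if "rater2" in df else None)


# --------------------------------------------------------------------------
# Trial configuration
# --------------------------------------------------------------------------

@dataclass
class TrialConfig:
    """Everything that parameterizes one participant's trial analysis."""

    participant: str = "child"
    exercises: dict[str, ExerciseDefinition] = field(default_factory=default_exercises)
    n_sessions: int = 16
    max_run: int = 2
    balance: bool = True
    schedule_seed: int = 0
    alternative: str = "greater"
    n_mc: int = ss.DEFAULT_N_MC
    alpha: float = 0.05
    feedback_caps: bool = True
    aggregate: str = "mean"
    small_sample_cutoff: int = 5  # below this per condition: Bayes factor
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_sessions < 2 or self.max_run < 1:
            raise ConfigurationError("need n_sessions >= 2 and max_run >= 1")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "exercises"}
        d["exercises"] = {
            name: {k: v for k, v in ex.__dict__.items() if v not in (None, {}, [])}
            for name, ex in self.exercises.items()}
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @staticmethod
    def from_yaml(path) -> "TrialConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ex_raw = raw.pop("exercises", None)
        cfg = TrialConfig(**raw)
        if ex_raw:
            cfg.exercises = {
                name: ExerciseDefinition(
                    **{"name": name, **{k: v for k, v in spec.items() if k != "name"}})
                for name, spec in ex_raw.items()}
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# End-to-end trial analysis
# --------------------------------------------------------------------------

def score_session(streams: dict[str, SkeletonSequence], config: TrialConfig,
                  condition: str, session_index: int = 0,
                  phase: str = "comparison") -> SessionRecord:
    """Detect and grade repetitions in one session's skeleton streams."""
    observations = {}
    for name, seq in streams.items():
        if name not in config.exercises:
            raise ConfigurationError(f"no definition for exercise {name!r}")
        ex = config.exercises[name]
        if ex.mode == "timed":
            observations[name] = time_hold(seq, ex)
        else:
            events = detect_attempts(seq, ex)
            if ex.quality_rules:
                events = [assess_quality(e, seq, ex) for e in events]
            else:
                events = [e for e in events]
                for e in events:
                    e.quality = False
            observations[name] = events
    return summarize_session(observations, config.exercises, condition,
                             session_index=session_index,
                             feedback_caps=config.feedback_caps,
                             aggregate=config.aggregate, phase=phase)


def run_trial(config: TrialConfig, sessions: list[SessionRecord],
              agreement_table: agr.AgreementTable | None = None) -> dict:
    """The full analysis chain on scored session records.

    Produces visual summaries and PND per outcome, the best-alone decision,
    the configured statistical battery on the comparison phase, and an
    agreement section when manual counts are supplied. Per-session failures
    are isolated and recorded rather than aborting the run.
    """
    report: dict = {
        "participant": config.participant,
        "settings": {"alpha": config.alpha, "alternative": config.alternative,
                     "n_mc": config.n_mc, "seed": config.seed,
                     "config_hash": config.config_hash()},
        "sessions": [], "outcomes": {}, "errors": [],
    }
    for rec in sessions:
        report["sessions"].append({
            "session_index": rec.session_index, "condition": rec.condition,
            "phase": rec.phase, "adherence": rec.adherence,
            "fidelity": rec.fidelity, "fun": rec.fun_rating,
            "helpful": rec.helpful_rating})

    comparison = [r for r in sessions if r.phase == "comparison"]
    for outcome in ("adherence", "fidelity", "fun", "helpful"):
        recs = [r for r in comparison
                if getattr(r, ss.ATDSeries._FIELD[outcome]) is not None]
        if len(recs) < 2:
            continue
        series = ss.ATDSeries(recs, outcome_name=outcome)
        entry: dict = {}
        try:
            vs = ss.visual_summary(series, OUTCOME_SCALES[outcome])
            entry["visual"] = {"level": vs.level, "trend": vs.trend,
                               "variability": vs.variability,
                               "mean": vs.mean, "pnd": vs.pnd}
        except Exception as exc:  # degenerate series: record, keep going
            report["errors"].append({"stage": "visual", "outcome": outcome,
                                     "error": str(exc)})
        report["outcomes"][outcome] = entry

    # best-alone decision on comparison-phase adherence
    adh_series = ss.ATDSeries(comparison, outcome_name="adherence")
    try:
        decision = select_best_alone(adh_series)
        report["best_alone"] = {
            "condition": decision.condition, "rule": decision.rule,
            "pnd_feedback": decision.pnd_feedback,
            "pnd_no_feedback": decision.pnd_no_feedback,
            "mean_feedback": decision.mean_feedback,
            "mean_no_feedback": decision.mean_no_feedback,
            "detail": decision.detail}
    except Exception as exc:
        report["errors"].append({"stage": "best_alone", "error": str(exc)})

    # statistical battery on the comparison phase
    tests: list[dict] = []
    conds = adh_series.conditions
    n_f = int((conds == "feedback").sum())
    n_n = int((conds == "no_feedback").sum())
    a = adh_series.condition_values("feedback")
    b = adh_series.condition_values("no_feedback")
    try:
        if min(n_f, n_n) < config.small_sample_cutoff:
            res = ss.bayes_factor_t(a, b)
        else:
            space = enumerate_schedules(len(conds), config.max_run, config.balance)
            res = ss.scrt(adh_series, space, alternative=config.alternative,
                          n_mc=config.n_mc, seed=config.seed)
        tests.append(_test_record(res, "adherence"))
    except Exception as exc:
        report["errors"].append({"stage": "adherence_test", "error": str(exc)})

    fid = ss.ATDSeries([r for r in comparison if r.fidelity is not None],
                       outcome_name="fidelity")
    fa = fid.condition_values("feedback")
    fb = fid.condition_values("no_feedback")
    try:
        if len(fa) == len(fb):
            res = ss.wilcoxon_pratt(fa, fb, alternative=config.alternative,
                                    n_mc=config.n_mc, seed=config.seed)
        else:
            res = ss.fisher_pitman(fa, fb, alternative=config.alternative,
                                   n_mc=config.n_mc, seed=config.seed)
        tests.append(_test_record(res, "fidelity"))
    except Exception as exc:
        report["errors"].append({"stage": "fidelity_test", "error": str(exc)})
    report["tests"] = tests

    if agreement_table is not None:
        w = agr.wmre(agreement_table)
        ba = agr.bland_altman(agreement_table)
        section = {"wmre_pct": w.wmre, "acceptable": w.acceptable,
                   "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high}
        if agreement_table.rater2 is not None:
            icc = agr.icc_2_1(np.column_stack(
                [agreement_table.manual, agreement_table.rater2]))
            section["icc"] = icc.icc
            section["icc_ci"] = list(icc.icc_ci)
            section["icc_grade"] = icc.icc_grade
        report["agreement"] = section
    return report


def _test_record(res: ss.TestResult, outcome: str) -> dict:
    return {"outcome": outcome, "method": res.method,
            "statistic": res.statistic, "p_value": res.p_value,
            "bayes_factor": res.bayes_factor, "n_resamples": res.n_resamples,
            "exhaustive": res.exhaustive, "alternative": res.alternative,
            "seed": res.seed}


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def write_report(report: dict, out_dir) -> dict[str, Path]:
    """Write a machine-readable JSON report plus a human-readable summary.

    The JSON round-trips losslessly; the text summary prints PND to one
    decimal place. Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")

    lines = [f"Trial report: {report.get('participant', '?')}",
             f"config hash: {report['settings']['config_hash']}  "
             f"seed: {report['settings']['seed']}", ""]
    for outcome, entry in report.get("outcomes", {}).items():
        v = entry.get("visual")
        if v:
            pnd_txt = "n/a" if v["pnd"] is None else f"{v['pnd']:.1f}%"
            lines.append(f"{outcome}: level {v['level']}, trend {v['trend']}, "
                         f"{v['variability']}, PND {pnd_txt}")
    if "best_alone" in report:
        ba = report["best_alone"]
        lines += ["", f"best-alone condition: {ba['condition']} "
                      f"(rule: {ba['rule']}) - {ba['detail']}"]
    for t in report.get("tests", []):
        if t["p_value"] is not None:
            lines.append(f"{t['outcome']}: {t['method']} stat={t['statistic']:.4f} "
                         f"p={t['p_value']:.4g}")
        else:
            lines.append(f"{t['outcome']}: {t['method']} stat={t['statistic']:.4f} "
                         f"BF10={t['bayes_factor']:.3g}")
    if "agreement" in report:
        a = report["agreement"]
        lines += ["", f"agreement: WMRE {a['wmre_pct']:.1f}% "
                      f"({'acceptable' if a['acceptable'] else 'not acceptable'}), "
                      f"bias {a['bias']:.2f} "
                      f"[{a['loa_low']:.2f}, {a['loa_high']:.2f}]"]
        if "icc" in a:
            lines.append(f"ICC(2,1) {a['icc']:.3f} "
                         f"CI [{a['icc_ci'][0]:.3f}, {a['icc_ci'][1]:.3f}] "
                         f"({a['icc_grade']})")
    if report.get("errors"):
        lines += ["", "recorded failures:"]
        lines += [f"  {e}" for e in report["errors"]]
    txt_path = out / "summary.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "summary": txt_path}


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(path) -> dict:
    with open(Path(path) / "report.json" if Path(path).is_dir() else path) as fh:
        return json.load(fh)
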
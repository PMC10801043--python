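"""Session log data model and delimited-text persistence.

A *session* is one participant completing (or aborting) one VR condition:
16 object-relocation trials (4 items x 4 repetition blocks), one foot-motion-pad
trace per task phase (encoding, recall) sampled at 100 Hz, and per-phase
durations.  Questionnaire responses (SUS, ITC-SOPI negative effects) are stored
per cohort.

On-disk layout (all files are UTF-8 CSV, ``.`` decimal, comma separator, with a
version line ``# navassess-log v1`` above the header row)::

    <root>/sessions.csv         one row per session (durations, completed flag)
    <root>/trials.csv           all trial records of the cohort
    <root>/questionnaires.csv   long-format item responses
    <root>/motion/<pid>__<condition>__<phase>.csv   t_ms,pitch_y,yaw_z

Column-by-column schema documentation ships in ``docs/log_format.md``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, InputError, ParseError, SessionValidationError

FORMAT_VERSION = "navassess-log v1"
_VERSION_LINE = f"# {FORMAT_VERSION}"

CONDITIONS = ("immersive", "semi_immersive")
LANDMARKS = ("allocentric", "egocentric")
INSTRUMENTS = ("SUS", "ITC_SOPI_NE")
PHASES = ("encoding", "recall")

#: nominal motion-pad sampling interval (100 Hz)
NOMINAL_DT_MS = 10
#: a gap longer than this many nominal intervals is flagged by validation
GAP_FACTOR = 2
#: trials in a completed session: 4 items x 4 repetition blocks
TRIALS_PER_SESSION = 16
#: tolerated mismatch between the stored phase duration and the trace extent
DURATION_TOL_MIN = 0.01


@dataclass(frozen=True)
class TrialRecord:
    """One encoding-item / recall-response pair.

    Coordinates live on the horizontal (x, z) plane of the virtual environment,
    in virtual units; ``recall_latency`` is the time (s) taken to replace the
    item at recall.
    """

    participant_id: str
    condition: str
    landmark: str
    item_id: int
    repetition: int
    enc_x: float
    enc_z: float
    rec_x: float
    rec_z: float
    recall_latency: float


@dataclass(frozen=True)
class MotionSample:
    """One 100 Hz foot-motion-pad sample.

    ``pitch_y`` is the toe–heel tilt (drives forward/backward translation),
    ``yaw_z`` the left–right tilt (drives rotation); both are dimensionless
    normalized tilts, nominally in [-1, 1].
    """

    t_ms: int
    pitch_y: float
    yaw_z: float


class MotionTrace:
    """A motion-pad trace stored as aligned numpy arrays.

    Iterating yields :class:`MotionSample` records; array access is via the
    ``t_ms``, ``pitch_y`` and ``yaw_z`` attributes.
    """

    __slots__ = ("t_ms", "pitch_y", "yaw_z")

    def __init__(self, t_ms, pitch_y, yaw_z):
        t_ms = np.asarray(t_ms, dtype=np.int64)
        pitch_y = np.asarray(pitch_y, dtype=np.float64)
        yaw_z = np.asarray(yaw_z, dtype=np.float64)
        if not (t_ms.shape == pitch_y.shape == yaw_z.shape) or t_ms.ndim != 1:
            raise InputError("trace arrays must be 1-D and of equal length")
        self.t_ms = t_ms
        self.pitch_y = pitch_y
        self.yaw_z = yaw_z

    @classmethod
    def from_samples(cls, samples: Iterable[MotionSample]) -> "MotionTrace":
        samples = list(samples)
        return cls(
            [s.t_ms for s in samples],
            [s.pitch_y for s in samples],
            [s.yaw_z for s in samples],
        )

    def __len__(self) -> int:
        return self.t_ms.size

    def __iter__(self) -> Iterator[MotionSample]:
        for t, p, y in zip(self.t_ms, self.pitch_y, self.yaw_z):
            yield MotionSample(int(t), float(p), float(y))

    def __eq__(self, other) -> bool:
        if not isinstance(other, MotionTrace):
            return NotImplemented
        return (
            np.array_equal(self.t_ms, other.t_ms)
            and np.array_equal(self.pitch_y, other.pitch_y)
            and np.array_equal(self.yaw_z, other.yaw_z)
        )

    def __repr__(self) -> str:
        return f"MotionTrace(n={len(self)})"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t_ms, "pitch_y": self.pitch_y, "yaw_z": self.yaw_z}
        )


@dataclass
class SessionLog:
    """All data of one participant x condition session.

    ``completed`` is False for sessions aborted mid-task (the study's
    cybersickness dropouts); aborted sessions may carry fewer than 16 trials.
    Durations are in minutes.
    """

    participant_id: str
    condition: str
    trials: list[TrialRecord] = field(default_factory=list)
    encoding_trace: MotionTrace | None = None
    recall_trace: MotionTrace | None = None
    encoding_duration: float = 0.0
    recall_duration: float = 0.0
    completed: bool = True

    @property
    def key(self) -> tuple[str, str]:
        return (self.participant_id, self.condition)


@dataclass(frozen=True)
class QuestionnaireResponse:
    """An ordered Likert item vector for one instrument in one condition.

    Items are integers 1–5; ``None`` marks an item left blank (the ITC-SOPI
    negative-effects score is the mean of completed items only).
    """

    participant_id: str
    condition: str
    instrument: str
    items: tuple[int | None, ...]


@dataclass(frozen=True)
class Violation:
    """One structural-invariant violation found by :func:`validate_session`."""

    invariant: str
    location: str
    message: str

    def __str__(self) -> str:
        return f"[{self.invariant}] {self.location}: {self.message}"


# ---------------------------------------------------------------------------
# validation


def _validate_trace(trace: MotionTrace | None, where: str) -> list[Violation]:
    out: list[Violation] = []
    if trace is None or len(trace) == 0:
        return out
    dt = np.diff(trace.t_ms)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        out.append(
            Violation(
                "monotone_timestamps",
                where,
                f"t_ms not strictly increasing at sample {i + 1}",
            )
        )
    gaps = np.nonzero(dt > GAP_FACTOR * NOMINAL_DT_MS)[0]
    for i in gaps:
        out.append(
            Violation(
                "sampling_gap",
                where,
                f"gap of {int(dt[i])} ms after sample {int(i)} "
                f"(> {GAP_FACTOR} x {NOMINAL_DT_MS} ms nominal interval)",
            )
        )
    if not (np.isfinite(trace.pitch_y).all() and np.isfinite(trace.yaw_z).all()):
        out.append(Violation("finite_tilt", where, "non-finite pitch/yaw value"))
    return out


def validate_session(s: SessionLog) -> list[Violation]:
    """Check every structural invariant of a session; violations are data.

    Returns an empty list iff the session is well formed.  Never raises.
    """
    out: list[Violation] = []
    where = f"session {s.participant_id}/{s.condition}"

    if s.condition not in CONDITIONS:
        out.append(Violation("condition_label", where, f"unknown condition {s.condition!r}"))
    if s.completed and len(s.trials) != TRIALS_PER_SESSION:
        out.append(
            Violation(
                "trial_count",
                where,
                f"completed session has {len(s.trials)} trials, expected {TRIALS_PER_SESSION}",
            )
        )

    seen: set[tuple[int, int]] = set()
    block_landmark: dict[int, str] = {}
    for i, t in enumerate(s.trials):
        twhere = f"{where} trial {i}"
        if t.landmark not in LANDMARKS:
            out.append(Violation("landmark_label", twhere, f"unknown landmark {t.landmark!r}"))
        coords = (t.enc_x, t.enc_z, t.rec_x, t.rec_z)
        if not all(math.isfinite(c) for c in coords):
            out.append(Violation("finite_coordinates", twhere, f"non-finite coordinate in {coords}"))
        if not (t.recall_latency >= 0 and math.isfinite(t.recall_latency)):
            out.append(Violation("latency_nonnegative", twhere, f"recall_latency {t.recall_latency}"))
        key = (t.item_id, t.repetition)
        if key in seen:
            out.append(
                Violation("unique_item_repetition", twhere, f"duplicate (item_id, repetition) {key}")
            )
        seen.add(key)
        prev = block_landmark.setdefault(t.repetition, t.landmark)
        if prev != t.landmark:
            out.append(
                Violation(
                    "landmark_constant_in_block",
                    twhere,
                    f"repetition block {t.repetition} mixes landmarks {prev!r} and {t.landmark!r}",
                )
            )

    for phase, trace, duration in (
        ("encoding", s.encoding_trace, s.encoding_duration),
        ("recall", s.recall_trace, s.recall_duration),
    ):
        twhere = f"{where} {phase} trace"
        out.extend(_validate_trace(trace, twhere))
        if duration < 0:
            out.append(Violation("duration_nonnegative", twhere, f"duration {duration} min"))
        if trace is not None and len(trace) >= 2:
            extent_min = float(trace.t_ms[-1] - trace.t_ms[0]) / 60000.0
            if abs(extent_min - duration) > DURATION_TOL_MIN:
                out.append(
                    Violation(
                        "duration_matches_trace",
                        twhere,
                        f"stored duration {duration:.4f} min vs trace extent "
                        f"{extent_min:.4f} min (tolerance {DURATION_TOL_MIN} min)",
                    )
                )
    return out


def validate_questionnaire(q: QuestionnaireResponse) -> list[Violation]:
    """Instrument-specific structural checks on a response vector."""
    out: list[Violation] = []
    where = f"questionnaire {q.participant_id}/{q.condition}/{q.instrument}"
    if q.instrument not in INSTRUMENTS:
        out.append(Violation("instrument_label", where, f"unknown instrument {q.instrument!r}"))
    if q.instrument == "SUS":
        if len(q.items) != 10:
            out.append(Violation("sus_item_count", where, f"{len(q.items)} items, expected 10"))
        if any(i is None for i in q.items):
            out.append(Violation("sus_complete", where, "SUS items must all be answered"))
    for idx, item in enumerate(q.items, start=1):
        if item is not None and item not in (1, 2, 3, 4, 5):
            out.append(Violation("likert_range", where, f"item {idx} response {item!r} not in 1–5"))
    return out


# ---------------------------------------------------------------------------
# reading and writing


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_VERSION_LINE + "\n")
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path, columns: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith("# navassess-log"):
        raise ParseError(path, f"missing version line (got {first!r})", line=1)
    if first != _VERSION_LINE:
        raise ParseError(path, f"unsupported log version {first!r}", line=1)
    try:
        df = pd.read_csv(path, skiprows=1, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas messages vary
        raise ParseError(path, f"unreadable CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(path, f"missing column(s) {missing}", line=2)
    for col in numeric:
        raw = df[col]
        conv = pd.to_numeric(raw, errors="coerce")
        bad = conv.isna() & (raw.str.strip() != "")
        empty = raw.str.strip() == ""
        bad |= empty
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            # +3: version line, header line, 1-based data rows
            raise ParseError(
                path, f"malformed value {raw.iloc[i]!r}", line=i + 3, column=col
            )
        # numpy's string parser is correctly rounded, so %.17g output
        # round-trips bit-identically (pandas' fast to_numeric parser is not)
        df[col] = np.asarray(raw.to_numpy(), dtype=np.float64)
    return df


_TRIAL_COLS = [
    "participant_id", "condition", "landmark", "item_id", "repetition",
    "enc_x", "enc_z", "rec_x", "rec_z", "recall_latency_s",
]
_TRIAL_NUM = ["item_id", "repetition", "enc_x", "enc_z", "rec_x", "rec_z", "recall_latency_s"]
_SESSION_COLS = [
    "participant_id", "condition", "encoding_duration_min", "recall_duration_min", "completed",
]
_MOTION_COLS = ["t_ms", "pitch_y", "yaw_z"]
_QUEST_COLS = ["participant_id", "condition", "instrument", "item_index", "response"]


def _motion_path(root: Path, pid: str, condition: str, phase: str) -> Path:
    return root / "motion" / f"{pid}__{condition}__{phase}.csv"


def write_sessions(sessions: Iterable[SessionLog], path: str | os.PathLike) -> None:
    """Write a session collection to ``path`` in the documented CSV layout.

    An empty collection produces a valid (empty) ``sessions.csv`` /
    ``trials.csv`` pair.  Numeric fields are serialized at full precision so
    that :func:`read_sessions` round-trips bit-identically.
    """
    root = Path(path)
    sessions = list(sessions)
    srows, trows = [], []
    for s in sessions:
        srows.append(
            {
                "participant_id": s.participant_id,
                "condition": s.condition,
                "encoding_duration_min": s.encoding_duration,
                "recall_duration_min": s.recall_duration,
                "completed": "true" if s.completed else "false",
            }
        )
        for t in s.trials:
            trows.append(
                {
                    "participant_id": t.participant_id,
                    "condition": t.condition,
                    "landmark": t.landmark,
                    "item_id": t.item_id,
                    "repetition": t.repetition,
                    "enc_x": t.enc_x,
                    "enc_z": t.enc_z,
                    "rec_x": t.rec_x,
                    "rec_z": t.rec_z,
                    "recall_latency_s": t.recall_latency,
                }
            )
    _write_csv(pd.DataFrame(srows, columns=_SESSION_COLS), root / "sessions.csv")
    _write_csv(pd.DataFrame(trows, columns=_TRIAL_COLS), root / "trials.csv")
    for s in sessions:
        for phase, trace in (("encoding", s.encoding_trace), ("recall", s.recall_trace)):
            if trace is not None:
                _write_csv(trace.to_frame(), _motion_path(root, s.participant_id, s.condition, phase))


def read_sessions(path: str | os.PathLike, schema: str = "v1") -> list[SessionLog]:
    """Read every session under ``path``.

    An existing directory without a ``sessions.csv`` yields an empty list.
    Malformed rows raise :class:`ParseError` naming file, line and column;
    duplicated (item_id, repetition) pairs and non-monotone motion timestamps
    raise :class:`SessionValidationError`.  Softer invariants (sampling gaps,
    trial counts of aborted sessions, duration mismatches) are left to
    :func:`validate_session`.
    """
    if schema != "v1":
        raise ConfigError(f"unknown log schema {schema!r}")
    root = Path(path)
    if not root.is_dir():
        raise InputError(f"session directory {root} does not exist")
    sfile = root / "sessions.csv"
    if not sfile.exists():
        return []
    sdf = _read_csv(sfile, _SESSION_COLS, ["encoding_duration_min", "recall_duration_min"])
    tfile = root / "trials.csv"
    tdf = (
        _read_csv(tfile, _TRIAL_COLS, _TRIAL_NUM)
        if tfile.exists()
        else pd.DataFrame(columns=_TRIAL_COLS)
    )

    sessions: list[SessionLog] = []
    for _, row in sdf.iterrows():
        pid, cond = row["participant_id"], row["condition"]
        completed = str(row["completed"]).strip().lower()
        if completed not in ("true", "false"):
            raise ParseError(sfile, f"completed flag {row['completed']!r} not true/false")
        mask = (tdf["participant_id"] == pid) & (tdf["condition"] == cond) if len(tdf) else []
        trials = []
        seen: set[tuple[int, int]] = set()
        sub = tdf[mask] if len(tdf) else tdf
        for _, tr in sub.iterrows():
            rec = TrialRecord(
                participant_id=pid,
                condition=cond,
                landmark=tr["landmark"],
                item_id=int(tr["item_id"]),
                repetition=int(tr["repetition"]),
                enc_x=float(tr["enc_x"]),
                enc_z=float(tr["enc_z"]),
                rec_x=float(tr["rec_x"]),
                rec_z=float(tr["rec_z"]),
                recall_latency=float(tr["recall_latency_s"]),
            )
            key = (rec.item_id, rec.repetition)
            if key in seen:
                raise SessionValidationError(
                    f"{tfile}: duplicate (item_id, repetition) {key} in session {pid}/{cond}"
                )
            seen.add(key)
            trials.append(rec)
        traces: dict[str, MotionTrace | None] = {}
        for phase in PHASES:
            mpath = _motion_path(root, pid, cond, phase)
            if mpath.exists():
                mdf = _read_csv(mpath, _MOTION_COLS, _MOTION_COLS)
                t_ms = mdf["t_ms"].to_numpy()
                if np.any(np.diff(t_ms) <= 0):
                    raise SessionValidationError(
                        f"{mpath}: non-monotone t_ms in {phase} trace of {pid}/{cond}"
                    )
                traces[phase] = MotionTrace(t_ms, mdf["pitch_y"].to_numpy(), mdf["yaw_z"].to_numpy())
            else:
                traces[phase] = None
        sessions.append(
            SessionLog(
                participant_id=pid,
                condition=cond,
                trials=trials,
                encoding_trace=traces["encoding"],
                recall_trace=traces["recall"],
                encoding_duration=float(row["encoding_duration_min"]),
                recall_duration=float(row["recall_duration_min"]),
                completed=completed == "true",
            )
        )
    return sessions


def write_questionnaires(
    responses: Iterable[QuestionnaireResponse], path: str | os.PathLike
) -> None:
    """Write questionnaire responses in long format (one row per item)."""
    root = Path(path)
    rows = []
    for q in responses:
        for idx, item in enumerate(q.items, start=1):
            rows.append(
                {
                    "participant_id": q.participant_id,
                    "condition": q.condition,
                    "instrument": q.instrument,
                    "item_index": idx,
                    "response": "" if item is None else item,
                }
            )
    df = pd.DataFrame(rows, columns=_QUEST_COLS)
    _write_csv(df, root / "questionnaires.csv")


def read_questionnaires(path: str | os.PathLike) -> list[QuestionnaireResponse]:
    """Read the cohort questionnaire file; missing file yields an empty list."""
    root = Path(path)
    qfile = root / "questionnaires.csv"
    if not qfile.exists():
        return []
    df = _read_csv(qfile, _QUEST_COLS, ["item_index"])
    out: list[QuestionnaireResponse] = []
    keys = df[["participant_id", "condition", "instrument"]].drop_duplicates()
    for _, k in keys.iterrows():
        sub = df[
            (df["participant_id"] == k["participant_id"])
            & (df["condition"] == k["condition"])
            & (df["instrument"] == k["instrument"])
        ].sort_values("item_index")
        items: list[int | None] = []
        for _, r in sub.iterrows():
            raw = str(r["response"]).strip()
            if raw == "":
                items.append(None)
            else:
                try:
                    items.append(int(float(raw)))
                except ValueError as exc:
                    raise ParseError(qfile, f"malformed response {raw!r}", column="response") from exc
        out.append(
            QuestionnaireResponse(
                participant_id=k["participant_id"],
                condition=k["condition"],
                instrument=k["instrument"],
                items=tuple(items),
            )
        )
    return out


def write_cohort(
    sessions: Iterable[SessionLog],
    questionnaires: Iterable[QuestionnaireResponse],
    path: str | os.PathLike,
) -> None:
    """Write sessions and questionnaires side by side under one root."""
    write_sessions(sessions, path)
    write_questionnaires(questionnaires, path)


def read_cohort(
    path: str | os.PathLike,
) -> tuple[list[SessionLog], list[QuestionnaireResponse]]:
    return read_sessions(path), read_questionnaires(path)
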
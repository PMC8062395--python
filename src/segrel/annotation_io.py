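"""Domain types and I/O for word-boundary annotation data.

The toolkit evaluates how consistently human annotators place the onset
and offset boundaries of spoken words.  Data arrive in three shapes:

* **annotation tables** (CSV) — one row per word token x annotator x
  modality x boundary, with the placed time in milliseconds;
* **Praat TextGrids** — the conventional (baseline) modality's native
  format, tiered interval annotations with times in seconds;
* **timing logs** (CSV) — one row per annotator interaction with a word
  candidate or trial, the raw material of the efficiency analysis.

All boundary times are held internally in milliseconds; seconds appear
only at the TextGrid boundary.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

__all__ = [
    "Rate",
    "Modality",
    "Boundary",
    "Task",
    "Outcome",
    "WordToken",
    "BoundaryAnnotation",
    "Interval",
    "IntervalTier",
    "TextGridDoc",
    "TimingEvent",
    "TextGridParseError",
    "parse_textgrid",
    "read_textgrid",
    "write_textgrid",
    "textgrid_to_annotations",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_timing_csv",
    "write_timing_csv",
    "ANNOTATION_COLUMNS",
    "TIMING_COLUMNS",
]


class Rate(str, Enum):
    """Trained speaking rate of a trial."""

    FAST = "fast"
    MEDIUM = "medium"
    SLOW = "slow"


class Modality(str, Enum):
    """Annotation modality: the streamlined pipeline vs. conventional Praat."""

    PONSS = "ponss"
    BASELINE = "baseline"


class Boundary(str, Enum):
    ONSET = "onset"
    OFFSET = "offset"


class Task(str, Enum):
    TRIAGE = "triage"
    RETRIM = "retrim"
    BASELINE_TRIAL = "baseline_trial"


class Outcome(str, Enum):
    ACCEPTED = "accepted"
    RETRIM_REQUESTED = "retrim_requested"
    REJECTED = "rejected"
    FLAGGED = "flagged"
    SAVED = "saved"


@dataclass(frozen=True)
class WordToken:
    """One word slot of one trial (position is ordinal within the trial)."""

    token_id: str
    trial_id: str
    position: int
    label: str
    speaker_id: str
    rate: Rate

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class BoundaryAnnotation:
    """One annotator's placement of one boundary of one word token."""

    token_id: str
    annotator_id: str
    modality: Modality
    boundary: Boundary
    time_ms: float

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ValueError(f"time_ms must be >= 0, got {self.time_ms}")


@dataclass(frozen=True)
class TimingEvent:
    """One annotator interaction with a word candidate or baseline trial."""

    unit_id: str
    annotator_id: str
    modality: Modality
    task: Task
    t_start: float
    t_end: float
    outcome: Outcome

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError(
                f"t_end ({self.t_end}) before t_start ({self.t_start}) "
                f"for unit {self.unit_id}"
            )
        if self.task is Task.BASELINE_TRIAL and self.modality is not Modality.BASELINE:
            raise ValueError("task=baseline_trial requires modality=baseline")

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# TextGrid documents
# ---------------------------------------------------------------------------


class TextGridParseError(ValueError):
    """Malformed TextGrid text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: list[Interval] = field(default_factory=list)

    def validate(self) -> None:
        prev_xmax = None
        for iv in self.intervals:
            if iv.xmax < iv.xmin:
                raise ValueError(
                    f"tier {self.name!r}: interval xmax {iv.xmax} < xmin {iv.xmin}"
                )
            if prev_xmax is not None and abs(iv.xmin - prev_xmax) > 1e-9:
                raise ValueError(
                    f"tier {self.name!r}: intervals not contiguous at t={iv.xmin}"
                )
            prev_xmax = iv.xmax
        if self.intervals:
            if self.intervals[0].xmin < self.xmin - 1e-9:
                raise ValueError(f"tier {self.name!r}: interval before tier xmin")
            if self.intervals[-1].xmax > self.xmax + 1e-9:
                raise ValueError(f"tier {self.name!r}: interval after tier xmax")


@dataclass
class TextGridDoc:
    """A Praat TextGrid: ordered interval tiers over [xmin, xmax] seconds."""

    xmin: float
    xmax: float
    tiers: list[IntervalTier] = field(default_factory=list)

    def validate(self) -> None:
        if self.xmax < self.xmin:
            raise ValueError(f"document xmax {self.xmax} < xmin {self.xmin}")
        for tier in self.tiers:
            if tier.xmin < self.xmin - 1e-9 or tier.xmax > self.xmax + 1e-9:
                raise ValueError(
                    f"tier {tier.name!r} bounds outside document bounds"
                )
            tier.validate()

    def tier(self, name: str) -> IntervalTier:
        for t in self.tiers:
            if t.name == name:
                return t
        available = [t.name for t in self.tiers]
        raise KeyError(f"no tier named {name!r}; available tiers: {available}")


class _Lines:
    """Line cursor over TextGrid text, tracking position for error messages."""

    def __init__(self, text: str):
        self.lines = text.splitlines()
        self.pos = 0

    def next_content(self) -> tuple[str, int]:
        while self.pos < len(self.lines):
            line = self.lines[self.pos].strip()
            self.pos += 1
            if line:
                return line, self.pos
        raise TextGridParseError("unexpected end of file", len(self.lines))


_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def _extract_number(line: str, lineno: int) -> float:
    m = _NUM_RE.search(line)
    if m is None:
        raise TextGridParseError(f"expected a number, got {line!r}", lineno)
    return float(m.group())


def _extract_string(line: str, lineno: int) -> str:
    # Praat escapes embedded quotes by doubling them.
    start = line.find('"')
    if start < 0:
        raise TextGridParseError(f"expected a quoted string, got {line!r}", lineno)
    body = line[start + 1 :]
    if not body.endswith('"'):
        raise TextGridParseError(f"unterminated string in {line!r}", lineno)
    return body[:-1].replace('""', '"')


def parse_textgrid(source: Union[str, io.TextIOBase]) -> TextGridDoc:
    """Parse Praat TextGrid text (long or short dialect) into a document.

    Only interval tiers are supported; a point tier ("TextTier") raises a
    :class:`TextGridParseError`.  Times are kept in seconds as written.
    """
    text = source.read() if hasattr(source, "read") else source
    if "\x00" in text or text.startswith("�"):
        raise TextGridParseError(
            "input looks like UTF-16 (or another non-UTF-8 encoding); "
            "transcode the file to UTF-8 before parsing"
        )
    text = text.lstrip("﻿")
    cur = _Lines(text)

    line, n = cur.next_content()
    if "ooTextFile" not in line:
        raise TextGridParseError(f"not a Praat ooTextFile header: {line!r}", n)
    line, n = cur.next_content()
    if "TextGrid" not in line:
        raise TextGridParseError(f"not a TextGrid object: {line!r}", n)

    line, n = cur.next_content()
    long_format = "xmin" in line
    xmin = _extract_number(line, n)
    line, n = cur.next_content()
    xmax = _extract_number(line, n)
    line, n = cur.next_content()  # tiers? <exists>
    if "exists" not in line:
        raise TextGridParseError(f"expected tier-existence flag, got {line!r}", n)
    line, n = cur.next_content()
    n_tiers = int(_extract_number(line, n))
    if long_format:
        cur.next_content()  # "item []:"

    tiers: list[IntervalTier] = []
    for _ in range(n_tiers):
        if long_format:
            cur.next_content()  # "item [k]:"
        line, n = cur.next_content()
        klass = _extract_string(line, n)
        if klass != "IntervalTier":
            raise TextGridParseError(
                f"unsupported tier class {klass!r} (only IntervalTier)", n
            )
        line, n = cur.next_content()
        name = _extract_string(line, n)
        line, n = cur.next_content()
        t_xmin = _extract_number(line, n)
        line, n = cur.next_content()
        t_xmax = _extract_number(line, n)
        line, n = cur.next_content()
        n_intervals = int(_extract_number(line, n))
        intervals = []
        for _ in range(n_intervals):
            if long_format:
                cur.next_content()  # "intervals [k]:"
            line, n = cur.next_content()
            i_xmin = _extract_number(line, n)
            line, n = cur.next_content()
            i_xmax = _extract_number(line, n)
            line, n = cur.next_content()
            i_text = _extract_string(line, n)
            intervals.append(Interval(i_xmin, i_xmax, i_text))
        tiers.append(IntervalTier(name, t_xmin, t_xmax, intervals))

    doc = TextGridDoc(xmin, xmax, tiers)
    try:
        doc.validate()
    except ValueError as exc:
        raise TextGridParseError(str(exc)) from exc
    return doc


def read_textgrid(path: Union[str, Path]) -> TextGridDoc:
    """Read a TextGrid file, rejecting UTF-16 exports with a clear message."""
    raw = Path(path).read_bytes()
    if raw[:2] in (b"\xff\xfe", b"\xfe\xff"):
        raise TextGridParseError(
            f"{path}: file is UTF-16 encoded (Praat default for non-ASCII); "
            "transcode to UTF-8 before parsing, e.g. "
            "`iconv -f UTF-16 -t UTF-8`"
        )
    return parse_textgrid(raw.decode("utf-8"))


def _fmt_time(t: float) -> str:
    # 17 significant digits: round-trips any double exactly.
    return repr(float(t))


def write_textgrid(doc: TextGridDoc, stream: io.TextIOBase | None = None) -> str:
    """Serialize a document as long-format TextGrid text.

    Returns the text; if *stream* is given it is also written there.
    """
    doc.validate()
    out = []
    out.append('File type = "ooTextFile"')
    out.append('Object class = "TextGrid"')
    out.append("")
    out.append(f"xmin = {_fmt_time(doc.xmin)} ")
    out.append(f"xmax = {_fmt_time(doc.xmax)} ")
    out.append("tiers? <exists> ")
    out.append(f"size = {len(doc.tiers)} ")
    out.append("item []: ")
    for k, tier in enumerate(doc.tiers, 1):
        out.append(f"    item [{k}]:")
        out.append('        class = "IntervalTier" ')
        out.append(f'        name = "{tier.name.replace(chr(34), chr(34) * 2)}" ')
        out.append(f"        xmin = {_fmt_time(tier.xmin)} ")
        out.append(f"        xmax = {_fmt_time(tier.xmax)} ")
        out.append(f"        intervals: size = {len(tier.intervals)} ")
        for j, iv in enumerate(tier.intervals, 1):
            out.append(f"        intervals [{j}]:")
            out.append(f"            xmin = {_fmt_time(iv.xmin)} ")
            out.append(f"            xmax = {_fmt_time(iv.xmax)} ")
            out.append(f'            text = "{iv.text.replace(chr(34), chr(34) * 2)}" ')
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def textgrid_to_annotations(
    doc: TextGridDoc,
    tier_name: str,
    annotator_id: str,
    modality: Modality,
    trial_id: str = "trial",
    token_ids: Sequence[str] | None = None,
) -> list[BoundaryAnnotation]:
    """Extract onset/offset annotations from the labeled intervals of a tier.

    Each interval with a non-empty label yields two annotations: onset at
    the interval's xmin and offset at its xmax, converted to milliseconds.
    Tokens are identified positionally: the *k*-th labeled interval maps to
    ``token_ids[k]`` if given, else to ``"<trial_id>/w<k+1>"``.
    """
    try:
        tier = doc.tier(tier_name)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    modality = Modality(modality)
    labeled = [iv for iv in tier.intervals if iv.text.strip()]
    if token_ids is not None and len(token_ids) != len(labeled):
        raise ValueError(
            f"{len(token_ids)} token_ids supplied for {len(labeled)} "
            f"labeled intervals in tier {tier_name!r}"
        )
    records: list[BoundaryAnnotation] = []
    for k, iv in enumerate(labeled):
        tid = token_ids[k] if token_ids is not None else f"{trial_id}/w{k + 1}"
        records.append(
            BoundaryAnnotation(tid, annotator_id, modality, Boundary.ONSET, iv.xmin * 1000.0)
        )
        records.append(
            BoundaryAnnotation(tid, annotator_id, modality, Boundary.OFFSET, iv.xmax * 1000.0)
        )
    return records


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "token_id",
    "trial_id",
    "position",
    "label",
    "speaker_id",
    "rate",
    "modality",
    "annotator_id",
    "boundary",
    "time_ms",
]

TIMING_COLUMNS = [
    "unit_id",
    "annotator_id",
    "modality",
    "task",
    "t_start_s",
    "t_end_s",
    "outcome",
]


def _validate_enum_column(df: pd.DataFrame, column: str, enum: type[Enum], path) -> None:
    valid = {e.value for e in enum}
    bad = ~df[column].isin(valid)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"{path}: row {row}: invalid {column} value "
            f"{df.loc[df.index[bad][0], column]!r} (expected one of {sorted(valid)})"
        )


def read_annotations_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read an annotation table, validating schema and enum fields.

    Returns a DataFrame with :data:`ANNOTATION_COLUMNS`; ``time_ms`` is
    float, ``position`` integer.
    """
    df = pd.read_csv(path, dtype={"token_id": str, "trial_id": str,
                                  "speaker_id": str, "annotator_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    _validate_enum_column(df, "rate", Rate, path)
    _validate_enum_column(df, "modality", Modality, path)
    _validate_enum_column(df, "boundary", Boundary, path)
    df["time_ms"] = df["time_ms"].astype(float)
    if (df["time_ms"] < 0).any():
        row = int(df.index[df["time_ms"] < 0][0])
        raise ValueError(f"{path}: row {row}: negative time_ms")
    df["position"] = df["position"].astype(int)
    dup = df.duplicated(["token_id", "annotator_id", "modality", "boundary"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValueError(
            f"{path}: row {row}: duplicate (token_id, annotator_id, modality, boundary)"
        )
    return df[ANNOTATION_COLUMNS]


def write_annotations_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write annotations: missing columns {missing}")
    df[ANNOTATION_COLUMNS].to_csv(path, index=False)


def read_timing_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a timing log; validates enums, non-negative durations, and the
    constraint that baseline_trial events carry the baseline modality."""
    df = pd.read_csv(path, dtype={"unit_id": str, "annotator_id": str})
    missing = [c for c in TIMING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    _validate_enum_column(df, "modality", Modality, path)
    _validate_enum_column(df, "task", Task, path)
    _validate_enum_column(df, "outcome", Outcome, path)
    df["t_start_s"] = df["t_start_s"].astype(float)
    df["t_end_s"] = df["t_end_s"].astype(float)
    bad = df["t_end_s"] < df["t_start_s"]
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"{path}: row {row}: t_end_s before t_start_s")
    bad = (df["task"] == Task.BASELINE_TRIAL.value) & (
        df["modality"] != Modality.BASELINE.value
    )
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"{path}: row {row}: baseline_trial with non-baseline modality")
    return df[TIMING_COLUMNS]


def write_timing_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    missing = [c for c in TIMING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write timing log: missing columns {missing}")
    df[TIMING_COLUMNS].to_csv(path, index=False)


def annotations_to_frame(records: Iterable[BoundaryAnnotation],
                         tokens: Iterable[WordToken]) -> pd.DataFrame:
    """Join typed annotation records with their word tokens into the
    denormalized annotation-table schema."""
    tok = {t.token_id: t for t in tokens}
    rows = []
    for r in records:
        t = tok[r.token_id]
        rows.append(
            dict(token_id=r.token_id, trial_id=t.trial_id, position=t.position,
                 label=t.label, speaker_id=t.speaker_id, rate=t.rate.value,
                 modality=r.modality.value, annotator_id=r.annotator_id,
                 boundary=r.boundary.value, time_ms=r.time_ms)
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
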
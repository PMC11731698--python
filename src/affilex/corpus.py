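"""Corpus I/O, engagement computation, and descriptive summary tables.

A corpus is a flat list of :class:`~affilex.records.MessageRecord`.  On disk
it is a UTF-8 CSV (quoted, comma-delimited) or JSON-lines file with columns
``message_id, user_id, topic_id, year, text, themes, speech_acts, bcts``;
multi-label cells join tokens with ``|``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import SchemaError, VocabularyError
from .records import (
    DiagnosisStatus,
    LifestyleStatus,
    MedicationStatus,
    MessageRecord,
    UserPersona,
)
from .vocab import Bct, SpeechAct, Theme
from .utils import percent

REQUIRED_COLUMNS = ("message_id", "user_id", "topic_id", "year")
LABEL_COLUMNS = ("themes", "speech_acts", "bcts")
DEFAULT_DELIMITER = "|"


def _split_labels(cell, parser, delimiter: str, where: str):
    if cell is None:
        return frozenset()
    cell = str(cell).strip()
    if not cell:
        return frozenset()
    try:
        return frozenset(parser(tok) for tok in cell.split(delimiter) if tok.strip())
    except VocabularyError as e:
        raise VocabularyError(f"{e} ({where})") from None


def _record_from_mapping(row: dict, line_no: int, delimiter: str) -> MessageRecord:
    for col in REQUIRED_COLUMNS:
        if col not in row or row[col] in (None, ""):
            raise SchemaError(f"missing required column {col!r} (line {line_no})")
    where = f"line {line_no}"
    return MessageRecord(
        message_id=str(row["message_id"]),
        user_id=str(row["user_id"]),
        topic_id=str(row["topic_id"]),
        year=int(row["year"]),
        text=str(row["text"]) if row.get("text") else None,
        themes=_split_labels(row.get("themes"), Theme.parse, delimiter, where),
        speech_acts=_split_labels(
            row.get("speech_acts"), SpeechAct.parse, delimiter, where
        ),
        bcts=_split_labels(row.get("bcts"), Bct.parse, delimiter, where),
    )


def read_corpus(
    path, format: Optional[str] = None, delimiter: str = DEFAULT_DELIMITER
) -> list[MessageRecord]:
    """Read a message corpus from CSV or JSON-lines, preserving input order.

    ``format`` defaults from the file suffix (``.jsonl`` / anything else =
    CSV).  Unknown theme / speech-act / BCT tokens raise
    :class:`VocabularyError` naming the token and line; a missing required
    column raises :class:`SchemaError`.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    records: list[MessageRecord] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                records.append(
                    _record_from_mapping(json.loads(line), line_no, delimiter)
                )
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for col in REQUIRED_COLUMNS:
                if col not in header:
                    raise SchemaError(f"missing required column {col!r} in header")
            for line_no, row in enumerate(reader, start=2):
                records.append(_record_from_mapping(row, line_no, delimiter))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return records


def write_corpus(
    records: Iterable[MessageRecord],
    path,
    format: Optional[str] = None,
    delimiter: str = DEFAULT_DELIMITER,
) -> None:
    """Write a corpus in the CSV / JSON-lines dialect `read_corpus` accepts."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"

    def row(r: MessageRecord) -> dict:
        return {
            "message_id": r.message_id,
            "user_id": r.user_id,
            "topic_id": r.topic_id,
            "year": r.year,
            "text": r.text or "",
            "themes": delimiter.join(sorted(t.value for t in r.themes)),
            "speech_acts": delimiter.join(sorted(s.value for s in r.speech_acts)),
            "bcts": delimiter.join(sorted(b.value for b in r.bcts)),
        }

    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(row(r), sort_keys=True) + "\n")
    else:
        fields = list(REQUIRED_COLUMNS) + ["text", "themes", "speech_acts", "bcts"]
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields, quoting=csv.QUOTE_ALL)
            writer.writeheader()
            for r in records:
                writer.writerow(row(r))


def write_personas(personas: Iterable[UserPersona], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(
            ["user_id", "medication_status", "diagnosis_status", "lifestyle_status"]
        )
        for p in personas:
            writer.writerow(
                [
                    p.user_id,
                    p.medication_status.value,
                    p.diagnosis_status.value,
                    p.lifestyle_status.value,
                ]
            )


def read_personas(path) -> list[UserPersona]:
    out = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                UserPersona(
                    user_id=row["user_id"],
                    medication_status=MedicationStatus(row["medication_status"]),
                    diagnosis_status=DiagnosisStatus(row["diagnosis_status"]),
                    lifestyle_status=LifestyleStatus(row["lifestyle_status"]),
                )
            )
    return out


def compute_engagement(
    corpus: Sequence[MessageRecord], users: Optional[Iterable[str]] = None
) -> pd.Series:
    """Posting frequency per user over the full window (the model outcome y).

    When ``users`` is given the count is restricted to (and indexed by) that
    user set, with zero counts for users who posted nothing — e.g. the
    signature subset that enters the exposure model.
    """
    counts: dict[str, int] = {}
    if users is not None:
        users = list(dict.fromkeys(users))
        counts = {u: 0 for u in users}
        allowed = set(users)
        for r in corpus:
            if r.user_id in allowed:
                counts[r.user_id] += 1
    else:
        for r in corpus:
            counts[r.user_id] = counts.get(r.user_id, 0) + 1
    return pd.Series(counts, dtype=int, name="engagement")


def summarize_corpus(
    corpus: Sequence[MessageRecord],
    personas: Optional[Sequence[UserPersona]] = None,
) -> dict[str, pd.DataFrame]:
    """Descriptive tables: yearly totals, persona distribution, per-theme sizes.

    Returns three frames keyed ``by_year``, ``personas``, ``by_theme``:

    * ``by_year`` — messages / unique topics / unique users per calendar year
      with each count's share of the corpus-wide total;
    * ``personas`` — counts per persona axis level with shares of the number
      of persona-extracted users;
    * ``by_theme`` — messages / topics / users per theme, restricted to the
      exposure-model subset (messages by persona users when personas are
      given), with shares of that subset's totals.

    All shares are percentages rounded half-up to one decimal.  Yearly user
    counts may sum to more than the unique-user total: users active in
    several years are counted in each.
    """
    n_messages = len(corpus)
    topics = {r.topic_id for r in corpus}
    users = {r.user_id for r in corpus}

    years = sorted({r.year for r in corpus})
    rows = []
    for y in years:
        msgs = [r for r in corpus if r.year == y]
        rows.append(
            {
                "year": y,
                "messages": len(msgs),
                "messages_pct": percent(len(msgs), n_messages),
                "topics": len({r.topic_id for r in msgs}),
                "topics_pct": percent(len({r.topic_id for r in msgs}), len(topics)),
                "users": len({r.user_id for r in msgs}),
                "users_pct": percent(len({r.user_id for r in msgs}), len(users)),
            }
        )
    by_year = pd.DataFrame(
        rows,
        columns=[
            "year",
            "messages",
            "messages_pct",
            "topics",
            "topics_pct",
            "users",
            "users_pct",
        ],
    )

    personas = personas or []
    n_personas = len(personas)
    prow = []
    for axis, enum_cls in (
        ("medication", MedicationStatus),
        ("diagnosis", DiagnosisStatus),
        ("lifestyle", LifestyleStatus),
    ):
        for level in enum_cls:
            count = sum(
                1 for p in personas if getattr(p, f"{axis}_status") is level
            )
            prow.append(
                {
                    "axis": axis,
                    "level": level.value,
                    "users": count,
                    "users_pct": percent(count, n_personas),
                }
            )
    persona_table = pd.DataFrame(prow, columns=["axis", "level", "users", "users_pct"])

    # Exposure-model subset: messages by users with extracted personas.
    if personas:
        subset_users = {p.user_id for p in personas}
        subset = [r for r in corpus if r.user_id in subset_users]
    else:
        subset = list(corpus)
    sub_messages = len(subset)
    sub_topics = {r.topic_id for r in subset}
    sub_users = {r.user_id for r in subset}
    trow = []
    for theme in Theme:
        tm = [r for r in subset if theme in r.themes]
        trow.append(
            {
                "theme": theme.value,
                "messages": len(tm),
                "messages_pct": percent(len(tm), sub_messages),
                "topics": len({r.topic_id for r in tm}),
                "topics_pct": percent(len({r.topic_id for r in tm}), len(sub_topics)),
                "users": len({r.user_id for r in tm}),
                "users_pct": percent(len({r.user_id for r in tm}), len(sub_users)),
            }
        )
    by_theme = pd.DataFrame(
        trow,
        columns=[
            "theme",
            "messages",
            "messages_pct",
            "topics",
            "topics_pct",
            "users",
            "users_pct",
        ],
    )

    return {"by_year": by_year, "personas": persona_table, "by_theme": by_theme}
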
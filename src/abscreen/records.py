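"""Reading and preprocessing bibliographic screening exports.

Raw search exports arrive as delimited tables with one row per record and
at minimum a title, an abstract and a first-stage human screening label.
Preprocessing mirrors the standard cleanup before machine screening: rows
with empty abstracts are removed, duplicates are collapsed (first
occurrence kept), non-English records are dropped when a language tag (or
a pluggable detector) says so, and each surviving record gets a
deterministic unique identifier plus a ``record_text`` field joining title
and abstract — the unit of judging.

The original (pre-cleanup) record count is kept on the dataset because it
is the denominator of workload-reduction accounting: records dropped here
still land on the second human reviewer's desk.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    EmptyDatasetError,
    InconsistentLabelsError,
    LabelParseError,
    MissingColumnError,
)

__all__ = [
    "Label",
    "RawRecordRow",
    "ScreeningRecord",
    "ReviewDataset",
    "parse_label",
    "load_raw_table",
    "load_ris",
    "preprocess",
    "read_dataset_csv",
    "write_dataset_csv",
]


class Label(enum.Enum):
    """Ternary human screening label."""

    INCLUDED = "included"
    EXCLUDED = "excluded"
    UNKNOWN = "unknown"


_TRUE_LABELS = {"1", "true", "included", "include", "yes"}
_FALSE_LABELS = {"0", "false", "excluded", "exclude", "no"}


def parse_label(value: object) -> Label:
    """Parse a screening label cell.

    Accepts 1/0, true/false, included/excluded (case-insensitive); empty or
    missing cells map to UNKNOWN; anything else raises
    :class:`~abscreen.errors.LabelParseError`.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return Label.UNKNOWN
    if isinstance(value, bool):
        return Label.INCLUDED if value else Label.EXCLUDED
    if isinstance(value, (int,)):
        value = str(value)
    text = str(value).strip().lower()
    if not text:
        return Label.UNKNOWN
    if text in _TRUE_LABELS:
        return Label.INCLUDED
    if text in _FALSE_LABELS:
        return Label.EXCLUDED
    raise LabelParseError(f"unrecognized screening label: {value!r}")


@dataclass
class RawRecordRow:
    """One row of a raw screening export, before any cleanup."""

    title: str = ""
    abstract: str = ""
    screening1: Label = Label.UNKNOWN
    screening2: Label | None = None
    language: str | None = None
    source_key: str | None = None


@dataclass
class ScreeningRecord:
    """A cleaned record: the unit fed to the judge."""

    record_id: str
    title: str
    abstract: str
    record_text: str
    human_screen1: bool
    human_screen2: bool | None = None


@dataclass
class ReviewDataset:
    """Cleaned records plus the bookkeeping workload accounting needs."""

    review_name: str
    records: list[ScreeningRecord]
    original_total: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def preprocessed_total(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def labels(self) -> dict[str, bool]:
        return {r.record_id: r.human_screen1 for r in self.records}


_DEFAULT_COLUMN_MAP = {
    "title": "title",
    "abstract": "abstract",
    "screening1": "screening1",
    "screening2": "screening2",
    "language": "language",
    "source_key": "source_key",
}
_REQUIRED_FIELDS = ("title", "abstract", "screening1")


def _resolve_column(df: pd.DataFrame, name: str) -> str | None:
    """Case-insensitive column lookup; returns the actual column or None."""
    lowered = {c.lower(): c for c in df.columns}
    return lowered.get(name.lower())


def _cell(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value)


def load_raw_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> list[RawRecordRow]:
    """Read a delimited export into raw rows, preserving order.

    ``column_map`` maps logical field names (title, abstract, screening1,
    and optionally screening2/language/source_key) to column headers in the
    file; lookup is case-insensitive. Extra columns are ignored. A missing
    mapped *required* column raises
    :class:`~abscreen.errors.MissingColumnError`.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    resolved: dict[str, str | None] = {
        logical: _resolve_column(df, actual) for logical, actual in cmap.items()
    }
    for logical in _REQUIRED_FIELDS:
        if resolved[logical] is None:
            raise MissingColumnError(cmap[logical])

    rows: list[RawRecordRow] = []
    for _, r in df.iterrows():
        def get(logical: str) -> str:
            col = resolved[logical]
            return _cell(r[col]) if col is not None else ""

        s2_raw = get("screening2")
        rows.append(
            RawRecordRow(
                title=get("title"),
                abstract=get("abstract"),
                screening1=parse_label(get("screening1")),
                screening2=parse_label(s2_raw) if s2_raw.strip() else None,
                language=get("language") or None,
                source_key=get("source_key") or None,
            )
        )
    return rows


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def load_ris(path: str | Path) -> list[RawRecordRow]:
    """Minimal RIS import: maps TI/T1 to title and AB/N2 to abstract.

    RIS carries no screening labels, so rows come back with UNKNOWN
    screening1; merge labels separately before preprocessing.
    """
    rows: list[RawRecordRow] = []
    current: dict[str, str] = {}
    last_tag: str | None = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        m = _RIS_TAG.match(line)
        if m:
            tag, value = m.group(1), m.group(2)
            last_tag = tag
            if tag == "ER":
                rows.append(
                    RawRecordRow(
                        title=current.get("TI", current.get("T1", "")),
                        abstract=current.get("AB", current.get("N2", "")),
                        language=current.get("LA") or None,
                        source_key=current.get("DO") or current.get("ID") or None,
                    )
                )
                current = {}
            else:
                current[tag] = (current.get(tag, "") + " " + value).strip() if tag in current else value
        elif last_tag and line.strip():
            current[last_tag] = (current.get(last_tag, "") + " " + line.strip()).strip()
    return rows


_WS = re.compile(r"\s+")


def _normalize(text: str) -> str:
    return _WS.sub(" ", text.strip().casefold())


_ENGLISH_TAGS = {"en", "eng", "english", "en-us", "en-gb"}


def _language_ok(tag: str | None) -> bool:
    if tag is None or not tag.strip():
        return True  # untagged records are kept
    return tag.strip().lower() in _ENGLISH_TAGS


def build_record_text(title: str, abstract: str, style: str = "labeled") -> str:
    """Join title and abstract into the judged ``record_text``.

    ``labeled`` (default) prefixes the parts with "Title:"/"Abstract:" for
    judge clarity; ``plain`` joins them with a single space. Both contain
    title and abstract verbatim.
    """
    if style == "labeled":
        return f"Title: {title} Abstract: {abstract}"
    if style == "plain":
        return f"{title} {abstract}"
    raise ValueError(f"unknown record_text style: {style!r}")


def preprocess(
    rows: Sequence[RawRecordRow],
    original_total: int | None = None,
    *,
    review_name: str = "review",
    record_text_style: str = "labeled",
    language_detector: Callable[[str, str], bool] | None = None,
) -> ReviewDataset:
    """Clean raw rows into a uniquely identified review dataset.

    Filters, in order: rows with an unknown screening-1 label, rows with an
    empty abstract, non-English rows (by ``language`` tag, else by
    ``language_detector`` when given; default accepts everything), and
    duplicates by case-folded whitespace-normalized (title, abstract) with
    the first occurrence kept. Record ids are assigned from surviving row
    order, so two runs on the same input produce identical ids and the
    operation is idempotent.
    """
    if original_total is None:
        original_total = len(rows)
    if original_total < len(rows):
        raise ValueError(
            f"original_total ({original_total}) < number of rows ({len(rows)})"
        )

    counts = {
        "original_total": original_total,
        "rows_received": len(rows),
        "dropped_unknown_label": 0,
        "dropped_empty_abstract": 0,
        "dropped_language": 0,
        "dropped_duplicate": 0,
    }
    seen: set[tuple[str, str]] = set()
    records: list[ScreeningRecord] = []
    for row in rows:
        if row.screening2 is not None and row.screening1 is not Label.UNKNOWN:
            if row.screening2 is Label.INCLUDED and row.screening1 is not Label.INCLUDED:
                raise InconsistentLabelsError(
                    f"record {row.title[:60]!r}: passed full-text screening "
                    "but not title/abstract screening"
                )
        if row.screening1 is Label.UNKNOWN:
            counts["dropped_unknown_label"] += 1
            continue
        if not row.abstract.strip():
            counts["dropped_empty_abstract"] += 1
            continue
        if not _language_ok(row.language):
            counts["dropped_language"] += 1
            continue
        if row.language is None and language_detector is not None:
            if not language_detector(row.title, row.abstract):
                counts["dropped_language"] += 1
                continue
        key = (_normalize(row.title), _normalize(row.abstract))
        if key in seen:
            counts["dropped_duplicate"] += 1
            continue
        seen.add(key)
        records.append(
            ScreeningRecord(
                record_id=f"rec-{len(records):05d}",
                title=row.title,
                abstract=row.abstract,
                record_text=build_record_text(row.title, row.abstract, record_text_style),
                human_screen1=row.screening1 is Label.INCLUDED,
                human_screen2=(
                    None if row.screening2 is None or row.screening2 is Label.UNKNOWN
                    else row.screening2 is Label.INCLUDED
                ),
            )
        )
    if not records:
        raise EmptyDatasetError("preprocessing removed every record")
    counts["preprocessed_total"] = len(records)
    return ReviewDataset(
        review_name=review_name,
        records=records,
        original_total=original_total,
        counts=counts,
    )


def write_dataset_csv(dataset: ReviewDataset, path: str | Path, sidecar: bool = True) -> None:
    """Write a cleaned dataset as CSV plus a JSON sidecar of counts."""
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in dataset.records],
            "title": [r.title for r in dataset.records],
            "abstract": [r.abstract for r in dataset.records],
            "record_text": [r.record_text for r in dataset.records],
            "human_screen1": [r.human_screen1 for r in dataset.records],
            "human_screen2": [r.human_screen2 for r in dataset.records],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    if sidecar:
        meta = {
            "review_name": dataset.review_name,
            "original_total": dataset.original_total,
            "preprocessed_total": dataset.preprocessed_total,
            "counts": dataset.counts,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2), encoding="utf-8"
        )


def read_dataset_csv(path: str | Path, review_name: str | None = None) -> ReviewDataset:
    """Read a dataset written by :func:`write_dataset_csv`."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"record_id": str, "title": str, "abstract": str, "record_text": str}, keep_default_na=False)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    original_total = len(df)
    counts: dict[str, int] = {}
    name = review_name or path.stem
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        original_total = meta.get("original_total", original_total)
        counts = meta.get("counts", {})
        name = review_name or meta.get("review_name", name)

    def to_bool(v: object) -> bool | None:
        s = str(v).strip().lower()
        if s in {"", "none", "nan"}:
            return None
        return s in {"true", "1"}

    records = [
        ScreeningRecord(
            record_id=str(r["record_id"]),
            title=str(r["title"]),
            abstract=str(r["abstract"]),
            record_text=str(r["record_text"]),
            human_screen1=bool(to_bool(r["human_screen1"])),
            human_screen2=to_bool(r.get("human_screen2", "")),
        )
        for _, r in df.iterrows()
    ]
    return ReviewDataset(
        review_name=name, records=records, original_total=original_total, counts=counts
    )
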
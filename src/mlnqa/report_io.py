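"""Read/write cytology report corpora and apply the cohort inclusion filter.

A corpus is a flat file of pseudonymized report records: JSON-lines primary
(one object per line, addenda as an array) or CSV secondary (addenda joined
by ``|||``). Identifiers are opaque tokens assumed pseudonymized upstream;
this module validates only that they are present and non-empty.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ADDENDA_DELIM = "|||"

REQUIRED_FIELDS = (
    "specimen_id",
    "patient_pseudo_id",
    "sps_id",
    "pathologist_id",
    "received_date",
    "source_text",
    "diagnosis_text",
)


class CorpusError(ValueError):
    """Malformed corpus file or record."""


@dataclass
class ReportRecord:
    """One specimen's sectioned report text plus provider identifiers.

    ``sps_id`` identifies the submitting physician/surgeon (SPS) who obtained
    the aspirate; ``pathologist_id`` the interpreting pathologist. Addenda
    are later report sections, kept in the order they were appended.
    """

    specimen_id: str
    patient_pseudo_id: str
    sps_id: str
    pathologist_id: str
    received_date: str
    source_text: str
    diagnosis_text: str
    consult_text: str = ""
    addenda: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sps_id or not self.pathologist_id:
            raise CorpusError(
                f"record {self.specimen_id!r}: sps_id and pathologist_id must be non-empty"
            )
        try:
            datetime.date.fromisoformat(self.received_date)
        except ValueError as exc:
            raise CorpusError(
                f"record {self.specimen_id!r}: received_date {self.received_date!r} is not ISO-8601"
            ) from exc
        self.addenda = list(self.addenda)


@dataclass(frozen=True)
class CorpusMeta:
    n_records: int
    date_range: tuple[str, str]
    provider_census: dict[str, dict[str, int]]


def corpus_meta(records: Sequence[ReportRecord]) -> CorpusMeta:
    """Summary counts for a corpus (record count, date span, provider census)."""
    if not records:
        raise CorpusError("empty corpus")
    dates = sorted(r.received_date for r in records)
    census: dict[str, dict[str, int]] = {"sps": {}, "pathologist": {}}
    for r in records:
        census["sps"][r.sps_id] = census["sps"].get(r.sps_id, 0) + 1
        census["pathologist"][r.pathologist_id] = census["pathologist"].get(r.pathologist_id, 0) + 1
    return CorpusMeta(len(records), (dates[0], dates[-1]), census)


def _record_from_mapping(row: dict, index: int) -> ReportRecord:
    for f in REQUIRED_FIELDS:
        if f not in row or row[f] is None or (isinstance(row[f], str) and row[f] == "" and f != "source_text" and f != "diagnosis_text"):
            raise CorpusError(f"record {index}: missing required field {f!r}")
    addenda = row.get("addenda", [])
    if isinstance(addenda, str):
        addenda = [a for a in addenda.split(ADDENDA_DELIM) if a != ""]
    try:
        return ReportRecord(
            specimen_id=str(row["specimen_id"]),
            patient_pseudo_id=str(row["patient_pseudo_id"]),
            sps_id=str(row["sps_id"]),
            pathologist_id=str(row["pathologist_id"]),
            received_date=str(row["received_date"]),
            source_text=str(row["source_text"]),
            diagnosis_text=str(row["diagnosis_text"]),
            consult_text=str(row.get("consult_text", "") or ""),
            addenda=list(addenda),
        )
    except CorpusError as exc:
        raise CorpusError(f"record {index}: {exc}") from exc


def _check_unique_ids(records: Sequence[ReportRecord]) -> None:
    seen: dict[str, int] = {}
    dups = []
    for r in records:
        if r.specimen_id in seen:
            dups.append(r.specimen_id)
        seen[r.specimen_id] = 1
    if dups:
        raise CorpusError(f"duplicate specimen_id values: {sorted(set(dups))}")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise CorpusError(f"unknown corpus format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise CorpusError(f"cannot infer corpus format from {path.name!r}; pass format=")


def read_corpus(path: str | Path, format: str | None = None) -> list[ReportRecord]:
    """Read a corpus file into a list of :class:`ReportRecord`.

    Missing optional sections become empty text; identifiers pass through
    verbatim. Raises :class:`CorpusError` naming the offending record index
    and field on validation failure, and listing duplicates if any
    ``specimen_id`` repeats.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus file not found: {path}")
    fmt = _infer_format(path, format)
    records: list[ReportRecord] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"record {i}: invalid JSON ({exc})") from exc
                records.append(_record_from_mapping(row, i))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                records.append(_record_from_mapping(row, i))
    _check_unique_ids(records)
    return records


def write_corpus(records: Sequence[ReportRecord], path: str | Path, format: str | None = None) -> None:
    """Serialize records losslessly; inverse of :func:`read_corpus`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    _check_unique_ids(records)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(dataclasses.asdict(r), sort_keys=True) + "\n")
    else:
        cols = list(REQUIRED_FIELDS) + ["consult_text", "addenda"]
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for r in records:
                if any(ADDENDA_DELIM in a for a in r.addenda):
                    raise CorpusError(
                        f"record {r.specimen_id!r}: addendum contains the CSV addenda "
                        f"delimiter {ADDENDA_DELIM!r}; write as jsonl instead"
                    )
                row = dataclasses.asdict(r)
                row["addenda"] = ADDENDA_DELIM.join(r.addenda)
                writer.writerow(row)


def filter_inclusion(records: Iterable[ReportRecord]) -> list[ReportRecord]:
    """Keep records meeting the cohort inclusion criteria.

    The "source of specimen" section must contain (case-insensitively) the
    substring ``"lymph node"`` and at least one of ``"EBUS"``/``"EUS"``.
    Raw substring semantics, so "EBUS-TBNA" qualifies. Idempotent and
    order-preserving.
    """
    kept = []
    for r in records:
        src = r.source_text.lower()
        if "lymph node" in src and ("ebus" in src or "eus" in src):
            kept.append(r)
    return kept
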
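"""Hierarchical free-text string-match classification of cytology reports.

Each report is mapped to one diagnostic category, one mutually exclusive
group (severity order malignant > suspicious > insufficient > benign), and
one nodal station, by greedy phrase matching against prioritized lexicons:

* entries are tried in rank order (by default longest phrase first), and a
  span consumed by an earlier entry cannot be re-matched by a later entry
  that overlaps it — this is what separates "non-small cell carcinoma" from
  its embedded substring "small cell carcinoma";
* diagnosis classification reads the diagnosis section, then the
  consultation, then all addenda in order; the latest section that yields a
  category wins (pathology amendments supersede the original report), and a
  record whose final category came from a consult/addendum and differs from
  the diagnosis-section call is flagged ``changed_by_addendum``;
* within one section, if several categories match, the category whose group
  is highest in the severity hierarchy wins; ties within a group go to the
  earliest match offset;
* negations ("negative for malignant cells") are ordinary lexicon entries
  mapped to a benign category and ranked above their embedded malignant
  substring — no grammar engine.

Records with no diagnosis match anywhere are ``UNCLASSIFIED``; records with
no station match are station ``UNKNOWN``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mlnqa.lexicon import GROUP_HIERARCHY, Lexicon, LexiconError, UNCLASSIFIED
from mlnqa.report_io import ReportRecord
from mlnqa.text import normalize_text

UNCLASSIFIED_CATEGORY = "UNCLASSIFIED"
UNKNOWN_STATION = "UNKNOWN"

_SEVERITY = {g: i for i, g in enumerate(GROUP_HIERARCHY)}
_PATTERN_CACHE: dict[str, re.Pattern] = {}


def _pattern(phrase: str) -> re.Pattern:
    pat = _PATTERN_CACHE.get(phrase)
    if pat is None:
        # word-boundary guards so "7" cannot fire inside "17"
        pat = re.compile(r"(?<!\w)" + re.escape(phrase) + r"(?!\w)")
        _PATTERN_CACHE[phrase] = pat
    return pat


@dataclass(frozen=True)
class MatchSpan:
    """Provenance of one surviving phrase match (offsets into the
    normalized section text, 0-based half-open)."""

    phrase: str
    category_id: str
    start: int
    end: int
    section: str = "diagnosis"


@dataclass
class ClassifiedRecord:
    record: ReportRecord
    diagnosis_category: str  # category_id or UNCLASSIFIED_CATEGORY
    exclusive_group: str  # benign|suspicious|malignant|insufficient|unclassified
    station: str  # station_label or UNKNOWN_STATION
    matches: list[MatchSpan] = field(default_factory=list)
    changed_by_addendum: bool = False


def match_phrases(text: str, lex: Lexicon) -> list[MatchSpan]:
    """Greedy rank-ordered scan of ``text`` against a lexicon.

    Entries are processed in rank order; each occurrence whose span overlaps
    a span already consumed by an earlier (higher-priority) entry is
    discarded. Returns surviving spans in processing order (rank-major,
    offset-minor). ``text`` is normalized internally (idempotent, so
    pre-normalized input is fine).
    """
    text = normalize_text(text)
    if not text:
        return []
    consumed = np.zeros(len(text), dtype=bool)
    spans: list[MatchSpan] = []
    for entry in lex.entries:
        for m in _pattern(entry.phrase).finditer(text):
            s, e = m.start(), m.end()
            if consumed[s:e].any():
                continue
            consumed[s:e] = True
            spans.append(MatchSpan(entry.phrase, entry.category_id, s, e))
    return spans


def resolve_group(category_ids: Iterable[str], lex: Lexicon) -> str:
    """Collapse a set of diagnosis categories to one exclusive group.

    Returns the highest-severity group present (malignant > suspicious >
    insufficient > benign); the empty set maps to ``unclassified``.
    """
    best: str | None = None
    for cid in category_ids:
        group = lex.group_of(cid)  # raises LexiconError on unknown category
        if group == "none":
            continue
        if best is None or _SEVERITY[group] < _SEVERITY[best]:
            best = group
    return best if best is not None else UNCLASSIFIED


def _section_winner(spans: Sequence[MatchSpan], lex: Lexicon) -> str | None:
    """Pick one category from a single section's surviving spans:
    highest-severity group first, then earliest offset."""
    best_key: tuple[int, int] | None = None
    best_cat: str | None = None
    for sp in spans:
        group = lex.group_of(sp.category_id)
        sev = _SEVERITY.get(group, len(_SEVERITY))
        key = (sev, sp.start)
        if best_key is None or key < best_key:
            best_key, best_cat = key, sp.category_id
    return best_cat


@dataclass
class DiagnosisCall:
    category_id: str | None
    matches: list[MatchSpan]
    changed_by_addendum: bool


def classify_diagnosis(record: ReportRecord, lex: Lexicon) -> DiagnosisCall:
    """Classify one record's diagnosis from its sections.

    Sections are matched in report order (diagnosis → consultation →
    addenda, chronological); the latest section producing any category
    supplies the final call. ``changed_by_addendum`` is set when the
    diagnosis section produced a category and a later section's winner
    differs from it.
    """
    sections: list[tuple[str, str]] = [("diagnosis", record.diagnosis_text)]
    if record.consult_text:
        sections.append(("consult", record.consult_text))
    sections.extend((f"addendum_{k}", text) for k, text in enumerate(record.addenda))

    all_spans: list[MatchSpan] = []
    base_cat: str | None = None
    final_cat: str | None = None
    changed = False
    for name, text in sections:
        spans = [
            MatchSpan(sp.phrase, sp.category_id, sp.start, sp.end, name)
            for sp in match_phrases(text, lex)
        ]
        all_spans.extend(spans)
        winner = _section_winner(spans, lex)
        if winner is None:
            continue
        if name == "diagnosis":
            base_cat = winner
        elif base_cat is not None and winner != base_cat:
            changed = True
        elif base_cat is not None and winner == base_cat:
            changed = False  # a later section restating the original is not a change
        final_cat = winner
    if final_cat == base_cat:
        changed = False
    return DiagnosisCall(final_cat, all_spans, changed)


def classify_site(record: ReportRecord, site_lex: Lexicon) -> str:
    """Assign the nodal station from the "source of specimen" section.

    The first surviving match (highest rank, then earliest offset) wins;
    no match → ``UNKNOWN``.
    """
    spans = match_phrases(record.source_text, site_lex)
    if not spans:
        return UNKNOWN_STATION
    cat = site_lex.categories[spans[0].category_id]
    return cat.station_label  # type: ignore[union-attr]


def classify_corpus(
    records: Sequence[ReportRecord], dx_lex: Lexicon, site_lex: Lexicon
) -> list[ClassifiedRecord]:
    """Classify every record (diagnosis category, exclusive group, station).

    Deterministic: the same corpus and lexicons always produce the same
    output.
    """
    out: list[ClassifiedRecord] = []
    for r in records:
        call = classify_diagnosis(r, dx_lex)
        if call.category_id is None:
            category, group = UNCLASSIFIED_CATEGORY, UNCLASSIFIED
        else:
            category = call.category_id
            group = resolve_group([category], dx_lex)
        out.append(
            ClassifiedRecord(
                record=r,
                diagnosis_category=category,
                exclusive_group=group,
                station=classify_site(r, site_lex),
                matches=call.matches,
                changed_by_addendum=call.changed_by_addendum,
            )
        )
    return out


def classified_frame(classified: Sequence[ClassifiedRecord]) -> pd.DataFrame:
    """Tabular view of a classified corpus (one row per specimen)."""
    return pd.DataFrame(
        {
            "specimen_id": [c.record.specimen_id for c in classified],
            "sps_id": [c.record.sps_id for c in classified],
            "pathologist_id": [c.record.pathologist_id for c in classified],
            "station": [c.station for c in classified],
            "diagnosis_category": [c.diagnosis_category for c in classified],
            "exclusive_group": [c.exclusive_group for c in classified],
            "changed_by_addendum": [c.changed_by_addendum for c in classified],
        }
    )


def audit_sample(
    classified: Sequence[ClassifiedRecord], n: int, seed: int
) -> pd.DataFrame:
    """Seeded uniform sample (without replacement) for human audit.

    The worksheet carries the report text and assigned labels plus blank
    verdict columns (``verdict_category``, ``verdict_station``: fill with
    "correct"/"incorrect"). Re-running with the same seed selects the same
    specimens.
    """
    if n > len(classified):
        raise ValueError(f"audit sample n={n} exceeds corpus size {len(classified)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(classified), size=n, replace=False)
    rows = []
    for i in sorted(idx):
        c = classified[i]
        rows.append(
            {
                "specimen_id": c.record.specimen_id,
                "source_text": c.record.source_text,
                "diagnosis_text": c.record.diagnosis_text,
                "consult_text": c.record.consult_text,
                "addenda": " ||| ".join(c.record.addenda),
                "assigned_category": c.diagnosis_category,
                "assigned_group": c.exclusive_group,
                "assigned_station": c.station,
                "verdict_category": "",
                "verdict_station": "",
            }
        )
    return pd.DataFrame(rows)


def audit_summary(worksheet: pd.DataFrame) -> dict[str, float]:
    """Percent categorized and percent of categorized cases judged correct.

    ``percent_correct`` is computed over categorized rows whose
    ``verdict_category`` has been filled ("correct"/"incorrect").
    """
    n = len(worksheet)
    if n == 0:
        raise ValueError("empty audit worksheet")
    categorized = worksheet["assigned_category"] != UNCLASSIFIED_CATEGORY
    filled = categorized & (worksheet["verdict_category"] != "")
    pct_cat = 100.0 * categorized.mean()
    pct_correct = (
        100.0 * (worksheet.loc[filled, "verdict_category"] == "correct").mean()
        if filled.any()
        else float("nan")
    )
    return {"percent_categorized": pct_cat, "percent_correct": pct_correct}


def audit_against_truth(
    classified: Sequence[ClassifiedRecord], truth: pd.DataFrame
) -> dict[str, float]:
    """Accuracy of assigned category/station against a ground-truth table.

    ``truth`` must be indexed (or indexable) by ``specimen_id`` with columns
    ``category`` and ``station``. Returns percent agreement among all
    records.
    """
    t = truth.set_index("specimen_id") if "specimen_id" in truth.columns else truth
    cat_ok = 0
    st_ok = 0
    for c in classified:
        row = t.loc[c.record.specimen_id]
        cat_ok += int(c.diagnosis_category == row["category"])
        st_ok += int(c.station == row["station"])
    n = len(classified)
    return {"percent_category_correct": 100.0 * cat_ok / n, "percent_station_correct": 100.0 * st_ok / n}
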
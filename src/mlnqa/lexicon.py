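"""Categorization dictionaries for the free-text classifier.

Two lexicon kinds are supported: *diagnosis* (phrase → diagnostic category,
each category assigned to one mutually exclusive group) and *site*
(phrase → IASLC/AJCC nodal station). Phrases are normalized at load time and
ordered by an integer rank; lower rank is matched earlier. The default rank
is descending phrase length (ties lexicographic), which is what makes the
matcher hierarchical: a phrase containing another ("non-small cell
carcinoma" ⊃ "small cell carcinoma") is always tried first and consumes the
span, so the embedded shorter phrase cannot fire.

The packaged dictionaries under ``mlnqa/data`` are synthetic representative
stand-ins sized for testing; a site-specific dictionary in the same TSV/YAML
format can be dropped in via :func:`load_lexicon`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

from mlnqa.text import normalize_text

#: mutually exclusive groups, most severe first; "unclassified" is the
#: sentinel for records with no diagnosis match anywhere.
GROUP_HIERARCHY = ("malignant", "suspicious", "insufficient", "benign")
UNCLASSIFIED = "unclassified"

# entries without an explicit rank sort after any explicit small-integer
# rank, longest phrase first
_DEFAULT_RANK_BASE = 1_000_000


class LexiconError(ValueError):
    """Malformed lexicon file or inconsistent dictionary."""


@dataclass(frozen=True)
class LexiconEntry:
    phrase: str  # normalized
    category_id: str
    rank: int


@dataclass(frozen=True)
class DiagnosisCategory:
    category_id: str
    display_name: str
    exclusive_group: str  # benign|suspicious|malignant|insufficient|none
    group_rank: int


@dataclass(frozen=True)
class SiteCategory:
    category_id: str
    station_label: str


Category = Union[DiagnosisCategory, SiteCategory]


@dataclass
class Lexicon:
    kind: str  # diagnosis|site
    entries: list[LexiconEntry]  # sorted by (rank, phrase)
    categories: dict[str, Category]

    def group_of(self, category_id: str) -> str:
        cat = self.categories.get(category_id)
        if cat is None:
            raise LexiconError(f"unknown category {category_id!r}")
        if isinstance(cat, DiagnosisCategory):
            return cat.exclusive_group
        raise LexiconError("site lexicon has no exclusive groups")

    def phrases_for(self, category_id: str) -> list[str]:
        return [e.phrase for e in self.entries if e.category_id == category_id]


def _load_categories(path: Path, kind: str) -> dict[str, Category]:
    with Path(path).open(encoding="utf-8") as fh:
        spec = yaml.safe_load(fh)
    if spec.get("kind") != kind:
        raise LexiconError(f"category table {path} is kind {spec.get('kind')!r}, expected {kind!r}")
    cats: dict[str, Category] = {}
    for row in spec["categories"]:
        cid = str(row["category_id"])
        if cid in cats:
            raise LexiconError(f"duplicate category_id {cid!r} in {path}")
        if kind == "diagnosis":
            group = row["exclusive_group"]
            if group not in GROUP_HIERARCHY + ("none",):
                raise LexiconError(f"category {cid!r}: unknown exclusive_group {group!r}")
            cats[cid] = DiagnosisCategory(cid, row["display_name"], group, int(row["group_rank"]))
        else:
            cats[cid] = SiteCategory(cid, str(row["station_label"]))
    return cats


def load_lexicon(path: str | Path, kind: str, categories_path: str | Path) -> Lexicon:
    """Load a TSV lexicon (``phrase<TAB>category_id[<TAB>rank]``).

    Phrases are normalized (lowercased, punctuation stripped except
    intra-word hyphens, whitespace collapsed). Entries without an explicit
    rank get rank ``1_000_000 - len(phrase)`` so longer phrases match first;
    explicit ranks (small integers) take priority over all defaults.
    """
    if kind not in ("diagnosis", "site"):
        raise LexiconError(f"unknown lexicon kind {kind!r}")
    categories = _load_categories(Path(categories_path), kind)
    entries: list[LexiconEntry] = []
    seen: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["phrase", "category_id"]:
            raise LexiconError(f"{path}: expected columns phrase<TAB>category_id[<TAB>rank]")
        for i, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            phrase = normalize_text(row[0])
            if not phrase:
                raise LexiconError(f"{path} line {i}: empty phrase after normalization")
            cid = row[1].strip()
            if cid not in categories:
                raise LexiconError(f"{path} line {i}: unknown category_id {cid!r}")
            if phrase in seen:
                raise LexiconError(
                    f"{path} line {i}: duplicate phrase {phrase!r} "
                    f"(categories {seen[phrase]!r} and {cid!r})"
                )
            seen[phrase] = cid
            rank_txt = row[2].strip() if len(row) > 2 and row[2].strip() else None
            rank = int(rank_txt) if rank_txt is not None else _DEFAULT_RANK_BASE - len(phrase)
            entries.append(LexiconEntry(phrase, cid, rank))
    entries.sort(key=lambda e: (e.rank, e.phrase))
    return Lexicon(kind=kind, entries=entries, categories=categories)


def validate_conflicts(lex: Lexicon) -> list[tuple[str, str]]:
    """Report substring conflicts between entries of different categories.

    Returns every ordered pair ``(phrase_a, phrase_b)`` where ``phrase_b`` is
    a proper substring of ``phrase_a`` and the two map to different
    categories. Such pairs are benign as long as the containing phrase has
    strictly lower rank (is matched first); callers can verify that with the
    entries' ranks. Report-only; never raises.
    """
    pairs: list[tuple[str, str]] = []
    for a in lex.entries:
        for b in lex.entries:
            if a.phrase != b.phrase and b.phrase in a.phrase and a.category_id != b.category_id:
                pairs.append((a.phrase, b.phrase))
    return pairs


def _data_path(name: str):
    return resources.files("mlnqa.data").joinpath(name)


def load_default_diagnosis_lexicon() -> Lexicon:
    """Packaged representative diagnosis dictionary (synthetic stand-in)."""
    return load_lexicon(_data_path("diagnosis_lexicon.tsv"), "diagnosis", _data_path("diagnosis_categories.yaml"))


def load_default_site_lexicon() -> Lexicon:
    """Packaged nodal-station dictionary (24 IASLC/AJCC stations)."""
    return load_lexicon(_data_path("site_lexicon.tsv"), "site", _data_path("site_categories.yaml"))
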
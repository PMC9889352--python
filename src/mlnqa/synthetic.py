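"""Ground-truth synthetic report corpora with the statistical structure the
analysis assumes.

Each record draws a nodal station from a configured multinomial, providers
uniformly (patients are assumed randomly assigned to providers), a
mutually exclusive group from a softmax over per-station base log-odds plus
additive per-provider log-odds offsets, and a diagnosis category within the
group. Records are rendered to sectioned free text by embedding lexicon
phrases in a versioned template bank, optionally with distractor prose and
negation sentences; a configurable fraction of non-small-cell-carcinoma
records gains a refining addendum (emulating the common "non-small cell
carcinoma → adenocarcinoma" amendment pattern).

The default configuration emulates a large referral-center cohort: 13
stations with the subcarinal station (7) dominant, per-station group
mixes matching the published per-station fractions of such a cohort, 7
submitting physicians/surgeons and 11 pathologists, and no provider
effects. It is an emulation with known truth labels, not data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mlnqa.lexicon import Lexicon, load_default_diagnosis_lexicon, load_default_site_lexicon
from mlnqa.report_io import ReportRecord, write_corpus

GROUPS4 = ("benign", "suspicious", "malignant", "insufficient")

#: station sampling probabilities (volume-ordered; subcarinal dominant)
DEFAULT_STATIONS: tuple[tuple[str, float], ...] = (
    ("7", 0.351),
    ("4R", 0.277),
    ("4L", 0.146),
    ("2R", 0.049),
    ("10R", 0.056),
    ("11R", 0.040),
    ("11L", 0.026),
    ("2L", 0.012),
    ("10L", 0.012),
    ("12R", 0.008),
    ("8", 0.008),
    ("5", 0.008),
    ("9", 0.007),
)

#: per-station (benign, suspicious, malignant, insufficient) probabilities;
#: "*" is the fallback profile for stations not listed. Normalized at use.
DEFAULT_BASE_GROUP_PROBS: dict[str, tuple[float, float, float, float]] = {
    "7": (0.527, 0.037, 0.208, 0.222),
    "4R": (0.493, 0.039, 0.268, 0.190),
    "4L": (0.419, 0.043, 0.187, 0.346),
    "2R": (0.300, 0.053, 0.413, 0.231),
    "10R": (0.374, 0.050, 0.274, 0.296),
    "11R": (0.345, 0.048, 0.238, 0.356),
    "11L": (0.362, 0.070, 0.262, 0.297),
    "*": (0.459, 0.042, 0.248, 0.243),
}

#: category mix within each group (approximate cohort composition)
DEFAULT_CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "malignant": {
        "adenocarcinoma": 749,
        "squamous_cell_carcinoma": 282,
        "small_cell_carcinoma": 344,
        "non_small_cell_carcinoma": 469,
        "carcinoma_nos": 210,
        "metastasis": 291,
        "lymphoma": 50,
        "malignant_nos": 60,
    },
    "benign": {
        "benign_reactive": 1500,
        "granulomatous_inflammation": 696,
        "benign_lymphocytes": 1400,
        "negative_for_malignancy": 463,
    },
    "suspicious": {"suspicious_for_malignancy": 320, "atypical": 55},
    "insufficient": {"insufficient": 1.0},
}


class SyntheticError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults emulate the reference cohort."""

    n_records: int = 8846
    seed: int = 0
    stations: tuple[tuple[str, float], ...] = DEFAULT_STATIONS
    base_group_probs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_GROUP_PROBS)
    )
    category_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_CATEGORY_PROBS.items()}
    )
    n_sps: int = 7
    n_pathologists: int = 11
    #: per-provider additive log-odds offsets: {provider_id: {group: offset}}
    sps_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    pathologist_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: probability a non-small-cell-carcinoma record gains a refining addendum
    addendum_prob: float = 0.2
    #: refinement targets and their relative weights
    addendum_targets: tuple[tuple[str, float], ...] = (
        ("adenocarcinoma", 0.786),
        ("squamous_cell_carcinoma", 0.214),
    )
    distractor_level: str = "none"  # none|mild|heavy
    date_range: tuple[str, str] = ("2012-07-01", "2019-12-31")

    def __post_init__(self) -> None:
        probs = np.array([p for _, p in self.stations], dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise SyntheticError("station probabilities must be non-negative and sum to 1")
        if self.distractor_level not in ("none", "mild", "heavy"):
            raise SyntheticError(f"unknown distractor_level {self.distractor_level!r}")
        if not (0.0 <= self.addendum_prob <= 1.0):
            raise SyntheticError("addendum_prob must be in [0, 1]")

    @property
    def sps_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sps)]

    @property
    def pathologist_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_pathologists)]

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _station_base_logits(config: SyntheticConfig) -> np.ndarray:
    """(n_stations, 4) log of normalized per-station group probabilities."""
    rows = []
    for st, _ in config.stations:
        p = config.base_group_probs.get(st) or config.base_group_probs.get("*")
        if p is None:
            raise SyntheticError(f"no base group probabilities for station {st!r}")
        p = np.asarray(p, dtype=float)
        if p.min() < 0 or p.sum() <= 0:
            raise SyntheticError(f"invalid group probabilities for station {st!r}")
        p = p / p.sum()
        with np.errstate(divide="ignore"):
            rows.append(np.log(p))
    return np.vstack(rows)


def _effect_matrix(ids: Sequence[str], effects: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    mat = np.zeros((len(ids), len(GROUPS4)))
    for i, pid in enumerate(ids):
        for g, off in effects.get(pid, {}).items():
            if g not in GROUPS4:
                raise SyntheticError(f"unknown group {g!r} in provider effects")
            mat[i, GROUPS4.index(g)] = off
    return mat


def _sample_categorical(rng: np.random.Generator, prob_rows: np.ndarray) -> np.ndarray:
    """Row-wise categorical sampling from an (n, k) probability matrix."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(len(prob_rows))[:, None]
    return (u > cum[:, :-1]).sum(axis=1)


def sample_truth_frame(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized i.i.d. draw of ``n_records`` latent truth records.

    Columns: specimen/patient pseudo-ids, provider ids, ISO received date,
    station, group, final category, initial category, and whether the record
    carries a refining addendum.
    """
    n = config.n_records
    station_labels = [s for s, _ in config.stations]
    station_p = np.array([p for _, p in config.stations])
    st_idx = rng.choice(len(station_labels), size=n, p=station_p)
    sps_idx = rng.integers(0, config.n_sps, size=n)
    path_idx = rng.integers(0, config.n_pathologists, size=n)

    logits = (
        _station_base_logits(config)[st_idx]
        + _effect_matrix(config.sps_ids, config.sps_effects)[sps_idx]
        + _effect_matrix(config.pathologist_ids, config.pathologist_effects)[path_idx]
    )
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    grp_idx = _sample_categorical(rng, probs)
    groups = np.array(GROUPS4, dtype=object)[grp_idx]

    categories = np.empty(n, dtype=object)
    for gi, g in enumerate(GROUPS4):
        mask = grp_idx == gi
        m = int(mask.sum())
        if m == 0:
            continue
        table = config.category_probs.get(g)
        if not table:
            raise SyntheticError(f"no category distribution configured for group {g!r}")
        cats = list(table)
        w = np.array([table[c] for c in cats], dtype=float)
        w /= w.sum()
        categories[mask] = np.array(cats, dtype=object)[_sample_categorical(rng, np.tile(w, (m, 1)))]

    initial = categories.copy()
    refined = np.zeros(n, dtype=bool)
    nscc = categories == "non_small_cell_carcinoma"
    if config.addendum_prob > 0 and nscc.any():
        hit = nscc & (rng.random(n) < config.addendum_prob)
        m = int(hit.sum())
        if m:
            tgt_cats = [c for c, _ in config.addendum_targets]
            tw = np.array([w for _, w in config.addendum_targets], dtype=float)
            tw /= tw.sum()
            categories[hit] = np.array(tgt_cats, dtype=object)[
                _sample_categorical(rng, np.tile(tw, (m, 1)))
            ]
            refined[hit] = True

    d0 = date.fromisoformat(config.date_range[0])
    d1 = date.fromisoformat(config.date_range[1])
    span = (d1 - d0).days
    offsets = rng.integers(0, span + 1, size=n)
    dates = [(d0 + timedelta(days=int(o))).isoformat() for o in offsets]

    return pd.DataFrame(
        {
            "specimen_id": [f"SP{i:06d}" for i in range(n)],
            "patient_pseudo_id": [f"PT{i:06d}" for i in range(n)],
            "sps_id": np.array(config.sps_ids, dtype=object)[sps_idx],
            "pathologist_id": np.array(config.pathologist_ids, dtype=object)[path_idx],
            "received_date": dates,
            "station": np.array(station_labels, dtype=object)[st_idx],
            "group": groups,
            "category": categories,
            "initial_category": initial,
            "refined": refined,
        }
    )


def sample_truth(config: SyntheticConfig, rng: np.random.Generator) -> pd.Series:
    """One latent truth draw (row of :func:`sample_truth_frame`)."""
    one = dataclasses.replace(config, n_records=1)
    return sample_truth_frame(one, rng).iloc[0]


def load_templates(path: str | Path | None = None) -> dict:
    """The versioned template bank shipped with the package (or a drop-in)."""
    if path is None:
        from importlib import resources

        path = resources.files("mlnqa.data").joinpath("templates.yaml")
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def render_report_text(
    truth: Mapping,
    dx_lex: Lexicon,
    site_lex: Lexicon,
    templates: dict,
    rng: np.random.Generator,
    distractor_level: str = "none",
) -> ReportRecord:
    """Render one truth row to a sectioned free-text report.

    The source section embeds a station synonym plus the procedure keywords
    required by the inclusion filter; the diagnosis section embeds a lexicon
    phrase of the (initial) true category, optionally padded with distractor
    prose; refined records gain an addendum naming the final category.
    Distractor text is designed to exercise, not defeat, the matcher: heavy
    mode adds a negation sentence ("negative for malignant cells") to benign
    reports, which the lexicon handles as its own benign entry.
    """
    pick = lambda seq: seq[rng.integers(0, len(seq))]
    station = truth["station"]
    site_syns = [p for p in site_lex.phrases_for(station)]
    if not site_syns:
        raise SyntheticError(f"site lexicon has no phrase for station {station!r}")
    proc = "EBUS" if rng.random() < 0.75 else "EUS"
    source = pick(templates["source_templates"]).format(proc=proc, site=pick(site_syns))

    dx_phrases = dx_lex.phrases_for(truth["initial_category"])
    if not dx_phrases:
        raise SyntheticError(f"diagnosis lexicon has no phrase for {truth['initial_category']!r}")
    diagnosis = pick(templates["diagnosis_templates"]).format(phrase=pick(dx_phrases))

    extras: list[str] = []
    if distractor_level == "mild":
        if rng.random() < 0.5:
            extras.append(pick(templates["distractors_mild"]))
    elif distractor_level == "heavy":
        for _ in range(int(rng.integers(1, 3))):
            extras.append(pick(templates["distractors_heavy"]))
        if truth["group"] == "benign" and rng.random() < 0.7:
            extras.append(templates["negation_distractor"])
    if extras:
        diagnosis = diagnosis + " " + " ".join(extras)

    addenda: list[str] = []
    if truth.get("refined", False):
        phrase = pick(dx_lex.phrases_for(truth["category"]))
        addenda.append(pick(templates["addendum_templates"]).format(phrase=phrase))

    return ReportRecord(
        specimen_id=truth["specimen_id"],
        patient_pseudo_id=truth["patient_pseudo_id"],
        sps_id=truth["sps_id"],
        pathologist_id=truth["pathologist_id"],
        received_date=truth["received_date"],
        source_text=source,
        diagnosis_text=diagnosis,
        consult_text="",
        addenda=addenda,
    )


def generate_corpus(
    config: SyntheticConfig,
    corpus_path: str | Path | None = None,
    truth_path: str | Path | None = None,
    dx_lex: Lexicon | None = None,
    site_lex: Lexicon | None = None,
    templates: dict | None = None,
) -> tuple[list[ReportRecord], pd.DataFrame]:
    """Generate a rendered corpus plus its ground-truth table.

    Deterministic given ``config.seed``. If paths are given, the corpus is
    written in the standard JSONL format and the truth as JSONL keyed by
    specimen_id, with a sidecar ``<truth>.meta.json`` recording the seed and
    config hash.
    """
    rng = np.random.default_rng(config.seed)
    dx_lex = dx_lex or load_default_diagnosis_lexicon()
    site_lex = site_lex or load_default_site_lexicon()
    templates = templates or load_templates()
    truth = sample_truth_frame(config, rng)
    records = [
        render_report_text(row, dx_lex, site_lex, templates, rng, config.distractor_level)
        for row in truth.to_dict("records")
    ]
    if corpus_path is not None:
        write_corpus(records, corpus_path, format="jsonl")
    if truth_path is not None:
        truth_path = Path(truth_path)
        with truth_path.open("w", encoding="utf-8") as fh:
            for row in truth.to_dict("records"):
                row = {k: (bool(v) if isinstance(v, np.bool_) else v) for k, v in row.items()}
                fh.write(json.dumps(row, sort_keys=True) + "\n")
        meta = {"seed": config.seed, "config_hash": config.config_hash(), "n_records": config.n_records}
        truth_path.with_suffix(truth_path.suffix + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
    return records, truth


def truth_as_classified(truth: pd.DataFrame) -> pd.DataFrame:
    """View a truth table as a classified-corpus frame (perfect classifier).

    Useful for studying the statistical machinery (rate tables, charts,
    regression) in isolation from text rendering and matching.
    """
    return pd.DataFrame(
        {
            "specimen_id": truth["specimen_id"],
            "sps_id": truth["sps_id"],
            "pathologist_id": truth["pathologist_id"],
            "station": truth["station"],
            "diagnosis_category": truth["category"],
            "exclusive_group": truth["group"],
            "changed_by_addendum": truth["refined"],
        }
    )
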
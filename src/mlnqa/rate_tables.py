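"""Cohort crosstabs and per-provider rate tables with group median rates.

All fractions are kept at full precision internally; 3-decimal rounding is
applied only in the display helpers, matching the convention of the cohort
tables this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mlnqa.lexicon import GROUP_HIERARCHY, UNCLASSIFIED

#: canonical group order used in tables
GROUP_ORDER = ("benign", "suspicious", "malignant", "insufficient", UNCLASSIFIED)

ROLE_COLUMNS = {"pathologist": "pathologist_id", "sps": "sps_id"}


class RateTableError(ValueError):
    """Empty corpus or insufficient providers for a comparison."""


def _as_frame(classified) -> pd.DataFrame:
    """Accept a classified-corpus DataFrame or a sequence of
    ClassifiedRecord-like objects."""
    if isinstance(classified, pd.DataFrame):
        return classified
    from mlnqa.classifier import classified_frame  # local import to avoid cycle

    return classified_frame(list(classified))


@dataclass
class GroupCountTable:
    """Counts and fractions per mutually exclusive group (plus unclassified)."""

    counts: dict[str, int]
    total: int
    fractions: dict[str, float]

    def display_fractions(self, ndigits: int = 3) -> dict[str, float]:
        return {g: round(f, ndigits) for g, f in self.fractions.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(GROUP_ORDER),
                "number": [self.counts.get(g, 0) for g in GROUP_ORDER],
                "fraction": [self.fractions.get(g, 0.0) for g in GROUP_ORDER],
            }
        )


def tabulate_groups(classified) -> GroupCountTable:
    """Exact group counts and fractions for a classified corpus.

    ``classified`` may be a list of classified records, a DataFrame with an
    ``exclusive_group`` column, or a plain iterable of group labels.
    """
    if isinstance(classified, pd.DataFrame):
        groups = classified["exclusive_group"].tolist()
    else:
        classified = list(classified)
        groups = [c if isinstance(c, str) else c.exclusive_group for c in classified]
    if not groups:
        raise RateTableError("cannot tabulate an empty corpus")
    counts = {g: 0 for g in GROUP_ORDER}
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
    total = len(groups)
    fractions = {g: counts[g] / total for g in counts}
    return GroupCountTable(counts=counts, total=total, fractions=fractions)


@dataclass
class StationCrosstab:
    """Per-station group fractions plus the derived insufficient+suspicious
    row, station totals, and each station's fraction of the corpus."""

    table: pd.DataFrame  # index: rows; columns: stations + "all"
    station_counts: dict[str, int]
    total: int

    def display(self, ndigits: int = 3) -> pd.DataFrame:
        out = self.table.copy()
        frac_rows = [r for r in out.index if r not in ("number",)]
        out.loc[frac_rows] = out.loc[frac_rows].astype(float).round(ndigits)
        return out


def tabulate_by_station(classified, min_records: int = 1) -> StationCrosstab:
    """Crosstab of exclusive group by nodal station.

    Stations with fewer than ``min_records`` specimens (and the UNKNOWN
    station) are excluded from the per-station columns; the "all" column
    always reflects the full corpus. The derived ``insufficient_plus_
    suspicious`` row is the sum of those two per-station fractions.
    """
    df = _as_frame(classified)
    if df.empty:
        raise RateTableError("cannot tabulate an empty corpus")
    total = len(df)
    station_n = df[df["station"] != "UNKNOWN"]["station"].value_counts()
    stations = [s for s, n in station_n.items() if n >= min_records]
    # order stations by volume, largest first
    stations = sorted(stations, key=lambda s: (-station_n[s], s))

    def _col(sub: pd.DataFrame) -> dict[str, float]:
        n = len(sub)
        col = {g: (sub["exclusive_group"] == g).sum() / n for g in GROUP_ORDER}
        col["insufficient_plus_suspicious"] = col["insufficient"] + col["suspicious"]
        col["number"] = n
        col["fraction"] = n / total
        return col

    data = {s: _col(df[df["station"] == s]) for s in stations}
    data["all"] = _col(df)
    rows = list(GROUP_ORDER) + ["insufficient_plus_suspicious", "number", "fraction"]
    table = pd.DataFrame(data).reindex(rows)
    return StationCrosstab(table=table, station_counts={s: int(station_n[s]) for s in stations}, total=total)


@dataclass
class ProviderRateTable:
    """Per-provider counts/rates for one role, with group median rates.

    ``rows`` is indexed by provider_id with columns ``n``, ``count_<group>``
    and ``rate_<group>``. ``group_median_rate`` (the GMR) is the median of
    per-provider rates among *included* providers — not the pooled rate.
    ``station_counts`` (provider × station) and ``stratum_rates``
    (station × group, pooled over included records) support indirect
    case-mix standardization downstream.
    """

    role: str
    rows: pd.DataFrame
    group_median_rate: dict[str, float]
    min_n: int
    station_counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    stratum_rates: pd.DataFrame = field(default_factory=pd.DataFrame)


def provider_rates(classified, role: str, min_n: int = 250) -> ProviderRateTable:
    """Per-provider per-group counts and rates for ``role`` ("pathologist"
    or "sps"), excluding providers with fewer than ``min_n`` specimens.

    Raises :class:`RateTableError` if fewer than two providers survive the
    volume threshold (no peer group to compare against).
    """
    if role not in ROLE_COLUMNS:
        raise RateTableError(f"unknown role {role!r}; expected one of {sorted(ROLE_COLUMNS)}")
    df = _as_frame(classified)
    if df.empty:
        raise RateTableError("cannot tabulate an empty corpus")
    col = ROLE_COLUMNS[role]
    volumes = df[col].value_counts()
    included = sorted(volumes[volumes >= min_n].index)
    if len(included) < 2:
        raise RateTableError(
            f"only {len(included)} {role}(s) with >= {min_n} specimens; "
            "need at least 2 to form a comparison group"
        )
    sub = df[df[col].isin(included)]
    rows = {}
    for pid, grp in sub.groupby(col):
        n = len(grp)
        row: dict[str, float] = {"n": n}
        for g in GROUP_ORDER:
            c = int((grp["exclusive_group"] == g).sum())
            row[f"count_{g}"] = c
            row[f"rate_{g}"] = c / n
        rows[pid] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[included]
    table.index.name = col
    gmr = {g: float(np.median(table[f"rate_{g}"])) for g in GROUP_ORDER}

    station_counts = (
        sub.pivot_table(index=col, columns="station", aggfunc="size", fill_value=0)
        .loc[included]
    )
    pooled = sub[sub["station"] != "UNKNOWN"]
    strat = {}
    for st, grp in pooled.groupby("station"):
        n = len(grp)
        strat[st] = {g: (grp["exclusive_group"] == g).sum() / n for g in GROUP_ORDER}
    stratum_rates = pd.DataFrame.from_dict(strat, orient="index")

    return ProviderRateTable(
        role=role,
        rows=table,
        group_median_rate=gmr,
        min_n=min_n,
        station_counts=station_counts,
        stratum_rates=stratum_rates,
    )
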
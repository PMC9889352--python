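"""Funnel plots and control charts with exact binomial limits.

Charts are centered on the group median rate (GMR) of the included
providers. Control limits are obtained by exact inversion of the binomial
CDF — not a normal approximation, which fails badly in the far tails used
here (bands at p = 0.05, 1e-3, 1e-6, 1e-12). The GMR is treated as a fixed
plug-in center (standard funnel-plot practice; no uncertainty on the center
line). A provider is flagged only when its observed count lies strictly
outside the limit counts; a tie with the limit is in-control.

Case-mix ("normalized") rates use indirect standardization by nodal
station: observed / expected × GMR, where the expectation applies pooled
per-station rates to the provider's own station mix. Flagging always uses
the raw observed count against Binomial(n, GMR); the normalized rate is
used for ordering and display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from mlnqa.rate_tables import ProviderRateTable

#: default significance levels, largest (narrowest band) first
DEFAULT_ALPHAS = (0.05, 1e-3, 1e-6, 1e-12)


class ChartError(ValueError):
    """Invalid chart inputs."""


@dataclass(frozen=True)
class ControlLimits:
    """Exact binomial control band for one (n, center, alpha).

    ``k_lower``/``k_upper`` are the limit *counts*; ``lower``/``upper`` the
    corresponding rates. lower = (largest k with CDF(k-1) <= alpha/2)/n,
    upper = (smallest k with P(X > k) <= alpha/2)/n under
    X ~ Binomial(n, p0).
    """

    alpha: float
    n: int
    p0: float
    k_lower: int
    k_upper: int

    @property
    def lower(self) -> float:
        return self.k_lower / self.n

    @property
    def upper(self) -> float:
        return self.k_upper / self.n


def binomial_limits(n: int, p0: float, alpha: float) -> ControlLimits:
    """Exact two-sided binomial control limits at significance ``alpha``."""
    if n < 1:
        raise ChartError(f"n must be >= 1, got {n}")
    if not (0.0 <= p0 <= 1.0):
        raise ChartError(f"p0 must be in [0, 1], got {p0}")
    if not (0.0 < alpha < 1.0):
        raise ChartError(f"alpha must be in (0, 1), got {alpha}")
    a2 = alpha / 2.0
    k = np.arange(0, n + 1)
    # CDF(k-1): P(X <= k-1); CDF(-1) = 0, so k_lower always exists
    cdf_km1 = np.concatenate(([0.0], stats.binom.cdf(k[:-1], n, p0)))
    k_lower = int(k[cdf_km1 <= a2].max())
    # P(X > k) = sf(k); sf(n) = 0, so k_upper always exists
    sf_k = stats.binom.sf(k, n, p0)
    k_upper = int(k[sf_k <= a2].min())
    return ControlLimits(alpha=alpha, n=n, p0=p0, k_lower=k_lower, k_upper=k_upper)


def two_sided_binomial_p(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial tail probability.

    ``2 * min(P(X <= k), P(X >= k))`` capped at 1, X ~ Binomial(n, p0).
    """
    if not (0 <= k <= n):
        raise ChartError(f"k must be in [0, n], got k={k}, n={n}")
    lo = stats.binom.cdf(k, n, p0)
    hi = stats.binom.sf(k - 1, n, p0)  # P(X >= k)
    return float(min(1.0, 2.0 * min(lo, hi)))


def normalize_rate(
    observed_count: int,
    station_counts: Mapping[str, int],
    stratum_rates: Mapping[str, float],
    p0: float,
    mode: str = "indirect",
) -> float:
    """Case-mix normalized rate for one provider.

    ``raw`` returns the observed rate unchanged. ``indirect`` returns
    ``observed_count / expected_count * p0`` where ``expected_count`` sums
    the provider's per-station volumes times the pooled per-station rate
    (indirect standardization re-centered at the GMR). Stations with no
    pooled rate data are excluded from the expectation with a warning.
    """
    n = sum(station_counts.values())
    if mode == "raw":
        if n == 0:
            raise ChartError("provider has no records")
        return observed_count / n
    if mode != "indirect":
        raise ChartError(f"unknown normalization mode {mode!r}")
    expected = 0.0
    for st, n_st in station_counts.items():
        if n_st == 0:
            continue
        r = stratum_rates.get(st)
        if r is None or not np.isfinite(r):
            warnings.warn(
                f"station {st!r} has no pooled rate data; excluded from expectation",
                stacklevel=2,
            )
            continue
        expected += n_st * r
    if expected <= 0:
        raise ChartError("expected count is zero; cannot normalize indirectly")
    return observed_count / expected * p0


@dataclass
class ProviderChartPoint:
    provider_id: str
    n: int
    observed_count: int
    raw_rate: float
    normalized_rate: float
    two_sided_p: float
    flags: dict[float, str]  # alpha -> in_control | high | low
    limits: dict[float, ControlLimits]

    def to_dict(self) -> dict:
        return {
            "provider_id": str(self.provider_id),
            "n": self.n,
            "observed_count": self.observed_count,
            "raw_rate": self.raw_rate,
            "normalized_rate": self.normalized_rate,
            "two_sided_p": self.two_sided_p,
            "flags": {repr(a): f for a, f in self.flags.items()},
            "limits": {
                repr(a): {"lower": l.lower, "upper": l.upper, "k_lower": l.k_lower, "k_upper": l.k_upper}
                for a, l in self.limits.items()
            },
        }


@dataclass
class ChartResult:
    role: str
    group: str
    p0: float  # the GMR
    mode: str
    points: list[ProviderChartPoint]  # ordered by normalized rate
    outlier_counts: dict[float, int]
    alphas: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "group": self.group,
            "p0": self.p0,
            "mode": self.mode,
            "alphas": list(self.alphas),
            "outlier_counts": {repr(a): c for a, c in self.outlier_counts.items()},
            "points": [p.to_dict() for p in self.points],
        }


def build_chart(
    rate_table: ProviderRateTable,
    group: str,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    mode: str = "indirect",
) -> ChartResult:
    """Per-provider control-chart data for one exclusive group.

    The center ``p0`` is the group median rate. Flags compare each
    provider's observed count to the exact limit counts at that provider's
    volume (strictly outside flags; tie is in-control). Points are returned
    sorted by normalized rate.
    """
    if f"rate_{group}" not in rate_table.rows.columns:
        raise ChartError(f"unknown group {group!r}")
    p0 = rate_table.group_median_rate[group]
    strat = (
        rate_table.stratum_rates[group].to_dict()
        if (mode == "indirect" and group in getattr(rate_table.stratum_rates, "columns", []))
        else {}
    )
    points = []
    for pid, row in rate_table.rows.iterrows():
        n = int(row["n"])
        count = int(row[f"count_{group}"])
        raw = count / n
        if mode == "indirect" and len(strat):
            scounts = rate_table.station_counts.loc[pid].to_dict()
            norm = normalize_rate(count, scounts, strat, p0, mode="indirect")
        else:
            norm = raw
        flags: dict[float, str] = {}
        limits: dict[float, ControlLimits] = {}
        for a in alphas:
            lim = binomial_limits(n, p0, a)
            limits[a] = lim
            if count > lim.k_upper:
                flags[a] = "high"
            elif count < lim.k_lower:
                flags[a] = "low"
            else:
                flags[a] = "in_control"
        points.append(
            ProviderChartPoint(
                provider_id=str(pid),
                n=n,
                observed_count=count,
                raw_rate=raw,
                normalized_rate=norm,
                two_sided_p=two_sided_binomial_p(count, n, p0),
                flags=flags,
                limits=limits,
            )
        )
    points.sort(key=lambda p: (p.normalized_rate, p.provider_id))
    outlier_counts = {
        a: sum(1 for p in points if p.flags[a] != "in_control") for a in alphas
    }
    return ChartResult(
        role=rate_table.role,
        group=group,
        p0=p0,
        mode=mode,
        points=points,
        outlier_counts=outlier_counts,
        alphas=tuple(alphas),
    )


def render_chart(chart: ChartResult, kind: str, path: str | Path) -> None:
    """Render a chart to SVG/PNG (format from the file suffix).

    ``control_chart``: providers on x (ordered by normalized rate),
    normalized rate on y, center line at the GMR, per-provider limit bands
    (dashed 95%, solid 99.9%, dashed outer bands). ``funnel``: volume on x,
    raw rate on y, continuous limit curves. Output depends only on the
    chart data.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if kind not in ("control_chart", "funnel"):
        raise ChartError(f"unknown chart kind {kind!r}")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    styles = {0.05: ("tab:blue", "--"), 1e-3: ("tab:blue", "-"), 1e-6: ("tab:blue", ":"), 1e-12: ("tab:blue", "-.")}
    if kind == "control_chart":
        x = np.arange(1, len(chart.points) + 1)
        y = [p.normalized_rate for p in chart.points]
        ax.axhline(chart.p0, color="black", lw=1.5, label="GMR")
        for a in chart.alphas:
            color, ls = styles.get(a, ("tab:blue", "--"))
            lo = [p.limits[a].lower for p in chart.points]
            hi = [p.limits[a].upper for p in chart.points]
            ax.step(x, lo, where="mid", color=color, ls=ls, lw=0.9)
            ax.step(x, hi, where="mid", color=color, ls=ls, lw=0.9, label=f"p={a:g}")
        ax.plot(x, y, "o", color="tab:red", ms=6)
        ax.set_xlabel(f"{chart.role} (ordered by normalized rate)")
        ax.set_xticks(x)
    else:
        ns = np.array([p.n for p in chart.points])
        grid = np.linspace(max(1, ns.min() * 0.8), ns.max() * 1.1, 120).astype(int)
        grid = np.unique(grid)
        for a in chart.alphas:
            color, ls = styles.get(a, ("tab:blue", "--"))
            lims = [binomial_limits(int(n), chart.p0, a) for n in grid]
            ax.plot(grid, [l.lower for l in lims], color=color, ls=ls, lw=0.9)
            ax.plot(grid, [l.upper for l in lims], color=color, ls=ls, lw=0.9, label=f"p={a:g}")
        ax.axhline(chart.p0, color="black", lw=1.5, label="GMR")
        ax.plot(ns, [p.raw_rate for p in chart.points], "o", color="tab:red", ms=6)
        ax.set_xlabel("specimens (n)")
    ax.set_ylabel(f"{chart.group} rate")
    ax.set_title(f"{chart.role} {chart.group} ({'normalized' if chart.mode == 'indirect' else 'raw'})")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
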
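"""Exact binomial limits, tail probabilities, normalization, chart flags."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mlnqa.control_charts import (
    DEFAULT_ALPHAS,
    ChartError,
    build_chart,
    binomial_limits,
    normalize_rate,
    render_chart,
    two_sided_binomial_p,
)
from mlnqa.rate_tables import provider_rates


def oracle_limits(n, p0, alpha):
    """Limit counts by full pmf enumeration with plain-float accumulation
    (forward for the lower tail, backward for the upper tail)."""
    q = 1.0 - p0
    pmf = [math.comb(n, k) * p0**k * q ** (n - k) for k in range(n + 1)]
    a2 = alpha / 2.0
    cdf = list(itertools.accumulate(pmf))
    # P(X <= k-1) <= a2 ; cdf(-1) = 0
    k_lower = max(k for k in range(n + 1) if (0.0 if k == 0 else cdf[k - 1]) <= a2)
    tail = list(itertools.accumulate(reversed(pmf)))[::-1]  # tail[k] = P(X >= k)
    # P(X > k) <= a2 ; P(X > n) = 0
    k_upper = min(k for k in range(n + 1) if (0.0 if k == n else tail[k + 1]) <= a2)
    return k_lower, k_upper


def oracle_two_sided(k, n, p0):
    q = 1.0 - p0
    pmf = [math.comb(n, i) * p0**i * q ** (n - i) for i in range(n + 1)]
    lo = math.fsum(pmf[: k + 1])
    hi = math.fsum(pmf[k:])
    return min(1.0, 2.0 * min(lo, hi))


class TestBinomialLimits:
    def test_degenerate_p0_zero(self):
        lim = binomial_limits(50, 0.0, 0.05)
        assert lim.lower == lim.upper == 0.0

    def test_degenerate_p0_one(self):
        lim = binomial_limits(50, 1.0, 0.05)
        assert lim.lower == lim.upper == 1.0

    def test_small_case_matches_enumeration(self):
        lim = binomial_limits(20, 0.25, 0.05)
        assert (lim.k_lower, lim.k_upper) == oracle_limits(20, 0.25, 0.05)

    @pytest.mark.parametrize("alpha", DEFAULT_ALPHAS)
    def test_far_tail_alphas_match_enumeration(self, alpha):
        for n, p0 in [(60, 0.25), (150, 0.042), (150, 0.459)]:
            lim = binomial_limits(n, p0, alpha)
            assert (lim.k_lower, lim.k_upper) == oracle_limits(n, p0, alpha)

    def test_band_contains_center(self):
        for n, p0 in [(10, 0.3), (500, 0.042), (37, 0.9)]:
            lim = binomial_limits(n, p0, 0.05)
            assert 0.0 <= lim.lower <= p0 <= lim.upper <= 1.0

    def test_limits_narrow_with_volume(self):
        big = binomial_limits(1000, 0.25, 0.05)
        small = binomial_limits(100, 0.25, 0.05)
        assert small.lower <= big.lower <= big.upper <= small.upper

    def test_bands_nest_across_alpha(self):
        lims = [binomial_limits(400, 0.24, a) for a in DEFAULT_ALPHAS]
        for tight, wide in zip(lims, lims[1:]):  # alphas descend -> bands widen
            assert wide.lower <= tight.lower
            assert tight.upper <= wide.upper

    def test_invalid_inputs(self):
        with pytest.raises(ChartError):
            binomial_limits(0, 0.5, 0.05)
        with pytest.raises(ChartError):
            binomial_limits(10, 1.5, 0.05)
        with pytest.raises(ChartError):
            binomial_limits(10, 0.5, 0.0)


class TestTwoSidedP:
    def test_central_value_near_one(self):
        assert two_sided_binomial_p(25, 100, 0.25) > 0.9

    def test_extreme_tail_closed_form(self):
        assert two_sided_binomial_p(0, 50, 0.5) == pytest.approx(2 * 0.5**50, rel=1e-12)

    def test_matches_pmf_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 120))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.02, 0.98))
            assert two_sided_binomial_p(k, n, p0) == pytest.approx(
                oracle_two_sided(k, n, p0), rel=1e-9, abs=1e-300
            )


class TestNormalizeRate:
    def test_raw_mode_identity(self):
        assert normalize_rate(30, {"7": 100}, {}, p0=0.2, mode="raw") == pytest.approx(0.3)

    def test_matching_mix_indirect_equals_raw(self):
        # provider station mix equal to pooled mix, observed at pooled rates
        counts = {"7": 200, "4R": 100}
        strat = {"7": 0.25, "4R": 0.25}
        p0 = 0.25
        obs = 75  # 0.25 * 300
        assert normalize_rate(obs, counts, strat, p0, "indirect") == pytest.approx(obs / 300)

    def test_double_insufficiency_stations_halve_rate(self):
        # pooled overall rate p0=0.2; provider samples only a station where
        # the pooled rate is doubled (0.4) -> indirect rate is raw/2
        counts = {"B": 100}
        strat = {"B": 0.4}
        raw = 0.4
        norm = normalize_rate(40, counts, strat, p0=0.2, mode="indirect")
        assert norm == pytest.approx(raw / 2)

    def test_unknown_station_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no pooled rate"):
            out = normalize_rate(20, {"7": 100, "X": 50}, {"7": 0.2}, p0=0.2)
        assert out == pytest.approx(20 / (100 * 0.2) * 0.2)


def _rate_frame(counts_by_provider, n_per):
    rows = []
    for pid, k in counts_by_provider.items():
        for i in range(n_per):
            rows.append(
                {
                    "pathologist_id": pid,
                    "sps_id": "S1",
                    "station": "7",
                    "exclusive_group": "insufficient" if i < k else "benign",
                }
            )
    return pd.DataFrame(rows)


class TestBuildChart:
    def test_null_identical_rates_no_outliers(self):
        table = provider_rates(_rate_frame({f"P{i}": 100 for i in range(5)}, 400), "pathologist")
        chart = build_chart(table, "insufficient", mode="raw")
        assert chart.p0 == pytest.approx(0.25)
        assert all(c == 0 for c in chart.outlier_counts.values())

    def test_flags_nest_across_alpha(self):
        rng = np.random.default_rng(8)
        counts = {f"P{i}": int(rng.binomial(400, 0.25 + 0.1 * (i == 0))) for i in range(8)}
        table = provider_rates(_rate_frame(counts, 400), "pathologist")
        chart = build_chart(table, "insufficient", mode="raw")
        order = list(chart.alphas)  # descending alpha
        for p in chart.points:
            for tight, wide in zip(order[1:], order[:-1]):
                if p.flags[tight] != "in_control":
                    assert p.flags[wide] == p.flags[tight]

    def test_points_ordered_by_normalized_rate(self):
        table = provider_rates(_rate_frame({"P1": 120, "P2": 80, "P3": 100}, 400), "pathologist")
        chart = build_chart(table, "insufficient", mode="raw")
        rates = [p.normalized_rate for p in chart.points]
        assert rates == sorted(rates)

    def test_flag_strictly_outside_limit(self):
        # observed count exactly at the limit count is in-control
        table = provider_rates(_rate_frame({"P1": 100, "P2": 100, "P3": 100}, 400), "pathologist")
        chart = build_chart(table, "insufficient", mode="raw", alphas=(0.05,))
        lim = chart.points[0].limits[0.05]
        assert chart.points[0].flags[0.05] == "in_control"
        assert lim.k_lower <= 100 <= lim.k_upper

    def test_indirect_mode_uses_station_mix(self):
        # one provider concentrated on a high-insufficiency station gets
        # pulled toward the center after normalization
        rows = []
        for i in range(300):
            rows.append({"pathologist_id": "P1", "sps_id": "S1", "station": "11R",
                         "exclusive_group": "insufficient" if i < 120 else "benign"})
            rows.append({"pathologist_id": "P2", "sps_id": "S1", "station": "7",
                         "exclusive_group": "insufficient" if i < 60 else "benign"})
        table = provider_rates(pd.DataFrame(rows), "pathologist")
        chart = build_chart(table, "insufficient", mode="indirect")
        p1 = next(p for p in chart.points if p.provider_id == "P1")
        assert p1.normalized_rate < p1.raw_rate


def test_render_chart_writes_files(tmp_path):
    table = provider_rates(_rate_frame({"P1": 90, "P2": 100, "P3": 115}, 400), "pathologist")
    chart = build_chart(table, "insufficient", mode="raw")
    for kind, name in [("control_chart", "cc.svg"), ("funnel", "fp.png")]:
        out = tmp_path / name
        render_chart(chart, kind, out)
        assert out.stat().st_size > 0
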
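"""Multivariable categorical logistic regression of diagnostic outcomes.

For each outcome (a mutually exclusive group, or a specific diagnosis
category) an additive logistic model is fitted with the submitting
physician/surgeon (SPS), pathologist, and nodal station as categorical
predictors. Per-factor significance is assessed with likelihood-ratio
(Type-3-like) tests — the full fit against a fit without that factor, with
df = (levels - 1) — which are better behaved than Wald tests when some
cells are small. The reference level of each factor is its highest-volume
level, for numerical stability.

Low-volume providers and rare stations are trimmed before fitting to avoid
over-fitting sparse levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from mlnqa.rate_tables import GROUP_ORDER, _as_frame

FACTORS = ("sps", "pathologist", "station")
_FACTOR_COLS = {"sps": "sps_id", "pathologist": "pathologist_id", "station": "station"}


class RegressionError(ValueError):
    """Degenerate design or outcome."""


@dataclass
class TrimmedDesign:
    """Records retained for modeling plus factor-level bookkeeping.

    ``levels`` maps each factor to its retained levels ordered by volume
    (largest first); the first level is the reference.
    """

    frame: pd.DataFrame  # columns: sps, pathologist, station, exclusive_group, diagnosis_category
    levels: dict[str, list[str]]
    reference: dict[str, str]
    n_input: int
    n_retained: int


def trim_design(classified, min_n: int = 250, min_station: int = 20) -> TrimmedDesign:
    """Drop records of low-volume providers and rare/unknown stations.

    A single pass over the input counts: SPS and pathologists with fewer
    than ``min_n`` records are excluded, as are stations with fewer than
    ``min_station`` records or an UNKNOWN station.
    """
    df = _as_frame(classified)
    if df.empty:
        raise RegressionError("empty corpus")
    keep = pd.Series(True, index=df.index)
    for factor, col in _FACTOR_COLS.items():
        counts = df[col].value_counts()
        thresh = min_station if factor == "station" else min_n
        ok = set(counts[counts >= thresh].index)
        if factor == "station":
            ok.discard("UNKNOWN")
        keep &= df[col].isin(ok)
    out = df[keep].copy()
    if out.empty:
        raise RegressionError(
            f"no records survive trimming (min_n={min_n}, min_station={min_station})"
        )
    out = out.rename(columns={v: k for k, v in _FACTOR_COLS.items() if v != k})
    levels: dict[str, list[str]] = {}
    reference: dict[str, str] = {}
    for factor in FACTORS:
        counts = out[factor].value_counts()
        lv = list(counts.sort_values(ascending=False).index)
        if len(lv) < 2:
            raise RegressionError(f"factor {factor!r} has fewer than 2 levels after trimming")
        levels[factor] = [str(x) for x in lv]
        reference[factor] = str(lv[0])
    return TrimmedDesign(
        frame=out.reset_index(drop=True),
        levels=levels,
        reference=reference,
        n_input=len(df),
        n_retained=len(out),
    )


@dataclass(frozen=True)
class FactorTest:
    factor: str
    df: int
    statistic: float  # likelihood-ratio chi-square
    p_value: float


@dataclass
class ModelResult:
    outcome: str
    coefficients: pd.DataFrame  # term, coef, odds_ratio, se, ci_low, ci_high (Wald)
    factor_tests: list[FactorTest]
    converged: bool
    separation_flag: bool
    llf: float
    n: int
    fitted_prob: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def factor_test(self, factor: str) -> FactorTest:
        for t in self.factor_tests:
            if t.factor == factor:
                return t
        raise KeyError(factor)


def _design_matrix(design: TrimmedDesign, drop: str | None = None) -> pd.DataFrame:
    cols = [np.ones(len(design.frame))]
    names = ["intercept"]
    for factor in FACTORS:
        if factor == drop:
            continue
        ref = design.reference[factor]
        vals = design.frame[factor].astype(str)
        for lv in design.levels[factor]:
            if lv == ref:
                continue
            cols.append((vals == lv).to_numpy(dtype=float))
            names.append(f"{factor}[{lv}]")
    X = pd.DataFrame(np.column_stack(cols), columns=names)
    return X


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import warnings as _warnings

    model = sm.Logit(y, X)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200, method="newton")
        except Exception:
            res = None
        if res is None or not res.mle_retvals.get("converged", False) or not np.isfinite(res.llf):
            res_b = model.fit(disp=0, maxiter=1000, method="bfgs")
            if res is None or not np.isfinite(res.llf) or (np.isfinite(res_b.llf) and res_b.llf >= res.llf):
                res = res_b
    return res


def fit_category_model(
    design: TrimmedDesign, outcome: str, factor_tests: bool = True
) -> ModelResult:
    """Maximum-likelihood logistic fit of a binary outcome on SPS +
    pathologist + station.

    ``outcome`` is an exclusive group name (indicator: record in that
    group) or a diagnosis category id. Per-factor likelihood-ratio tests
    refit the model without each factor (df = levels - 1). Non-convergence
    or (quasi-)separation is flagged in the result, never silent.
    """
    df = design.frame
    if outcome in GROUP_ORDER:
        y = (df["exclusive_group"] == outcome).to_numpy(dtype=float)
    elif "diagnosis_category" in df.columns and (df["diagnosis_category"] == outcome).any():
        y = (df["diagnosis_category"] == outcome).to_numpy(dtype=float)
    else:
        raise RegressionError(f"outcome {outcome!r} is neither a group nor an observed category")
    if y.min() == y.max():
        raise RegressionError(f"outcome {outcome!r} is constant in the trimmed design")

    X = _design_matrix(design)
    res = _fit_logit(y, X)
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    # crude separation screen: enormous coefficients with enormous SEs
    separation = bool(np.any(np.abs(res.params) > 15))

    params = res.params
    bse = res.bse
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # separation -> infinite Wald CI, flagged above
        coef = pd.DataFrame(
            {
                "term": X.columns,
                "coef": params.to_numpy(),
                "odds_ratio": np.exp(params.to_numpy()),
                "se": bse.to_numpy(),
                "ci_low": np.exp(params.to_numpy() - z * bse.to_numpy()),
                "ci_high": np.exp(params.to_numpy() + z * bse.to_numpy()),
            }
        )

    tests: list[FactorTest] = []
    if factor_tests:
        for factor in FACTORS:
            X_red = _design_matrix(design, drop=factor)
            res_red = _fit_logit(y, X_red)
            stat = 2.0 * (res.llf - res_red.llf)
            k = len(design.levels[factor]) - 1
            tests.append(
                FactorTest(
                    factor=factor,
                    df=k,
                    statistic=max(stat, 0.0),
                    p_value=float(stats.chi2.sf(max(stat, 0.0), k)),
                )
            )

    return ModelResult(
        outcome=outcome,
        coefficients=coef,
        factor_tests=tests,
        converged=converged,
        separation_flag=separation,
        llf=float(res.llf),
        n=len(df),
        fitted_prob=np.asarray(res.predict(X)),
        y=y,
    )


@dataclass
class RocCurve:
    points: pd.DataFrame  # columns fpr, tpr (threshold sweep, ends pinned)
    area: float


def roc_from_model(model: ModelResult) -> RocCurve:
    """In-sample ROC from a fitted model's predicted probabilities.

    Thresholds sweep all unique predicted values; the area is computed by
    the trapezoid rule over (FPR, TPR).
    """
    p = np.asarray(model.fitted_prob, dtype=float)
    y = np.asarray(model.y, dtype=int)
    pos = y.sum()
    neg = len(y) - pos
    if pos == 0 or neg == 0:
        raise RegressionError("ROC undefined: outcome has a single class")
    thresholds = np.unique(p)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        pred = p >= t
        tpr.append(float((pred & (y == 1)).sum() / pos))
        fpr.append(float((pred & (y == 0)).sum() / neg))
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    fpr_a = np.array(fpr)
    tpr_a = np.array(tpr)
    area = float(np.trapezoid(tpr_a, fpr_a))
    return RocCurve(points=pd.DataFrame({"fpr": fpr_a, "tpr": tpr_a}), area=area)
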
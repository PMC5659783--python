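"""Behavioral analysis battery for choice and reaction time.

Trials are classified as correct (greater-valued option chosen), incorrect
(lesser-valued option chosen) or indifferent (equal values).  Option values
are normalized linearly so the scale minimum maps to 0 and the maximum to
1, making coefficients comparable across rating scales.  Two complementary
parameterizations are fitted for each outcome:

* ``greater_lesser`` — intercept + greater value + lesser value;
* ``difference_sum`` — intercept + |value difference| + value sum,
  an orthogonal linear recombination of the first.

Accuracy is modeled by logistic regression (indifferent trials excluded);
RT in seconds by least squares, separately per trial category, with each
coefficient also reported divided by the intercept ("constant-normalized":
a value of -0.1 means a 10% speed-up relative to the mean RT when that
regressor is at its maximum).  For indifferent trials only the sum model
is defined, the difference being structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "RegressionTable",
    "classify",
    "normalize_values",
    "fit_accuracy",
    "fit_rt",
    "abs_contrast",
    "category_rt_test",
    "meta_aggregate",
]

#: default fast-guess cutoff (ms); faster responses are contaminants
MIN_RT_MS = 300


@dataclass
class RegressionTable:
    """Fitted coefficients of one regression model.

    ``est``/``se`` are on the raw scale.  For RT outcomes, ``norm_est`` and
    ``norm_se`` divide every non-constant entry by the fitted intercept
    (the intercept itself stays in seconds); the SE is scaled the same way,
    intercept uncertainty being ignored.
    """

    outcome: str
    parameterization: str
    terms: list[str]
    est: np.ndarray
    se: np.ndarray
    n_trials: int
    norm_est: np.ndarray | None = None
    norm_se: np.ndarray | None = None
    flagged: str | None = None
    contrasts: dict = field(default_factory=dict)

    def coef(self, term: str, normalized: bool = False) -> tuple[float, float]:
        i = self.terms.index(term)
        if normalized:
            if self.norm_est is None:
                raise ValueError("no normalized coefficients for this table")
            return float(self.norm_est[i]), float(self.norm_se[i])
        return float(self.est[i]), float(self.se[i])

    def pvalue(self, term: str) -> float:
        i = self.terms.index(term)
        z = self.est[i] / self.se[i]
        return float(2.0 * stats.norm.sf(abs(z)))

    def to_frame(self) -> pd.DataFrame:
        data = {"est": self.est, "se": self.se}
        if self.norm_est is not None:
            data["norm_est"] = self.norm_est
            data["norm_se"] = self.norm_se
        data["p"] = [self.pvalue(t) for t in self.terms]
        return pd.DataFrame(data, index=pd.Index(self.terms, name="term"))


def normalize_values(values, levels=None) -> np.ndarray:
    """Map a rating scale linearly onto [0, 1].

    ``levels`` gives the scale (its min and max are used); by default it is
    inferred from the data.  Idempotent on already-normalized input.
    """
    values = np.asarray(values, dtype=float)
    if levels is None:
        lo, hi = values.min(), values.max()
    else:
        levels = np.asarray(levels, dtype=float)
        lo, hi = levels.min(), levels.max()
    if hi <= lo:
        raise ValueError("need at least two distinct scale values")
    return (values - lo) / (hi - lo)


def classify(dataset: pd.DataFrame, min_rt_ms: int = MIN_RT_MS,
             levels=None) -> pd.DataFrame:
    """Label trials and prepare the regression design columns.

    Drops non-responses and contaminant RTs below ``min_rt_ms``, then adds
    ``greater``/``lesser`` (raw and normalized), ``absdiff``/``vsum``
    (normalized), ``category`` in {correct, incorrect, indifferent} and
    ``rt_s`` (seconds).
    """
    df = dataset.loc[
        dataset["choice"].isin(["L", "R"]) & (dataset["rt_ms"] >= min_rt_ms)
    ].copy()
    vl = df["v_left"].to_numpy(dtype=float)
    vr = df["v_right"].to_numpy(dtype=float)
    chosen = np.where(df["choice"].to_numpy() == "L", vl, vr)
    other = np.where(df["choice"].to_numpy() == "L", vr, vl)
    df["greater"] = np.maximum(vl, vr)
    df["lesser"] = np.minimum(vl, vr)
    df["category"] = np.select(
        [vl == vr, chosen > other], ["indifferent", "correct"], "incorrect")
    if levels is None:
        levels = np.unique(np.concatenate([vl, vr]))
    g = normalize_values(df["greater"], levels)
    l = normalize_values(df["lesser"], levels)
    df["greater_n"] = g
    df["lesser_n"] = l
    df["absdiff"] = g - l
    df["vsum"] = g + l
    df["rt_s"] = df["rt_ms"] / 1000.0
    return df


def _design(df: pd.DataFrame, parameterization: str) -> tuple[np.ndarray, list[str]]:
    if parameterization == "greater_lesser":
        cols, names = ["greater_n", "lesser_n"], ["const", "greater", "lesser"]
    elif parameterization == "difference_sum":
        cols, names = ["absdiff", "vsum"], ["const", "absdiff", "sum"]
    elif parameterization == "sum_only":
        cols, names = ["vsum"], ["const", "sum"]
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    X = sm.add_constant(df[cols].to_numpy(dtype=float), has_constant="add")
    return X, names


def fit_accuracy(classified: pd.DataFrame) -> tuple[RegressionTable, RegressionTable]:
    """Logistic regressions of accuracy, both parameterizations.

    Indifferent trials are excluded (accuracy is undefined for them).
    Perfect separation yields a flagged table without coefficients.
    """
    df = classified[classified["category"] != "indifferent"]
    y = (df["category"] == "correct").to_numpy(dtype=float)
    out = []
    for parameterization in ("greater_lesser", "difference_sum"):
        X, names = _design(df, parameterization)
        try:
            res = sm.Logit(y, X).fit(disp=0)
            if not np.all(np.isfinite(res.bse)):
                raise np.linalg.LinAlgError("non-finite standard errors")
            table = RegressionTable(
                outcome="accuracy", parameterization=parameterization,
                terms=names, est=np.asarray(res.params),
                se=np.asarray(res.bse), n_trials=len(df))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as err:
            table = RegressionTable(
                outcome="accuracy", parameterization=parameterization,
                terms=names, est=np.full(len(names), np.nan),
                se=np.full(len(names), np.nan), n_trials=len(df),
                flagged=f"fit failed: {err}")
        out.append(table)
    return out[0], out[1]


def fit_rt(classified: pd.DataFrame, category: str,
           min_trials: int = 10):
    """Linear regressions of RT (seconds) for one trial category.

    Returns the (greater+lesser, difference+sum) pair of tables, or a
    single sum-only table for the indifferent category.  Fewer than
    ``min_trials`` trials yields flagged tables with no coefficients.
    """
    if category not in ("correct", "incorrect", "indifferent"):
        raise ValueError(f"unknown category {category!r}")
    df = classified[classified["category"] == category]
    outcome = f"rt_{category}"
    parameterizations = (
        ("sum_only",) if category == "indifferent"
        else ("greater_lesser", "difference_sum"))
    y = df["rt_s"].to_numpy(dtype=float)
    out = []
    for parameterization in parameterizations:
        X, names = _design(df, parameterization)
        if len(df) < min_trials:
            out.append(RegressionTable(
                outcome=outcome, parameterization=parameterization,
                terms=names, est=np.full(len(names), np.nan),
                se=np.full(len(names), np.nan), n_trials=len(df),
                flagged=f"only {len(df)} trials (< {min_trials})"))
            continue
        res = sm.OLS(y, X).fit()
        est = np.asarray(res.params)
        se = np.asarray(res.bse)
        const = est[0]
        norm_est = est / const
        norm_se = se / const
        norm_est[0] = const  # intercept reported raw, in seconds
        norm_se[0] = se[0]
        out.append(RegressionTable(
            outcome=outcome, parameterization=parameterization,
            terms=names, est=est, se=se, n_trials=len(df),
            norm_est=norm_est, norm_se=norm_se))
    if category == "indifferent":
        return out[0]
    return out[0], out[1]


def abs_contrast(coef1: float, se1: float, coef2: float,
                 se2: float) -> tuple[float, float, float]:
    """Two-tailed contrast of the *absolute values* of two coefficients.

    Returns ``(M, z, p)`` where ``M = |coef1| - |coef2|`` and the test
    statistic uses the combined standard error sqrt(se1^2 + se2^2).
    """
    M = abs(coef1) - abs(coef2)
    se = float(np.hypot(se1, se2))
    z = M / se if se > 0 else np.inf * np.sign(M) if M else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(M), float(z), p


def category_rt_test(classified: pd.DataFrame, cat_a: str,
                     cat_b: str) -> tuple[float, float, float]:
    """Welch two-sample t test of mean RT between two trial categories.

    Returns ``(mean difference in ms, t, p)`` with the difference signed
    as ``cat_a`` minus ``cat_b``.
    """
    a = classified.loc[classified["category"] == cat_a, "rt_ms"]
    b = classified.loc[classified["category"] == cat_b, "rt_ms"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both categories must be nonempty")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(t), float(p)


def meta_aggregate(tables: list[RegressionTable],
                   weights=None) -> RegressionTable:
    """Trial-weighted aggregation of regression tables across datasets.

    Coefficients are averaged with weights proportional to each table's
    trial count (or explicit ``weights``); the aggregate standard error is
    the weighted between-dataset dispersion of the estimates,
    ``sqrt(sum_i w_i (b_i - b_bar)^2 / (1 - sum_i w_i^2))`` scaled by
    ``sqrt(sum_i w_i^2)`` (i.e. an unbiased weighted variance divided by
    the effective number of datasets).  A single input table is returned
    unchanged.
    """
    if not tables:
        raise ValueError("need at least one table")
    first = tables[0]
    for t in tables[1:]:
        if (t.outcome, t.parameterization) != (first.outcome,
                                               first.parameterization):
            raise ValueError("tables must share outcome and parameterization")
    if len(tables) == 1:
        return first
    if weights is None:
        weights = [t.n_trials for t in tables]
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    def _agg(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = w @ values
        resid2 = (values - mean) ** 2
        denom = max(1.0 - float(w @ w), np.finfo(float).eps)
        var = (w @ resid2) / denom  # unbiased weighted between-set variance
        se = np.sqrt(var * float(w @ w))
        return mean, se

    est_mat = np.vstack([t.est for t in tables])
    est, se = _agg(est_mat)
    norm_est = norm_se = None
    if first.norm_est is not None:
        norm_mat = np.vstack([t.norm_est for t in tables])
        norm_est, norm_se = _agg(norm_mat)
    return RegressionTable(
        outcome=first.outcome, parameterization=first.parameterization,
        terms=list(first.terms), est=est, se=se,
        n_trials=int(sum(t.n_trials for t in tables)),
        norm_est=norm_est, norm_se=norm_se)
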
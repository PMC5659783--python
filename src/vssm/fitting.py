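"""Chi-square quantile fitting, benchmarks, and model comparison.

The objective follows the quantile-based chi-square method for fitting
simulation-only models to choice/RT data: per input vector (unordered
value pair), the observed choice frequencies and the 10/30/50/70/90% RT
quantiles of each choice define six RT bins per choice; a model is
simulated (2,000 trials per vector by default), its trials are sorted into
those bins, and the Pearson discrepancy between observed and predicted bin
proportions — input vectors weighted equally — is minimized over the free
parameters by Nelder-Mead with random restarts and common random numbers
within each restart.

Observed bin proportions are computed empirically from the data with the
same binning convention used for predictions (closed on the right), rather
than fixed at the nominal (0.1, 0.2, 0.2, 0.2, 0.2, 0.1) masses: RTs live
on a 10-ms grid, and with heavy ties the nominal masses are unattainable,
whereas the empirical convention makes the objective exactly zero when
predicted and observed distributions coincide.

Null and saturated benchmarks bracket attainable performance, and
likelihood-ratio tests, AICc and BIC (with the chi-square objective as
deviance proxy) compare the nested models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (
    ACTIVE_PARAMS,
    ModelParams,
    NESTED_WITHIN,
    SimConfig,
)
from .simulate import simulate_pairs

__all__ = [
    "QuantileCell",
    "QuantileTable",
    "FitResult",
    "summarize",
    "summarize_arrays",
    "chi2_statistic",
    "EmpiricalPredictor",
    "NullPredictor",
    "saturated_predict",
    "null_predict",
    "fit_model",
    "information_criteria",
    "lr_test",
    "parity_split",
]

#: contaminant cutoff shared with the analysis battery (ms)
MIN_RT_MS = 300

#: RT quantile probabilities defining the six bins
QUANTILE_PROBS = (0.10, 0.30, 0.50, 0.70, 0.90)

#: a choice needs at least this many trials in a cell for RT quantiles;
#: below it the cell contributes its frequency only
MIN_TRIALS_FOR_QUANTILES = 5

#: floor applied to predicted proportions in the Pearson denominator
PRED_FLOOR = 1e-4


@dataclass(frozen=True)
class QuantileCell:
    """Summary of one (input vector, choice) cell.

    ``cat`` is 1 for choosing the greater-valued option (the second
    element of the sorted pair; for ties, the second presented
    alternative).  ``props`` are proportions of the *vector's* responded
    trials, so the two cells of a vector sum to one; when ``edges`` is
    None the cell is frequency-only.
    """

    pair: tuple[float, float]
    cat: int
    n: int
    freq: float
    edges: np.ndarray | None
    props: np.ndarray


@dataclass(frozen=True)
class QuantileTable:
    """Per-input-vector choice frequencies and RT quantile bins."""

    cells: tuple[QuantileCell, ...]
    n_responded: int
    pairs: tuple[tuple[float, float], ...]

    @property
    def n_vectors(self) -> int:
        return len(self.pairs)

    @property
    def n_bin_cells(self) -> int:
        """Number of scalar observations entering the objective."""
        return int(sum(len(c.props) for c in self.cells))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {"pair_lo": c.pair[0], "pair_hi": c.pair[1],
                   "cat": c.cat, "n": c.n, "freq": c.freq}
            if c.edges is not None:
                for p, q in zip(QUANTILE_PROBS, c.edges):
                    row[f"q{int(100 * p)}"] = q
            rows.append(row)
        return pd.DataFrame(rows)


def _bin_counts(rt: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts in the bins cut by ``edges`` (right-closed at each edge)."""
    idx = np.searchsorted(edges, rt, side="left")
    return np.bincount(idx, minlength=len(edges) + 1).astype(float)


def _dataset_arrays(dataset: pd.DataFrame):
    """Reduce a trial table to (pairs, pair_idx, cat, rt) arrays."""
    vl = dataset["v_left"].to_numpy(dtype=float)
    vr = dataset["v_right"].to_numpy(dtype=float)
    lo = np.minimum(vl, vr)
    hi = np.maximum(vl, vr)
    side = dataset["choice"].to_numpy()
    crossed = (side == "L") | (side == "R")
    chose_right = side == "R"
    chosen = np.where(chose_right, vr, vl)
    # cat 1 = greater value chosen; ties resolved by presentation side
    cat = np.where(lo == hi, chose_right.astype(int),
                   (chosen == hi).astype(int))
    rt = dataset["rt_ms"].to_numpy(dtype=float)
    pairs = np.unique(np.column_stack([lo, hi]), axis=0)
    keys = lo * (hi.max() + 1) + hi
    pair_keys = pairs[:, 0] * (hi.max() + 1) + pairs[:, 1]
    pair_idx = np.searchsorted(pair_keys, keys)
    return pairs, pair_idx, cat, rt, crossed


def summarize_arrays(
    pairs: np.ndarray,
    pair_idx: np.ndarray,
    cat_or_choice: np.ndarray,
    rt: np.ndarray,
    crossed: np.ndarray,
    min_rt_ms: int = MIN_RT_MS,
) -> QuantileTable:
    """Array-interface version of :func:`summarize`.

    ``pairs`` rows must be sorted pairs ``(lo, hi)``; ``cat_or_choice`` is
    the chosen column index, which for sorted pairs equals the
    greater-chosen indicator.
    """
    keep = crossed & (rt >= min_rt_ms)
    pair_idx = pair_idx[keep]
    cat = cat_or_choice[keep]
    rt = rt[keep].astype(float)
    cells = []
    kept_pairs = []
    for j, pair in enumerate(map(tuple, np.asarray(pairs, dtype=float))):
        mask = pair_idx == j
        n_vec = int(mask.sum())
        if n_vec == 0:
            continue  # empty cell after filtering: excluded, flagged by absence
        kept_pairs.append(pair)
        # equal-value pairs: the two choices are the same event up to an
        # arbitrary side label, so their trials pool into one cell
        cats = (1,) if pair[0] == pair[1] else (0, 1)
        for c in cats:
            sel = mask if len(cats) == 1 else mask & (cat == c)
            n = int(sel.sum())
            freq = n / n_vec
            if n >= MIN_TRIALS_FOR_QUANTILES:
                r = rt[sel]
                edges = np.quantile(r, QUANTILE_PROBS, method="linear")
                props = _bin_counts(r, edges) / n_vec
            else:
                edges = None
                props = np.array([freq])
            cells.append(QuantileCell(pair=pair, cat=c, n=n, freq=freq,
                                      edges=edges, props=props))
    return QuantileTable(cells=tuple(cells),
                         n_responded=int(keep.sum()),
                         pairs=tuple(kept_pairs))


def summarize(dataset: pd.DataFrame, min_rt_ms: int = MIN_RT_MS) -> QuantileTable:
    """Quantile summary of a behavioral dataset.

    Drops non-responses and RTs below the contaminant cutoff, groups by
    unordered value pair, and computes per-choice frequencies plus the
    10/30/50/70/90% RT quantiles (linear interpolation between order
    statistics) wherever a choice has at least five trials.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    pairs, pair_idx, cat, rt, crossed = _dataset_arrays(dataset)
    return summarize_arrays(pairs, pair_idx, cat, rt, crossed, min_rt_ms)


class EmpiricalPredictor:
    """Predicted proportions read off a (simulated or held-out) dataset."""

    def __init__(self, pairs, pair_idx, cat, rt, crossed,
                 min_rt_ms: int = MIN_RT_MS):
        keep = crossed & (rt >= min_rt_ms)
        self._pairs = {tuple(map(float, p)): j
                       for j, p in enumerate(np.asarray(pairs, dtype=float))}
        self._pair_idx = pair_idx[keep]
        self._cat = cat[keep]
        self._rt = rt[keep].astype(float)

    @classmethod
    def from_dataset(cls, dataset: pd.DataFrame,
                     min_rt_ms: int = MIN_RT_MS) -> "EmpiricalPredictor":
        pairs, pair_idx, cat, rt, crossed = _dataset_arrays(dataset)
        return cls(pairs, pair_idx, cat, rt, crossed, min_rt_ms)

    def predict_props(self, cell: QuantileCell) -> np.ndarray:
        j = self._pairs.get(tuple(map(float, cell.pair)))
        if j is None:
            raise ValueError(f"predictor has no trials for pair {cell.pair}")
        mask = self._pair_idx == j
        n_vec = int(mask.sum())
        if n_vec == 0:
            raise ValueError(f"predictor has no trials for pair {cell.pair}")
        if cell.pair[0] == cell.pair[1]:
            sel = mask  # tie pairs pool both (equivalent) choices
        else:
            sel = mask & (self._cat == cell.cat)
        if cell.edges is None:
            return np.array([sel.sum() / n_vec])
        return _bin_counts(self._rt[sel], cell.edges) / n_vec


class NullPredictor:
    """The three-df no-input-effect benchmark.

    A single choice frequency (the mean across vectors) and a single
    uniform RT distribution whose support is the mean of the per-cell
    minima to the mean of the per-cell maxima of the training RTs.
    """

    def __init__(self, freq_cat1: float, rt_lo: float, rt_hi: float):
        self.freq_cat1 = float(freq_cat1)
        self.rt_lo = float(rt_lo)
        self.rt_hi = float(rt_hi)
        if not rt_hi > rt_lo:
            raise ValueError("degenerate RT support")

    @classmethod
    def from_dataset(cls, dataset: pd.DataFrame,
                     min_rt_ms: int = MIN_RT_MS) -> "NullPredictor":
        pairs, pair_idx, cat, rt, crossed = _dataset_arrays(dataset)
        keep = crossed & (rt >= min_rt_ms)
        pair_idx, cat, rt = pair_idx[keep], cat[keep], rt[keep]
        freqs, mins, maxs = [], [], []
        for j in range(len(pairs)):
            mask = pair_idx == j
            if not mask.any():
                continue
            freqs.append((cat[mask] == 1).mean())
            for c in (0, 1):
                sel = mask & (cat == c)
                if sel.any():
                    mins.append(rt[sel].min())
                    maxs.append(rt[sel].max())
        return cls(np.mean(freqs), np.mean(mins), np.mean(maxs))

    def _cdf(self, x: np.ndarray) -> np.ndarray:
        return np.clip((x - self.rt_lo) / (self.rt_hi - self.rt_lo), 0.0, 1.0)

    def predict_props(self, cell: QuantileCell) -> np.ndarray:
        if cell.pair[0] == cell.pair[1]:
            freq = 1.0  # tie pairs carry a single pooled cell
        else:
            freq = self.freq_cat1 if cell.cat == 1 else 1.0 - self.freq_cat1
        if cell.edges is None:
            return np.array([freq])
        cdf = np.concatenate([[0.0], self._cdf(cell.edges), [1.0]])
        return freq * np.diff(cdf)


def saturated_predict(training: pd.DataFrame) -> EmpiricalPredictor:
    """Saturated benchmark: the training data reused directly."""
    return EmpiricalPredictor.from_dataset(training)


def null_predict(training: pd.DataFrame) -> NullPredictor:
    """Null benchmark: no input effects, uniform RT distribution."""
    return NullPredictor.from_dataset(training)


def chi2_statistic(observed: QuantileTable, predicted,
                   floor: float = PRED_FLOOR) -> float:
    """Pearson discrepancy between observed and predicted bin proportions.

    ``predicted`` may be a behavioral dataset (DataFrame) or any object
    with a ``predict_props(cell)`` method.  Every input vector carries the
    same effective count ``N_eff = n_responded / n_vectors``; predicted
    proportions are floored at ``floor`` in the denominator.
    """
    if isinstance(predicted, pd.DataFrame):
        predicted = EmpiricalPredictor.from_dataset(predicted)
    n_eff = observed.n_responded / observed.n_vectors
    total = 0.0
    for cell in observed.cells:
        pp = predicted.predict_props(cell)
        if len(pp) != len(cell.props):
            raise ValueError("predictor returned wrong number of bins")
        total += n_eff * float(
            np.sum((cell.props - pp) ** 2 / np.maximum(pp, floor)))
    return total


def information_criteria(chi2: float, k: int, n_cells: int) -> tuple[float, float]:
    """AICc and BIC with the chi-square objective as deviance proxy.

    ``AICc = chi2 + 2k + 2k(k+1)/(n_cells - k - 1)``;
    ``BIC = chi2 + k ln(n_cells)``.
    """
    if n_cells <= k + 1:
        raise ValueError("AICc undefined: n_cells must exceed k + 1")
    aicc = chi2 + 2 * k + 2 * k * (k + 1) / (n_cells - k - 1)
    bic = chi2 + k * np.log(n_cells)
    return float(aicc), float(bic)


@dataclass
class FitResult:
    """Outcome of fitting one model to a quantile summary."""

    params: ModelParams
    chi2: float
    df: int
    n_cells: int
    aicc: float
    bic: float
    seed: object = None
    n_trials_per_vector: int = 2000
    restarts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "chi2": self.chi2, "df": self.df, "n_cells": self.n_cells,
            "aicc": self.aicc, "bic": self.bic,
            "seed": repr(self.seed),
            "n_trials_per_vector": self.n_trials_per_vector,
            "restarts": self.restarts,
        }


def lr_test(fit_nested: FitResult, fit_full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio-style test between two nested fits.

    The chi-square objective difference is referred to a chi-square law
    with the difference in degrees of freedom.  Negative statistics
    (Monte-Carlo noise) are clamped to zero with a warning.
    """
    nested_id = fit_nested.params.model_id
    full_id = fit_full.params.model_id
    if full_id not in NESTED_WITHIN[nested_id]:
        raise ValueError(
            f"{nested_id} is not nested within {full_id}; "
            "use information criteria (AICc/BIC) for non-nested comparison")
    delta_df = fit_full.df - fit_nested.df
    statistic = fit_nested.chi2 - fit_full.chi2
    if statistic < 0:
        warnings.warn("nested model fit better than full model "
                      "(Monte-Carlo noise); statistic clamped to 0")
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, delta_df)) if delta_df > 0 else float(
        statistic == 0.0)
    return float(statistic), delta_df, p


def parity_split(dataset: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic training/test partition by index parity.

    Odd-numbered trials from odd-numbered subjects and even-numbered
    trials from even-numbered subjects form the training half; the rest is
    the test half.  The two halves are disjoint and exhaustive, and the
    split is idempotent on its outputs.
    """
    for col in ("subject", "trial"):
        if col not in dataset.columns:
            raise ValueError(f"dataset lacks required column {col!r}")
    s = dataset["subject"].to_numpy().astype(int) % 2
    t = dataset["trial"].to_numpy().astype(int) % 2
    train = s == t
    return dataset.loc[train].copy(), dataset.loc[~train].copy()


# ---------------------------------------------------------------------------
# parameter transforms: optimizer works on an unconstrained scale

_POSITIVE = ("b", "g", "sigma", "s")
_UNIT = ("i_v", "i_d")
_TINY = 1e-12


def _to_unconstrained(params: ModelParams) -> np.ndarray:
    theta = []
    for name, value in zip(params.active, params.free_values()):
        if name in _POSITIVE:
            theta.append(np.log(max(value, _TINY)))
        elif name in _UNIT:
            v = np.clip(value, _TINY, 1 - _TINY)
            theta.append(np.log(v / (1 - v)))
        else:  # a >= 1
            theta.append(np.log(max(value - 1.0, _TINY)))
    return np.array(theta)


def _from_unconstrained(model_id: str, theta: np.ndarray) -> ModelParams:
    values = []
    for name, t in zip(ACTIVE_PARAMS[model_id], theta):
        if name in _POSITIVE:
            values.append(np.exp(t))
        elif name in _UNIT:
            values.append(1.0 / (1.0 + np.exp(-t)))
        else:
            values.append(1.0 + np.exp(t))
    return ModelParams.from_free_values(model_id, values)


#: structural parent used for incremental (nested-first) fitting; the
#: parents are the reliable four-parameter models (SNFI is nested in both
#: subtractive hybrids, DNFI in the divisive one)
NESTED_START_PARENTS = {"SCA": "SNFI", "SSCA": "SNFI", "DCA": "DNFI"}

#: neutral values for parameters a richer model adds over its parent
_PROMOTE_DEFAULTS = {"i_v": 0.3, "s": 5.0, "i_d": 0.01, "a": 1.05}


def _promote(parent: ModelParams, model_id: str) -> ModelParams:
    """Lift a nested model's fit into a richer model's parameter space."""
    values = {k: getattr(parent, k) for k in parent.active}
    for name in ACTIVE_PARAMS[model_id]:
        if name not in values:
            values[name] = _PROMOTE_DEFAULTS[name]
    return ModelParams(model_id, **{k: values[k]
                                    for k in ACTIVE_PARAMS[model_id]})


#: plausible natural-scale sampling ranges for randomized restarts
_START_RANGES = {
    "b": (0.05, 5.0, "log"),
    "g": (0.02, 8.0, "log"),
    "sigma": (0.5, 6.0, "log"),
    "i_v": (0.05, 0.95, "lin"),
    "s": (0.5, 20.0, "log"),
    "i_d": (0.002, 0.2, "log"),
    "a": (1.05, 2.5, "shiftlog"),
}


def _loguniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _random_start(model_id: str, rng: np.random.Generator) -> ModelParams:
    values = []
    for name in ACTIVE_PARAMS[model_id]:
        lo, hi, scale = _START_RANGES[name]
        u = rng.random()
        if scale == "lin":
            values.append(lo + u * (hi - lo))
        elif scale == "log":
            values.append(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        else:
            values.append(1.0 + np.exp(
                np.log(lo - 1.0) + u * (np.log(hi - 1.0) - np.log(lo - 1.0))))
    params = dict(zip(ACTIVE_PARAMS[model_id], values))
    if model_id in ("DNFI", "DCA"):
        # g, b and s are strongly coupled in the divisive drift
        # g(b+v)/(s+V); independent draws almost never yield workable
        # accumulation rates.  Sample the pre-onset drift g*b/s on a
        # plausible scale instead and solve for the gain.
        drift0 = _loguniform(rng, 0.05, 2.5)
        params["g"] = drift0 * params["s"] / params["b"]
    return ModelParams(model_id=model_id, **{
        k: params.get(k) for k in ("b", "g", "sigma", "i_v", "s", "i_d", "a")
        if k in params})


def fit_model(
    model_id: str,
    observed: QuantileTable,
    config: SimConfig,
    n_trials_per_vector: int = 2000,
    restarts: int = 20,
    maxiter: int = 400,
    probes: int | None = None,
    coarse_trials: int | None = None,
    simplex_step: float = 0.6,
    seed=None,
    init: ModelParams | None = None,
    nested_init: bool = False,
) -> FitResult:
    """Fit one model to a quantile summary by simplex minimization.

    Randomized seeding proceeds in stages: ``probes`` random parameter
    sets (default ``2 * restarts``; the caller's ``init`` joins them) are
    each evaluated once, and the ``restarts`` best become Nelder-Mead
    starting points.  Every restart fixes its own simulation seed so that
    objective evaluations within it share common random numbers, and runs
    on log/logit-transformed parameters with a deliberately wide initial
    simplex (``simplex_step`` on the unconstrained scale) to step over the
    Monte-Carlo ruggedness of the objective.  The winner is refined with a
    fresh narrower simplex (which lets the simplex re-expand after
    collapsing at convergence).

    If ``coarse_trials`` is given, probing and the restart runs simulate
    only that many trials per vector (cheap, noisier evaluations for
    global search); the refinement stage always uses the full
    ``n_trials_per_vector``, which defines the reported objective.

    ``nested_init=True`` fits the model's structural parent first (on the
    same summary, same budget) and promotes its parameters into one of the
    starting candidates — incremental nested fitting, which is how the
    hybrid models' narrow basins are found reliably.
    """
    if observed.n_vectors < 2:
        raise ValueError("need at least two input vectors to fit")
    pairs = np.asarray(observed.pairs, dtype=float)
    if probes is None:
        probes = 2 * restarts
    probes = max(probes, restarts)
    from .simulate import _as_seed_sequence
    ss = _as_seed_sequence(seed)
    if nested_init and init is None and model_id in NESTED_START_PARENTS:
        parent_fit = fit_model(
            NESTED_START_PARENTS[model_id], observed, config,
            n_trials_per_vector=n_trials_per_vector, restarts=restarts,
            maxiter=min(maxiter, 250), probes=probes,
            coarse_trials=coarse_trials, simplex_step=simplex_step,
            seed=ss.spawn(1)[0])
        init = _promote(parent_fit.params, model_id)
    start_rng = np.random.default_rng(ss.spawn(1)[0])
    probe_seeds = ss.spawn(probes)
    # selection decisions (probe ranking, restart winner) are made under
    # one shared stream so candidates are compared on equal footing;
    # search within a restart keeps its own common-random-number seed
    select_seed = ss.spawn(1)[0]
    refine_seed = ss.spawn(1)[0]
    n_coarse = coarse_trials or n_trials_per_vector

    def objective(theta: np.ndarray, sim_seed, n_sim: int) -> float:
        try:
            params = _from_unconstrained(model_id, theta)
        except (ValueError, OverflowError):
            return np.inf
        pair_idx, choice, rt, crossed = simulate_pairs(
            params, pairs, n_sim, config, sim_seed)
        predictor = EmpiricalPredictor(pairs, pair_idx, choice, rt, crossed)
        try:
            return chi2_statistic(observed, predictor)
        except ValueError:  # a vector with no responded predicted trials
            return np.inf

    n_free = len(ACTIVE_PARAMS[model_id])

    def run_simplex(theta0, sim_seed, n_sim, step, iters):
        simplex = np.vstack(
            [theta0] + [theta0 + step * np.eye(n_free)[i]
                        for i in range(n_free)])
        return optimize.minimize(
            objective, theta0, args=(sim_seed, n_sim), method="Nelder-Mead",
            options={"maxiter": iters, "xatol": 1e-3, "fatol": 1e-2,
                     "initial_simplex": simplex})

    candidates = []
    for r, rseed in enumerate(probe_seeds):
        if r == 0 and init is not None:
            start = init
        else:
            start = _random_start(model_id, start_rng)
        theta0 = _to_unconstrained(start)
        candidates.append((objective(theta0, select_seed, n_coarse), r,
                           theta0, rseed))
    candidates.sort(key=lambda c: c[0])
    selected = candidates[:restarts]
    if init is not None and all(c[1] != 0 for c in selected):
        # the caller's start is privileged information (e.g. a nested
        # model's fit); never let noisy probe ranking drop it
        selected[-1] = next(c for c in candidates if c[1] == 0)

    trace = []
    best = None
    for f0, r, theta0, rseed in selected:
        if not np.isfinite(f0):
            trace.append({"restart": r, "chi2": None,
                          "note": "non-finite objective at start"})
            continue
        res = run_simplex(theta0, rseed, n_coarse, simplex_step, maxiter)
        fitted = _from_unconstrained(model_id, res.x)
        # score the endpoint under the shared selection stream at full
        # resolution so restart winners are comparable
        score = objective(res.x, select_seed, n_trials_per_vector)
        trace.append({"restart": r, "start_chi2": float(f0),
                      "chi2": float(res.fun), "score": float(score),
                      "nfev": int(res.nfev), "n_sim": n_coarse,
                      "params": fitted.to_dict()})
        if best is None or score < best[0]:
            best = (score, fitted)
    if best is None:
        raise RuntimeError(
            f"all {probes} probed starts produced a non-finite objective; "
            "trace: " + repr(trace))

    # refinement at full resolution, then a final narrow-simplex polish;
    # refinement is local, so its iteration budget is capped
    theta = _to_unconstrained(best[1])
    chi2 = np.inf
    for step, iters in ((0.5 * simplex_step, min(maxiter, 150)),
                        (0.25 * simplex_step, min(maxiter // 2, 75) or 1)):
        res = run_simplex(theta, refine_seed, n_trials_per_vector, step,
                          iters)
        if res.fun <= chi2:
            chi2 = float(res.fun)
            theta = res.x
        trace.append({"restart": "refine", "chi2": float(res.fun),
                      "nfev": int(res.nfev), "n_sim": n_trials_per_vector})
    params = _from_unconstrained(model_id, theta)
    k = params.df
    aicc, bic = information_criteria(chi2, k, observed.n_bin_cells)
    return FitResult(params=params, chi2=chi2, df=k,
                     n_cells=observed.n_bin_cells, aicc=aicc, bic=bic,
                     seed=seed, n_trials_per_vector=n_trials_per_vector,
                     restarts=trace)
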
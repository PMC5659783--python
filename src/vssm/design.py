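"""Experiment designs, synthetic studies, and validation harnesses.

The design generator emulates the JC1 food-choice paradigm: a 4-level
value-rating scale, the 10 unordered value pairs, 720 trials per subject
with value differences (0-3) balanced first and pairs balanced within each
difference bin, the side of the greater value counterbalanced within each
pair, and no stimulus pair repeated on consecutive trials.  On top of it
sit three harnesses: full synthetic studies, parameter-recovery
experiments, and regeneration of the regression battery predicted by each
model at its bundled fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .models import ModelParams, SimConfig
from .simulate import _as_seed_sequence, simulate_dataset, simulate_pairs
from .analysis import (
    MIN_RT_MS,
    RegressionTable,
    classify,
    fit_accuracy,
    fit_rt,
)
from .reference import FITTED_PARAMS, REFERENCE_ROWS

__all__ = [
    "DesignSpec",
    "value_pairs",
    "make_design",
    "generate_study",
    "recovery_experiment",
    "run_battery",
    "reproduce_model_rows",
    "compare_to_reference",
]


@dataclass(frozen=True)
class DesignSpec:
    """A balanced two-alternative design over a discrete value scale."""

    levels: tuple[int, ...] = (1, 2, 3, 4)
    n_trials: int = 720
    n_subjects: int = 1
    balance: str = "difference"  # 'difference' (bins first) or 'pair'
    counterbalance_sides: bool = True
    no_immediate_repeat: bool = True

    def __post_init__(self) -> None:
        if len(set(self.levels)) < 2:
            raise ValueError("need at least two distinct value levels")
        if self.balance not in ("difference", "pair"):
            raise ValueError("balance must be 'difference' or 'pair'")
        if self.n_trials < len(list(value_pairs(self.levels))):
            raise ValueError("fewer trials than value pairs")


def value_pairs(levels=(1, 2, 3, 4)) -> list[tuple[int, int]]:
    """All unordered value pairs (with ties), sorted ascending."""
    return list(combinations_with_replacement(sorted(levels), 2))


def pair_counts(spec: DesignSpec) -> dict[tuple[int, int], int]:
    """Target repetition count per pair under the design's balancing rule.

    ``balance='difference'``: trials are split evenly over the value
    differences first, then evenly over the pairs within each difference
    bin.  ``balance='pair'``: split evenly over the 10 pairs directly.
    Remainders are spread deterministically over the smallest pairs.
    """
    pairs = value_pairs(spec.levels)

    def _spread(total: int, keys: list) -> dict:
        base, extra = divmod(total, len(keys))
        return {k: base + (i < extra) for i, k in enumerate(keys)}

    if spec.balance == "pair":
        return _spread(spec.n_trials, pairs)
    diffs = sorted({b - a for a, b in pairs})
    per_bin = _spread(spec.n_trials, diffs)
    counts: dict[tuple[int, int], int] = {}
    for d in diffs:
        members = [p for p in pairs if p[1] - p[0] == d]
        counts.update(_spread(per_bin[d], members))
    return counts


def make_design(spec: DesignSpec, seed=None) -> pd.DataFrame:
    """One subject's ordered trial list with side assignment.

    Within each unequal pair the greater value sits left on half of the
    repetitions (+/- 1).  The order is a seeded shuffle; when
    ``no_immediate_repeat`` is set, consecutive duplicates of the same
    stimulus pair are resolved by swapping with the next differing trial.
    """
    counts = pair_counts(spec)
    rows = []
    for (lo, hi), count in counts.items():
        if spec.counterbalance_sides and lo != hi:
            n_hi_left = count // 2
        else:
            n_hi_left = 0 if lo == hi else count // 2
        rows += [(hi, lo)] * n_hi_left + [(lo, hi)] * (count - n_hi_left)
    layout = np.array(rows, dtype=int)
    rng = np.random.default_rng(_as_seed_sequence(seed))
    order = rng.permutation(len(layout))
    layout = layout[order]
    if spec.no_immediate_repeat:
        pair_id = np.sort(layout, axis=1)
        i = 1
        while i < len(layout):
            if (pair_id[i] == pair_id[i - 1]).all():
                j = i + 1
                while j < len(layout) and (pair_id[j] == pair_id[i]).all():
                    j += 1
                if j == len(layout):
                    break  # tail of identical pairs; best effort
                layout[[i, j]] = layout[[j, i]]
                pair_id[[i, j]] = pair_id[[j, i]]
            i += 1
    df = pd.DataFrame(layout, columns=["v_left", "v_right"])
    df["pair_lo"] = df[["v_left", "v_right"]].min(axis=1)
    df["pair_hi"] = df[["v_left", "v_right"]].max(axis=1)
    return df


def generate_study(
    params: ModelParams,
    spec: DesignSpec,
    config: SimConfig | None = None,
    seed=None,
) -> pd.DataFrame:
    """A full synthetic study: per-subject designs simulated under a model.

    Suitable input for the parity split, fitting and the regression
    battery.  Provenance (model fingerprint, seed) lives in ``df.attrs``.
    """
    config = config or SimConfig()
    ss = _as_seed_sequence(seed)
    children = ss.spawn(2 * spec.n_subjects)
    frames = []
    for s in range(1, spec.n_subjects + 1):
        design = make_design(spec, children[2 * (s - 1)])
        df = simulate_dataset(params, design, config,
                              seed=children[2 * s - 1], subject=s)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs = dict(frames[0].attrs)
    out.attrs["seed"] = repr(seed)
    return out


def run_battery(
    params: ModelParams,
    seed=None,
    trials_per_vector: int = 20000,
    config: SimConfig | None = None,
    levels=(1, 2, 3, 4),
    min_rt_ms: int = MIN_RT_MS,
) -> dict[str, RegressionTable]:
    """Simulate a model and run the full choice/RT regression battery.

    Simulates ``trials_per_vector`` trials for each unordered value pair,
    applies the contaminant cutoff, classifies trials, and fits the
    complementary accuracy and RT regressions.  Keys of the result:
    ``accuracy_gl``, ``accuracy_ds``, ``rt_correct_gl``, ``rt_correct_ds``,
    ``rt_incorrect_gl``, ``rt_incorrect_ds``, ``rt_indifferent``.
    """
    config = config or SimConfig()
    pairs = np.array(value_pairs(levels), dtype=float)
    pair_idx, choice, rt, crossed = simulate_pairs(
        params, pairs, trials_per_vector, config, seed)
    v = pairs[pair_idx]
    # columns are (lo, hi); choice==1 means the greater value was chosen.
    # The models are exchangeable in their alternatives, so the left/right
    # presentation side is immaterial; record alternative 0 as "left".
    df = pd.DataFrame({
        "subject": 1,
        "trial": np.arange(1, len(v) + 1),
        "v_left": v[:, 0].astype(int),
        "v_right": v[:, 1].astype(int),
        "choice": np.where(crossed, np.where(choice == 0, "L", "R"), "NONE"),
        "rt_ms": rt,
    })
    classified = classify(df, min_rt_ms=min_rt_ms, levels=levels)
    acc_gl, acc_ds = fit_accuracy(classified)
    rtc_gl, rtc_ds = fit_rt(classified, "correct")
    rti_gl, rti_ds = fit_rt(classified, "incorrect")
    rt_ind = fit_rt(classified, "indifferent")
    return {
        "accuracy_gl": acc_gl, "accuracy_ds": acc_ds,
        "rt_correct_gl": rtc_gl, "rt_correct_ds": rtc_ds,
        "rt_incorrect_gl": rti_gl, "rt_incorrect_ds": rti_ds,
        "rt_indifferent": rt_ind,
    }


_TABLE_KEYS = {
    "accuracy": (("accuracy_gl", False), ("accuracy_ds", False)),
    "rt_correct": (("rt_correct_gl", True), ("rt_correct_ds", True)),
    "rt_incorrect": (("rt_incorrect_gl", True), ("rt_incorrect_ds", True)),
    "rt_indifferent": (("rt_indifferent", True),),
}


def compare_to_reference(model_id: str,
                         battery: dict[str, RegressionTable]) -> pd.DataFrame:
    """Side-by-side comparison of a battery against the frozen reference.

    One row per (outcome, term) with the recomputed estimate, the
    reference estimate and SE, and their discrepancy in reference-SE
    units.
    """
    ref = REFERENCE_ROWS[model_id]
    records = []
    for outcome, sources in _TABLE_KEYS.items():
        for term, (ref_est, ref_se) in ref[outcome].items():
            for key, normalized in sources:
                table = battery[key]
                if term not in table.terms:
                    continue
                norm = normalized and term != "const"
                est, se = table.coef(term, normalized=norm)
                records.append({
                    "outcome": outcome, "term": term,
                    "est": est, "se": se,
                    "ref_est": ref_est, "ref_se": ref_se,
                    "diff": est - ref_est,
                    "diff_in_ref_se": (est - ref_est) / ref_se,
                })
                break
    return pd.DataFrame.from_records(records)


def reproduce_model_rows(
    model_id: str,
    params: ModelParams | None = None,
    seed=None,
    trials_per_vector: int = 20000,
    config: SimConfig | None = None,
) -> tuple[dict[str, RegressionTable], pd.DataFrame]:
    """Regenerate a model's predicted regression battery and compare it.

    Runs :func:`run_battery` for ``model_id`` (at its bundled fitted
    parameters unless ``params`` is given) and returns the battery together
    with the comparison against the frozen reference coefficients.
    """
    params = params or FITTED_PARAMS[model_id]
    if params.model_id != model_id:
        raise ValueError("params.model_id does not match model_id")
    battery = run_battery(params, seed=seed,
                          trials_per_vector=trials_per_vector, config=config)
    return battery, compare_to_reference(model_id, battery)


def recovery_experiment(
    true_params: ModelParams,
    n_replicates: int = 10,
    seed=None,
    n_trials_per_vector: int = 2000,
    config: SimConfig | None = None,
    levels=(1, 2, 3, 4),
    **fit_kwargs,
) -> pd.DataFrame:
    """Generate-and-refit validation of the fitting machinery.

    Each replicate simulates a dataset from ``true_params``
    (``n_trials_per_vector`` per value pair), fits the same model to its
    quantile summary, and records the signed relative error of every
    recovered parameter.  Returns one row per (replicate, parameter).
    """
    from .fitting import fit_model, summarize_arrays

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if true_params.sigma == 0:
        raise ValueError("zero-noise input is unfittable (sigma boundary)")
    config = config or SimConfig()
    pairs = np.array(value_pairs(levels), dtype=float)
    ss = _as_seed_sequence(seed)
    records = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        data_seed, fit_seed = child.spawn(2)
        pair_idx, choice, rt, crossed = simulate_pairs(
            true_params, pairs, n_trials_per_vector, config, data_seed)
        observed = summarize_arrays(pairs, pair_idx, choice, rt, crossed)
        result = fit_model(true_params.model_id, observed, config,
                           n_trials_per_vector=n_trials_per_vector,
                           seed=fit_seed, **fit_kwargs)
        for name in true_params.active:
            truth = getattr(true_params, name)
            got = getattr(result.params, name)
            records.append({
                "replicate": rep, "parameter": name,
                "true": truth, "fitted": got,
                "rel_error": (got - truth) / truth,
            })
    return pd.DataFrame.from_records(records)
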
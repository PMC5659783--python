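"""First-passage simulation of the accumulator models.

Trials run the shared recurrence until the first decision signal reaches
the threshold ``D``; the post-update time of that step is the reaction
time.  Baseline input and noise act from t = 0, so starting-point
variability emerges during the predecision phase before value onset.
Trials that never cross within the response window are flagged and carry
no choice.

All randomness flows from a single seed through `numpy.random.SeedSequence`
children, one independent stream per simulation batch (design cell or
subject), so results are reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    ModelParams,
    SimConfig,
    STATE_DEPENDENT,
    state_free_drift,
    value_transform,
)

__all__ = [
    "TrialResult",
    "simulate_trial",
    "simulate_trials",
    "simulate_pairs",
    "simulate_dataset",
]


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept an int, None, or an existing SeedSequence child."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of a single simulated trial."""

    choice: int | None  # index of the winning alternative, None if no cross
    rt_ms: int | None
    crossed: bool


def simulate_trials(
    params: ModelParams,
    values: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate many trials in lockstep.

    Parameters
    ----------
    values
        Array of shape ``(m, n_alternatives)`` of latent option values,
        one row per trial.
    rng
        The noise stream; also used for uniform tie-breaking when several
        signals cross on the same step.

    Returns
    -------
    choice, rt_ms, crossed
        ``choice[i]`` is the winning alternative's column index (-1 if the
        trial never crossed), ``rt_ms[i]`` the crossing time in ms (0 if
        none), ``crossed[i]`` a boolean flag.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m, n = values.shape
    if n != config.n_alternatives:
        raise ValueError("values width must equal n_alternatives")
    D = config.threshold_D
    dt = config.dt_ms
    n_steps = config.t_max_ms // dt
    onset_step = config.T0_ms // dt

    v_on = value_transform(params, values)
    inc_off = state_free_drift(params, np.zeros_like(values))
    inc_on = state_free_drift(params, v_on)
    state_dep = params.model_id in STATE_DEPENDENT
    i_d = params.i_d if state_dep else 0.0
    sigma = params.sigma

    d = np.zeros((m, n))
    alive = np.arange(m)
    choice = np.full(m, -1, dtype=np.int64)
    rt = np.zeros(m, dtype=np.int64)

    for k in range(n_steps):
        base = inc_on if k >= onset_step else inc_off
        da = d[alive]
        inc = base[alive]
        if state_dep:
            inc = inc - i_d * (da.sum(axis=1, keepdims=True) - da)
        if sigma > 0:
            noise = sigma * rng.standard_normal((alive.size, n))
            da = np.maximum(0.0, da + inc + noise)
        else:
            da = np.maximum(0.0, da + inc)
        d[alive] = da
        hit = da >= D
        done = hit.any(axis=1)
        if done.any():
            rows = alive[done]
            h = hit[done]
            # uniform tie-break among simultaneous crossers
            r = rng.random(h.shape)
            choice[rows] = np.argmax(np.where(h, r, -1.0), axis=1)
            rt[rows] = (k + 1) * dt
            alive = alive[~done]
            if alive.size == 0:
                break
    return choice, rt, rt > 0


def simulate_trial(
    params: ModelParams,
    values: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> TrialResult:
    """Run one trial to threshold crossing (or to the response deadline)."""
    choice, rt, crossed = simulate_trials(params, np.atleast_2d(values),
                                          config, rng)
    if crossed[0]:
        return TrialResult(int(choice[0]), int(rt[0]), True)
    return TrialResult(None, None, False)


def simulate_pairs(
    params: ModelParams,
    pairs: np.ndarray,
    n_per_pair: int,
    config: SimConfig,
    seed,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n_per_pair`` trials for each row of ``pairs``.

    Lightweight array interface used by the fitting objective and the
    battery reproductions.  Returns ``(pair_idx, choice, rt_ms, crossed)``.
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    k = pairs.shape[0]
    values = np.repeat(pairs, n_per_pair, axis=0)
    pair_idx = np.repeat(np.arange(k), n_per_pair)
    rng = np.random.default_rng(_as_seed_sequence(seed))
    choice, rt, crossed = simulate_trials(params, values, config, rng)
    return pair_idx, choice, rt, crossed


def _params_fingerprint(params: ModelParams) -> str:
    items = [f"{k}={getattr(params, k)!r}" for k in params.active]
    return f"{params.model_id}({', '.join(items)})"


def simulate_dataset(
    params: ModelParams,
    design,
    config: SimConfig,
    seed=None,
    subject: int = 1,
) -> pd.DataFrame:
    """Simulate a behavioral dataset over an experiment design.

    Parameters
    ----------
    design
        Either a list of ``(values, count)`` cells — in which case the
        left/right assignment of each unordered pair is counterbalanced
        across its repetitions — or a DataFrame with ``v_left``/``v_right``
        columns giving the explicit per-trial layout (e.g. from
        :func:`vssm.design.make_design`).
    seed
        Master seed; each design cell gets an independent child stream.

    Returns
    -------
    DataFrame with columns ``subject, trial, v_left, v_right, choice,
    rt_ms`` where ``choice`` is ``"L"``, ``"R"`` or ``"NONE"`` and
    ``rt_ms`` is 0 for non-crossing trials.  Provenance (model, parameter
    fingerprint, seed) is stored in ``df.attrs``.
    """
    ss = _as_seed_sequence(seed)
    if isinstance(design, pd.DataFrame):
        layout = np.atleast_2d(design[["v_left", "v_right"]]
                               .to_numpy(dtype=float))
        rng = np.random.default_rng(ss.spawn(1)[0])
        choice, rt, crossed = simulate_trials(params, layout, config, rng)
    else:
        design = list(design)
        blocks, parts = [], []
        children = ss.spawn(len(design))
        for (values, count), child in zip(design, children):
            a, b = (float(values[0]), float(values[1]))
            n_first = (count + 1) // 2  # first orientation gets the odd one
            block = np.concatenate(
                [np.tile([a, b], (n_first, 1)),
                 np.tile([b, a], (count - n_first, 1))], axis=0)
            blocks.append(block)
            rng = np.random.default_rng(child)
            parts.append(simulate_trials(params, block, config, rng))
        layout = np.concatenate(blocks, axis=0)
        choice = np.concatenate([p[0] for p in parts])
        rt = np.concatenate([p[1] for p in parts])
        crossed = np.concatenate([p[2] for p in parts])
    side = np.where(crossed, np.where(choice == 0, "L", "R"), "NONE")
    df = pd.DataFrame(
        {
            "subject": subject,
            "trial": np.arange(1, layout.shape[0] + 1),
            "v_left": layout[:, 0].astype(int),
            "v_right": layout[:, 1].astype(int),
            "choice": side,
            "rt_ms": rt,
        }
    )
    df.attrs["provenance"] = "simulated"
    df.attrs["model"] = _params_fingerprint(params)
    df.attrs["seed"] = repr(seed)
    return df
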
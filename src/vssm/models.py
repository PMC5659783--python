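"""Core model family for value-based binary choice.

Eight nested connectionist accumulator models share one discrete-time
recurrence for the decision signal of each alternative ``x``::

    d_x(t + dt) = max{0, d_x(t) + f_x(t) + N(0, sigma^2)}

where ``f_x`` is a model-specific drift term built from a baseline input
``b``, an input gain ``g``, and optional competition terms, and the max
operator rectifies negative activity.  The value signal feeding the drift is
a step function: zero before the predecision time ``T0`` and the latent
option value afterwards (raised to a power ``a`` in the SSCA model).
Accumulation is perfect (no leak): self-excitation and leakage are assumed
balanced.  The first decision signal to reach the threshold ``D`` defines
the choice and the reaction time.

The family, ordered by complexity:

========  ==  ===========================================================
model     df  drift term f_x (two alternatives; y is the other one)
========  ==  ===========================================================
RACE       3  b + g*v_x
NDD        3  b + g*(v_x - v_y)                  (perfect subtraction)
SNFI       4  b + g*(v_x - i_v*v_y)              (imperfect subtraction)
DNFI       4  g*(b + v_x)/(s + v_x + v_y)        (divisive normalization)
CA         4  b + g*v_x - i_d*d_y                (lateral inhibition)
SCA        5  SNFI drift - i_d*d_y
DCA        5  DNFI drift - i_d*d_y
SSCA       6  SCA drift with v_x = V_x**a        (attentional power law)
========  ==  ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "MODEL_IDS",
    "ACTIVE_PARAMS",
    "STATE_DEPENDENT",
    "NESTED_WITHIN",
    "ModelParams",
    "SimConfig",
    "DecisionState",
    "value_transform",
    "value_signal",
    "drift_increment",
    "update_state",
]

MODEL_IDS: tuple[str, ...] = (
    "RACE", "NDD", "SNFI", "DNFI", "CA", "SCA", "DCA", "SSCA",
)

#: free parameters each model activates (defines its degrees of freedom)
ACTIVE_PARAMS: dict[str, tuple[str, ...]] = {
    "RACE": ("b", "g", "sigma"),
    "NDD": ("b", "g", "sigma"),
    "SNFI": ("b", "g", "sigma", "i_v"),
    "DNFI": ("b", "g", "sigma", "s"),
    "CA": ("b", "g", "sigma", "i_d"),
    "SCA": ("b", "g", "sigma", "i_v", "i_d"),
    "DCA": ("b", "g", "sigma", "s", "i_d"),
    "SSCA": ("b", "g", "sigma", "i_v", "i_d", "a"),
}

#: models whose drift depends on the other accumulators' current state
STATE_DEPENDENT: frozenset[str] = frozenset({"CA", "SCA", "DCA", "SSCA"})

#: exact nesting relations (nested -> parents), closed under transitivity.
#: Only *exact* reductions are listed; e.g. RACE is only effectively nested
#: in DNFI (s >> sum of values), which does not qualify.
NESTED_WITHIN: dict[str, frozenset[str]] = {
    "RACE": frozenset({"SNFI", "CA", "SCA", "SSCA"}),
    "NDD": frozenset({"SNFI", "SCA", "SSCA"}),
    "SNFI": frozenset({"SCA", "SSCA"}),
    "DNFI": frozenset({"DCA"}),
    "CA": frozenset({"SCA", "DCA", "SSCA"}),
    "SCA": frozenset({"SSCA"}),
    "DCA": frozenset(),
    "SSCA": frozenset(),
}


@dataclass(frozen=True)
class ModelParams:
    """A parameter set for one model of the family.

    Only the parameters active for ``model_id`` may be set; inactive ones
    must remain ``None``.  ``b``, ``g`` and ``sigma`` are shared by every
    model.  Units: ``b`` and ``sigma`` are activation units per step,
    ``g`` converts value units to activation units per step, ``i_v`` and
    ``i_d`` are dimensionless inhibition weights in [0, 1], ``s`` is a
    semisaturation constant in value units, and ``a >= 1`` is the
    dimensionless attentional exponent.
    """

    model_id: str
    b: float
    g: float
    sigma: float
    i_v: float | None = None
    s: float | None = None
    i_d: float | None = None
    a: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for name in ("b", "g", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        active = set(ACTIVE_PARAMS[self.model_id])
        for name in ("i_v", "s", "i_d", "a"):
            value = getattr(self, name)
            if name in active:
                if value is None:
                    raise ValueError(
                        f"{self.model_id} requires parameter {name}")
            elif value is not None:
                raise ValueError(
                    f"{name} is not a free parameter of {self.model_id}")
        if self.i_v is not None and not 0.0 <= self.i_v <= 1.0:
            raise ValueError("i_v must lie in [0, 1]")
        if self.i_d is not None and not 0.0 <= self.i_d <= 1.0:
            raise ValueError("i_d must lie in [0, 1]")
        if self.s is not None and self.s <= 0:
            raise ValueError("s must be positive")
        if self.a is not None and self.a < 1.0:
            raise ValueError("a must be >= 1")

    @property
    def active(self) -> tuple[str, ...]:
        """Names of this model's free parameters."""
        return ACTIVE_PARAMS[self.model_id]

    @property
    def df(self) -> int:
        """Degrees of freedom (number of free parameters)."""
        return len(self.active)

    def free_values(self) -> np.ndarray:
        """Active parameter values, in :attr:`active` order."""
        return np.array([getattr(self, k) for k in self.active], dtype=float)

    @classmethod
    def from_free_values(cls, model_id: str,
                         values: Iterable[float]) -> "ModelParams":
        names = ACTIVE_PARAMS[model_id]
        values = list(values)
        if len(values) != len(names):
            raise ValueError(
                f"{model_id} expects {len(names)} values, got {len(values)}")
        return cls(model_id=model_id, **dict(zip(names, map(float, values))))

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        d["active"] = list(self.active)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = {k: v for k, v in d.items() if k != "active"}
        return cls(**d)


@dataclass(frozen=True)
class SimConfig:
    """Fixed simulation constants.

    The threshold ``D`` is an arbitrary scaling constant (100, read as
    "percent of threshold"); the step is 10 ms; value signals switch on at
    ``T0_ms`` = 150 ms; trials that have not terminated by ``t_max_ms``
    (the 3-s response window) are flagged as non-crossing.  ``sigma`` is
    defined per 10-ms step, so simulations at another ``dt_ms`` are
    off-label unless the noise is rescaled by sqrt(dt/10 ms).
    """

    threshold_D: float = 100.0
    dt_ms: int = 10
    T0_ms: int = 150
    t_max_ms: int = 3000
    n_alternatives: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.threshold_D <= 0:
            raise ValueError("threshold_D must be positive")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if not 0 <= self.T0_ms < self.t_max_ms:
            raise ValueError("require 0 <= T0_ms < t_max_ms")
        if self.T0_ms % self.dt_ms:
            raise ValueError("T0_ms must be a multiple of dt_ms")
        if self.n_alternatives < 2:
            raise ValueError("need at least two alternatives")


@dataclass
class DecisionState:
    """Decision-signal activations (one per alternative) at time ``t_ms``."""

    d: np.ndarray
    t_ms: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("decision signals are rectified: d >= 0")


def value_transform(params: ModelParams, values: np.ndarray) -> np.ndarray:
    """Post-onset value signal for latent values ``V``.

    Identity for every model except SSCA, whose supralinear power law
    ``V**a`` statically approximates value-dependent attentional
    amplification.
    """
    values = np.asarray(values, dtype=float)
    if params.model_id == "SSCA":
        return values ** params.a
    return values


def value_signal(values: np.ndarray, t_ms: float, params: ModelParams,
                 config: SimConfig) -> np.ndarray:
    """Value signal v(t): zero before onset at ``T0``, stepped-on after."""
    if t_ms < 0:
        raise ValueError("t_ms must be nonnegative")
    out = value_transform(params, values)
    if t_ms < config.T0_ms:
        return np.zeros_like(out)
    return out


def state_free_drift(params: ModelParams, v: np.ndarray) -> np.ndarray:
    """The part of the drift that does not depend on the decision state.

    ``v`` holds the current (already transformed) value signals with the
    alternatives on the last axis.
    """
    v = np.asarray(v, dtype=float)
    n = v.shape[-1]
    total = v.sum(axis=-1, keepdims=True)
    others = total - v
    m = params.model_id
    if m == "RACE" or m == "CA":
        return params.b + params.g * v
    if m == "NDD":
        return params.b + params.g * (v - others / (n - 1))
    if m in ("SNFI", "SCA", "SSCA"):
        return params.b + params.g * (v - params.i_v * others)
    if m in ("DNFI", "DCA"):
        # the divisive pool sums over *all* alternatives, including x
        return params.g * (params.b + v) / (params.s + total)
    raise ValueError(f"unknown model_id {m!r}")


def drift_increment(params: ModelParams, v: np.ndarray,
                    d: np.ndarray) -> np.ndarray:
    """Deterministic per-step increment f_x(t) (noise excluded).

    ``v`` and ``d`` broadcast against each other with alternatives on the
    last axis; ``d`` must be nonnegative (rectified state).
    """
    v = np.asarray(v, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("decision state must be nonnegative")
    base = state_free_drift(params, v)
    if params.model_id in STATE_DEPENDENT:
        others_d = d.sum(axis=-1, keepdims=True) - d
        return base - params.i_d * others_d
    shape = np.broadcast_shapes(v.shape, d.shape)
    return np.broadcast_to(base, shape).copy()


def update_state(state: DecisionState, increment: np.ndarray,
                 noise_draw: np.ndarray, dt_ms: int = 10) -> DecisionState:
    """One rectified stochastic update of the recurrence."""
    d_new = np.maximum(0.0, state.d + increment + noise_draw)
    return DecisionState(d=d_new, t_ms=state.t_ms + dt_ms)
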
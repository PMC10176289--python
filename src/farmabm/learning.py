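"""Event-triggered learning: adaptation types and the alpha functions.

Every extreme event persistently increases a farmer's willingness to adapt.
The willingness of adaptation type ``i`` after ``x`` cumulative regional
events is

    alpha_i(x) = (x / 37) ** z_i,

capped at 1.  The exponent ``z_i`` expresses inertia towards change: the
larger it is, the slower willingness grows.  Types are mapped from farming
styles — innovative farmers react most readily (type 1), both optimizer
styles share a lighter response (type 2), idealists react weakly (type 3)
and traditionalists barely at all (type 4).  ``alpha`` reaches its maximum
of 1 only if an event occurred in every one of the 37 simulated years.

``alpha`` scales the likelihood of the four adaptive actions —
extensification, organic conversion, land-use change and expansion — by
``(1 + alpha)``, so at ``alpha = 1`` their weight doubles before the action
vector is renormalized to a proper probability distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ADAPTIVE_ACTIONS, N_ACTIONS, STYLES

#: event count at which alpha saturates at 1 (one event in every model year)
ALPHA_DENOMINATOR = 37


@dataclass
class AdaptationParams:
    """Inertia exponents per adaptation type and the style -> type mapping.

    The exact exponents are free parameters; the defaults (1, 2, 4, 8)
    reproduce the intended qualitative spread — near-linear growth for
    type 1 and strongly convex, late-onset growth for type 4 — while
    keeping the required strict ordering ``z_1 < z_2 < z_3 < z_4``.
    """

    type_exponents: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 2.0, 3: 4.0, 4: 8.0}
    )
    style_map: dict[str, int] = field(
        default_factory=lambda: {
            "innovative": 1,
            "yield_optimizer": 2,
            "support_optimizer": 2,
            "idealist": 3,
            "traditionalist": 4,
        }
    )

    def __post_init__(self) -> None:
        zs = [self.type_exponents[i] for i in sorted(self.type_exponents)]
        if sorted(self.type_exponents) != [1, 2, 3, 4]:
            raise ValueError("type_exponents must cover types 1..4")
        if any(z <= 0 for z in zs):
            raise ValueError("inertia exponents must be positive")
        if any(a >= b for a, b in zip(zs, zs[1:])):
            raise ValueError("inertia exponents must be strictly increasing")
        if set(self.style_map) != set(STYLES):
            raise ValueError("style_map must cover all farming styles")

    def style_code_types(self) -> np.ndarray:
        """Adaptation type per style code (aligned with ``STYLES``)."""
        return np.array([self.style_map[s] for s in STYLES], dtype=np.int8)


def alpha(x: int | float, z: float) -> float:
    """Willingness to adapt after ``x`` cumulative extreme events.

    Returns ``min(1, (x / 37) ** z)``; 0 at ``x = 0`` and exactly 1 at
    ``x = 37`` for every exponent.
    """
    if x < 0:
        raise ValueError(f"event count must be >= 0, got {x}")
    if z <= 0:
        raise ValueError(f"inertia exponent must be positive, got {z}")
    return min(1.0, (x / ALPHA_DENOMINATOR) ** z)


def alpha_by_type(x: int, params: AdaptationParams) -> dict[int, float]:
    """``alpha_i(x)`` for all four adaptation types."""
    return {i: alpha(x, z) for i, z in params.type_exponents.items()}


@dataclass
class AdaptationState:
    """Cumulative regional event count and the per-type willingness values."""

    x: int = 0
    params: AdaptationParams = field(default_factory=AdaptationParams)

    @property
    def alpha_by_type(self) -> dict[int, float]:
        return alpha_by_type(self.x, self.params)

    def record_event(self) -> None:
        self.x += 1


def boosted_weights(base: np.ndarray, a: float) -> np.ndarray:
    """Pre-normalization action weights: adaptive entries scaled by (1 + alpha)."""
    if base.shape != (N_ACTIONS,):
        raise ValueError(f"action vector must have length {N_ACTIONS}")
    if np.any(base < 0):
        raise ValueError("action weights must be nonnegative")
    out = base.astype(float).copy()
    out[list(ADAPTIVE_ACTIONS)] *= 1.0 + a
    return out


def adapt_likelihoods(base: np.ndarray, a: float) -> np.ndarray:
    """Apply the learning boost to an action probability vector.

    The four adaptive actions are scaled by ``(1 + alpha)`` and the vector
    is renormalized to sum to 1.  Zeros are preserved, and the relative
    odds within the adaptive set and within the non-adaptive set are
    unchanged.
    """
    base = np.asarray(base, dtype=float)
    total = base.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"action vector must sum to 1, got {total}")
    if a == 0.0:
        return base.copy()  # exact identity at zero willingness
    out = boosted_weights(base, a)
    return out / out.sum()
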
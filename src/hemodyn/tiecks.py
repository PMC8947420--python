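"""Second-order autoregulation model of Tiecks et al. and its grade table.

The model maps a normalized arterial-pressure deviation ``dP`` to a cerebral
blood-flow-velocity fraction through two coupled first-order state
recursions.  Ten canonical parameter triples (time constant T, damping D,
gain K) define autoregulation grades 0 (absent) through 9 (best); matching a
measured step response against the ten template responses yields the
autoregulation index (ARI).

The state recursion, at sampling rate ``f = 1/dt``::

    dP(n) = (P(n) - P_base) / (P_base - CCP)
    x1(n) = x1(n-1) + (dP(n) - x2(n-1)) / (f * T)
    x2(n) = x2(n-1) + (x1(n) - 2 * D * x2(n-1)) / (f * T)
    v(n)  = V_base * (1 + dP(n) - K * x2(n))

``CCP`` is the critical closing pressure below which flow ceases; it is
configurable (default 12 mmHg, a mid-range value in the ARI literature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError, StabilityError

#: default critical closing pressure in mmHg
DEFAULT_CCP_MMHG = 12.0

# Grade -> (T [s], D [-], K [-]) from the original Tiecks formulation
# (transcribed from the 1995 thigh-cuff comparison study, Table 2 therein).
TIECKS_TABLE: dict[int, tuple[float, float, float]] = {
    0: (2.00, 0.00, 0.00),
    1: (2.00, 1.60, 0.20),
    2: (2.00, 1.50, 0.40),
    3: (2.00, 1.15, 0.60),
    4: (2.00, 0.90, 0.80),
    5: (1.90, 0.75, 0.90),
    6: (1.60, 0.65, 0.94),
    7: (1.20, 0.55, 0.96),
    8: (0.87, 0.52, 0.97),
    9: (0.65, 0.50, 0.98),
}

GRADES = tuple(sorted(TIECKS_TABLE))


@dataclass(frozen=True)
class TiecksParams:
    """Parameter triple of one autoregulation grade."""

    T: float
    D: float
    K: float
    grade: int | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise StabilityError(f"time constant must be positive, got T={self.T}")
        if not (0.0 <= self.K <= 1.0):
            raise InvalidSpecError(f"gain K must lie in [0, 1], got {self.K}")
        if self.D < 0:
            raise InvalidSpecError(f"damping must be non-negative, got {self.D}")
        if self.grade is not None and self.grade not in TIECKS_TABLE:
            raise InvalidSpecError(f"grade must be in 0..9, got {self.grade}")


def params_for_grade(grade: int) -> TiecksParams:
    """Canonical (T, D, K) for an integer autoregulation grade 0-9."""
    if grade not in TIECKS_TABLE:
        raise InvalidSpecError(f"autoregulation grade must be in 0..9, got {grade}")
    T, D, K = TIECKS_TABLE[grade]
    return TiecksParams(T=T, D=D, K=K, grade=grade)


def pressure_deviation(
    bp: np.ndarray, baseline: float, ccp: float = DEFAULT_CCP_MMHG
) -> np.ndarray:
    """Normalized pressure deviation dP relative to baseline and CCP."""
    if baseline <= ccp:
        raise InvalidSpecError(
            f"baseline pressure {baseline} must exceed critical closing pressure {ccp}"
        )
    return (np.asarray(bp, dtype=float) - baseline) / (baseline - ccp)


def flow_fraction(dp: np.ndarray, params: TiecksParams, dt: float) -> np.ndarray:
    """Run the two-state recursion on a normalized pressure deviation.

    Returns ``v / V_base``, i.e. flow as a fraction of its baseline.  The
    forward-Euler discretization requires ``dt < T``.
    """
    if dt <= 0:
        raise StabilityError(f"sampling interval must be positive, got {dt}")
    if dt >= params.T:
        raise StabilityError(
            f"sampling interval {dt} s is too coarse for time constant {params.T} s"
        )
    dp = np.asarray(dp, dtype=float)
    fT = params.T / dt  # = f * T
    x1 = 0.0
    x2 = 0.0
    out = np.empty(dp.size)
    two_d = 2.0 * params.D
    k = params.K
    for i in range(dp.size):
        x1 = x1 + (dp[i] - x2) / fT
        x2 = x2 + (x1 - two_d * x2) / fT
        out[i] = 1.0 + dp[i] - k * x2
    return out
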
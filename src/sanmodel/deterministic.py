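"""Deterministic (expected-value) SAN model.

Averaged over many independent lineages the SAN dynamics become linear ODEs
for the expected numbers of S-, A- and N-cells::

    ds/dt = (r_SS - r_del - r_SA - r_SN) * s
    da/dt = r_SA * s - r_AN * a
    dn/dt = r_SN * s + (r_AAN + r_AN) * a

Within each constant-rate interval this is a lower-triangular linear system
whose exact solution is the matrix exponential of the 3x3 generator; the
solver below chains these closed-form propagators across intervals, so the
result is exact up to floating point (no time stepping).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .rates import RateInterval, RateSchedule


@dataclass(frozen=True)
class DeterministicState:
    """Expected (s, a, n) cell counts at day t."""

    s: float
    a: float
    n: float
    t: float

    @property
    def total(self) -> float:
        return self.s + self.a + self.n


def total_organoid_size(state: DeterministicState) -> float:
    """Total expected cell count s + a + n."""
    return state.total


def _generator(iv: RateInterval) -> np.ndarray:
    g = iv.s_ss - iv.s_del - iv.s_a - iv.s_n
    return np.array(
        [
            [g, 0.0, 0.0],
            [iv.s_a, -iv.a_n, 0.0],
            [iv.s_n, iv.a_an + iv.a_n, 0.0],
        ]
    )


def solve_deterministic(
    schedule: RateSchedule,
    s0: float,
    query_times: Sequence[float],
    a0: float = 0.0,
    n0: float = 0.0,
) -> list[DeterministicState]:
    """Expected (s, a, n) at each query time under the given schedule.

    Starts from (s0, a0, n0) at day 0; the solution is continuous across
    interval boundaries.  Query times must lie inside the schedule coverage
    but need not be sorted.
    """
    if s0 < 0 or a0 < 0 or n0 < 0:
        raise ValueError("initial counts must be non-negative")
    times = np.asarray(query_times, dtype=float)
    if times.size and (times.min() < 0.0 or times.max() > schedule.t_end):
        raise ValueError(
            f"query times must lie in [0, {schedule.t_end}]"
        )

    # propagate interval by interval, caching the state at each boundary
    boundary_states = [np.array([s0, a0, n0])]
    for iv in schedule.intervals:
        M = _generator(iv)
        boundary_states.append(expm(M * (iv.t_end - iv.t_start)) @ boundary_states[-1])

    out: list[DeterministicState] = []
    for t in times:
        iv = schedule.interval_at(float(t))
        idx = schedule.intervals.index(iv)
        x = expm(_generator(iv) * (t - iv.t_start)) @ boundary_states[idx]
        # clip tiny negative round-off
        x = np.maximum(x, 0.0)
        out.append(DeterministicState(s=x[0], a=x[1], n=x[2], t=float(t)))
    return out


def lineage_removal_probability(schedule: RateSchedule, t: float) -> float:
    """Probability that a single founder S-cell lineage is empty by day t.

    Valid while no division occurs: the founder cell either gets removed
    (rate ``s_del``, emptying the lineage) or converts to a persistent
    non-dividing cell (``s_n``) or A-cell (``s_a``).  Competing-risks gives

        P(removed by t) = sum over intervals of the removal hazard share.

    Raises if any division rate (``s_ss`` or ``a_an``) is non-zero before t,
    because with division the lineage-extinction problem is no longer a
    single-cell competing-risks problem.
    """
    if t < 0 or t > schedule.t_end:
        raise ValueError("t outside schedule coverage")
    p_removed = 0.0
    surv_in_s = 1.0  # probability the founder is still an undecided S-cell
    for iv in schedule.intervals:
        if iv.t_start >= t:
            break
        if iv.s_ss > 0 or iv.a_an > 0:
            raise ValueError(
                "lineage_removal_probability requires division-free dynamics up to t"
            )
        dt = min(t, iv.t_end) - iv.t_start
        tot = iv.total_s_rate
        if tot > 0:
            decided = 1.0 - np.exp(-tot * dt)
            p_removed += surv_in_s * (iv.s_del / tot) * decided
            surv_in_s *= np.exp(-tot * dt)
    return p_removed


def expected_extant_lineages(schedule: RateSchedule, n_lineages: int, t: float) -> float:
    """Expected number of lineages with >= 1 cell (of any type) on day t.

    Uses the competing-risks removal probability, so it applies to phases
    with no division (in the packaged schedule, removal only happens during
    days 0-3, before any division; afterwards the extant count is flat).
    """
    t_eff = t
    # after the last interval with removal the extant count cannot change
    last_removal_end = 0.0
    for iv in schedule.intervals:
        if iv.s_del > 0:
            last_removal_end = iv.t_end
    t_eff = min(t, last_removal_end) if last_removal_end > 0 else 0.0
    if t_eff == 0.0:
        return float(n_lineages)
    return n_lineages * (1.0 - lineage_removal_probability(schedule, t_eff))
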
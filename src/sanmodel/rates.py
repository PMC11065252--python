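"""Piecewise-constant event-rate schedules for the SAN model.

The SAN model distinguishes symmetrically dividing S-cells, asymmetrically
dividing A-cells and non-proliferating N-cells.  Six event types drive the
dynamics, each occurring independently per cell with a per-day rate that is
constant within named day intervals:

========  =============================================
event     meaning
========  =============================================
s_ss      S -> S S   symmetric division (self-renewal)
s_del     S -> 0     removal of an S-cell from the organoid
s_a       S -> A     differentiation into an A-cell
s_n       S -> N     direct conversion to a non-dividing cell
a_an      A -> A N   asymmetric division (A persists, one N produced)
a_n       A -> N     terminal conversion of an A-cell
========  =============================================

Rates are expected events per cell per day.  The packaged default schedule
(:func:`map_rate_schedule`) carries the maximum-a-posteriori rates for a
40-day cerebral-organoid culture, split into the four protocol phases:
embryoid-body formation (days 0-3 and 3-6), neural induction (6-11) and the
asymmetric-division phase (11-40).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import yaml

EVENTS: tuple[str, ...] = ("s_ss", "s_del", "s_a", "s_n", "a_an", "a_n")

#: events that consume an S-cell (used for clamping in the simulator)
S_REMOVAL_EVENTS: tuple[str, ...] = ("s_del", "s_a", "s_n")


@dataclass(frozen=True)
class RateInterval:
    """Constant per-cell event rates over the half-open day interval [t_start, t_end)."""

    t_start: float
    t_end: float
    s_ss: float = 0.0
    s_del: float = 0.0
    s_a: float = 0.0
    s_n: float = 0.0
    a_an: float = 0.0
    a_n: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"empty interval [{self.t_start}, {self.t_end})")
        for name in EVENTS:
            r = getattr(self, name)
            if not (r >= 0.0 and r == r and r != float("inf")):
                raise ValueError(f"rate {name}={r!r} must be finite and >= 0")

    def rate(self, event: str) -> float:
        if event not in EVENTS:
            raise KeyError(event)
        return getattr(self, event)

    @property
    def total_s_rate(self) -> float:
        """Total per-S-cell event rate (all four S events compete)."""
        return self.s_ss + self.s_del + self.s_a + self.s_n

    @property
    def total_a_rate(self) -> float:
        return self.a_an + self.a_n


@dataclass(frozen=True)
class RateSchedule:
    """Ordered, contiguous rate intervals covering [0, t_end]."""

    intervals: tuple[RateInterval, ...]

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        if not ivs:
            raise ValueError("schedule needs at least one interval")
        if ivs[0].t_start != 0.0:
            raise ValueError("schedule must start at day 0")
        for prev, nxt in zip(ivs, ivs[1:]):
            if prev.t_end != nxt.t_start:
                raise ValueError(
                    f"intervals must be contiguous: [{prev.t_start},{prev.t_end}) "
                    f"then [{nxt.t_start},{nxt.t_end})"
                )
        object.__setattr__(self, "intervals", ivs)

    @property
    def t_end(self) -> float:
        return self.intervals[-1].t_end

    def interval_at(self, t: float) -> RateInterval:
        """Interval whose half-open [t_start, t_end) contains day t.

        ``t == t_end`` of the schedule maps to the last interval so that the
        closing instant of the simulation is well-defined.
        """
        if t < 0.0 or t > self.t_end:
            raise ValueError(f"day {t} outside schedule coverage [0, {self.t_end}]")
        for iv in self.intervals:
            if iv.t_start <= t < iv.t_end:
                return iv
        return self.intervals[-1]

    def max_per_cell_rate(self) -> float:
        """Max over intervals and cell types of the total per-cell event rate."""
        return max(max(iv.total_s_rate, iv.total_a_rate) for iv in self.intervals)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> list[dict]:
        return [asdict(iv) for iv in self.intervals]

    @classmethod
    def from_dict(cls, data: Iterable[dict]) -> "RateSchedule":
        return cls(tuple(RateInterval(**d) for d in data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"intervals": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RateSchedule":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["intervals"])


@lru_cache(maxsize=1)
def map_rate_schedule() -> RateSchedule:
    """The packaged maximum-a-posteriori rate schedule (events/cell/day).

    Days 0-3: removal 0.35, S->N 0.15 (embryoid-body formation, no division);
    3-6: S->SS 0.6, S->N 0.15; 6-11: S->SS 0.94, S->N 1.14 (neural
    induction); 11-40: S->SS 1.68, S->A 1.69, A->AN 0.71, A->N 0.07.
    """
    with resources.files("sanmodel.data").joinpath("map_rates.yaml").open() as fh:
        data = yaml.safe_load(fh)
    return RateSchedule.from_dict(data["intervals"])


def schedule_from_theta(theta: Sequence[float]) -> RateSchedule:
    """Build a full 0-40 day schedule from the six estimable rates.

    ``theta`` = (s_ss, s_n on days 6-11; s_ss, s_a, a_an, a_n on days 11-40).
    The day 0-6 rates are fixed to the packaged defaults; they are calibrated
    to the embryoid-body phase and not estimated.
    """
    theta = tuple(float(x) for x in theta)
    if len(theta) != 6:
        raise ValueError("theta must have six components")
    base = map_rate_schedule().intervals
    return RateSchedule(
        (
            base[0],
            base[1],
            RateInterval(6.0, 11.0, s_ss=theta[0], s_n=theta[1]),
            RateInterval(11.0, 40.0, s_ss=theta[2], s_a=theta[3], a_an=theta[4], a_n=theta[5]),
        )
    )
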
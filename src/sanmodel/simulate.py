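"""Discrete-time (tau-leaping) stochastic simulation of SAN lineages.

Each lineage evolves independently from a single founder S-cell.  Time is
advanced in steps small enough that the probability of one cell undergoing
two events within a step is below a tolerance ``eps`` (default 1e-3); within
a step the number of cells undergoing each event is Poisson with mean
``rate * count * dt``.  An exact event-by-event (Gillespie) simulator is
provided as a slow cross-validation oracle.

The per-lineage S-cell extinction time ``T_S`` — the day a lineage loses its
last S-cell — is tracked inline and recorded as the midpoint of the step in
which the S-count reached zero (sub-step timing is unresolved at the tau-leap
resolution); lineages whose S-cells survive the horizon carry ``inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .rates import RateInterval, RateSchedule

#: sentinel for "S-cells still extant at the simulation horizon"
NOT_EXTINCT = np.inf

#: per-lineage ceiling on proliferating-cell counts.  Rate vectors near the
#: prior bound (4 events/cell/day) explode exponentially past any physical
#: organoid size and would overflow 64-bit counters; counts saturate here
#: instead, far above anything the likelihood does not already reject.
MAX_CELLS_PER_LINEAGE = 10**12


@dataclass(frozen=True)
class LineageState:
    """Integer (s, a, n) cell counts of one lineage at day t."""

    s: int
    a: int
    n: int
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.s < 0 or self.a < 0 or self.n < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class LineageEnsemble:
    """Per-lineage (s, a, n) trajectories recorded at fixed days.

    ``s``, ``a``, ``n`` have shape (n_lineages, n_record_days); ``t_s`` holds
    the per-lineage S-extinction day (``inf`` if S-cells survive the horizon).
    Lineage count is constant over time: extinct lineages stay as rows of
    frozen counts.
    """

    record_days: np.ndarray
    s: np.ndarray
    a: np.ndarray
    n: np.ndarray
    t_s: np.ndarray
    seed: int | None = None
    n_clamped_steps: int = 0

    @property
    def n_lineages(self) -> int:
        return self.s.shape[0]

    def totals(self) -> np.ndarray:
        """Total lineage sizes s + a + n, shape (n_lineages, n_days)."""
        return self.s + self.a + self.n

    def sizes_at(self, day: float) -> np.ndarray:
        """Total sizes at a recorded day."""
        idx = np.nonzero(np.isclose(self.record_days, day))[0]
        if idx.size == 0:
            raise ValueError(f"day {day} was not recorded")
        return (self.s + self.a + self.n)[:, idx[0]]

    def column(self, which: str, day: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.record_days, day))[0]
        if idx.size == 0:
            raise ValueError(f"day {day} was not recorded")
        return getattr(self, which)[:, idx[0]]

    def to_frame(self):
        """Long-format table (day, lineage_id, s, a, n) for TSV export."""
        import pandas as pd

        days = np.repeat(self.record_days, self.n_lineages)
        lids = np.tile(np.arange(self.n_lineages), self.record_days.size)
        return pd.DataFrame(
            {
                "day": days,
                "lineage_id": lids,
                "s": self.s.T.ravel(),
                "a": self.a.T.ravel(),
                "n": self.n.T.ravel(),
            }
        )


def choose_dt(schedule: RateSchedule, eps: float = 1e-3, cap: float = 0.1) -> float:
    """Largest step for which a double event per cell has probability <= eps.

    For per-cell total rate r the number of events in dt is Poisson(r*dt),
    so P(>= 2 events) = 1 - e^(-r dt)(1 + r dt).  The returned dt solves this
    at the maximum per-cell rate of the schedule; an all-zero schedule gets
    the configured cap.
    """
    if not 0.0 < eps < 1.0:
        raise ValueError("eps must lie in (0, 1)")
    r = schedule.max_per_cell_rate()
    if r == 0.0:
        return cap
    # solve 1 - e^-x (1+x) = eps;  x ~ sqrt(2 eps) for small eps
    x = brentq(lambda x: 1.0 - np.exp(-x) * (1.0 + x) - eps, 1e-12, 10.0)
    return min(x / r, cap)


def _step_arrays(
    s: np.ndarray,
    a: np.ndarray,
    iv: RateInterval,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """One tau-leap step on integer count arrays.

    Returns (new_s, new_a, delta_n, clamped) where clamped counts the
    lineages whose removal draws had to be thinned to preserve s >= 0.
    """
    sf = s * dt
    af = a * dt
    d_ss = rng.poisson(iv.s_ss * sf) if iv.s_ss else np.zeros_like(s)
    d_del = rng.poisson(iv.s_del * sf) if iv.s_del else np.zeros_like(s)
    d_sa = rng.poisson(iv.s_a * sf) if iv.s_a else np.zeros_like(s)
    d_sn = rng.poisson(iv.s_n * sf) if iv.s_n else np.zeros_like(s)
    d_aan = rng.poisson(iv.a_an * af) if iv.a_an else np.zeros_like(a)
    d_an = rng.poisson(iv.a_n * af) if iv.a_n else np.zeros_like(a)

    clamped = 0
    removals = d_del + d_sa + d_sn
    over = removals > s
    if np.any(over):
        # thin the offending removal draws hypergeometrically so that exactly
        # s cells are removed, preserving the relative event proportions
        idx = np.nonzero(over)[0]
        clamped += idx.size
        for i in idx:
            thinned = rng.multivariate_hypergeometric(
                [int(d_del[i]), int(d_sa[i]), int(d_sn[i])], int(s[i])
            )
            d_del[i], d_sa[i], d_sn[i] = thinned
        removals = d_del + d_sa + d_sn
    over_a = d_an > a
    if np.any(over_a):
        clamped += int(np.count_nonzero(over_a))
        d_an = np.minimum(d_an, a)

    new_s = np.minimum(s - removals + d_ss, MAX_CELLS_PER_LINEAGE)
    new_a = np.minimum(a + d_sa - d_an, MAX_CELLS_PER_LINEAGE)
    delta_n = d_sn + d_aan + d_an
    return new_s, new_a, delta_n, clamped


def step(
    state: LineageState,
    rates: RateInterval,
    dt: float,
    rng: np.random.Generator,
) -> LineageState:
    """Advance a single lineage by one tau-leap step."""
    s = np.array([state.s], dtype=np.int64)
    a = np.array([state.a], dtype=np.int64)
    new_s, new_a, dn, _ = _step_arrays(s, a, rates, dt, rng)
    return LineageState(
        s=int(new_s[0]), a=int(new_a[0]), n=state.n + int(dn[0]), t=state.t + dt
    )


def _time_grid(
    schedule: RateSchedule, record_days: np.ndarray, dt: float
) -> list[tuple[float, float, int]]:
    """Segments (t0, t1, n_steps) between consecutive breakpoints.

    Breakpoints are interval boundaries and record days, so every step lies
    wholly inside one rate interval and every record day is hit exactly.
    """
    bps = {iv.t_start for iv in schedule.intervals} | {schedule.t_end}
    bps |= {float(d) for d in record_days}
    pts = sorted(bps)
    horizon = float(max(record_days.max(), 0.0)) if record_days.size else schedule.t_end
    pts = [p for p in pts if p <= horizon + 1e-12]
    segs = []
    for t0, t1 in zip(pts, pts[1:]):
        n = max(1, int(np.ceil((t1 - t0) / dt - 1e-12)))
        segs.append((t0, t1, n))
    return segs


def simulate_ensemble(
    n_lineages: int,
    schedule: RateSchedule,
    record_days: Sequence[float],
    rng: np.random.Generator | int | None = None,
    eps: float = 1e-3,
    block_size: int = 50_000,
    init: tuple[int, int, int] = (1, 0, 0),
) -> LineageEnsemble:
    """Simulate independent lineages and record (s, a, n) at given days.

    Lineages are simulated in blocks; block b uses the rng stream spawned as
    ``SeedSequence(seed).spawn()[b]``, so any lineage can be reproduced in
    isolation by re-simulating only its block.
    """
    if n_lineages < 1:
        raise ValueError("need at least one lineage")
    record_days = np.asarray(sorted(set(float(d) for d in record_days)))
    if record_days.size and record_days.max() > schedule.t_end:
        raise ValueError("record day beyond schedule coverage")
    dt = choose_dt(schedule, eps=eps)
    segs = _time_grid(schedule, record_days, dt)

    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        seqs = np.random.SeedSequence(seed)
    elif rng is None:
        seqs = np.random.SeedSequence()
    else:
        seqs = None  # externally supplied generator: single stream
    n_blocks = int(np.ceil(n_lineages / block_size))
    if seqs is not None:
        streams = [np.random.default_rng(s) for s in seqs.spawn(n_blocks)]
    else:
        streams = [rng] * n_blocks

    nd = record_days.size
    S = np.empty((n_lineages, nd), dtype=np.int64)
    A = np.empty((n_lineages, nd), dtype=np.int64)
    N = np.empty((n_lineages, nd), dtype=np.int64)
    TS = np.full(n_lineages, NOT_EXTINCT)
    clamped_total = 0

    for b in range(n_blocks):
        lo, hi = b * block_size, min((b + 1) * block_size, n_lineages)
        nb = hi - lo
        gen = streams[b]
        s = np.full(nb, init[0], dtype=np.int64)
        a = np.full(nb, init[1], dtype=np.int64)
        n = np.full(nb, init[2], dtype=np.int64)
        ts = np.full(nb, NOT_EXTINCT)
        if init[0] == 0:
            ts[:] = 0.0
        rec_ptr = 0
        if rec_ptr < nd and np.isclose(record_days[rec_ptr], 0.0):
            S[lo:hi, 0], A[lo:hi, 0], N[lo:hi, 0] = s, a, n
            rec_ptr += 1
        active = np.nonzero((s > 0) | (a > 0))[0]
        for t0, t1, nsteps in segs:
            iv = schedule.interval_at(t0)
            h = (t1 - t0) / nsteps
            for k in range(nsteps):
                if active.size:
                    sa, aa = s[active], a[active]
                    new_s, new_a, dn, cl = _step_arrays(sa, aa, iv, h, gen)
                    clamped_total += cl
                    died = (sa > 0) & (new_s == 0)
                    if np.any(died):
                        ts[active[died]] = t0 + (k + 0.5) * h
                    s[active], a[active] = new_s, new_a
                    n[active] += dn
                    keep = (new_s > 0) | (new_a > 0)
                    if not keep.all():
                        active = active[keep]
            if rec_ptr < nd and np.isclose(record_days[rec_ptr], t1):
                S[lo:hi, rec_ptr], A[lo:hi, rec_ptr], N[lo:hi, rec_ptr] = s, a, n
                rec_ptr += 1
        TS[lo:hi] = ts

    return LineageEnsemble(
        record_days=record_days,
        s=S,
        a=A,
        n=N,
        t_s=TS,
        seed=seed,
        n_clamped_steps=clamped_total,
    )


def extinction_times(ensemble: LineageEnsemble) -> np.ndarray:
    """Per-lineage S-cell extinction day (``inf`` = survived the horizon)."""
    return ensemble.t_s.copy()


@dataclass
class Stratum:
    """Quantile trajectories of one extinction-time stratum."""

    label: str
    n_lineages: int
    flagged: bool  # True when the stratum is too small to be reliable
    days: np.ndarray
    quantiles: dict = field(default_factory=dict)  # kind -> (n_q, n_days)


def stratify_by_extinction(
    ensemble: LineageEnsemble,
    strata_days: Sequence[float],
    half_width: float = 0.5,
    qs: Sequence[float] = (0.025, 0.5, 0.975),
    min_lineages: int = 100,
    survivor_stratum: bool = True,
) -> list[Stratum]:
    """Quantile growth trajectories stratified by S-extinction time.

    Each stratum collects lineages with ``|T_S - day| <= half_width``; an
    extra stratum holds lineages whose S-cells survived past the horizon.
    Empty or small strata are flagged rather than dropped.
    """
    qs = np.asarray(qs)
    totals = ensemble.totals()
    out: list[Stratum] = []
    masks = [
        (f"T_S={d:g}", np.abs(ensemble.t_s - d) <= half_width) for d in strata_days
    ]
    if survivor_stratum:
        masks.append(("survived", ~np.isfinite(ensemble.t_s)))
    for label, mask in masks:
        cnt = int(mask.sum())
        stratum = Stratum(
            label=label,
            n_lineages=cnt,
            flagged=cnt < min_lineages,
            days=ensemble.record_days.copy(),
        )
        if cnt:
            for kind, arr in (
                ("s", ensemble.s),
                ("a", ensemble.a),
                ("n", ensemble.n),
                ("total", totals),
            ):
                stratum.quantiles[kind] = np.quantile(arr[mask], qs, axis=0)
        out.append(stratum)
    return out


def simulate_exact(
    n_lineages: int,
    schedule: RateSchedule,
    record_days: Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> LineageEnsemble:
    """Exact continuous-time (event-by-event) simulation.

    Slow cross-validation oracle for the tau-leaping simulator; runtime grows
    with the number of events, so keep lineage counts and rates small.
    """
    gen = np.random.default_rng(rng)
    record_days = np.asarray(sorted(set(float(d) for d in record_days)))
    horizon = record_days.max()
    nd = record_days.size
    S = np.zeros((n_lineages, nd), dtype=np.int64)
    A = np.zeros((n_lineages, nd), dtype=np.int64)
    N = np.zeros((n_lineages, nd), dtype=np.int64)
    TS = np.full(n_lineages, NOT_EXTINCT)

    for i in range(n_lineages):
        s, a, n = 1, 0, 0
        t = 0.0
        rec = 0
        while True:
            iv = schedule.interval_at(min(t, schedule.t_end - 1e-12))
            props = np.array(
                [
                    iv.s_ss * s,
                    iv.s_del * s,
                    iv.s_a * s,
                    iv.s_n * s,
                    iv.a_an * a,
                    iv.a_n * a,
                ]
            )
            total = props.sum()
            t_next = t + (gen.exponential(1.0 / total) if total > 0 else np.inf)
            # the next event may fall beyond the current rate interval; if so,
            # re-draw from the boundary (valid by memorylessness)
            if t_next > iv.t_end and iv.t_end < horizon:
                while rec < nd and record_days[rec] <= iv.t_end:
                    S[i, rec], A[i, rec], N[i, rec] = s, a, n
                    rec += 1
                t = iv.t_end
                continue
            while rec < nd and record_days[rec] <= min(t_next, horizon):
                S[i, rec], A[i, rec], N[i, rec] = s, a, n
                rec += 1
            if t_next >= horizon or rec >= nd and t_next == np.inf:
                break
            if t_next == np.inf:
                break
            t = t_next
            e = gen.choice(6, p=props / total)
            if e == 0:
                s += 1
            elif e == 1:
                s -= 1
            elif e == 2:
                s -= 1
                a += 1
            elif e == 3:
                s -= 1
                n += 1
            elif e == 4:
                n += 1
            else:
                a -= 1
                n += 1
            if s == 0 and TS[i] == NOT_EXTINCT:
                TS[i] = t
            if rec >= nd:
                break
        # fill any remaining record days with the final frozen state
        while rec < nd:
            S[i, rec], A[i, rec], N[i, rec] = s, a, n
            rec += 1

    return LineageEnsemble(record_days=record_days, s=S, a=A, n=N, t_s=TS, seed=None)
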
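"""Power-law statistics for lineage-size distributions.

A sample of lineage sizes l_1..l_n following a Pareto law has
P(size >= l) proportional to l^(-alpha); equivalently the r-th largest size
follows the Zipfian rank-size law l_(r) ~ r^(-1/alpha).  In organoids, only
slow/non-growing lineages obey the Zipf line: the largest (fast-growing,
S-cell-containing) lineages fall below it.  The threshold size l_Th at which
the rank-size curve departs from the Zipf line separates the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class LineageSizeSample:
    """Positive lineage sizes for one organoid/sample."""

    sizes: np.ndarray
    day: float = np.nan
    replicate: str = ""

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        if sizes.size < 1:
            raise ValueError("sample must contain at least one lineage")
        if np.any(sizes <= 0):
            raise ValueError("lineage sizes must be positive (drop zero-size lineages)")
        object.__setattr__(self, "sizes", sizes)

    @property
    def n(self) -> int:
        return self.sizes.size


@dataclass(frozen=True)
class ThresholdFit:
    """Fast/slow threshold fit for one sample.

    The Pareto-induced Zipf line log10 L(r) = -1/alpha_bar * log10 r + d_pareto
    is anchored at the smallest observed lineage; ranks 1..R (where observed
    sizes first reach the line) get a separate log-log-linear fit with slope k
    and intercept d_large; l_Th is the size where the two lines cross.
    """

    alpha_bar: float
    d_pareto: float
    R: int
    k: float
    d_large: float
    l_th: float


class DegenerateSampleError(ValueError):
    """All sizes equal: the Pareto index is undefined."""


def pareto_mle(sample: LineageSizeSample | np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Pareto fit (m_hat, alpha_hat).

    m_hat = min_i l_i and alpha_hat = n / sum_i log(l_i / m_hat)
    (natural log).  Raises :class:`DegenerateSampleError` when all sizes are
    equal (the log-sum vanishes).
    """
    sizes = sample.sizes if isinstance(sample, LineageSizeSample) else np.asarray(sample, float)
    if sizes.size < 2:
        raise ValueError("need at least two lineages")
    m_hat = sizes.min()
    log_sum = np.log(sizes / m_hat).sum()
    if log_sum == 0.0:
        raise DegenerateSampleError("all lineage sizes equal; alpha undefined")
    return float(m_hat), float(sizes.size / log_sum)


def steady_state_alpha(samples: Sequence[LineageSizeSample], min_day: float = 11.0) -> float:
    """Mean Pareto index over all samples from ``min_day`` onward.

    The per-sample index stabilizes once lineage sizes are dominated by the
    neutral-competition regime, so only late samples enter the average.
    """
    alphas = [pareto_mle(s)[1] for s in samples if s.day >= min_day]
    if not alphas:
        raise ValueError(f"no samples on day >= {min_day}")
    return float(np.mean(alphas))


def rank_size(sample: LineageSizeSample | np.ndarray) -> np.ndarray:
    """Sizes in descending order (rank 1 = largest); ties keep input order."""
    sizes = sample.sizes if isinstance(sample, LineageSizeSample) else np.asarray(sample, float)
    order = np.argsort(-sizes, kind="stable")
    return sizes[order]


def estimate_threshold(
    sample: LineageSizeSample | np.ndarray, alpha_bar: float
) -> ThresholdFit:
    """Fast/slow threshold from the truncated-Zipf construction.

    1. Anchor the Zipf line at the smallest lineage:
       d_pareto = log10 l_(n) + (1/alpha_bar) log10 n.
    2. R = smallest rank whose observed size matches or exceeds the line.
    3. OLS fit of log10 l_(r) on log10 r for ranks 1..R (slope k, intercept
       d_large); a single qualifying rank gets slope 0 through that point.
    4. l_Th = size at which the two lines intersect.
    """
    ranked = rank_size(sample)
    n = ranked.size
    if n < 3:
        raise ValueError("need at least three lineages")
    inv_a = 1.0 / alpha_bar
    d_pareto = np.log10(ranked[-1]) + inv_a * np.log10(n)

    ranks = np.arange(1, n + 1)
    line = d_pareto - inv_a * np.log10(ranks)
    meets = np.log10(ranked) >= line - 1e-12
    if not meets.any():
        raise ValueError("no rank reaches the Zipf line; threshold undefined")
    R = int(ranks[meets][0])

    log_r = np.log10(ranks[:R])
    log_l = np.log10(ranked[:R])
    if R < 2:
        k, d_large = 0.0, float(log_l[0])
    else:
        k, d_large = np.polyfit(log_r, log_l, 1)

    # intersection of log10 l = d_large + k log10 r and d_pareto - inv_a log10 r
    if np.isclose(k, -inv_a):
        log_lth = float(log_l[-1])  # parallel lines: fall back to the pivot rank
    else:
        log_r_cross = (d_pareto - d_large) / (k + inv_a)
        log_lth = d_large + k * log_r_cross
    return ThresholdFit(
        alpha_bar=float(alpha_bar),
        d_pareto=float(d_pareto),
        R=R,
        k=float(k),
        d_large=float(d_large),
        l_th=float(10.0 ** log_lth),
    )


def fast_slow_counts(
    sample: LineageSizeSample | np.ndarray, l_th: float
) -> tuple[int, int]:
    """(n_fast, n_slow): lineages strictly above vs at-or-below l_Th."""
    sizes = sample.sizes if isinstance(sample, LineageSizeSample) else np.asarray(sample, float)
    n_fast = int(np.count_nonzero(sizes > l_th))
    return n_fast, sizes.size - n_fast


def emergent_zipf_alpha(
    final_sizes: np.ndarray,
    extinction_days: np.ndarray,
    s0_bar: float = 5.0,
    r_s_ss: float = 1.68,
    t_ref: float = 11.0,
    crossover_factor: float = 2.0,
    alpha_bar: float | None = None,
) -> tuple[float, int]:
    """Pareto index of the slow/non-growing (S-extinct) lineage regime.

    The neutral-competition prediction alpha = 1/2 holds for lineages whose
    S-pool died out *well after* the start of the asymmetric-division phase:
    the final-size law L(dT) = (s0 dT/3 + r_SS dT^2/4) * const is quadratic
    (hence Pareto-1/2-generating) only past the crossover time
    dT* = 4 s0 / (3 r_SS).  Lineages are kept when their extinction falls at
    least ``crossover_factor`` crossover times after ``t_ref`` and their size
    sits at or below the fast/slow threshold; the printed MLE is then applied.

    Returns (alpha_hat, n_lineages_used).
    """
    sizes = np.asarray(final_sizes, dtype=float)
    days = np.asarray(extinction_days, dtype=float)
    pos = sizes > 0
    if alpha_bar is None:
        _, alpha_bar = pareto_mle(sizes[pos])
    fit = estimate_threshold(sizes[pos], alpha_bar)
    cutoff = t_ref + crossover_factor * 4.0 * s0_bar / (3.0 * r_s_ss)
    sel = pos & np.isfinite(days) & (days >= cutoff) & (sizes <= fit.l_th)
    if sel.sum() < 10:
        raise ValueError("too few extinct-regime lineages for a Pareto fit")
    _, alpha = pareto_mle(sizes[sel])
    return alpha, int(sel.sum())


def fastslow_toy(
    gamma: float,
    sigma: float,
    n: int,
    horizon: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Toy fast/slow model: exponential growth with random drop-out.

    Each lineage grows as e^(gamma t) until an Exp(sigma) stopping time
    (capped at the horizon), then freezes.  The frozen sizes are Pareto with
    index sigma/gamma, which is how a rank-size power law can arise from
    lineage-specific growth-arrest times alone.
    """
    if gamma <= 0 or sigma <= 0:
        raise ValueError("gamma and sigma must be positive")
    gen = np.random.default_rng(rng)
    stop = np.minimum(gen.exponential(1.0 / sigma, size=n), horizon)
    return np.exp(gamma * stop)
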
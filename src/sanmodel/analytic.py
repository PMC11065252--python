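"""Closed-form neutral-competition theory for the post-induction phase.

From day 11 on, symmetric division and differentiation of S-cells are
(nearly) balanced, so the per-lineage S-count is a critical birth-death
process; in the diffusion approximation it obeys ds = sqrt(lambda s) dW with
diffusion rate lambda = 2 * r_S->SS.  Conditioned on extinction Delta_T days
after day 11, the most probable S-trajectory is a parabola, and integrating
the A/N output along it yields a closed-form prediction for the final
lineage size L(Delta_T).  Because L grows ~ Delta_T^2 for large Delta_T and
extinction times have tail density ~ 2 s0 / (lambda t^2), final sizes follow
a Pareto law with index 1/2 — the emergent Zipf exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the day-11-onward neutral-competition regime.

    s0: S-cells per (surviving) lineage at day 11; ~5 under the packaged
        MAP rates.
    r_s_ss, r_s_a, r_a_an, r_a_n: per-cell event rates (per day) of the
        asymmetric-division phase; the diffusion rate is lambda = 2 r_s_ss
        (symmetric division and differentiation are treated as identical,
        r_s_ss = r_s_a = lambda / 2).
    t_ref: absolute day at which the regime starts (trajectory time 0).
    """

    s0: float = 5.0
    r_s_ss: float = 1.68
    r_s_a: float = 1.69
    r_a_an: float = 0.71
    r_a_n: float = 0.07
    t_ref: float = 11.0

    @property
    def diffusion_rate(self) -> float:
        return 2.0 * self.r_s_ss

    @property
    def a_output_factor(self) -> float:
        """Cells eventually produced per S->A event: the A-cell itself plus
        its expected lifetime N output r_A->AN / r_A->N."""
        if self.r_a_n <= 0:
            raise ValueError("r_a_n must be positive for the A-output factor")
        return self.r_s_a * (1.0 + self.r_a_an / self.r_a_n)


def most_probable_trajectory(t, params: TheoryParams, delta_t: float):
    """Most probable S-count at time t of a lineage extinct at delta_t.

    s_ext(t) = s0 (1 - t/delta_t)(1 + rho t/delta_t) with
    rho = 3 lambda delta_t / (4 s0) - 1; s_ext(0) = s0, s_ext(delta_t) = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > delta_t):
        raise ValueError("t must lie in [0, delta_t]")
    lam = params.diffusion_rate
    rho = 3.0 * lam * delta_t / (4.0 * params.s0) - 1.0
    u = t / delta_t
    return params.s0 * (1.0 - u) * (1.0 + rho * u)


def final_lineage_size(delta_t, params: TheoryParams):
    """Expected final size of a lineage whose S-cells die out at delta_t.

    L(delta_t) = (s0 delta_t / 3 + r_S->SS delta_t^2 / 4) * r_S->A
                 * (1 + r_A->AN / r_A->N),

    i.e. the integral of the most probable S-trajectory times the per-S-cell
    A/N output.  Monotone increasing, L(0) = 0.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be non-negative")
    integral = params.s0 * delta_t / 3.0 + params.r_s_ss * delta_t**2 / 4.0
    return integral * params.a_output_factor


def extinction_time_cdf(t, s0: float, lam: float):
    """Probability that the S-pool of a lineage is extinct by time t.

    exp(-2 s0 / (lambda t)); increases to 1 (extinction is certain at
    criticality) with tail density ~ 2 s0 t^-2 / lambda for large t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    return np.exp(-2.0 * s0 / (lam * t))


def predicted_zipf_alpha(params: TheoryParams | None = None) -> float:
    """Predicted Pareto index of final lineage sizes: 1/2.

    Valid when the S-cell population is long-lived and roughly constant:
    then L ~ delta_t^2 for large delta_t while P(extinction at ~t) ~ t^-2,
    so P(L >= l) ~ l^(-1/2).
    """
    return 0.5


def invert_final_size(l_obs, params: TheoryParams):
    """Extinction time delta_t at which L(delta_t) equals the observed size.

    Unique non-negative root of
    r_S->SS/4 * dt^2 + s0/3 * dt - l_obs / a_output_factor = 0.
    """
    l_obs = np.asarray(l_obs, dtype=float)
    if np.any(l_obs < 0):
        raise ValueError("observed sizes must be non-negative")
    aa = params.r_s_ss / 4.0
    bb = params.s0 / 3.0
    cc = -l_obs / params.a_output_factor
    return (-bb + np.sqrt(bb * bb - 4.0 * aa * cc)) / (2.0 * aa)


def recover_extinction_histogram(
    day40_sizes, params: TheoryParams, bin_days
) -> np.ndarray:
    """Histogram of inferred S-extinction days from observed final sizes.

    Each size is inverted through L(delta_t) and offset to the absolute day
    ``t_ref + delta_t``; counts are binned by ``bin_days`` (edges).  Sizes
    below L(0+) = 0 land in the earliest bin by construction.
    """
    sizes = np.asarray(day40_sizes, dtype=float)
    edges = np.asarray(bin_days, dtype=float)
    if sizes.size == 0:
        return np.zeros(edges.size - 1, dtype=int)
    day = params.t_ref + invert_final_size(sizes, params)
    day = np.clip(day, edges[0], None)
    counts, _ = np.histogram(day, bins=edges)
    return counts


def bd_extinction_prob(birth: float, death: float, t: float, k: int = 1) -> float:
    """Extinction probability of a linear birth-death clone of k cells by t.

    Single-cell extinction probability p0(t) is the classical closed form
    d (e^((b-d)t) - 1) / (b e^((b-d)t) - d); at criticality (b = d = r) it
    is r t / (1 + r t).  Independence across cells gives p0^k.
    """
    if birth < 0 or death < 0 or k < 1:
        raise ValueError("rates must be >= 0 and k >= 1")
    if death == 0:
        return 0.0
    if np.isclose(birth, death):
        r = 0.5 * (birth + death)
        p0 = r * t / (1.0 + r * t)
    else:
        e = np.exp((birth - death) * t)
        p0 = death * (e - 1.0) / (birth * e - death)
    return float(p0**k)
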
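"""Truncated master-equation oracle for single-lineage SAN dynamics.

The probability p(s, a, n, t) of a lineage holding exactly s S-, a A- and
n N-cells obeys a linear master equation.  On a finite lattice
0 <= s <= s_max, 0 <= a <= a_max, 0 <= n <= n_max the generator is a sparse
matrix and p(t) = exp(Q t) p(0) can be evaluated exactly (up to truncation).
Probability flowing off the lattice is *lost* (the diagonal carries the full
outflow), so the total-probability deficit plus the mass sitting on the
boundary slices measures the truncation error; the oracle refuses to answer
when that exceeds a tolerance.

This module exists to validate the tau-leaping simulator on small systems,
not for production-size runs (the lattice grows as s_max*a_max*n_max).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import expm_multiply

from .rates import RateInterval


class TruncationError(RuntimeError):
    """Raised when boundary mass exceeds the configured tolerance."""


def master_equation_oracle(
    rates: RateInterval,
    truncation: tuple[int, int, int],
    t: float,
    init: tuple[int, int, int] = (1, 0, 0),
    boundary_tol: float = 1e-6,
) -> np.ndarray:
    """p(s, a, n, t) on the truncated lattice, from p(init) = 1 at t = 0.

    Returns an array of shape (s_max+1, a_max+1, n_max+1).  Raises
    :class:`TruncationError` if the truncation error (lost mass + boundary
    mass) exceeds ``boundary_tol``.
    """
    s_max, a_max, n_max = truncation
    shape = (s_max + 1, a_max + 1, n_max + 1)
    size = shape[0] * shape[1] * shape[2]

    S, A, N = np.meshgrid(
        np.arange(s_max + 1), np.arange(a_max + 1), np.arange(n_max + 1), indexing="ij"
    )
    S, A, N = S.ravel(), A.ravel(), N.ravel()

    def idx(s, a, n):
        return (s * shape[1] + a) * shape[2] + n

    rows, cols, vals = [], [], []

    def add_flow(rate_per_event, ds, da, dn):
        """Transition (s,a,n) -> (s+ds, a+da, n+dn) at rate rate_per_event."""
        tgt_s, tgt_a, tgt_n = S + ds, A + da, N + dn
        ok = (
            (rate_per_event > 0)
            & (tgt_s >= 0) & (tgt_s <= s_max)
            & (tgt_a >= 0) & (tgt_a <= a_max)
            & (tgt_n >= 0) & (tgt_n <= n_max)
        )
        rows.append(idx(tgt_s[ok], tgt_a[ok], tgt_n[ok]))
        cols.append(idx(S[ok], A[ok], N[ok]))
        vals.append(rate_per_event[ok])

    add_flow(rates.s_ss * S, +1, 0, 0)
    add_flow(rates.s_del * S, -1, 0, 0)
    add_flow(rates.s_a * S, -1, +1, 0)
    add_flow(rates.s_n * S, -1, 0, +1)
    add_flow(rates.a_an * A, 0, 0, +1)
    add_flow(rates.a_n * A, 0, -1, +1)

    # diagonal: full outflow, including transitions leaving the lattice
    out = rates.total_s_rate * S + rates.total_a_rate * A
    rows.append(idx(S, A, N))
    cols.append(idx(S, A, N))
    vals.append(-out)

    Q = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(size, size),
    )

    p0 = np.zeros(size)
    p0[idx(*init)] = 1.0
    p = expm_multiply(Q * t, p0)
    p = np.clip(p, 0.0, None).reshape(shape)

    lost = 1.0 - p.sum()
    # boundary mass is only an escape risk along coordinates that can grow
    boundary = 0.0
    if rates.s_ss > 0:
        boundary += p[s_max, :, :].sum()
    if rates.s_a > 0:
        boundary += p[:, a_max, :].sum()
    if rates.s_n > 0 or rates.a_an > 0 or rates.a_n > 0:
        boundary += p[:, :, n_max].sum()
    if lost + boundary > boundary_tol:
        raise TruncationError(
            f"truncation too small: lost mass {lost:.3g} + boundary mass "
            f"{boundary:.3g} exceeds {boundary_tol:g}"
        )
    return p
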
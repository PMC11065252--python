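"""Sequencing-readout model for barcode lineage tracing.

True lineage sizes (cell counts) are observed through PCR amplification and
sequencing.  Each of a lineage's template molecules (one per cell) is
amplified through a Galton-Watson PCR: in every cycle each copy duplicates
independently with probability E (the PCR efficiency).  Reads are then drawn
Poisson with mean proportional to the lineage's total post-PCR copy number,
scaled so that the ensemble-expected reads for lineage i equal
``W * l_i / sum_j l_j`` (W = library size).  For E < 1 the random family
sizes make read counts over-dispersed relative to Poisson; for E = 1
amplification is deterministic and reads are exactly Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SeqReadoutParams:
    """PCR + sequencing observation-model parameters.

    pcr_efficiency: per-molecule duplication probability per cycle (the
        study's estimate from day-0 data is 0.35).
    n_cycles: PCR cycles; the normalized family-size distribution converges
        for large cycle numbers, so results are insensitive to this beyond
        ~20 cycles.
    library_size: expected total reads W.
    detection_threshold: minimum reads for a lineage to count as observed.
    """

    pcr_efficiency: float = 0.35
    n_cycles: int = 30
    library_size: float = 1e6
    detection_threshold: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.pcr_efficiency <= 1.0:
            raise ValueError("pcr_efficiency must lie in (0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def simulate_readcounts(
    lineage_sizes: np.ndarray,
    params: SeqReadoutParams,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate one read count per lineage.

    The total post-PCR copy number of a lineage with l_i cells is the sum of
    l_i independent Galton-Watson families; the sum is simulated directly by
    iterating ``X <- X + Binomial(X, E)`` from X = l_i.  Reads are Poisson
    with mean ``W * X_i / ((1+E)^cycles * sum_j l_j)`` which makes the
    marginal expectation exactly ``W * l_i / sum_j l_j``.
    """
    gen = np.random.default_rng(rng)
    sizes = np.asarray(lineage_sizes)
    if np.any(sizes < 0):
        raise ValueError("lineage sizes must be non-negative")
    total_cells = sizes.sum()
    if total_cells == 0:
        raise ValueError("all lineage sizes are zero; read scale undefined")

    E = params.pcr_efficiency
    copies = sizes.astype(np.int64).copy()
    for _ in range(params.n_cycles):
        copies = copies + gen.binomial(copies, E)
    mean_amplification = (1.0 + E) ** params.n_cycles
    lam = params.library_size * copies / (mean_amplification * total_cells)
    return gen.poisson(lam)


def reads_to_cells(reads: np.ndarray, library_size: float, total_cells: float) -> np.ndarray:
    """Back-normalize read counts to cell-count estimates.

    Divides by the average reads per cell, W / total_cells; unbiased by
    construction of :func:`simulate_readcounts`.
    """
    if library_size <= 0 or total_cells <= 0:
        raise ValueError("library_size and total_cells must be positive")
    return np.asarray(reads) * (total_cells / library_size)


def count_observed(reads: np.ndarray, threshold: int = 1) -> int:
    """Number of lineages with at least ``threshold`` reads."""
    return int(np.count_nonzero(np.asarray(reads) >= threshold))
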
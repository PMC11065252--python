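"""Readers, writers and normalization for lineage-tracing tables.

Two table kinds are used throughout:

* count tables — one row per (sample, lineage): tab-separated with columns
  ``sample``, ``day``, ``replicate``, ``lid`` (the barcode lineage
  identifier) and ``reads`` (>= 1; unobserved lineages are simply absent);
* size tables — total organoid sizes: ``day``, ``replicate``, ``cells`` and
  a ``source`` tag (FACS or volume-derived).

Read counts are converted to absolute cell counts by *mode normalization*:
assuming the most common lineage size is one cell, the mode of the
log-transformed read-count distribution corresponds to one cell, and all
counts are divided by it.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .inference import ObservationSet

COUNT_COLUMNS = ("sample", "day", "replicate", "lid", "reads")
SIZE_COLUMNS = ("day", "replicate", "cells", "source")


class TableFormatError(ValueError):
    """Malformed input table (missing columns, bad values, duplicates)."""


def read_count_table(
    path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a lineage-tracing count table (TSV with header).

    ``columns`` maps canonical names (sample, day, replicate, lid, reads) to
    the file's actual column names, since deposited datasets vary in layout.
    Malformed rows are reported with their line numbers; duplicate
    (sample, lid) pairs and non-positive read counts are rejected.
    """
    colmap = {c: c for c in COUNT_COLUMNS}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[list(COUNT_COLUMNS)]

    bad_lines = []
    for col, conv in (("day", float), ("reads", int)):
        converted = []
        for i, v in enumerate(df[col]):
            try:
                converted.append(conv(v))
            except (TypeError, ValueError):
                bad_lines.append(i + 2)  # +2: header line + 1-based
                converted.append(np.nan)
        df[col] = converted
    if bad_lines:
        raise TableFormatError(
            f"{path}: malformed numeric field(s) on line(s) {sorted(set(bad_lines))}"
        )
    if (df["reads"] < 1).any():
        lines = (df.index[df["reads"] < 1] + 2).tolist()
        raise TableFormatError(f"{path}: reads must be >= 1 (line(s) {lines})")
    dup = df.duplicated(subset=["sample", "lid"], keep=False)
    if dup.any():
        lids = sorted(df.loc[dup, "lid"].unique())
        raise TableFormatError(f"{path}: duplicate (sample, lid) for LID(s) {lids}")
    df["reads"] = df["reads"].astype(np.int64)
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_size_table(path) -> pd.DataFrame:
    """Read a total-organoid-size table (day, replicate, cells, source)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SIZE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    if (df["cells"] <= 0).any():
        raise TableFormatError(f"{path}: cells must be positive")
    return df[list(SIZE_COLUMNS)]


def mode_normalize(
    reads: np.ndarray,
    min_lineages: int = 30,
    library_size: float | None = None,
    total_cells: float | None = None,
) -> np.ndarray:
    """Normalize per-lineage read counts to absolute cell counts.

    Locates the mode of the log read-count distribution with a Gaussian KDE
    (Silverman bandwidth) and divides by it, anchoring the most common
    lineage size at one cell.  Samples with fewer than ``min_lineages``
    lineages are too sparse for the mode to be reliable; they fall back to
    library-size normalization (reads * total_cells / library_size), which
    must then be supplied.
    """
    reads = np.asarray(reads, dtype=float)
    if np.any(reads <= 0):
        raise ValueError("read counts must be positive")
    if reads.size < min_lineages:
        warnings.warn(
            f"only {reads.size} lineages (<{min_lineages}); falling back to "
            "library-size normalization"
        )
        if library_size is None or total_cells is None:
            raise ValueError(
                "library_size and total_cells required for the fallback"
            )
        return reads * (total_cells / library_size)
    log_reads = np.log(reads)
    if np.allclose(log_reads, log_reads[0]):
        mode_reads = reads[0]
    else:
        kde = gaussian_kde(log_reads, bw_method="silverman")
        grid = np.linspace(log_reads.min(), log_reads.max(), 2048)
        dens = kde(grid)
        # refine the grid argmax locally for a sharper mode estimate
        j = int(np.argmax(dens))
        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, grid.size - 1)]
        fine = np.linspace(lo, hi, 256)
        mode_reads = np.exp(fine[np.argmax(kde(fine))])
    return reads / mode_reads


def build_observation_set(
    counts: pd.DataFrame,
    sizes: pd.DataFrame,
    days: Sequence[float],
    ranks: Sequence[int],
    rank_days: Sequence[float] = (11.0, 40.0),
    sd_floor: float = 0.05,
    exclude_samples: Sequence[str] = (),
) -> ObservationSet:
    """Replicate-aggregated log-scale observations for rate inference.

    Total sizes: for each day in ``days``, mean and SD of log total cells
    across replicates in the size table.  Ranked sizes: for each day in
    ``rank_days``, each sample's reads are mode-normalized to cells, ranked,
    and the requested ranks aggregated across replicates.  Ranks beyond a
    sample's lineage count are left missing (NaN) and excluded from the
    likelihood.  Degenerate replicate SDs are floored at ``sd_floor``.
    """
    days = np.asarray(sorted(days), dtype=float)
    ranks = np.asarray(sorted(ranks), dtype=int)
    rank_days = np.asarray(sorted(rank_days), dtype=float)
    if exclude_samples:
        counts = counts[~counts["sample"].isin(exclude_samples)]

    mu_tot = np.empty(days.size)
    sd_tot = np.empty(days.size)
    for i, d in enumerate(days):
        rep = sizes.loc[np.isclose(sizes["day"], d), "cells"].to_numpy(float)
        if rep.size == 0:
            raise ValueError(f"no organoid-size data for day {d:g}")
        logs = np.log(rep)
        mu_tot[i] = logs.mean()
        sd_tot[i] = max(logs.std(ddof=1) if rep.size > 1 else 0.0, sd_floor)

    mu_rank = np.full((rank_days.size, ranks.size), np.nan)
    sd_rank = np.full((rank_days.size, ranks.size), np.nan)
    for i, d in enumerate(rank_days):
        day_counts = counts[np.isclose(counts["day"], d)]
        per_rep = []
        for _, grp in day_counts.groupby("sample"):
            cells = mode_normalize(grp["reads"].to_numpy())
            ranked = np.sort(cells)[::-1]
            row = np.full(ranks.size, np.nan)
            ok = ranks <= ranked.size
            row[ok] = ranked[ranks[ok] - 1]
            per_rep.append(row)
        if not per_rep:
            continue
        mat = np.log(np.vstack(per_rep))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            n_ok = np.sum(~np.isnan(mat), axis=0)
            mu_rank[i] = np.nanmean(mat, axis=0)
            sd_rank[i] = np.where(
                n_ok > 1, np.maximum(np.nanstd(mat, axis=0, ddof=1), sd_floor), sd_floor
            )
        mu_rank[i, n_ok == 0] = np.nan
        sd_rank[i, n_ok == 0] = np.nan

    return ObservationSet(
        total_days=days,
        total_mu=mu_tot,
        total_sd=sd_tot,
        rank_days=rank_days,
        ranks=ranks,
        rank_mu=mu_rank,
        rank_sd=sd_rank,
    )
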
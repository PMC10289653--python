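"""Per-cell-type expression profiles from a labelled count matrix.

The central quantity is the *scaled TPM*: counts are normalised per
cell by a size factor (cell total over the geometric mean of totals),
averaged per gene within a cell type, and the per-type gene means are
rescaled to sum to one million. Bootstrap resampling of cells within
each type yields percentile confidence intervals; a gene is called
*robustly expressed* in a type when the lower bound of its 95% interval
is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CellTypeProfile",
    "PercentExpressed",
    "size_factor_normalize",
    "aggregate_scaled_tpm",
    "bootstrap_profile",
    "percent_expressed",
    "aggregate_log1p_cpm",
]


@dataclass
class CellTypeProfile:
    """Gene x cell-type scaled-TPM profile with bootstrap uncertainty."""

    scaled_tpm: pd.DataFrame
    ci_low: dict[int, pd.DataFrame] = field(default_factory=dict)
    ci_high: dict[int, pd.DataFrame] = field(default_factory=dict)
    robust_mask: pd.DataFrame | None = None
    n_cells: pd.Series | None = None
    n_bootstrap: int = 0


@dataclass
class PercentExpressed:
    pct: pd.DataFrame  # gene x cell type, values in [0, 100]


def _as_dense(counts) -> np.ndarray:
    if sparse.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def _check_labels(n_cells: int, labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != n_cells:
        raise ValueError(
            f"labels length {labels.shape[0]} does not match {n_cells} cells"
        )
    return labels


def size_factor_normalize(counts, cell_names: list[str] | None = None) -> np.ndarray:
    """Divide each cell by ``total_j / geometric_mean(totals)``.

    Raises on cells with zero total (the size factor is undefined).
    """
    dense = _as_dense(counts)
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        name = cell_names[zero[0]] if cell_names else f"column {zero[0]}"
        raise ValueError(f"cell {name!s} has zero total count; cannot size-factor normalise")
    geo = np.exp(np.mean(np.log(totals)))
    return dense / (totals / geo)[None, :]


def aggregate_scaled_tpm(
    norm_matrix: np.ndarray,
    labels,
    genes: list[str] | None = None,
) -> CellTypeProfile:
    """Mean per gene within each type, rescaled so each column sums to 1e6."""
    norm_matrix = np.asarray(norm_matrix, dtype=float)
    labels = _check_labels(norm_matrix.shape[1], labels)
    types = sorted(pd.unique(labels))
    cols = {}
    n_cells = {}
    for ct in types:
        mask = labels == ct
        if not mask.any():
            raise ValueError(f"cell type {ct!r} has no cells")
        means = norm_matrix[:, mask].mean(axis=1)
        total = means.sum()
        cols[ct] = means / total * 1e6 if total > 0 else means
        n_cells[ct] = int(mask.sum())
    idx = genes if genes is not None else pd.RangeIndex(norm_matrix.shape[0])
    tpm = pd.DataFrame(cols, index=idx)
    return CellTypeProfile(scaled_tpm=tpm, n_cells=pd.Series(n_cells))


def _scaled_tpm_one_type(norm_block: np.ndarray) -> np.ndarray:
    means = norm_block.mean(axis=1)
    total = means.sum()
    return means / total * 1e6 if total > 0 else means


def bootstrap_profile(
    counts,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
    genes: list[str] | None = None,
    ci_levels: tuple[int, ...] = (95, 80),
    cell_names: list[str] | None = None,
) -> CellTypeProfile:
    """Scaled-TPM point estimates plus percentile bootstrap CIs.

    For a type with N cells, each bootstrap replicate resamples N of its
    own cells with replacement and recomputes the scaled TPM; intervals
    are the corresponding percentile bands of the replicate distribution.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    norm = size_factor_normalize(counts, cell_names)
    labels = _check_labels(norm.shape[1], labels)
    profile = aggregate_scaled_tpm(norm, labels, genes=genes)
    rng = np.random.default_rng(seed)
    types = list(profile.scaled_tpm.columns)

    low = {lvl: {} for lvl in ci_levels}
    high = {lvl: {} for lvl in ci_levels}
    for ct in types:
        block = norm[:, labels == ct]
        n = block.shape[1]
        # resample-count matrix: boots as columns, entries sum to n
        draws = rng.integers(0, n, size=(n_boot, n))
        w = np.zeros((n, n_boot))
        for b in range(n_boot):
            w[:, b] = np.bincount(draws[b], minlength=n)
        boot_means = block @ (w / n)  # gene x n_boot mean over resampled cells
        totals = boot_means.sum(axis=0)
        totals[totals == 0] = 1.0
        boot_tpm = boot_means / totals[None, :] * 1e6
        for lvl in ci_levels:
            alpha = (100 - lvl) / 2
            lo, hi = np.percentile(boot_tpm, [alpha, 100 - alpha], axis=1)
            low[lvl][ct] = lo
            high[lvl][ct] = hi

    idx = profile.scaled_tpm.index
    profile.ci_low = {lvl: pd.DataFrame(low[lvl], index=idx) for lvl in ci_levels}
    profile.ci_high = {lvl: pd.DataFrame(high[lvl], index=idx) for lvl in ci_levels}
    profile.robust_mask = profile.ci_low[95] > 0
    profile.n_bootstrap = n_boot
    return profile


def percent_expressed(counts, labels, genes: list[str] | None = None) -> PercentExpressed:
    """Percent of a type's cells with count > 0, per gene."""
    dense = _as_dense(counts)
    labels = _check_labels(dense.shape[1], labels)
    cols = {}
    for ct in sorted(pd.unique(labels)):
        block = dense[:, labels == ct]
        cols[ct] = 100.0 * (block > 0).mean(axis=1)
    idx = genes if genes is not None else pd.RangeIndex(dense.shape[0])
    return PercentExpressed(pct=pd.DataFrame(cols, index=idx))


def aggregate_log1p_cpm(counts, labels, genes: list[str] | None = None,
                        cell_names: list[str] | None = None) -> pd.DataFrame:
    """Per-type mean of log1p(counts-per-million), the pseudobulk used
    for communication scoring."""
    dense = _as_dense(counts)
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        name = cell_names[zero[0]] if cell_names else f"column {zero[0]}"
        raise ValueError(f"cell {name!s} has zero total count; CPM undefined")
    labels = _check_labels(dense.shape[1], labels)
    logcpm = np.log1p(dense / totals[None, :] * 1e6)
    cols = {}
    for ct in sorted(pd.unique(labels)):
        cols[ct] = logcpm[:, labels == ct].mean(axis=1)
    idx = genes if genes is not None else pd.RangeIndex(dense.shape[0])
    return pd.DataFrame(cols, index=idx)
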
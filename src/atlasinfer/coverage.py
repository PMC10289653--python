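"""Transcriptome-coverage estimation per cell type.

How many genes would we detect in a cell type if we had unlimited
cells?  The detected-gene count as a function of the number of sampled
cells is a saturating curve; fitting a three-parameter log-logistic

    f(x) = d / (1 + exp(b * (ln x - ln e)))

gives the predicted asymptotic gene count ``d`` (G_MAX), the number of
cells at half coverage ``e`` (f(e) = d/2 exactly), and the slope ``b``
(negative for an increasing curve).  Evaluating f at the observed cell
count, divided by d, estimates the fraction of the type's transcriptome
already covered.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aggregate import _as_dense, _check_labels

__all__ = [
    "SaturationCurve",
    "LogLogisticFit",
    "log_logistic",
    "downsample_curve",
    "fit_log_logistic",
    "coverage_report",
]


@dataclass
class SaturationCurve:
    cell_type: str
    sizes: np.ndarray
    mean_genes: np.ndarray
    n_iter: int


@dataclass
class LogLogisticFit:
    b: float
    d: float  # upper asymptote, G_MAX
    e: float  # cells at half-maximum
    rss: float


def log_logistic(x, b: float, d: float, e: float):
    x = np.asarray(x, dtype=float)
    return d / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def default_sizes(n_cells: int, n_points: int = 10) -> np.ndarray:
    """Geometric grid of sample sizes from 5 (or fewer) up to N."""
    lo = min(5, n_cells)
    grid = np.unique(
        np.round(np.geomspace(lo, n_cells, num=n_points)).astype(int)
    )
    return grid


def downsample_curve(
    counts,
    labels,
    cell_type: str,
    sizes=None,
    n_iter: int = 100,
    seed: int = 0,
) -> SaturationCurve:
    """Mean detected-gene count over ``n_iter`` random subsamples of the
    type's cells, at each sample size (without replacement).

    A gene counts as detected when its scaled TPM in the subsample is
    positive, i.e. when any sampled cell carries a count for it.
    """
    dense = _as_dense(counts)
    labels = _check_labels(dense.shape[1], labels)
    block = dense[:, labels == cell_type]
    n = block.shape[1]
    if n == 0:
        raise ValueError(f"cell type {cell_type!r} has no cells")
    if sizes is None:
        sizes = default_sizes(n)
    sizes = np.asarray(sizes, dtype=int)
    if sizes.max() > n:
        raise ValueError(f"requested size {sizes.max()} exceeds {n} cells of {cell_type!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    positive = block > 0
    means = np.empty(sizes.size)
    for si, s in enumerate(sizes):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(cell_type.encode()), int(s)])
        )
        detected = np.empty(n_iter)
        for it in range(n_iter):
            pick = rng.choice(n, size=s, replace=False)
            detected[it] = positive[:, pick].any(axis=1).sum()
        means[si] = detected.mean()
    return SaturationCurve(cell_type=cell_type, sizes=sizes, mean_genes=means, n_iter=n_iter)


def fit_log_logistic(curve: SaturationCurve) -> LogLogisticFit:
    """Least-squares fit of the three-parameter log-logistic.

    Multi-start: the asymptote is started at 1x/1.2x/2x the largest
    observed mean, the half-coverage size at three quantiles of the
    size grid, and the slope at -1; the best residual wins.
    """
    x = np.asarray(curve.sizes, dtype=float)
    y = np.asarray(curve.mean_genes, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct sizes to fit the log-logistic")

    def resid(p):
        b, d, e = p
        return log_logistic(x, b, d, e) - y

    ymax = y.max()
    best = None
    for d0 in (ymax, 1.2 * ymax, 2.0 * ymax):
        for e0 in np.quantile(x, [0.1, 0.35, 0.7]):
            try:
                sol = least_squares(
                    resid,
                    x0=[-1.0, max(d0, 1.0), max(e0, 1e-6)],
                    bounds=([-np.inf, 1e-9, 1e-9], [0.0, np.inf, np.inf]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError(
            f"log-logistic fit failed to converge for {curve.cell_type!r} "
            f"(sizes={x.tolist()}, means={y.tolist()})"
        )
    rss, (b, d, e) = best
    return LogLogisticFit(b=float(b), d=float(d), e=float(e), rss=rss)


def coverage_report(fit: LogLogisticFit, n_cells_observed: int) -> tuple[float, float, float]:
    """(G_MAX, cells at half coverage, fraction of transcriptome covered)."""
    if n_cells_observed <= 0:
        raise ValueError("n_cells_observed must be positive")
    frac = float(log_logistic(n_cells_observed, fit.b, fit.d, fit.e) / fit.d)
    return fit.d, fit.e, float(np.clip(frac, 0.0, 1.0))
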
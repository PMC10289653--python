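"""Housekeeping-gene scoring across cell types.

Two complementary statistics quantify how evenly a gene is expressed
across the cell types of an atlas:

* the *skewness score*: moment skewness (g1) of the gene's
  percent-cells-expressing vector across types. A gene detected in
  nearly all cells of nearly all types piles mass near 100% and its
  density is right-shifted, giving a negative score; a gene expressed
  in few cells of few types gives a positive score.
* the *Gini coefficient* (Gc) of the gene's scaled-TPM vector across
  types: 0 for perfectly even expression, 1 for maximal concentration
  in one type.

Genes are binned into expression-equality brackets by Gc and filtered
into a concentric candidate hierarchy: consistently expressed
(Gc below threshold), also consistent in a second condition, also
essential, also conserved. Enrichment of essential genes in a
candidate set is tested with a one-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BRACKETS",
    "EnrichmentResult",
    "skewness_score",
    "gini_coefficient",
    "classify_gini",
    "score_genes",
    "housekeeping_candidates",
    "essentiality_enrichment",
]

# Gc bracket edges; upper edges are inclusive.
BRACKETS = (
    (0.2, "perfect"),
    (0.3, "good"),
    (0.4, "adequate"),
    (0.5, "big_gap"),
    (1.0, "severe_gap"),
)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: rows in-set/out-set, cols essential/non-essential
    odds_ratio: float
    p_value: float


def skewness_score(pct_row) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) of a percent-expressed vector.

    Returns NaN for constant vectors (the score is undefined there).
    """
    x = np.asarray(pct_row, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 cell types to score skewness")
    if np.ptp(x) == 0:
        return float("nan")
    return float(stats.skew(x, bias=True))


def gini_coefficient(expr_row) -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 xbar).

    Computed via the sorted-rank identity; NaN for an all-zero vector.
    """
    x = np.asarray(expr_row, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * xs) / (n * total) - (n + 1) / n)


def classify_gini(g: float) -> str:
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"Gini coefficient {g} outside [0, 1]")
    for edge, name in BRACKETS:
        if g <= edge:
            return name
    return BRACKETS[-1][1]  # pragma: no cover


def score_genes(pct: pd.DataFrame, scaled_tpm: pd.DataFrame) -> pd.DataFrame:
    """Skewness, Gc and bracket for every gene.

    Genes with zero expression everywhere get NaN scores and no bracket.
    """
    if not pct.index.equals(scaled_tpm.index):
        raise ValueError("percent-expressed and scaled-TPM tables must share a gene index")
    skew = pct.apply(lambda r: skewness_score(r.to_numpy()), axis=1)
    gini = scaled_tpm.apply(lambda r: gini_coefficient(r.to_numpy()), axis=1)
    bracket = gini.map(lambda g: classify_gini(g) if np.isfinite(g) else None)
    return pd.DataFrame({"skewness": skew, "gini": gini, "bracket": bracket})


def housekeeping_candidates(
    scores: pd.DataFrame,
    gini_threshold: float = 0.3,
    cross_condition_list=None,
    essential_list=None,
    conserved_list=None,
) -> list[dict]:
    """Concentric candidate filtration.

    Ring 1: genes with Gc strictly below ``gini_threshold``; each
    optional list intersects the previous ring. Empty/None lists skip
    their ring. Returns a list of {name, genes, size} dicts, outermost
    first.
    """
    ring = set(scores.index[scores["gini"] < gini_threshold])
    rings = [{"name": f"gini<{gini_threshold:g}", "genes": set(ring), "size": len(ring)}]
    for name, lst in (
        ("cross_condition", cross_condition_list),
        ("essential", essential_list),
        ("conserved", conserved_list),
    ):
        if lst is None or len(lst) == 0:
            continue
        ring = ring & set(lst)
        rings.append({"name": name, "genes": set(ring), "size": len(ring)})
    return rings


def essentiality_enrichment(gene_set, essential_set, universe) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test of essential-gene enrichment."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gene_set = set(gene_set) & universe
    essential_set = set(essential_set) & universe
    a = len(gene_set & essential_set)
    b = len(gene_set - essential_set)
    c = len(essential_set - gene_set)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(table=table, odds_ratio=float(odds), p_value=float(p))
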
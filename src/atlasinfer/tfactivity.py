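"""TF-activity inference from ChIP-Seq peaks and cell-type expression.

Pipeline: peaks are grouped along each chromosome into clusters broken
at apex gaps of >= 200 bp; clusters bound by a single TF (spurious) or
by more than 70 distinct TFs (HOT sites, not tissue-specific) are
discarded; surviving clusters are assigned to the gene with the nearest
TSS when that TSS is within 2000 bp of the cluster's mean apex and the
second-nearest TSS is at least 1.5x as far.  Peak strengths are rank-
normalised to cumulative probabilities within each (TF, stage)
experiment and aggregated per (target gene, TF) by maximum, giving a
gene x TF predictor matrix.  Each cell type's expression profile is
regressed on that matrix with an L1-penalised linear model (penalty by
cross-validation); negative coefficients are clipped to zero and the
clipped coefficient is read as the TF's activity in that cell type.

Cell-type dendrograms (Ward variance-minimising linkage on Euclidean
distances, the "Ward.D2" convention) built from different feature
matrices are compared with Baker's gamma: the Spearman correlation,
over leaf pairs, of the highest cluster count at which the pair is
still in one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import KFold

from .aggregate import CellTypeProfile

__all__ = [
    "PeakCluster",
    "TFActivityMatrix",
    "Dendrogram",
    "cluster_peaks",
    "filter_clusters",
    "assign_targets",
    "normalize_signals",
    "build_predictor_matrix",
    "fit_tf_models",
    "build_dendrogram",
    "bakers_gamma",
]

log = logging.getLogger(__name__)


@dataclass
class PeakCluster:
    cluster_id: int
    chrom: str
    mean_apex: float
    peak_index: np.ndarray  # row positions in the peak table
    tf_set: frozenset
    target_gene: str | None = None


@dataclass
class TFActivityMatrix:
    beta_raw: pd.DataFrame      # tf x cell type, unclipped coefficients
    beta: pd.DataFrame          # clipped at zero
    cv_mse: pd.Series           # per cell type CV mean square error
    associations: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class Dendrogram:
    linkage: np.ndarray
    leaves: list[str]


# ---------------------------------------------------------------------------
# peaks -> clusters -> targets


def cluster_peaks(peaks: pd.DataFrame, gap: int = 200) -> list[PeakCluster]:
    """Group peaks per chromosome; a new cluster starts at any apex gap
    >= ``gap`` bases. Every peak lands in exactly one cluster."""
    if (peaks["apex"] < 0).any():
        raise ValueError("negative peak apex position")
    clusters: list[PeakCluster] = []
    cid = 0
    for chrom, grp in peaks.groupby("chrom", sort=True):
        order = grp.sort_values("apex", kind="mergesort")
        apexes = order["apex"].to_numpy()
        idx = order.index.to_numpy()
        breaks = np.flatnonzero(np.diff(apexes) >= gap) + 1
        for seg in np.split(np.arange(apexes.size), breaks):
            members = idx[seg]
            clusters.append(
                PeakCluster(
                    cluster_id=cid,
                    chrom=chrom,
                    mean_apex=float(apexes[seg].mean()),
                    peak_index=members,
                    tf_set=frozenset(peaks.loc[members, "tf"]),
                )
            )
            cid += 1
    return clusters


def filter_clusters(
    clusters: list[PeakCluster], max_tfs: int = 70, min_tfs: int = 2
) -> list[PeakCluster]:
    """Drop single-TF clusters and HOT clusters (> ``max_tfs`` TFs)."""
    kept, n_hot, n_single = [], 0, 0
    for c in clusters:
        n = len(c.tf_set)
        if n > max_tfs:
            n_hot += 1
        elif n < min_tfs:
            n_single += 1
        else:
            kept.append(c)
    log.info(
        "filter_clusters: kept %d of %d (%d HOT >%d TFs, %d below %d TFs)",
        len(kept), len(clusters), n_hot, max_tfs, n_single, min_tfs,
    )
    return kept


def _nearest_two(tss_sorted: np.ndarray, pos: float) -> tuple[float, float]:
    """Distances to the nearest and second-nearest TSS on a chromosome."""
    i = np.searchsorted(tss_sorted, pos)
    cand = tss_sorted[max(0, i - 2): i + 2]
    dists = np.sort(np.abs(cand - pos))
    d1 = float(dists[0])
    d2 = float(dists[1]) if dists.size > 1 else float("inf")
    return d1, d2


def assign_targets(
    clusters: list[PeakCluster],
    tss_table: pd.DataFrame,
    max_dist: int = 2000,
    ratio: float = 1.5,
) -> list[PeakCluster]:
    """Assign each cluster to the gene with the nearest TSS when
    d1 <= ``max_dist`` and d2 >= ``ratio`` * d1 (unstranded distance
    from the cluster's mean apex).

    A cluster sitting exactly on a TSS (d1 = 0) is assigned outright;
    an exact d1 = d2 tie is ambiguous and left unassigned.
    """
    by_chrom = {}
    for chrom, grp in tss_table.groupby("chrom"):
        order = grp.sort_values("tss", kind="mergesort")
        by_chrom[chrom] = (order["tss"].to_numpy(dtype=float), order["gene_id"].to_numpy())
    for c in clusters:
        c.target_gene = None
        if c.chrom not in by_chrom:
            log.warning("no TSS on %s; cluster %d unassigned", c.chrom, c.cluster_id)
            continue
        tss, names = by_chrom[c.chrom]
        d1, d2 = _nearest_two(tss, c.mean_apex)
        if d1 > max_dist:
            continue
        if d1 == 0:
            pass  # ratio undefined; assign to the exact hit
        elif d2 == d1:
            continue  # ambiguous nearest gene
        elif d2 < ratio * d1:
            continue
        nearest = int(np.argmin(np.abs(tss - c.mean_apex)))
        c.target_gene = str(names[nearest])
    return clusters


def normalize_signals(peaks: pd.DataFrame) -> pd.DataFrame:
    """Rank peaks by strength within each (tf, stage) experiment and map
    to cumulative probability rank/N (average rank for ties)."""
    if (peaks["signal"] <= 0).any():
        raise ValueError("peak signal strengths must be positive")
    out = peaks.copy()
    norm = np.empty(len(out))
    for _, grp in out.groupby(["tf", "stage"], sort=False):
        ranks = stats.rankdata(grp["signal"].to_numpy(), method="average")
        norm[out.index.get_indexer(grp.index)] = ranks / len(grp)
    out["norm_signal"] = norm
    return out


def build_predictor_matrix(
    clusters: list[PeakCluster], peaks: pd.DataFrame
) -> pd.DataFrame:
    """Gene x TF matrix of max normalised signal over all peaks of the
    TF in clusters assigned to the gene."""
    if "norm_signal" not in peaks.columns:
        raise ValueError("run normalize_signals first")
    records: dict[tuple[str, str], float] = {}
    for c in clusters:
        if c.target_gene is None:
            continue
        sub = peaks.loc[c.peak_index]
        for tf, grp in sub.groupby("tf"):
            key = (c.target_gene, tf)
            v = float(grp["norm_signal"].max())
            if v > records.get(key, 0.0):
                records[key] = v
    if not records:
        return pd.DataFrame()
    ser = pd.Series(records)
    X = ser.unstack(fill_value=0.0)
    X.index.name = "gene"
    X.columns.name = "tf"
    return X.sort_index().sort_index(axis=1)


# ---------------------------------------------------------------------------
# regression


def fit_tf_models(
    X: pd.DataFrame,
    profile: CellTypeProfile,
    folds: int = 20,
    seed: int = 0,
    response: str = "log1p",
    l1_ratio: float = 1.0,
) -> TFActivityMatrix:
    """Per-cell-type L1-regularised regression of expression on TF signals.

    The response is log1p(scaled TPM) by default (``response="raw"`` uses
    the TPM scale directly); rows are restricted to genes present in both
    the predictor matrix and the profile. The penalty is chosen at the
    minimum of ``folds``-fold cross-validated MSE; ``l1_ratio`` < 1 turns
    the model into an elastic net with that mixing.
    """
    genes = X.index.intersection(profile.scaled_tpm.index)
    if len(genes) < folds:
        raise ValueError(f"{len(genes)} usable genes but {folds} CV folds requested")
    Xm = X.loc[genes].to_numpy(dtype=float)
    tf_ids = list(X.columns)
    types = list(profile.scaled_tpm.columns)

    beta_raw = np.zeros((len(tf_ids), len(types)))
    cv_mse = {}
    for j, ct in enumerate(types):
        y = profile.scaled_tpm.loc[genes, ct].to_numpy(dtype=float)
        if response == "log1p":
            y = np.log1p(y)
        elif response != "raw":
            raise ValueError("response must be 'log1p' or 'raw'")
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        if l1_ratio >= 1.0:
            model = LassoCV(cv=cv, random_state=seed, max_iter=50000, alphas=60)
        else:
            model = ElasticNetCV(
                cv=cv, l1_ratio=l1_ratio, random_state=seed, max_iter=50000, alphas=60
            )
        model.fit(Xm, y)
        beta_raw[:, j] = model.coef_
        i_alpha = int(np.argmin(model.mse_path_.mean(axis=-1)))
        cv_mse[ct] = float(model.mse_path_.mean(axis=-1)[i_alpha])

    beta_raw_df = pd.DataFrame(beta_raw, index=tf_ids, columns=types)
    beta = beta_raw_df.clip(lower=0.0)

    associations: set[tuple[str, str]] = set()
    robust = profile.robust_mask
    for tf in tf_ids:
        for ct in types:
            if beta.loc[tf, ct] <= 0:
                continue
            if robust is not None:
                if tf not in robust.index or not bool(robust.loc[tf, ct]):
                    continue
            associations.add((tf, ct))
    return TFActivityMatrix(
        beta_raw=beta_raw_df, beta=beta, cv_mse=pd.Series(cv_mse), associations=associations
    )


# ---------------------------------------------------------------------------
# dendrograms


def build_dendrogram(matrix: pd.DataFrame) -> Dendrogram:
    """Ward linkage over the matrix columns (cell types), Euclidean
    distance — the Ward.D2 convention."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 cell types to build a dendrogram")
    data = matrix.to_numpy(dtype=float).T
    if np.isnan(data).any():
        raise ValueError("dendrogram input contains NaN")
    Z = hierarchy.linkage(data, method="ward")
    return Dendrogram(linkage=Z, leaves=list(matrix.columns))


def _pair_depths(dend: Dendrogram) -> dict[tuple[str, str], int]:
    """For each leaf pair, the highest number of clusters at which the
    two leaves still share a cluster (n - merge step of their join)."""
    n = len(dend.leaves)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    depths: dict[tuple[str, str], int] = {}
    for step, (a, b, _, _) in enumerate(dend.linkage, start=1):
        la, lb = members.pop(int(a)), members.pop(int(b))
        k = n - step
        for i in la:
            for j in lb:
                key = tuple(sorted((dend.leaves[i], dend.leaves[j])))
                depths[key] = k
        members[n - 1 + step] = la + lb
    return depths


def bakers_gamma(tree_a: Dendrogram, tree_b: Dendrogram) -> float:
    """Spearman correlation of leaf-pair merge depths between two trees."""
    if set(tree_a.leaves) != set(tree_b.leaves):
        raise ValueError("dendrograms must share the same leaf set")
    da, db = _pair_depths(tree_a), _pair_depths(tree_b)
    keys = sorted(da)
    va = np.array([da[k] for k in keys], dtype=float)
    vb = np.array([db[k] for k in keys], dtype=float)
    rho = stats.spearmanr(va, vb).statistic
    return float(rho)


def to_newick(dend: Dendrogram) -> str:
    """Serialise the merge tree with branch lengths from merge heights."""
    n = len(dend.leaves)
    tree = hierarchy.to_tree(dend.linkage)

    def rec(node, parent_h):
        length = max(parent_h - node.dist, 0.0)
        if node.is_leaf():
            return f"{dend.leaves[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
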
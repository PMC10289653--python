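"""Ligand-receptor cell-cell communication scoring and signatures.

For every (LR pair, sender type, receiver type) triple the
communication score is the geometric mean of the ligand's pseudobulk
expression (mean log1p CPM) in the sender and the receptor's in the
receiver. Significance comes from a label permutation null: cell
labels are shuffled (preserving per-type cell counts), the pseudobulk
and all scores recomputed, and p = (1 + #{null >= observed}) /
(n_perm + 1). Scores passing the threshold populate a 3-D
communication tensor which a non-negative canonical polyadic (CP)
decomposition summarises into communication signatures: factors with
non-negative loading vectors over LR pairs, sender types and receiver
types.

The CP decomposition is a HALS (hierarchical alternating least
squares) implementation with random restarts; loading columns are
normalised to unit Euclidean norm with the scale absorbed into a
per-factor weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import _as_dense, _check_labels, aggregate_log1p_cpm

__all__ = [
    "CommunicationTensor",
    "SignatureSet",
    "LR_CLASSES",
    "communication_score",
    "score_tensor",
    "permutation_test",
    "build_tensor",
    "decompose",
    "rank_scan",
    "filter_by_class",
]

log = logging.getLogger(__name__)

LR_CLASSES = ("membrane-bound", "ECM", "secreted")

MODES = ("lr_pair", "sender", "receiver")


@dataclass
class CommunicationTensor:
    scores: np.ndarray           # masked scores, lr_pair x sender x receiver
    raw_scores: np.ndarray
    p_values: np.ndarray
    alpha: float
    lr_labels: list[str]
    cell_types: list[str]


@dataclass
class SignatureSet:
    rank: int
    loadings: dict[str, pd.DataFrame]  # mode -> element x factor, unit-norm columns
    weights: np.ndarray                # per-factor scale
    reconstruction_error: float        # relative Frobenius error


# ---------------------------------------------------------------------------
# scoring


def communication_score(expr: pd.DataFrame, ligand: str, receptor: str,
                        sender: str, receiver: str) -> float:
    """sqrt(expr[ligand, sender] * expr[receptor, receiver]); missing
    genes score 0 (logged) so tensor shapes stay consistent."""
    vals = []
    for g, ct in ((ligand, sender), (receptor, receiver)):
        if g not in expr.index:
            log.warning("gene %s absent from expression table; scoring 0", g)
            return 0.0
        vals.append(float(expr.loc[g, ct]))
    return float(np.sqrt(vals[0] * vals[1]))


def _expr_arrays(expr: pd.DataFrame, lr_pairs: pd.DataFrame):
    """Ligand and receptor expression blocks aligned to the pair list;
    missing genes become zero rows."""
    types = list(expr.columns)
    def rows(names):
        out = np.zeros((len(names), len(types)))
        for i, g in enumerate(names):
            if g in expr.index:
                out[i] = expr.loc[g].to_numpy()
            else:
                log.warning("gene %s absent from expression table; scoring 0", g)
        return out
    lig = rows(lr_pairs["ligand"].tolist())
    rec = rows(lr_pairs["receptor"].tolist())
    return lig, rec, types


def score_tensor(expr: pd.DataFrame, lr_pairs: pd.DataFrame) -> np.ndarray:
    """All scores as an (n_pairs, n_types, n_types) array."""
    lig, rec, _ = _expr_arrays(expr, lr_pairs)
    return np.sqrt(lig[:, :, None] * rec[:, None, :])


def permutation_test(
    counts,
    labels,
    lr_pairs: pd.DataFrame,
    genes: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed scores and label-permutation p-values.

    Only the ligand/receptor gene rows change across permutations (each
    cell's total count, hence its CPM denominator, is label-invariant),
    so the per-cell log1p CPM of those genes is precomputed once.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    dense = _as_dense(counts)
    labels = _check_labels(dense.shape[1], labels)
    totals = dense.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero-total cell; CPM undefined")

    expr = aggregate_log1p_cpm(dense, labels, genes=genes)
    observed = score_tensor(expr, lr_pairs)
    types = list(expr.columns)
    type_of = {ct: j for j, ct in enumerate(types)}

    used_genes = sorted(set(lr_pairs["ligand"]) | set(lr_pairs["receptor"]))
    gene_pos = {g: i for i, g in enumerate(genes)}
    rows = [gene_pos[g] for g in used_genes if g in gene_pos]
    present = [g for g in used_genes if g in gene_pos]
    logcpm = np.log1p(dense[rows] / totals[None, :] * 1e6)  # used x cells
    row_of = {g: i for i, g in enumerate(present)}

    lig_rows = np.array([row_of.get(g, -1) for g in lr_pairs["ligand"]])
    rec_rows = np.array([row_of.get(g, -1) for g in lr_pairs["receptor"]])
    label_idx = np.array([type_of[l] for l in labels])
    onehot = np.zeros((len(labels), len(types)))
    onehot[np.arange(len(labels)), label_idx] = 1.0
    n_per_type = onehot.sum(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    pad = np.zeros((1, len(types)))  # row for absent genes
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        means = (logcpm[:, perm] @ onehot) / n_per_type[None, :]
        means = np.concatenate([means, pad], axis=0)
        null = np.sqrt(means[lig_rows][:, :, None] * means[rec_rows][:, None, :])
        exceed += null >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    return observed, p


def build_tensor(
    scores: np.ndarray,
    p_values: np.ndarray,
    lr_labels: list[str],
    cell_types: list[str],
    alpha: float = 0.05,
) -> CommunicationTensor:
    """Zero out non-significant entries (p >= alpha)."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if scores.shape != p_values.shape:
        raise ValueError("scores and p-values must have matching shapes")
    mask = p_values < alpha
    kept = scores * mask
    log.info("communication tensor: %d of %d entries retained at alpha=%g",
             int(mask.sum()), mask.size, alpha)
    return CommunicationTensor(
        scores=kept, raw_scores=scores, p_values=p_values,
        alpha=alpha, lr_labels=list(lr_labels), cell_types=list(cell_types),
    )


# ---------------------------------------------------------------------------
# non-negative CP decomposition (HALS)


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _nncp_hals(
    T: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    n_iter: int = 400,
    tol: float = 1e-9,
    init: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], float]:
    """One HALS run; returns factor matrices and relative error."""
    dims = T.shape
    norm_T = np.linalg.norm(T)
    if init is None:
        factors = [rng.uniform(0.1, 1.0, size=(d, rank)) for d in dims]
    else:
        factors = [f.copy() for f in init]
    unfolds = [_unfold(T, m) for m in range(3)]
    prev = np.inf
    for _ in range(n_iter):
        for m in range(3):
            others = [factors[i] for i in range(3) if i != m]
            # khatri-rao ordering must match _unfold's reshape order
            kr = _khatri_rao(others[0], others[1])
            G = (others[0].T @ others[0]) * (others[1].T @ others[1])
            M = unfolds[m] @ kr
            A = factors[m]
            for r in range(rank):
                g = G[r, r]
                if g < 1e-14:
                    A[:, r] = 0.0
                    continue
                upd = (M[:, r] - A @ G[:, r] + A[:, r] * g) / g
                A[:, r] = np.maximum(upd, 0.0)
            # revive dead components so the rank is actually used
            dead = np.flatnonzero(A.sum(axis=0) == 0)
            for r in dead:
                A[:, r] = rng.uniform(0.0, 1e-3, size=A.shape[0])
        err = _rel_error(T, factors, norm_T)
        if prev - err < tol:
            break
        prev = err
    return factors, _rel_error(T, factors, norm_T)


def _reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    a, b, c = factors
    return np.einsum("ir,jr,kr->ijk", a, b, c)


def _rel_error(T, factors, norm_T=None) -> float:
    norm_T = norm_T if norm_T is not None else np.linalg.norm(T)
    if norm_T == 0:
        return 0.0
    return float(np.linalg.norm(T - _reconstruct(factors)) / norm_T)


def decompose(
    tensor: CommunicationTensor | np.ndarray,
    rank: int,
    n_restarts: int = 5,
    seed: int = 0,
    n_iter: int = 400,
    lr_labels: list[str] | None = None,
    cell_types: list[str] | None = None,
    _init: list[np.ndarray] | None = None,
) -> SignatureSet:
    """Best-of-restarts non-negative CP decomposition into signatures."""
    if isinstance(tensor, CommunicationTensor):
        T = tensor.scores
        lr_labels = tensor.lr_labels
        cell_types = tensor.cell_types
    else:
        T = np.asarray(tensor, dtype=float)
    if rank < 1 or rank > min(T.shape):
        raise ValueError(f"rank {rank} outside [1, {min(T.shape)}]")
    if (T < 0).any():
        raise ValueError("tensor must be non-negative")
    rng = np.random.default_rng(seed)
    best: tuple[float, list[np.ndarray]] | None = None
    starts = n_restarts + (1 if _init is not None else 0)
    for s in range(starts):
        init = _init if (_init is not None and s == 0) else None
        factors, err = _nncp_hals(T, rank, rng, n_iter=n_iter, init=init)
        if best is None or err < best[0]:
            best = (err, factors)
    err, factors = best

    # unit-norm columns per mode, scale absorbed into weights
    weights = np.ones(rank)
    normed = []
    for f in factors:
        norms = np.linalg.norm(f, axis=0)
        norms[norms == 0] = 1.0
        weights *= norms
        normed.append(f / norms)
    order = np.argsort(-weights)
    weights = weights[order]
    normed = [f[:, order] for f in normed]

    idx = {
        "lr_pair": lr_labels or [f"pair{i}" for i in range(T.shape[0])],
        "sender": cell_types or [f"ct{i}" for i in range(T.shape[1])],
        "receiver": cell_types or [f"ct{i}" for i in range(T.shape[2])],
    }
    loadings = {
        mode: pd.DataFrame(
            normed[m], index=idx[mode], columns=[f"factor{r+1}" for r in range(rank)]
        )
        for m, mode in enumerate(MODES)
    }
    return SignatureSet(rank=rank, loadings=loadings, weights=weights,
                        reconstruction_error=err)


def rank_scan(
    tensor: CommunicationTensor | np.ndarray,
    ranks,
    seed: int = 0,
    n_restarts: int = 3,
) -> pd.DataFrame:
    """Reconstruction error per candidate rank, with warm restarts so
    the error is non-increasing in rank; the suggested rank is the
    elbow (maximum second difference of the error curve)."""
    ranks = sorted(set(int(r) for r in ranks))
    if not ranks:
        raise ValueError("ranks must be non-empty")
    T = tensor.scores if isinstance(tensor, CommunicationTensor) else np.asarray(tensor)
    rng = np.random.default_rng(seed)
    rows = []
    prev_factors: list[np.ndarray] | None = None
    for r in ranks:
        init = None
        if prev_factors is not None and prev_factors[0].shape[1] < r:
            extra = r - prev_factors[0].shape[1]
            init = [
                np.concatenate([f, rng.uniform(0, 1e-3, size=(f.shape[0], extra))], axis=1)
                for f in prev_factors
            ]
        sig = decompose(T, rank=r, n_restarts=n_restarts,
                        seed=int(rng.integers(2**31)), _init=init)
        # carry the (denormalised) factors forward as a warm start
        prev_factors = [
            sig.loadings[mode].to_numpy() * (sig.weights ** (1 / 3))[None, :]
            for mode in MODES
        ]
        rows.append({"rank": r, "rel_error": sig.reconstruction_error})
    table = pd.DataFrame(rows)
    # enforce monotonicity against restart noise before the elbow search
    table["rel_error"] = np.minimum.accumulate(table["rel_error"])
    err = table["rel_error"].to_numpy()
    if len(err) >= 3:
        second = err[:-2] - 2 * err[1:-1] + err[2:]
        table.attrs["suggested_rank"] = int(table["rank"].iloc[int(np.argmax(second)) + 1])
    else:
        table.attrs["suggested_rank"] = int(table["rank"].iloc[-1])
    return table


def filter_by_class(
    lr_pairs: pd.DataFrame, tensor: CommunicationTensor, classes
) -> CommunicationTensor:
    """Restrict the LR mode to pairs whose class intersects ``classes``."""
    classes = {classes} if isinstance(classes, str) else set(classes)
    unknown = classes - set(LR_CLASSES)
    if unknown:
        raise ValueError(f"unknown LR class(es): {sorted(unknown)}")
    keep = lr_pairs["lr_class"].map(
        lambda c: bool(set(str(c).split("|")) & classes)
    ).to_numpy()
    idx = np.flatnonzero(keep)
    return CommunicationTensor(
        scores=tensor.scores[idx],
        raw_scores=tensor.raw_scores[idx],
        p_values=tensor.p_values[idx],
        alpha=tensor.alpha,
        lr_labels=[tensor.lr_labels[i] for i in idx],
        cell_types=tensor.cell_types,
    )
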
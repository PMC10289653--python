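"""Synthetic whole-body atlas generator with planted ground truth.

Emulates the statistical structure of a multi-cell-type single-cell UMI
experiment together with the auxiliary genomics inputs the downstream
analyses consume:

* a gene x cell negative-binomial count matrix over ``n_cell_types``
  labelled cell types, with planted housekeeping genes (equal mean in
  every type), per-type marker genes, TF genes, TF-target genes whose
  means respond to planted TF activities, and ligand/receptor genes
  carrying planted communication signatures;
* a ChIP-Seq-like peak table whose clusters exercise every rule of the
  peak-to-target assignment procedure (200-bp gap clustering, the
  2000-bp TSS window, the 1.5x nearest/next-TSS ratio, >70-TF HOT
  decoys, single-TF decoy peaks);
* a one-TSS-per-gene annotation on a small synthetic genome;
* a ligand-receptor pair list with class labels, a subset of which make
  up planted sender/receiver signatures.

Every planted feature is recorded in a :class:`SyntheticTruth` so that
recovery by the analysis stages can be scored exactly.

Cell types are organised into groups of three that share transcription
factors and target programs; this plants a two-level hierarchy that the
dendrogram comparison stage can try to recover. TF genes themselves are
expressed at a low, nearly type-independent level (as is typical for
regulators), so TF *expression* is a deliberately poor proxy for the
planted hierarchy while TF *activity* is a good one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_counts",
    "simulate_peaks",
    "simulate_lr_structure",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

LR_CLASSES = ("membrane-bound", "ECM", "secreted")


@dataclass
class SimConfig:
    """Parameters of the synthetic atlas.

    Defaults are sized for minute-scale runs while keeping every
    downstream recovery stable: 12 cell types x 150 cells, 2,000 genes,
    40 TFs, 60 LR pairs, 3 communication signatures.
    """

    n_cell_types: int = 12
    cells_per_type: int | list[int] = 150
    n_genes: int = 2000
    n_housekeeping: int = 100
    n_markers_per_type: int = 20
    nb_dispersion: float = 10.0  # NB size theta; var = mu + mu^2/theta
    libsize_lognormal_mu: float = 0.0
    libsize_lognormal_sigma: float = 0.35
    n_tfs: int = 40
    targets_per_tf: int = 25
    tf_activity_scale: float = 2.0
    n_lr_pairs: int = 60
    n_signatures: int = 3
    lr_pairs_per_signature: int = 8
    genome_n_chroms: int = 6
    chrom_length_bp: int = 8_000_000
    n_decoy_hot: int = 2
    n_singleton_peaks: int = 30
    # secondary effect-size knobs (per-gene means are in counts/cell
    # before per-type totals are rescaled to total_umi_per_cell)
    total_umi_per_cell: float = 1500.0
    background_sigma: float = 1.4   # cross-type log-normal sd of background genes
    marker_fold_floor: float = 2.0  # marker mean range (loguniform floor/ceiling)
    marker_fold_ceil: float = 6.0
    tf_gene_mean: float = 0.15      # TF genes: low, nearly flat expression
    tf_expression_bump: float = 0.05
    target_baseline: float = 0.3
    lr_boost: float = 8.0           # signature ligand/receptor mean in active types
    off_mean: float = 0.02          # "off" mean for markers / signature LR genes
    seed: int = 1

    def __post_init__(self) -> None:
        counts = [
            self.n_cell_types,
            self.n_genes,
            self.n_tfs,
            self.targets_per_tf,
            self.genome_n_chroms,
            self.chrom_length_bp,
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all structural counts must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.tf_activity_scale <= 0:
            raise ValueError("tf_activity_scale must be > 0")
        if self.n_signatures > self.n_lr_pairs:
            raise ValueError("n_signatures may not exceed n_lr_pairs")
        if self.n_signatures * self.lr_pairs_per_signature > self.n_lr_pairs:
            raise ValueError("signature LR pairs exceed n_lr_pairs")
        if self.reserved_genes() > self.n_genes:
            raise ValueError(
                "n_housekeeping + markers + TFs + TF targets + signature LR genes "
                f"({self.reserved_genes()}) exceed n_genes ({self.n_genes})"
            )

    @property
    def cells_per_type_list(self) -> list[int]:
        if isinstance(self.cells_per_type, int):
            return [self.cells_per_type] * self.n_cell_types
        if len(self.cells_per_type) != self.n_cell_types:
            raise ValueError("cells_per_type list length must equal n_cell_types")
        return list(self.cells_per_type)

    @property
    def n_target_genes(self) -> int:
        # each target gene is co-bound by two TFs of the same group
        return self.n_tfs * self.targets_per_tf // 2

    def reserved_genes(self) -> int:
        n_sig_genes = 2 * self.n_signatures * self.lr_pairs_per_signature
        return (
            self.n_housekeeping
            + self.n_cell_types * self.n_markers_per_type
            + self.n_tfs
            + self.n_target_genes
            + n_sig_genes
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth used as the recovery oracle."""

    housekeeping_genes: set[str] = field(default_factory=set)
    tf_activity_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    tf_targets: dict[str, set[str]] = field(default_factory=dict)
    lr_signatures: list[dict] = field(default_factory=list)
    decoy_hot_regions: list[tuple[str, int, int]] = field(default_factory=list)
    singleton_peaks: set[str] = field(default_factory=set)  # "chrom:apex:tf"

    def to_json(self) -> str:
        obj = {
            "housekeeping_genes": sorted(self.housekeeping_genes),
            "tf_activity_weights": [
                {"tf": t, "cell_type": k, "weight": w}
                for (t, k), w in sorted(self.tf_activity_weights.items())
            ],
            "tf_targets": {t: sorted(g) for t, g in sorted(self.tf_targets.items())},
            "lr_signatures": [
                {
                    "senders": sorted(s["senders"]),
                    "receivers": sorted(s["receivers"]),
                    "lr_pairs": sorted(map(list, s["lr_pairs"])),
                }
                for s in self.lr_signatures
            ],
            "decoy_hot_regions": [list(r) for r in self.decoy_hot_regions],
            "singleton_peaks": sorted(self.singleton_peaks),
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        return cls(
            housekeeping_genes=set(obj["housekeeping_genes"]),
            tf_activity_weights={
                (d["tf"], d["cell_type"]): d["weight"]
                for d in obj["tf_activity_weights"]
            },
            tf_targets={t: set(g) for t, g in obj["tf_targets"].items()},
            lr_signatures=[
                {
                    "senders": set(s["senders"]),
                    "receivers": set(s["receivers"]),
                    "lr_pairs": {tuple(p) for p in s["lr_pairs"]},
                }
                for s in obj["lr_signatures"]
            ],
            decoy_hot_regions=[tuple(r) for r in obj["decoy_hot_regions"]],
            singleton_peaks=set(obj["singleton_peaks"]),
        )


@dataclass
class SyntheticDataset:
    counts: sparse.csr_matrix  # gene x cell
    genes: list[str]
    cells: list[str]
    cell_labels: pd.Series  # index cell id -> cell type
    gene_annotation: pd.DataFrame | None = None  # gene_id, chrom, tss, strand
    peaks: pd.DataFrame | None = None  # chrom, apex, tf, stage, signal
    lr_pairs: pd.DataFrame | None = None  # ligand, receptor, lr_class
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)
    config: SimConfig | None = None
    # per-gene per-type mean matrix retained so later stages can add
    # planted structure and redraw affected rows deterministically
    mu: np.ndarray | None = None

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_labels.unique())


# ---------------------------------------------------------------------------
# gene-panel layout


@dataclass
class _Layout:
    hk: np.ndarray
    markers: np.ndarray          # (n_types, n_markers)
    tf_genes: np.ndarray
    targets: np.ndarray
    sig_lr: np.ndarray
    background: np.ndarray


def _layout(config: SimConfig) -> _Layout:
    n = 0

    def take(k: int) -> np.ndarray:
        nonlocal n
        idx = np.arange(n, n + k)
        n += k
        return idx

    hk = take(config.n_housekeeping)
    markers = take(config.n_cell_types * config.n_markers_per_type).reshape(
        config.n_cell_types, config.n_markers_per_type
    )
    tf_genes = take(config.n_tfs)
    targets = take(config.n_target_genes)
    sig_lr = take(2 * config.n_signatures * config.lr_pairs_per_signature)
    background = np.arange(n, config.n_genes)
    return _Layout(hk, markers, tf_genes, targets, sig_lr, background)


def _gene_names(config: SimConfig) -> list[str]:
    return [f"g{i:05d}" for i in range(config.n_genes)]


def _tf_names(config: SimConfig, genes: list[str]) -> list[str]:
    lay = _layout(config)
    return [genes[i] for i in lay.tf_genes]


def _groups(config: SimConfig) -> list[list[int]]:
    """Cell-type groups of three (last group absorbs any remainder)."""
    k = config.n_cell_types
    n_groups = max(1, k // 3)
    groups: list[list[int]] = [[] for _ in range(n_groups)]
    for i in range(k):
        groups[min(i // 3, n_groups - 1)].append(i)
    return groups


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# stage 1: counts


def simulate_counts(config: SimConfig) -> SyntheticDataset:
    """Draw the labelled count matrix and plant housekeeping/marker/TF
    structure. Peaks and LR structure are added by the later stages."""
    rng = np.random.default_rng(config.seed)
    lay = _layout(config)
    genes = _gene_names(config)
    k = config.n_cell_types
    cell_types = [f"ct{j:02d}" for j in range(k)]
    groups = _groups(config)

    mu = np.zeros((config.n_genes, k))

    # housekeeping: one mean per gene, identical in every type
    hk_mu = np.exp(rng.uniform(np.log(0.5), np.log(4.0), size=lay.hk.size))
    mu[lay.hk, :] = hk_mu[:, None]

    # markers: strong in the owning type, near-off elsewhere
    for j in range(k):
        m = lay.markers[j]
        on = np.exp(
            rng.uniform(
                np.log(config.marker_fold_floor),
                np.log(config.marker_fold_ceil),
                size=m.size,
            )
        )
        mu[m, :] = config.off_mean
        mu[m, j] = on

    # TF activity weights: each TF is active across its cell-type group
    truth = SyntheticTruth()
    tf_names = [genes[i] for i in lay.tf_genes]
    weights = np.zeros((config.n_tfs, k))
    tf_group = [g % len(groups) for g in range(config.n_tfs)]
    for t in range(config.n_tfs):
        for j in groups[tf_group[t]]:
            w = rng.uniform(0.5, 1.0)
            weights[t, j] = w
            truth.tf_activity_weights[(tf_names[t], cell_types[j])] = float(w)

    # TF genes: low expression with cross-type heterogeneity unrelated to
    # the planted hierarchy, plus a weak bump where the TF is active —
    # TF expression is a deliberately poor proxy for TF activity
    tf_het = rng.lognormal(0.0, config.background_sigma, size=(config.n_tfs, k))
    mu[lay.tf_genes, :] = config.tf_gene_mean * tf_het
    mu[lay.tf_genes, :] += config.tf_expression_bump * (weights > 0)

    # TF targets: each target gene is co-bound by two TFs of one group;
    # its mean responds additively to the planted activities
    tfs_by_group: list[list[int]] = [[] for _ in groups]
    for t, g in enumerate(tf_group):
        tfs_by_group[g].append(t)
    if any(len(tl) < 2 for tl in tfs_by_group):
        raise ValueError(
            "each cell-type group needs >= 2 TFs to co-bind targets; "
            "increase n_tfs or reduce n_cell_types"
        )
    per_group = lay.targets.size // len(groups)
    signal = np.zeros((config.n_tfs, config.n_genes))  # planted binding strength
    truth.tf_targets = {name: set() for name in tf_names}
    pos = 0
    binders_of: dict[int, tuple[int, int]] = {}
    for g, tf_list in enumerate(tfs_by_group):
        m = len(tf_list)
        n_here = per_group if g < len(groups) - 1 else lay.targets.size - pos
        for j in range(n_here):
            gene_idx = lay.targets[pos + j]
            a = tf_list[j % m]
            b = tf_list[(j % m + 1 + (j // m) % max(m - 1, 1)) % m]
            if b == a:
                b = tf_list[(j % m + 1) % m]
            for t in (a, b):
                s = rng.uniform(0.3, 1.0)
                signal[t, gene_idx] = s
                truth.tf_targets[tf_names[t]].add(genes[gene_idx])
            binders_of[int(gene_idx)] = (a, b)
        pos += n_here
    mu[lay.targets, :] = config.target_baseline
    mu[lay.targets, :] += config.tf_activity_scale * (
        signal[:, lay.targets].T @ weights
    )

    # signature LR genes: off everywhere until simulate_lr_structure
    mu[lay.sig_lr, :] = config.off_mean

    # background: per-gene base level with heavy cross-type heterogeneity
    if lay.background.size:
        base = np.exp(rng.uniform(np.log(0.2), np.log(2.0), size=lay.background.size))
        het = rng.lognormal(0.0, config.background_sigma, size=(lay.background.size, k))
        mu[lay.background, :] = base[:, None] * het

    # bring every type to the same expected UMI total so that library
    # size is the only per-cell depth factor; the background genes absorb
    # the per-type difference so structured genes (housekeeping above all)
    # keep exactly the means drawn for them
    if lay.background.size:
        structured = mu.sum(axis=0) - mu[lay.background, :].sum(axis=0)
        remainder = config.total_umi_per_cell - structured
        if np.any(remainder <= 0):
            raise ValueError(
                "total_umi_per_cell too small for the structured gene content; "
                "increase it or reduce effect sizes"
            )
        mu[lay.background, :] *= remainder / mu[lay.background, :].sum(axis=0)
    else:
        mu *= config.total_umi_per_cell / mu.sum(axis=0, keepdims=True)

    truth.housekeeping_genes = {genes[i] for i in lay.hk}

    # draw cells
    cells_per_type = config.cells_per_type_list
    labels: list[str] = []
    cols: list[np.ndarray] = []
    libs: list[np.ndarray] = []
    for j, n_cells in enumerate(cells_per_type):
        lib = rng.lognormal(
            config.libsize_lognormal_mu, config.libsize_lognormal_sigma, size=n_cells
        )
        mean = mu[:, j][:, None] * lib[None, :]
        cols.append(_draw_nb(rng, mean, config.nb_dispersion))
        libs.append(lib)
        labels.extend([cell_types[j]] * n_cells)
    counts = np.concatenate(cols, axis=1)

    # guard the column-sums-positive invariant (astronomically rare)
    empty = np.flatnonzero(counts.sum(axis=0) == 0)
    for c in empty:
        counts[int(rng.integers(config.n_genes)), c] = 1

    cells = [f"cell{i:05d}" for i in range(counts.shape[1])]
    ds = SyntheticDataset(
        counts=sparse.csr_matrix(counts),
        genes=genes,
        cells=cells,
        cell_labels=pd.Series(labels, index=cells, name="cell_type"),
        truth=truth,
        config=config,
        mu=mu,
    )
    ds._signal = signal  # type: ignore[attr-defined]
    ds._binders_of = binders_of  # type: ignore[attr-defined]
    ds._lib = np.concatenate(libs)  # type: ignore[attr-defined]
    return ds


# ---------------------------------------------------------------------------
# stage 2: genome, TSS annotation, peaks


def _place_genes(config: SimConfig, genes: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """One TSS per gene on a jittered grid; wide spacing guarantees the
    nearest/next-TSS 1.5x rule is satisfiable for promoter-proximal peaks."""
    n = len(genes)
    per_chrom = int(np.ceil(n / config.genome_n_chroms))
    spacing = config.chrom_length_bp // (per_chrom + 1)
    if spacing < 12_000:
        raise ValueError(
            "genome too small to place peaks without violating the nearest/next "
            f"TSS ratio rule (inter-TSS spacing {spacing} < 12000 bp); increase "
            "chrom_length_bp or genome_n_chroms"
        )
    rows = []
    order = rng.permutation(n)
    for slot, gi in enumerate(order):
        chrom = f"chr{slot % config.genome_n_chroms + 1}"
        rank_on_chrom = slot // config.genome_n_chroms
        tss = (rank_on_chrom + 1) * spacing + int(rng.integers(-3000, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((genes[gi], chrom, tss, strand))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return ann.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)


def simulate_peaks(dataset: SyntheticDataset, config: SimConfig | None = None) -> SyntheticDataset:
    """Emit the TSS annotation plus a peak table realising the planted
    TF->target map, together with decoy HOT regions and single-TF peaks."""
    config = config or dataset.config
    assert config is not None
    if not dataset.truth.tf_targets:
        raise ValueError("simulate_counts must run first (tf_targets empty)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = dataset.genes
    lay = _layout(config)
    ann = _place_genes(config, genes, rng)
    tss_of = dict(zip(ann.gene_id, zip(ann.chrom, ann.tss)))
    tf_names = [genes[i] for i in lay.tf_genes]
    signal: np.ndarray = dataset._signal  # type: ignore[attr-defined]
    binders_of: dict[int, tuple[int, int]] = dataset._binders_of  # type: ignore[attr-defined]

    rows: list[tuple[str, int, str, str, float]] = []
    # planted clusters: the two binders of each target gene get one peak
    # each, < 200 bp apart, within ~900 bp of the TSS; the raw strength
    # is monotone in the planted binding signal (rank-normalisation
    # downstream preserves the order within each TF's experiment)
    for gene_idx, (a, b) in binders_of.items():
        chrom, tss = tss_of[genes[gene_idx]]
        o1 = int(rng.integers(-800, 801))
        o2 = o1 + int(rng.integers(-150, 151))
        for t, off in ((a, o1), (b, o2)):
            raw = 100.0 * signal[t, gene_idx] + rng.uniform(0, 1e-3)
            rows.append((chrom, max(tss + off, 0), tf_names[t], "YA", raw))

    # singleton decoys: one lone real-TF peak near a non-target gene TSS
    non_target = [genes[i] for i in np.concatenate([lay.hk, lay.background[:200]])]
    pick = rng.choice(len(non_target), size=min(config.n_singleton_peaks, len(non_target)), replace=False)
    for gi in pick:
        chrom, tss = tss_of[non_target[gi]]
        apex = max(tss + int(rng.integers(-1500, 1501)), 0)
        tf = tf_names[int(rng.integers(len(tf_names)))]
        rows.append((chrom, apex, tf, "YA", float(rng.uniform(10, 90))))
        dataset.truth.singleton_peaks.add(f"{chrom}:{apex}:{tf}")

    # HOT decoys: >70 distinct TFs packed with < 200-bp gaps, placed in
    # an intergenic desert so they never merge with planted clusters
    n_hot_tfs = 75
    hot_extra = [f"hot{j:03d}" for j in range(max(0, n_hot_tfs - len(tf_names)))]
    hot_tfs = (tf_names + hot_extra)[:n_hot_tfs]
    per_chrom_ann = {c: g.tss.to_numpy() for c, g in ann.groupby("chrom")}
    for h in range(config.n_decoy_hot):
        chrom = f"chr{h % config.genome_n_chroms + 1}"
        tss_arr = per_chrom_ann[chrom]
        anchor = int(tss_arr[min(5 + 3 * h, len(tss_arr) - 2)])
        start = anchor + 6000
        apex = start
        first = apex
        for tf in hot_tfs:
            rows.append((chrom, apex, tf, "YA", float(rng.uniform(10, 90))))
            apex += int(rng.integers(20, 180))
        dataset.truth.decoy_hot_regions.append((chrom, first, apex))

    peaks = pd.DataFrame(rows, columns=["chrom", "apex", "tf", "stage", "signal"])
    peaks = peaks.sort_values(["chrom", "apex"], kind="mergesort").reset_index(drop=True)
    dataset.gene_annotation = ann
    dataset.peaks = peaks
    return dataset


# ---------------------------------------------------------------------------
# stage 3: ligand-receptor structure


def simulate_lr_structure(dataset: SyntheticDataset, config: SimConfig | None = None) -> SyntheticDataset:
    """Plant communication signatures and emit the LR pair list.

    Signature pairs use dedicated ligand/receptor genes expressed only in
    the signature's sender (ligand) or receiver (receptor) cell types;
    the affected count rows are redrawn from the boosted means.
    Non-signature pairs reuse broadly expressed genes (the housekeeping
    pool when present), so their expression carries no cell-type signal.
    """
    config = config or dataset.config
    assert config is not None
    if dataset.counts is None:
        raise ValueError("simulate_counts must run first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lay = _layout(config)
    genes = dataset.genes
    k = config.n_cell_types
    cell_types = sorted(dataset.cell_labels.unique())

    pairs: list[tuple[str, str, str]] = []
    sig_gene_rows: list[int] = []
    mu = dataset.mu
    assert mu is not None

    # disjoint sender/receiver sets walked around the type circle
    slot = 0
    for s in range(config.n_signatures):
        senders = {cell_types[(slot + i) % k] for i in range(2)}
        receivers = {cell_types[(slot + 2 + i) % k] for i in range(2)}
        slot += 4
        sig_pairs = set()
        for p in range(config.lr_pairs_per_signature):
            base = 2 * (s * config.lr_pairs_per_signature + p)
            lig_idx, rec_idx = lay.sig_lr[base], lay.sig_lr[base + 1]
            lig, rec = genes[lig_idx], genes[rec_idx]
            boost = rng.uniform(0.75, 1.25) * config.lr_boost
            mu[lig_idx, :] = config.off_mean
            mu[rec_idx, :] = config.off_mean
            for j, ct in enumerate(cell_types):
                if ct in senders:
                    mu[lig_idx, j] = boost
                if ct in receivers:
                    mu[rec_idx, j] = boost
            sig_gene_rows += [int(lig_idx), int(rec_idx)]
            cls = LR_CLASSES[int(rng.integers(len(LR_CLASSES)))]
            pairs.append((lig, rec, cls))
            sig_pairs.add((lig, rec))
        dataset.truth.lr_signatures.append(
            {"senders": senders, "receivers": receivers, "lr_pairs": sig_pairs}
        )

    # non-signature pairs: type-independent expression
    n_rest = config.n_lr_pairs - config.n_signatures * config.lr_pairs_per_signature
    pool = lay.hk if lay.hk.size else lay.background
    if pool.size == 0:
        raise ValueError("no gene pool available for non-signature LR pairs")
    for _ in range(n_rest):
        lig = genes[int(pool[rng.integers(pool.size)])]
        rec = genes[int(pool[rng.integers(pool.size)])]
        cls = LR_CLASSES[int(rng.integers(len(LR_CLASSES)))]
        pairs.append((lig, rec, cls))

    # redraw counts for the boosted rows from the updated means
    if sig_gene_rows:
        counts = dataset.counts.tolil()
        labels = dataset.cell_labels.to_numpy()
        type_index = {ct: j for j, ct in enumerate(cell_types)}
        col_type = np.array([type_index[l] for l in labels])
        lib = getattr(dataset, "_lib", None)
        if lib is None:
            lib = np.ones(len(dataset.cells))
        sub_mu = mu[np.array(sig_gene_rows)][:, col_type] * lib[None, :]
        new_rows = _draw_nb(rng, sub_mu, config.nb_dispersion)
        for r, gi in enumerate(sig_gene_rows):
            counts[gi, :] = new_rows[r]
        dataset.counts = counts.tocsr()

    dataset.lr_pairs = pd.DataFrame(pairs, columns=["ligand", "receptor", "lr_class"])
    return dataset


def simulate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Run all three generation stages and return the complete dataset."""
    config = config or SimConfig()
    ds = simulate_counts(config)
    ds = simulate_peaks(ds, config)
    ds = simulate_lr_structure(ds, config)
    return ds


# ---------------------------------------------------------------------------
# I/O


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Write the dataset as Matrix Market counts + TSV tables + JSON truth."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(d / "counts.mtx"), sparse.coo_matrix(dataset.counts))
    pd.Series(dataset.genes).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(dataset.cells).to_csv(d / "cells.tsv", sep="\t", index=False, header=False)
    dataset.cell_labels.rename_axis("cell_id").reset_index().to_csv(
        d / "labels.tsv", sep="\t", index=False
    )
    if dataset.gene_annotation is not None:
        dataset.gene_annotation.to_csv(d / "tss.tsv", sep="\t", index=False)
    if dataset.peaks is not None:
        dataset.peaks[["chrom", "apex", "tf", "stage", "signal"]].to_csv(
            d / "peaks.tsv", sep="\t", index=False
        )
    if dataset.lr_pairs is not None:
        dataset.lr_pairs.to_csv(d / "lr_pairs.tsv", sep="\t", index=False)
    (d / "truth.json").write_text(dataset.truth.to_json())
    if dataset.config is not None:
        (d / "config.json").write_text(
            json.dumps(dataclasses.asdict(dataset.config), indent=1, sort_keys=True)
        )


def read_dataset(directory: str | Path) -> SyntheticDataset:
    d = Path(directory)
    counts = sparse.csr_matrix(spio.mmread(str(d / "counts.mtx")))
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(d / "cells.tsv", sep="\t", header=None)[0].tolist()
    labels = pd.read_csv(d / "labels.tsv", sep="\t").set_index("cell_id")["cell_type"]
    config = None
    if (d / "config.json").exists():
        config = SimConfig(**json.loads((d / "config.json").read_text()))
    ds = SyntheticDataset(
        counts=counts,
        genes=genes,
        cells=cells,
        cell_labels=labels,
        config=config,
    )
    if (d / "tss.tsv").exists():
        ds.gene_annotation = pd.read_csv(d / "tss.tsv", sep="\t")
    if (d / "peaks.tsv").exists():
        ds.peaks = pd.read_csv(d / "peaks.tsv", sep="\t")
    if (d / "lr_pairs.tsv").exists():
        ds.lr_pairs = pd.read_csv(d / "lr_pairs.tsv", sep="\t")
    if (d / "truth.json").exists():
        ds.truth = SyntheticTruth.from_json((d / "truth.json").read_text())
    return ds
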
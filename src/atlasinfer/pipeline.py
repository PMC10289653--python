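"""End-to-end pipeline: simulate -> aggregate -> coverage ->
housekeeping -> tfactivity -> cci -> report.

Each stage reads its inputs from the run directory, writes plain-text
outputs there, and records a manifest entry (parameter snapshot, input
and output SHA-256 hashes, wall clock). A stage is skipped on rerun
when its parameters and input hashes are unchanged. A single top-level
seed fans out to per-stage seeds by stable hashing so stages are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import cci as cci_mod
from . import coverage as cov
from . import housekeeping as hk
from . import simdata
from . import tfactivity as tfa

__all__ = ["RunConfig", "run_pipeline", "report", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "aggregate", "coverage", "housekeeping", "tfactivity", "cci")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    n_boot: int = 1000
    coverage_iters: int = 100
    coverage_sizes: str | list[int] = "auto"
    gini_threshold: float = 0.3
    gap: int = 200
    max_dist: int = 2000
    ratio: float = 1.5
    hot_max: int = 70
    min_tfs: int = 2
    folds: int = 20
    response: str = "log1p"
    n_perm: int = 1000
    alpha: float = 0.05
    rank: int = 3
    n_restarts: int = 5
    make_report: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        obj = yaml.safe_load(Path(path).read_text())
        return cls(**obj)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 100003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index_label="gene") -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)


def _stage_params(config: RunConfig, stage: str) -> dict:
    keys = {
        "simulate": ["seed", "sim"],
        "aggregate": ["n_boot"],
        "coverage": ["coverage_iters", "coverage_sizes"],
        "housekeeping": ["gini_threshold"],
        "tfactivity": ["gap", "max_dist", "ratio", "hot_max", "min_tfs", "folds", "response"],
        "cci": ["n_perm", "alpha", "rank", "n_restarts"],
    }[stage]
    return {k: getattr(config, k) for k in keys}


_INPUTS = {
    "simulate": [],
    "aggregate": ["data/counts.mtx", "data/labels.tsv"],
    "coverage": ["data/counts.mtx", "data/labels.tsv"],
    "housekeeping": ["aggregate/scaled_tpm.tsv", "aggregate/pct_expressed.tsv"],
    "tfactivity": ["data/peaks.tsv", "data/tss.tsv", "aggregate/scaled_tpm.tsv",
                   "aggregate/robust_mask.tsv"],
    "cci": ["data/counts.mtx", "data/labels.tsv", "data/lr_pairs.tsv"],
}


def _load_counts(out: Path):
    ds = simdata.read_dataset(out / "data")
    labels = ds.cell_labels.loc[ds.cells].to_numpy()
    return ds, labels


def _run_simulate(config: RunConfig, out: Path) -> list[Path]:
    sim_cfg = simdata.SimConfig(**{"seed": config.stage_seed("simulate"), **config.sim})
    ds = simdata.simulate_dataset(sim_cfg)
    simdata.write_dataset(ds, out / "data")
    return sorted((out / "data").iterdir())


def _run_aggregate(config: RunConfig, out: Path) -> list[Path]:
    ds, labels = _load_counts(out)
    profile = agg.bootstrap_profile(
        ds.counts, labels, n_boot=config.n_boot,
        seed=config.stage_seed("aggregate"), genes=ds.genes, cell_names=ds.cells,
    )
    pct = agg.percent_expressed(ds.counts, labels, genes=ds.genes)
    logcpm = agg.aggregate_log1p_cpm(ds.counts, labels, genes=ds.genes, cell_names=ds.cells)
    d = out / "aggregate"
    d.mkdir(exist_ok=True)
    _write_df(profile.scaled_tpm, d / "scaled_tpm.tsv")
    for lvl in (95, 80):
        _write_df(profile.ci_low[lvl], d / f"ci_low_{lvl}.tsv")
        _write_df(profile.ci_high[lvl], d / f"ci_high_{lvl}.tsv")
    _write_df(profile.robust_mask.astype(int), d / "robust_mask.tsv")
    _write_df(pct.pct, d / "pct_expressed.tsv")
    _write_df(logcpm, d / "log1p_cpm.tsv")
    return sorted(d.iterdir())


def _run_coverage(config: RunConfig, out: Path) -> list[Path]:
    ds, labels = _load_counts(out)
    rows = []
    for ct in sorted(pd.unique(labels)):
        n = int((labels == ct).sum())
        sizes = None if config.coverage_sizes == "auto" else config.coverage_sizes
        curve = cov.downsample_curve(
            ds.counts, labels, ct, sizes=sizes,
            n_iter=config.coverage_iters, seed=config.stage_seed("coverage"),
        )
        fit = cov.fit_log_logistic(curve)
        g_max, half, frac = cov.coverage_report(fit, n)
        rows.append({"cell_type": ct, "n_cells": n, "b": fit.b, "d": g_max,
                     "e": half, "rss": fit.rss, "fraction_covered": frac})
    d = out / "coverage"
    d.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(d / "coverage.tsv", sep="\t", index=False,
                              float_format="%.10g")
    return [d / "coverage.tsv"]


def _run_housekeeping(config: RunConfig, out: Path) -> list[Path]:
    tpm = pd.read_csv(out / "aggregate/scaled_tpm.tsv", sep="\t", index_col=0)
    pct = pd.read_csv(out / "aggregate/pct_expressed.tsv", sep="\t", index_col=0)
    scores = hk.score_genes(pct, tpm)
    rings = hk.housekeeping_candidates(scores, gini_threshold=config.gini_threshold)
    d = out / "housekeeping"
    d.mkdir(exist_ok=True)
    _write_df(scores, d / "hk_scores.tsv")
    (d / "hk_rings.json").write_text(json.dumps(
        [{"name": r["name"], "size": r["size"], "genes": sorted(r["genes"])} for r in rings],
        indent=1, sort_keys=True,
    ))
    return sorted(d.iterdir())


def _run_tfactivity(config: RunConfig, out: Path) -> list[Path]:
    peaks = pd.read_csv(out / "data/peaks.tsv", sep="\t")
    tss = pd.read_csv(out / "data/tss.tsv", sep="\t")
    tpm = pd.read_csv(out / "aggregate/scaled_tpm.tsv", sep="\t", index_col=0)
    robust = pd.read_csv(out / "aggregate/robust_mask.tsv", sep="\t", index_col=0).astype(bool)
    profile = agg.CellTypeProfile(scaled_tpm=tpm, robust_mask=robust)

    peaks = tfa.normalize_signals(peaks)
    clusters = tfa.cluster_peaks(peaks, gap=config.gap)
    kept = tfa.filter_clusters(clusters, max_tfs=config.hot_max, min_tfs=config.min_tfs)
    kept = tfa.assign_targets(kept, tss, max_dist=config.max_dist, ratio=config.ratio)
    X = tfa.build_predictor_matrix(kept, peaks)
    act = tfa.fit_tf_models(X, profile, folds=config.folds,
                            seed=config.stage_seed("tfactivity"),
                            response=config.response)

    d = out / "tfactivity"
    d.mkdir(exist_ok=True)
    pd.DataFrame(
        [{"cluster_id": c.cluster_id, "chrom": c.chrom, "mean_apex": c.mean_apex,
          "n_tfs": len(c.tf_set), "target_gene": c.target_gene or ""} for c in kept]
    ).to_csv(d / "clusters.tsv", sep="\t", index=False, float_format="%.10g")
    _write_df(X, d / "predictor_matrix.tsv")
    long = act.beta_raw.stack().rename("beta_raw").to_frame()
    long["beta_clipped"] = act.beta.stack()
    long.index.names = ["tf", "cell_type"]
    long.reset_index().to_csv(d / "tf_activity.tsv", sep="\t", index=False,
                              float_format="%.10g")
    act.cv_mse.rename_axis("cell_type").rename("cv_mse").reset_index().to_csv(
        d / "cv_mse.tsv", sep="\t", index=False, float_format="%.10g")

    # dendrogram comparison: all genes vs TF activity vs TF expression
    tf_ids = [t for t in act.beta.index if t in tpm.index]
    trees = {
        "all_genes": tfa.build_dendrogram(np.log1p(tpm)),
        "tf_activity": tfa.build_dendrogram(act.beta),
        "tf_expression": tfa.build_dendrogram(np.log1p(tpm.loc[tf_ids])),
    }
    for name, tree in trees.items():
        (d / f"dendrogram_{name}.nwk").write_text(tfa.to_newick(tree))
    gammas = {
        "all_genes_vs_tf_activity": tfa.bakers_gamma(trees["all_genes"], trees["tf_activity"]),
        "all_genes_vs_tf_expression": tfa.bakers_gamma(trees["all_genes"], trees["tf_expression"]),
    }
    (d / "gamma.json").write_text(json.dumps(gammas, indent=1, sort_keys=True))
    return sorted(d.iterdir())


def _run_cci(config: RunConfig, out: Path) -> list[Path]:
    ds, labels = _load_counts(out)
    lr = pd.read_csv(out / "data/lr_pairs.tsv", sep="\t")
    observed, p = cci_mod.permutation_test(
        ds.counts, labels, lr, genes=ds.genes,
        n_perm=config.n_perm, seed=config.stage_seed("cci"),
    )
    types = sorted(pd.unique(labels))
    lr_labels = [f"{l}^{r}" for l, r in zip(lr["ligand"], lr["receptor"])]
    tensor = cci_mod.build_tensor(observed, p, lr_labels, types, alpha=config.alpha)
    sig = cci_mod.decompose(tensor, rank=config.rank, n_restarts=config.n_restarts,
                            seed=config.stage_seed("cci"))
    d = out / "cci"
    d.mkdir(exist_ok=True)
    np.savetxt(d / "scores_flat.tsv", tensor.scores.reshape(tensor.scores.shape[0], -1),
               delimiter="\t", fmt="%.10g")
    np.savetxt(d / "pvalues_flat.tsv", p.reshape(p.shape[0], -1), delimiter="\t", fmt="%.10g")
    (d / "tensor_index.json").write_text(json.dumps(
        {"lr_pairs": tensor.lr_labels, "cell_types": types}, indent=1))
    sdir = d / "signatures"
    sdir.mkdir(exist_ok=True)
    for mode, df in sig.loadings.items():
        _write_df(df, sdir / f"loadings_{mode}.tsv", index_label=mode)
    (sdir / "error.json").write_text(json.dumps(
        {"rank": sig.rank, "rel_error": sig.reconstruction_error,
         "weights": sig.weights.tolist()}, indent=1))
    return sorted(d.rglob("*.tsv")) + sorted(d.rglob("*.json"))


_RUNNERS = {
    "simulate": _run_simulate,
    "aggregate": _run_aggregate,
    "coverage": _run_coverage,
    "housekeeping": _run_housekeeping,
    "tfactivity": _run_tfactivity,
    "cci": _run_cci,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger().addHandler(fh)

    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            params = _stage_params(config, stage)
            inputs = {}
            for rel in _INPUTS[stage]:
                p = out / rel
                if not p.exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} requires missing input {rel} "
                        "(run its upstream stage first)"
                    )
                inputs[rel] = _sha256(p)
            prev = manifest.get(stage)
            if (
                prev is not None
                and prev.get("params") == params
                and prev.get("inputs") == inputs
                and all((out / f).exists() for f in prev.get("outputs", {}))
            ):
                log.info("[%s] unchanged; skipped", stage)
                manifest[stage]["status"] = "skipped"
                continue
            t0 = time.time()
            log.info("[%s] running", stage)
            produced = _RUNNERS[stage](config, out)
            manifest[stage] = {
                "status": "completed",
                "params": params,
                "inputs": inputs,
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in produced},
                "wall_clock_s": round(time.time() - t0, 3),
            }
            manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        if config.make_report and all(
            manifest.get(s, {}).get("status") in ("completed", "skipped")
            for s in config.stages
        ):
            report(manifest, out)
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def report(manifest: dict, out_dir: str | Path) -> Path:
    """Render summary tables and figures from completed stage outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    d = out / "report"
    d.mkdir(exist_ok=True)
    warnings = []
    summary: dict = {}

    def save(fig, name):
        fig.savefig(d / name, dpi=100, metadata={"Software": None})
        plt.close(fig)

    hk_scores = out / "housekeeping/hk_scores.tsv"
    if hk_scores.exists():
        scores = pd.read_csv(hk_scores, sep="\t", index_col=0)
        counts = scores["bracket"].value_counts().reindex(
            [b for _, b in hk.BRACKETS], fill_value=0
        )
        fig, ax = plt.subplots(figsize=(5, 3))
        counts.plot.bar(ax=ax, color="#4477aa")
        ax.set_ylabel("genes")
        ax.set_title("expression-equality brackets (Gc)")
        fig.tight_layout()
        save(fig, "bracket_histogram.png")
        summary["bracket_counts"] = counts.to_dict()
    else:
        warnings.append("housekeeping outputs missing; bracket histogram skipped")

    act_path = out / "tfactivity/tf_activity.tsv"
    if act_path.exists():
        act = pd.read_csv(act_path, sep="\t").pivot(
            index="tf", columns="cell_type", values="beta_clipped"
        )
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(act.to_numpy(), aspect="auto", cmap="viridis")
        fig.colorbar(im, ax=ax, label="clipped coefficient")
        ax.set_xlabel("cell type")
        ax.set_ylabel("TF")
        ax.set_title("TF activity")
        fig.tight_layout()
        save(fig, "tf_activity_heatmap.png")
        summary["n_positive_associations"] = int((act.to_numpy() > 0).sum())
    else:
        warnings.append("tfactivity outputs missing; heatmap skipped")

    sig_dir = out / "cci/signatures"
    if sig_dir.exists():
        for mode in cci_mod.MODES:
            df = pd.read_csv(sig_dir / f"loadings_{mode}.tsv", sep="\t", index_col=0)
            fig, ax = plt.subplots(figsize=(4, 5))
            im = ax.imshow(df.to_numpy(), aspect="auto", cmap="magma")
            fig.colorbar(im, ax=ax, label="loading")
            ax.set_title(f"signature loadings: {mode}")
            fig.tight_layout()
            save(fig, f"loadings_{mode}.png")
    else:
        warnings.append("cci outputs missing; loading heatmaps skipped")

    cov_path = out / "coverage/coverage.tsv"
    if cov_path.exists():
        cov_tab = pd.read_csv(cov_path, sep="\t")
        summary["median_fraction_covered"] = float(cov_tab["fraction_covered"].median())
        summary["coverage_table"] = cov_tab.to_dict(orient="records")
    else:
        warnings.append("coverage outputs missing")

    summary["warnings"] = warnings
    (d / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return d
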
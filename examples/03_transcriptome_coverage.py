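"""How much of a cell type's transcriptome have we seen?

Detected-gene counts under down-sampling follow a saturating curve;
a three-parameter log-logistic fit extrapolates the asymptotic gene
count (G_MAX), the cell count at half coverage, and the fraction of
the transcriptome already covered by the observed cells.
"""

import atlasinfer as ai

ds = ai.simulate_dataset(ai.SimConfig(seed=1))
labels = ds.cell_labels.loc[ds.cells].to_numpy()

ct = "ct03"
curve = ai.downsample_curve(ds.counts, labels, ct, n_iter=100, seed=4)
fit = ai.fit_log_logistic(curve)
n_cells = int((labels == ct).sum())
g_max, half_cells, fraction = ai.coverage_report(fit, n_cells)

for s, m in zip(curve.sizes, curve.mean_genes):
    print(f"  {s:4d} cells -> {m:7.1f} genes detected (mean of {curve.n_iter} draws)")
print(f"{ct}: G_MAX = {g_max:.0f} genes (predicted asymptote)")
print(f"half of G_MAX reached at ~{half_cells:.1f} cells")
print(f"with the observed {n_cells} cells, {100 * fraction:.1f}% of the "
      "type's detectable transcriptome is covered")
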
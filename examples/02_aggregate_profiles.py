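"""Per-cell-type scaled-TPM profiles with bootstrap confidence.

Counts are size-factor normalised, averaged per gene within each cell
type and rescaled to one million per type ("scaled TPM"). Resampling
each type's cells with replacement gives percentile confidence
intervals; a gene is robustly expressed where the 95% lower bound is
positive.
"""

import numpy as np

import atlasinfer as ai

ds = ai.simulate_dataset(ai.SimConfig(seed=1))
labels = ds.cell_labels.loc[ds.cells].to_numpy()

profile = ai.bootstrap_profile(
    ds.counts, labels, n_boot=300, seed=2, genes=ds.genes, cell_names=ds.cells
)

print("scaled-TPM column sums (should all be 1e6):",
      np.unique(np.round(profile.scaled_tpm.sum(axis=0))))
print(f"robustly expressed gene-type calls: {int(profile.robust_mask.to_numpy().sum())} "
      f"of {profile.robust_mask.size}")

g = sorted(ds.truth.housekeeping_genes)[0]
ct = profile.scaled_tpm.columns[0]
print(f"example: housekeeping gene {g} in {ct}: "
      f"{profile.scaled_tpm.loc[g, ct]:.0f} scaled TPM, "
      f"95% CI [{profile.ci_low[95].loc[g, ct]:.0f}, {profile.ci_high[95].loc[g, ct]:.0f}]")

pct = ai.percent_expressed(ds.counts, labels, genes=ds.genes)
print(f"that gene is detected in {pct.pct.loc[g, ct]:.0f}% of {ct} cells")
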
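"""Cross-validated classification of two synthetic bladder-cancer cell lines.

The two phantom classes share every Raman band except 789, 1003 and
1490 cm^-1, where the high-grade class is 15% stronger — a small, localised
biochemical difference.  The full pipeline (cosmic-ray removal, EMSC,
denoising, fingerprint crop, quality cull) runs before eleven classifier
configurations are evaluated under stratified 10-fold cross-validation.
"""

from cytoscreen.chemometrics import select_mr_channels, marginal_relevance
from cytoscreen.orchestrate import RunConfig, run_full_pipeline

import numpy as np

config = RunConfig(n_per_class=150, seed=11)  # 150 spectra per class
bundle = run_full_pipeline(config)

print("pooled 10-fold cross-validation metrics (positive = high grade):")
print(bundle["metrics"].round(3).to_string())
print()

ev = bundle["pca_explained_variance_ratio"]
print(f"PCA explained variance: PC1 {100 * ev[0]:.1f}%, PC2 {100 * ev[1]:.1f}%, "
      f"PC3 {100 * ev[2]:.1f}%")

processed = bundle["processed"]
mr = marginal_relevance(processed.matrix, np.asarray(processed.labels))
chans = select_mr_channels(mr, 10)
wn = processed.axis.values[chans]
print("MR-selected wavelengths (cm^-1):", np.round(wn).astype(int).tolist())
print("planted discriminating bands: [789, 1003, 1490]")
# Rows near 1.0 mean the classifier separates the two lines almost
# perfectly; the MR selection should hit the planted bands (each region
# contributes its best-scoring wavelength, so unrelated regions appear too).
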
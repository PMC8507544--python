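"""Locate cell nuclei on a simulated slide via their bright-spot images.

A defocused bright-field image of an epithelial cell shows a bright spot a
few tens of micrometres from focus: the nucleus acts as a micro-lens on
partially coherent illumination.  This script builds a synthetic ThinPrep
slide, runs the focus scan, images a 2x2 tile grid at the bright-spot
plane, detects the spots, and compares the targeted stage positions with
the phantom's ground truth.
"""

import numpy as np

from cytoscreen import generate_slide
from cytoscreen.orchestrate import RunConfig, run_acquisition
from cytoscreen.phantom import SimulatedInstrument, SlideParams

phantom = generate_slide(30, clustering=0.0, params=SlideParams.thinprep(), seed=42)
instrument = SimulatedInstrument(phantom)
config = RunConfig(n_targets=30, grid_rows=4, grid_cols=4)

targets, spectra, manifest = run_acquisition(instrument, config)

print(f"autofocus: bright-spot plane {manifest.focus['z_bright_spot']:+.1f} µm, "
      f"focal plane {manifest.focus['z_focus']:+.1f} µm "
      f"(planted displacement {phantom.z_spot:+.1f} µm)")

truth = phantom.positions
errors = []
single = 0
for nucleus in truth:
    d = np.hypot(targets.stage_xy[:, 0] - nucleus[0],
                 targets.stage_xy[:, 1] - nucleus[1])
    n_close = int(np.sum(d <= 2.0))
    single += n_close == 1
    if n_close:
        errors.append(d.min())

print(f"nuclei single-targeted within 2 µm: {single}/{len(truth)} "
      f"({100.0 * single / len(truth):.0f}%)")
print(f"median targeting error: {np.median(errors):.2f} µm")
print(f"spectra acquired: {len(spectra)} "
      f"({sum(m['kind'] == 'cell' for m in spectra.meta)} cell, "
      f"{sum(m['kind'] == 'substrate' for m in spectra.meta)} substrate)")
# A high single-target rate means the laser would land inside the nucleus of
# almost every cell; the error is dominated by stage repeatability (~0.25 µm).
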
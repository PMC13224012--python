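"""Segment one synthetic field and quantify every cell.

Renders a field of 20 cells, detects nuclei on the Hoechst channel, grows
cell bodies, extracts mitochondrial masks, and measures background-
corrected per-cell intensities.  Prints the object counts and the first
rows of the single-cell table; the segmentation recovers essentially all
simulated cells, and the mito-restricted mmp mean tracks each cell's
latent membrane potential.
"""

import numpy as np

from mitohicp import quantify, segment, simgen

spec = simgen.make_group("HPFC", "control", cells_per_field=20)
geom = simgen.default_geometry(image_size=256, nucleus_radius=(5, 7),
                               cell_radius=(11, 15), mito_count=(5, 9),
                               mito_segment_length=(6, 12))
latents = simgen.sample_latents(spec, 20, seed=7)
stack, truth = simgen.render_field(latents, geom, seed=8)

maps = segment.segment_field(stack, max_cell_distance=8)
print(f"simulated cells: {truth.n_cells}, segmented cells: {maps['cells'].max()}")

background = {role: quantify.estimate_background(stack[role], maps["cells"])
              for role in simgen.CHANNEL_ORDER}
table = quantify.measure_cells(stack, maps["cells"], maps["nuclei"], maps["mito"],
                               background)
cols = ["cell_id", "cell_px", "mito_px", "mmp_mito_corr_mean",
        "ros_corr_mean", "mtros_mito_corr_mean"]
print(table[cols].head(5).round(1).to_string(index=False))

# fidelity check against ground truth: measure on the true masks so each
# row pairs with its generating latent, then correlate readout with M
gt_table = quantify.measure_cells(stack, truth.cells, truth.nuclei, truth.mito,
                                  background).set_index("cell_id")
merged = truth.table.set_index("cell_id").join(gt_table)
r = np.corrcoef(merged["M"], merged["mmp_mito_corr_mean"])[0, 1]
print(f"\ncorrelation of measured mmp readout with latent M: r = {r:.3f}")
print("(close to 1: the measurement chain is faithful at this noise level)")
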
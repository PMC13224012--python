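"""Phenotypic PCA and hierarchical clustering of image profiles.

Simulates a mini screen (tumor line: control, EDL21 and a G4 ligand at
four images each), extracts image-level profiles, standardizes them, and
runs PCA plus correlation-distance clustering.  The G4-ligand images
separate from control/EDL21 along the leading components — the membrane-
potential drop propagates into many intensity and texture features —
while the inert EDL21 group stays interleaved with controls.
"""

import numpy as np
import pandas as pd

from mitohicp import features, profiling, segment, simgen
from mitohicp.manifest import default_manifest

geom = simgen.default_geometry(image_size=256, nucleus_radius=(5, 7),
                               cell_radius=(11, 15), mito_count=(5, 9),
                               mito_segment_length=(6, 12))
manifest = default_manifest()

frames = []
counter = 0
for compound in ("control", "EDL21", "360A"):
    spec = simgen.make_group("HeLa", compound, cells_per_field=14)
    for f in range(4):
        ss = np.random.SeedSequence(entropy=99, spawn_key=(counter,))
        s1, s2 = (int(s) for s in ss.generate_state(2) % (2**31))
        counter += 1
        latents = simgen.sample_latents(spec, 14, s1)
        stack, _ = simgen.render_field(latents, geom, s2)
        maps = segment.segment_field(stack, max_cell_distance=8)
        frames.append(features.extract_features(
            stack, maps, manifest,
            metadata={"well": compound, "field": f, "compound": compound}))

table = pd.concat(frames, ignore_index=True)
profiles = features.aggregate_image_profiles(
    table, keys=("well", "field"), feature_names=manifest.names)

X = profiles[manifest.names].dropna(axis=1)
normalized, dropped = profiling.zscore_normalize(X)
res = profiling.pca_embed(normalized, k=2, dropped_features=dropped)
print(f"variance explained: PC1 {100*res.variance_explained[0]:.1f}%, "
      f"PC2 {100*res.variance_explained[1]:.1f}%")

scores = res.scores.assign(compound=profiles["compound"].to_numpy())
print("\nmean PC1 per group (G4 ligand shifts away from control/EDL21):")
print(scores.groupby("compound")["PC1"].mean().round(2).to_string())

contrib = profiling.rank_family_contributions(
    res, manifest.subset(names=list(normalized.columns)))
print("\nfamily contributions to PC1-PC2 (fraction of squared loadings):")
print(contrib.round(3).to_string(index=False))

med = normalized.assign(compound=profiles["compound"].to_numpy())
med = med.groupby("compound").median()
hm = profiling.cluster_heatmap(med)
print("\nclustered group order (correlation distance, average linkage):")
print(" -> ".join(hm["row_labels"]))
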
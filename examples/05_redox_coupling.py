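"""Redox-coupling analysis: MMP-(mt)ROS correlations and Fisher z-tests.

Builds single-cell tables for an untreated normal line and tumor line
directly from the latent generator (the fast path; the image pipeline
gives the same structure), then measures the per-group Pearson coupling
and compares correlation strengths.  Expected structure: MMP couples more
tightly to mitochondrial ROS than to whole-cell ROS in both lines, and
more tightly in the normal line than in the tumor line.
"""

import numpy as np
import pandas as pd

from mitohicp import coupling, simgen

frames = []
for line in ("HeLa", "HPFC"):
    spec = simgen.make_group(line, "control")
    lat = simgen.sample_latents(spec, 1500, seed=11 if line == "HeLa" else 12)
    lat = lat.rename(columns={"M": "mmp", "R": "ros", "S": "mtros"})
    lat["cell_line"] = line
    lat["compound"] = "control"
    lat["well"] = line
    lat["field"] = np.arange(len(lat)) % 6
    frames.append(lat)
cells = pd.concat(frames, ignore_index=True)

readouts = {"MMP": "mmp", "ROS": "ros", "mtROS": "mtros"}
results, comparisons = coupling.coupling_profile(cells, readouts=readouts)

print("pooled Pearson coupling (n = 1500 cells per line):")
for r in results:
    lo, hi = r.ci95
    print(f"  {r.group:14s} {r.pair:10s} r = {r.r:+.3f}  "
          f"[{lo:+.3f}, {hi:+.3f}]  z_r = {r.z_r:+.3f}")

print("\nFisher z comparisons (Z, one-sided p):")
for c in comparisons:
    print(f"  {c.label1:26s} vs {c.label2:26s} Z = {c.Z:+7.3f}  p = {c.p_one_sided:.2e}")

print("\nmtROS couples to MMP more strongly than whole-cell ROS in both")
print("lines, and most strongly in the normal line - the baseline redox-")
print("coupling hierarchy the synthetic screen encodes.")
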
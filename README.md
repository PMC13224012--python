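# mitohicp

Mitochondrial high-content profiling in Python: an end-to-end, fully
synthetic-testable reimplementation of a live-cell screening analysis that
asks how compounds perturb mitochondrial health at single-cell resolution.

## The scientific problem

In a high-content screen, cells in 96-well plates are stained with four
live-cell dyes — Hoechst (DNA), a whole-cell ROS reporter, a mitochondrial
superoxide reporter (mtROS), and a membrane-potential dye (MMP, Δψm) — and
imaged field by field. Three questions drive the analysis:

1. **Single-cell pharmacology** — does a treatment shift the per-cell MMP,
   ROS and mtROS distributions relative to control (unpaired Student's *t*,
   one-way ANOVA, star coding)?
2. **Phenotypic profiling** — beyond the three readouts, does the treatment
   remodel cell morphology? A fixed catalogue of **541 morphological
   features** (shape, intensity, Haralick texture, cross-channel
   colocalization, granularity, radial distribution, neighbours, location)
   is extracted per cell, averaged per image, and embedded by PCA /
   hierarchical clustering.
3. **Redox coupling** — at single-cell level MMP correlates with ROS and
   mtROS. The coupling strength is measured by Pearson's *r* and compared
   across conditions with Fisher's z-test,

   z_r = atanh(r),  Z = (z_r1 − z_r2) / √(1/(n1−3) + 1/(n2−3)),

   so that a treatment that *uncouples* membrane potential from superoxide
   production is detected as a significant drop in *r*.

Because raw screening images are rarely shareable, the package ships a
**synthetic screen generator**: per-cell latent (MMP, ROS, mtROS) triples
are drawn from a trivariate log-normal with a group-specific correlation
matrix, rendered as noisy multichannel fluorescence fields with exact
ground-truth masks. Every downstream stage (segmentation, quantification,
features, coupling statistics) can therefore be validated against known
truth — the tests measure segmentation F1/IoU, latent-correlation recovery
and type-I calibration against the generator's parameters.

## Worked example

`examples/05_redox_coupling.py` builds single-cell tables for an untreated
normal line (HPFC) and tumor line (HeLa) and runs the coupling analysis:

```
pooled Pearson coupling (n = 1500 cells per line):
  HPFC:control   MMP-ROS    r = +0.357  [+0.312, +0.400]  z_r = +0.373
  HPFC:control   MMP-mtROS  r = +0.736  [+0.712, +0.758]  z_r = +0.941
  HeLa:control   MMP-ROS    r = +0.309  [+0.262, +0.354]  z_r = +0.319
  HeLa:control   MMP-mtROS  r = +0.587  [+0.553, +0.620]  z_r = +0.674

Fisher z comparisons (Z, one-sided p):
  HPFC:control|MMP-ROS       vs HPFC:control|MMP-mtROS     Z = -15.537  p = 9.74e-55
  HeLa:control|MMP-ROS       vs HeLa:control|MMP-mtROS     Z =  -9.690  p = 1.67e-22
  HPFC:control|MMP-mtROS     vs HeLa:control|MMP-mtROS     Z =  +7.318  p = 1.26e-13
```

Reading the numbers: in both lines MMP couples far more tightly to
mitochondrial superoxide than to whole-cell ROS (large negative Z for the
within-line contrast), and the mtROS–MMP coupling is significantly
stronger in the normal line than in the tumor line — the baseline
hierarchy the synthetic screen encodes. The other examples cover plate
simulation (`01`), segmentation + quantification (`02`), the 541-feature
catalogue (`03`), PCA/clustering with family contributions (`04`), and
group statistics + ddCt quantification (`06`).

## Pipeline CLI

The same workflow runs end-to-end from a shell:

```bash
mitohicp run all --seed 1 --out runs/demo        # simulate ... report
mitohicp run simulate --config my_screen.yaml    # one stage at a time
```

Stages write `cells.csv`, `features.csv`, `profiles.csv`, `coupling.csv`,
`coupling_tests.csv`, `group_summary.csv`, PCA/heatmap/violin figures and
a run manifest with per-artifact checksums; identical (config, seed) runs
are byte-identical.

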
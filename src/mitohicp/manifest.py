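"""The morphological feature catalogue.

The default ("reference") manifest enumerates exactly 541 per-cell
features across eight families; the manifest object is the single source
of truth for which columns a feature table contains and in what order.

Family ledger (counts must multiply out to 541):

================  ==========================================  =====
family            members                                     count
================  ==========================================  =====
shape             15 descriptors x 3 compartments                45
intensity         13 statistics x 3 compartments x 4 channels   156
texture           13 Haralick statistics x 3 x 4                156
correlation       3 metrics x 6 channel pairs x 2 compartments   36
granularity       16 opening radii x 4 channels (cell)           64
radial            3 statistics x 4 bins x 4 channels (cell)      48
neighbors         6 metrics x {cell, nucleus}                    12
location          centroid + weighted centroids (see below)      24
================  ==========================================  =====

Location detail: cell and nucleus each carry their centroid (2 coords)
plus the intensity-weighted centroid per channel (8); the mitochondrial
compartment carries its centroid (2) plus the mmp-weighted centroid (2).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path

import pandas as pd

__all__ = ["FeatureManifest", "default_manifest", "CATALOGUE_SIZE"]

CATALOGUE_SIZE = 541
MANIFEST_VERSION = "1"

CHANNELS = ("hoechst", "ros", "mtros", "mmp")
COMPARTMENTS = ("cell", "nucleus", "mito")

SHAPE_STATS = (
    "area", "perimeter", "form_factor", "eccentricity", "solidity", "extent",
    "major_axis", "minor_axis", "aspect_ratio", "orientation",
    "equiv_diameter", "euler_number", "bbox_width", "bbox_height",
    "compactness",
)
INTENSITY_STATS = (
    "mean", "median", "sd", "mad", "min", "max", "integrated",
    "q05", "q25", "q75", "q95", "mass_disp", "edge_mean",
)
HARALICK_STATS = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_avg",
    "sum_var", "sum_entropy", "entropy", "diff_var", "diff_entropy",
    "imc1", "imc2",
)
CORR_METRICS = ("pcc", "overlap", "manders")
RADIAL_STATS = ("frac_at_d", "mean_frac", "radial_cv")
NEIGHBOR_STATS = (
    "n_neighbors", "percent_touching", "dist1", "dist2", "angle", "mean_dist",
)
GRANULARITY_RADII = tuple(range(1, 17))
RADIAL_BINS = 4

FAMILIES = (
    "shape", "intensity", "texture", "correlation", "granularity", "radial",
    "neighbors", "location",
)


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature catalogue; rows: name, family, compartment, channel."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"name", "family", "compartment", "channel"}
        if not required <= set(self.table.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        if self.table["name"].duplicated().any():
            dup = self.table["name"][self.table["name"].duplicated()].iloc[0]
            raise ValueError(f"duplicate feature name {dup!r}")
        unknown = set(self.table["family"]) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, families=None, names=None) -> "FeatureManifest":
        t = self.table
        if families is not None:
            t = t[t["family"].isin(families)]
        if names is not None:
            t = t[t["name"].isin(names)]
        return FeatureManifest(t.reset_index(drop=True))

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.table["name"], self.table["family"]))

    def family_counts(self) -> pd.Series:
        return self.table["family"].value_counts()

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "manifest_version", MANIFEST_VERSION)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureManifest":
        t = pd.read_csv(path, keep_default_na=False)
        return cls(t[["name", "family", "compartment", "channel"]])


def _build_rows() -> list[dict]:
    rows = []

    def add(name, family, compartment, channel=""):
        rows.append(
            {"name": name, "family": family, "compartment": compartment,
             "channel": channel}
        )

    for comp in COMPARTMENTS:
        for stat in SHAPE_STATS:
            add(f"{comp}_shape_{stat}", "shape", comp)
    for comp in COMPARTMENTS:
        for ch in CHANNELS:
            for stat in INTENSITY_STATS:
                add(f"{comp}_{ch}_int_{stat}", "intensity", comp, ch)
    for comp in COMPARTMENTS:
        for ch in CHANNELS:
            for stat in HARALICK_STATS:
                add(f"{comp}_{ch}_tex_{stat}", "texture", comp, ch)
    for comp in ("cell", "nucleus"):
        for a, b in combinations(CHANNELS, 2):
            for metric in CORR_METRICS:
                add(f"{comp}_corr_{metric}_{a}_{b}", "correlation", comp, f"{a}|{b}")
    for ch in CHANNELS:
        for r in GRANULARITY_RADII:
            add(f"cell_{ch}_gran_r{r}", "granularity", "cell", ch)
    for ch in CHANNELS:
        for b in range(1, RADIAL_BINS + 1):
            for stat in RADIAL_STATS:
                add(f"cell_{ch}_radial_{stat}_b{b}", "radial", "cell", ch)
    for comp in ("cell", "nucleus"):
        for stat in NEIGHBOR_STATS:
            add(f"{comp}_nb_{stat}", "neighbors", comp)
    for comp in ("cell", "nucleus"):
        for ax in ("row", "col"):
            add(f"{comp}_loc_centroid_{ax}", "location", comp)
        for ch in CHANNELS:
            for ax in ("row", "col"):
                add(f"{comp}_loc_wcentroid_{ch}_{ax}", "location", comp, ch)
    for ax in ("row", "col"):
        add(f"mito_loc_centroid_{ax}", "location", "mito")
    for ax in ("row", "col"):
        add(f"mito_loc_wcentroid_mmp_{ax}", "location", "mito", "mmp")
    return rows


def default_manifest() -> FeatureManifest:
    """The reference catalogue of exactly 541 features."""
    m = FeatureManifest(pd.DataFrame(_build_rows()))
    assert len(m) == CATALOGUE_SIZE, f"catalogue size {len(m)} != {CATALOGUE_SIZE}"
    return m


def shipped_manifest_path() -> Path:
    """Path of the versioned manifest CSV shipped with the package."""
    return Path(resources.files("mitohicp") / "data" / "feature_manifest_v1.csv")
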
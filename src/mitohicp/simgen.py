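"""Synthetic fluorescence-screen generator with exported ground truth.

Emulates a live-cell high-content screen: 96-well plates of multichannel
fields (Hoechst nuclear stain, whole-cell ROS reporter, mitochondrial
superoxide reporter, mitochondrial membrane-potential dye).  Each cell
carries a latent triple (M, R, S) — MMP, total ROS, mtROS — drawn from a
trivariate log-normal whose log-scale correlation matrix encodes the
redox-coupling structure under study (MMP–mtROS coupling stronger than
MMP–ROS; stronger in normal than tumor lines; treatment-specific shifts).
Latents are rendered as noisy fluorescence images together with exact
ground-truth masks, so segmentation and correlation-recovery accuracy can
be measured against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GroupSpec",
    "FieldGeometry",
    "ChannelStack",
    "GroundTruth",
    "PlateLayout",
    "sample_latents",
    "render_field",
    "generate_plate",
    "default_screen_layout",
    "default_geometry",
    "CHANNEL_ORDER",
]

#: canonical fluorescence channel order used throughout the package
CHANNEL_ORDER = ("hoechst", "ros", "mtros", "mmp")

WELL_ROWS = "ABCDEFGH"
WELL_COLS = range(1, 13)
VALID_WELLS = frozenset(f"{r}{c}" for r in WELL_ROWS for c in WELL_COLS)


class ValidationError(ValueError):
    """Raised when a simulation spec violates its invariants."""


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: latent log-normal parameters plus plate plumbing.

    ``mu`` / ``sigma`` are log-scale means and SDs of the latent
    (M, R, S) triple; ``rho`` is the log-scale correlation matrix over
    (M, R, S). ``dose`` is carried as metadata only (µM).
    """

    cell_line: str
    compound: str
    dose: float
    mu: tuple[float, float, float]
    rho: np.ndarray
    sigma: tuple[float, float, float] = (0.3, 0.3, 0.3)
    cells_per_field: int = 30
    fields_per_well: int = 4
    wells: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", rho)
        if rho.shape != (3, 3):
            raise ValidationError(f"rho must be 3x3, got {rho.shape}")
        if not np.allclose(rho, rho.T):
            raise ValidationError(f"rho must be symmetric:\n{rho}")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValidationError(f"rho must have unit diagonal:\n{rho}")
        if np.linalg.eigvalsh(rho).min() < -1e-10:
            raise ValidationError(f"rho is not positive semi-definite:\n{rho}")
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValidationError("sigma must be strictly positive")
        if self.cells_per_field < 0 or self.fields_per_well < 0:
            raise ValidationError("counts must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.cell_line}:{self.compound}:{self.dose:g}"


@dataclass(frozen=True)
class FieldGeometry:
    """Rendering geometry and camera noise for one microscope field."""

    image_size: int = 512
    nucleus_radius: tuple[int, int] = (6, 9)
    cell_radius: tuple[int, int] = (14, 20)
    mito_count: tuple[int, int] = (6, 12)
    mito_segment_length: tuple[int, int] = (8, 16)
    background_level: float = 100.0
    poisson_gain: float = 2.0       # counts per photon; 0 disables shot noise
    read_noise_sd: float = 3.0      # counts; 0 disables read noise
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.nucleus_radius[0] < 2 or self.cell_radius[0] < 2:
            raise ValidationError("radii must be >= 2 px")
        if self.cell_radius[0] <= self.nucleus_radius[1]:
            raise ValidationError("cell radius must exceed nucleus radius")
        if min(self.background_level, self.poisson_gain, self.read_noise_sd) < 0:
            raise ValidationError("noise parameters must be >= 0")


# per-pixel amplitude factors converting latents to counts; chosen so that
# signals sit comfortably inside the 16-bit range at the default mu values
_HOECHST_AMPLITUDE = 3000.0
_ROS_PIXEL_FACTOR = 0.5      # ros counts/px = R * factor
_MITO_HAZE = 0.05            # cytoplasmic haze fraction of the mito amplitude


@dataclass
class ChannelStack:
    """Co-registered channel images of one field (uint16, identical shapes)."""

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(CHANNEL_ORDER) - set(self.channels)
        if missing:
            raise ValidationError(f"missing channels: {sorted(missing)}")
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) != 1:
            raise ValidationError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]


@dataclass
class GroundTruth:
    """Exact per-cell truth for one rendered field.

    ``table`` has one row per cell (cell_id, latent M/R/S, center coords);
    the three label maps share the cell_id labelling, and mitochondrial
    pixels are contained in their parent cell's pixels.
    """

    table: pd.DataFrame
    nuclei: np.ndarray
    cells: np.ndarray
    mito: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.table)


def sample_latents(spec: GroupSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` latent (M, R, S) triples from the group's log-normal model.

    Log-latents are a trivariate Gaussian with mean ``spec.mu``, SDs
    ``spec.sigma`` and correlation ``spec.rho`` (Cholesky construction);
    returned values are their exponentials, hence strictly positive with
    log-scale sample correlations converging to ``spec.rho``.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.asarray(spec.sigma)
    cov = spec.rho * np.outer(sigma, sigma)
    log_latents = rng.multivariate_normal(spec.mu, cov, size=n, method="cholesky")
    out = pd.DataFrame(np.exp(log_latents), columns=["M", "R", "S"])
    out.insert(0, "cell_id", np.arange(1, n + 1))
    return out


def _place_nuclei(
    n: int, size: int, min_sep: float, margin: int, rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Rejection-sample ``n`` non-overlapping nucleus centers."""
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"field too crowded: placed {len(centers)} of {n} nuclei "
                f"after {max_tries} attempts"
            )
        tries += 1
        cand = rng.uniform(margin, size - margin, size=2)
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep**2 for r, c in centers):
            centers.append((cand[0], cand[1]))
    return np.asarray(centers).reshape(n, 2)


def _random_walk_mito(
    cell_mask: np.ndarray, nucleus_mask: np.ndarray, count: int, length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render mitochondria as short 8-connected random-walk filaments
    confined to the cytoplasm (cell minus nucleus) of one cell."""
    cyto = cell_mask & ~nucleus_mask
    mito = np.zeros_like(cell_mask)
    coords = np.argwhere(cyto)
    if len(coords) == 0:
        return mito
    steps = np.array(
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    )
    for _ in range(count):
        r, c = coords[rng.integers(len(coords))]
        for _ in range(length):
            if cyto[r, c]:
                mito[r, c] = True
            dr, dc = steps[rng.integers(8)]
            nr, nc = r + dr, c + dc
            if 0 <= nr < cyto.shape[0] and 0 <= nc < cyto.shape[1] and cyto[nr, nc]:
                r, c = nr, nc
    return mito


def render_field(
    latents: pd.DataFrame, geom: FieldGeometry, seed: int
) -> tuple[ChannelStack, GroundTruth]:
    """Render one field's latent table into noisy channel images + truth.

    Signal model per cell: Hoechst is a constant-amplitude nuclear disc;
    ROS covers the whole cell scaled by R; mtROS and MMP concentrate on
    the cell's mitochondrial filaments scaled by S and M with a weak
    cytoplasmic haze.  Poisson shot noise then Gaussian read noise are
    applied last and the result clipped to the 16-bit range.  Ground-truth
    masks match the rendered object supports exactly (pre-noise).
    """
    rng = np.random.default_rng(seed)
    size = geom.image_size
    n = len(latents)

    nuc_radii = rng.integers(geom.nucleus_radius[0], geom.nucleus_radius[1] + 1, size=n)
    cell_radii = rng.integers(geom.cell_radius[0], geom.cell_radius[1] + 1, size=n)
    margin = geom.nucleus_radius[1] + 2
    min_sep = 2 * geom.nucleus_radius[1] + 3
    centers = _place_nuclei(n, size, min_sep, margin, rng)

    rr, cc = np.mgrid[0:size, 0:size]
    nuclei = np.zeros((size, size), dtype=np.int32)
    cells = np.zeros((size, size), dtype=np.int32)
    mito = np.zeros((size, size), dtype=np.int32)

    if n:
        # squared distance to every center; cells are discs trimmed to the
        # nearest-center (Voronoi) region so their masks stay disjoint
        d2 = (
            (rr[None] - centers[:, 0, None, None]) ** 2
            + (cc[None] - centers[:, 1, None, None]) ** 2
        )
        nearest = np.argmin(d2, axis=0)
        for i in range(n):
            cid = int(latents["cell_id"].iloc[i])
            own = nearest == i
            nuclei[(d2[i] <= nuc_radii[i] ** 2) & own] = cid
            cells[(d2[i] <= cell_radii[i] ** 2) & own] = cid

    images = {
        role: np.full((size, size), geom.background_level, dtype=float)
        for role in CHANNEL_ORDER
    }
    rows = []
    for i in range(n):
        cid = int(latents["cell_id"].iloc[i])
        nuc_mask = nuclei == cid
        cell_mask = cells == cid
        m_count = int(rng.integers(geom.mito_count[0], geom.mito_count[1] + 1))
        m_len = int(rng.integers(geom.mito_segment_length[0], geom.mito_segment_length[1] + 1))
        mito_mask = _random_walk_mito(cell_mask, nuc_mask, m_count, m_len, rng)
        mito[mito_mask] = cid

        M, R, S = (float(latents[k].iloc[i]) for k in ("M", "R", "S"))
        images["hoechst"][nuc_mask] += _HOECHST_AMPLITUDE
        images["ros"][cell_mask] += R * _ROS_PIXEL_FACTOR
        images["mtros"][cell_mask] += S * _MITO_HAZE
        images["mtros"][mito_mask] += S
        images["mmp"][cell_mask] += M * _MITO_HAZE
        images["mmp"][mito_mask] += M
        rows.append(
            {"cell_id": cid, "row": centers[i, 0], "col": centers[i, 1],
             "M": M, "R": R, "S": S}
        )

    max_count = 2**geom.bit_depth - 1
    noisy = {}
    for role in CHANNEL_ORDER:
        im = images[role]
        if geom.poisson_gain > 0:
            im = rng.poisson(im / geom.poisson_gain) * geom.poisson_gain
        im = im.astype(float)
        if geom.read_noise_sd > 0:
            im = im + rng.normal(0.0, geom.read_noise_sd, size=im.shape)
        noisy[role] = np.clip(np.round(im), 0, max_count).astype(np.uint16)

    table = pd.DataFrame(rows, columns=["cell_id", "row", "col", "M", "R", "S"])
    return ChannelStack(noisy), GroundTruth(table, nuclei, cells, mito)


# ---------------------------------------------------------------------------
# plate layout and default screen


@dataclass
class PlateLayout:
    """Assignment of 96-well IDs to treatment groups."""

    plate_id: str
    groups: dict[str, GroupSpec] = field(default_factory=dict)  # name -> spec

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, spec in self.groups.items():
            for well in spec.wells:
                if well not in VALID_WELLS:
                    raise ValidationError(f"invalid 96-well ID {well!r}")
                if well in seen:
                    raise ValidationError(
                        f"well {well} assigned to both {seen[well]} and {name}"
                    )
                seen[well] = name


#: baseline log-scale correlation structure: redox coupling rho(M, S) is
#: stronger than rho(M, R), and both are stronger in the normal line
_BASELINE_RHO = {
    "HPFC": {"MS": 0.75, "MR": 0.35, "RS": 0.45},
    "HeLa": {"MS": 0.60, "MR": 0.30, "RS": 0.45},
}
_BASELINE_MU = (7.3, 6.6, 7.0)  # log counts for (M, R, S)

#: treatment effects as (M, R, S) median multipliers plus an off-diagonal
#: correlation shrinkage factor, applied on top of the baseline per line
_TUMOR_EFFECTS = {
    "control":  ((1.0, 1.0, 1.0), 1.0),
    "EDL21":    ((1.0, 1.0, 1.0), 1.0),
    "Pt-ttpy":  ((0.5, 0.85, 0.85), 1.0),
    "360A":     ((0.5, 0.85, 0.85), 1.0),
    "Phen-DC3": ((0.5, 0.85, 0.85), 1.0),
    "cisplatin": ((0.4, 2.0, 2.0), 0.5),
}
# normal cells respond only weakly to G4 ligands (tumor-selective action);
# cisplatin toxicity is non-selective
_NORMAL_EFFECTS = {
    "control":  ((1.0, 1.0, 1.0), 1.0),
    "EDL21":    ((1.0, 1.0, 1.0), 1.0),
    "Pt-ttpy":  ((0.95, 1.0, 1.0), 1.0),
    "360A":     ((0.95, 1.0, 1.0), 1.0),
    "Phen-DC3": ((0.95, 1.0, 1.0), 1.0),
    "cisplatin": ((0.4, 2.0, 2.0), 0.5),
}
_DEFAULT_DOSES = {"control": 0.0, "EDL21": 10.0, "Pt-ttpy": 10.0,
                  "360A": 10.0, "Phen-DC3": 10.0, "cisplatin": 10.0}


def make_rho(ms: float, mr: float, rs: float) -> np.ndarray:
    """Build the (M, R, S) log-scale correlation matrix from its pairs."""
    return np.array([[1.0, mr, ms], [mr, 1.0, rs], [ms, rs, 1.0]])


def make_group(
    cell_line: str, compound: str, *, dose: float | None = None,
    cells_per_field: int = 30, fields_per_well: int = 4,
    wells: tuple[str, ...] = (),
) -> GroupSpec:
    """Default GroupSpec for one (cell line, compound) condition."""
    base = _BASELINE_RHO[cell_line]
    effects = _TUMOR_EFFECTS if cell_line == "HeLa" else _NORMAL_EFFECTS
    (mult, shrink) = effects[compound]
    rho = make_rho(base["MS"] * shrink, base["MR"] * shrink, base["RS"] * shrink)
    mu = tuple(m + np.log(k) for m, k in zip(_BASELINE_MU, mult))
    return GroupSpec(
        cell_line=cell_line, compound=compound,
        dose=_DEFAULT_DOSES[compound] if dose is None else dose,
        mu=mu, rho=rho, cells_per_field=cells_per_field,
        fields_per_well=fields_per_well, wells=wells,
    )


def default_screen_layout(
    cells_per_field: int = 30, fields_per_well: int = 4, wells_per_group: int = 2
) -> PlateLayout:
    """The default synthetic screen: 2 cell lines x 6 treatment groups,
    2 wells per group, 4 fields per well, ~30 cells per field (>= 200 cells
    per group after segmentation losses)."""
    all_wells = [f"{r}{c}" for r in WELL_ROWS for c in WELL_COLS]
    groups = {}
    i = 0
    for cell_line in ("HeLa", "HPFC"):
        for compound in _TUMOR_EFFECTS:
            wells = tuple(all_wells[i: i + wells_per_group])
            i += wells_per_group
            groups[f"{cell_line}:{compound}"] = make_group(
                cell_line, compound, cells_per_field=cells_per_field,
                fields_per_well=fields_per_well, wells=wells,
            )
    return PlateLayout(plate_id="synthetic-screen-01", groups=groups)


def default_geometry(**overrides) -> FieldGeometry:
    return replace(FieldGeometry(), **overrides) if overrides else FieldGeometry()


def _field_seed(master_seed: int, field_index: int) -> np.random.SeedSequence:
    """Documented counter scheme: child entropy = (master, field counter)."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(field_index,))


def generate_plate(
    layout: PlateLayout, geom: FieldGeometry, seed: int, out_dir: str | Path,
    write_masks: bool = True,
) -> dict:
    """Simulate every field of the plate, writing TIFFs, ground truth and a
    JSON manifest; fully deterministic under ``seed``.

    Returns the manifest dict.  Per field: a multi-page TIFF with pages in
    ``CHANNEL_ORDER`` (channel names in page descriptions); optionally a
    label-mask TIFF (pages: nuclei, cells, mito); ground-truth latents are
    pooled into ``ground_truth.csv``.
    """
    out = Path(out_dir)
    (out / "fields").mkdir(parents=True, exist_ok=True)
    if write_masks:
        (out / "masks").mkdir(exist_ok=True)

    manifest: dict = {
        "plate_id": layout.plate_id, "seed": int(seed),
        "geometry": {k: v for k, v in vars(geom).items()},
        "groups": {
            name: {
                "cell_line": spec.cell_line, "compound": spec.compound,
                "dose": spec.dose, "mu": list(spec.mu),
                "sigma": list(spec.sigma), "rho": spec.rho.tolist(),
                "cells_per_field": spec.cells_per_field,
                "fields_per_well": spec.fields_per_well,
                "wells": list(spec.wells),
            }
            for name, spec in layout.groups.items()
        },
        "fields": [],
    }
    gt_frames = []
    counter = 0
    for name, spec in layout.groups.items():
        for well in spec.wells:
            for fidx in range(spec.fields_per_well):
                ss = _field_seed(seed, counter)
                lat_seed, render_seed = ss.generate_state(2) % (2**31)
                latents = sample_latents(spec, spec.cells_per_field, int(lat_seed))
                stack, gt = render_field(latents, geom, int(render_seed))

                stem = f"{well}_f{fidx}"
                path = out / "fields" / f"{stem}.tiff"
                tifffile.imwrite(
                    path,
                    np.stack([stack[r] for r in CHANNEL_ORDER]),
                    metadata=None,
                    photometric="minisblack",
                    description=json.dumps({"channels": list(CHANNEL_ORDER)}),
                )
                entry = {
                    "well": well, "field": fidx, "path": str(path.relative_to(out)),
                    "group": name, "cell_line": spec.cell_line,
                    "compound": spec.compound, "dose": spec.dose,
                    "n_cells_true": gt.n_cells,
                }
                if write_masks:
                    mpath = out / "masks" / f"{stem}_labels.tiff"
                    tifffile.imwrite(
                        mpath,
                        np.stack([gt.nuclei, gt.cells, gt.mito]).astype(np.uint16),
                        photometric="minisblack",
                        description=json.dumps(
                            {"pages": ["nuclei", "cells", "mito"]}
                        ),
                    )
                    entry["mask_path"] = str(mpath.relative_to(out))
                manifest["fields"].append(entry)

                t = gt.table.copy()
                t.insert(0, "field", fidx)
                t.insert(0, "well", well)
                t["cell_line"] = spec.cell_line
                t["compound"] = spec.compound
                t["dose"] = spec.dose
                gt_frames.append(t)
                counter += 1

    gt_all = (
        pd.concat(gt_frames, ignore_index=True)
        if gt_frames
        else pd.DataFrame(columns=["well", "field", "cell_id", "M", "R", "S"])
    )
    gt_all.to_csv(out / "ground_truth.csv", index=False)
    manifest["ground_truth"] = "ground_truth.csv"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_field(plate_dir: str | Path, entry: dict) -> ChannelStack:
    """Load one manifest field entry back into a ChannelStack."""
    pages = tifffile.imread(Path(plate_dir) / entry["path"])
    return ChannelStack(dict(zip(CHANNEL_ORDER, pages)))
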
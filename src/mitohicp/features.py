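"""CellProfiler-style morphological feature extraction.

Computes the per-cell feature families enumerated by the manifest —
shape descriptors, intensity statistics, Haralick texture on gray-level
co-occurrence matrices, cross-channel colocalization, a granularity
spectrum of morphological openings, radial intensity distribution,
neighbour metrics and location — and aggregates cell-level tables into
per-image mean profiles for phenotypic analysis.

Conventions: features undefined on degenerate geometry are recorded as
NaN (never silently zero), with one deliberate exception: Haralick
correlation on a zero-variance region is defined as 0 to avoid
missing-value cascades through downstream profiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import disk, erosion, opening

from .manifest import (
    CHANNELS,
    FeatureManifest,
    GRANULARITY_RADII,
    HARALICK_STATS,
    INTENSITY_STATS,
    NEIGHBOR_STATS,
    RADIAL_BINS,
    RADIAL_STATS,
    SHAPE_STATS,
    default_manifest,
)

__all__ = [
    "glcm_texture",
    "shape_descriptors",
    "intensity_descriptors",
    "cross_channel_corr",
    "granularity_spectrum",
    "radial_distribution",
    "neighbor_metrics",
    "extract_features",
    "aggregate_image_profiles",
]

#: the 4 axial/diagonal co-occurrence offsets of length d, as (drow, dcol)
def _default_offsets(distance: int) -> list[tuple[int, int]]:
    d = int(distance)
    return [(0, d), (d, 0), (d, d), (d, -d)]


def _quantize(
    image: np.ndarray, mask: np.ndarray, levels: int,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rescale masked intensities to integer levels 0..levels-1; pixels
    outside the mask are marked -1.  Default range is the per-object
    min-max; a fixed ``value_range`` pins the quantization instead."""
    q = np.full(image.shape, -1, dtype=np.int64)
    vals = image[mask]
    lo, hi = value_range if value_range is not None else (vals.min(), vals.max())
    if hi > lo:
        q[mask] = np.clip(
            ((image[mask] - lo) / (hi - lo) * levels).astype(np.int64), 0, levels - 1
        )
    else:
        q[mask] = 0
    return q


def glcm_texture(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int = 64,
    distance: int = 3,
    offsets: list[tuple[int, int]] | None = None,
    value_range: tuple[float, float] | None = None,
) -> dict[str, float]:
    """13 Haralick statistics of the gray-level co-occurrence matrix.

    Masked intensities are min-max rescaled to ``levels`` gray levels
    (or to a fixed ``value_range`` when given);
    symmetric, normalized co-occurrence matrices are accumulated at the
    four axial/diagonal offsets of length ``distance`` (both pixels of a
    pair must lie in the mask) and averaged before computing the
    statistics.  An empty / sub-2-pixel mask yields all-NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        return {s: np.nan for s in HARALICK_STATS}
    image = np.asarray(image, dtype=float)
    q = _quantize(image, mask, levels, value_range)
    offsets = offsets if offsets is not None else _default_offsets(distance)

    acc = np.zeros((levels, levels))
    n_used = 0
    H, W = q.shape
    for dr, dc in offsets:
        # align the image with itself shifted by (dr, dc)
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr: r1 + dr, c0 + dc: c1 + dc]
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        counts = np.zeros((levels, levels))
        np.add.at(counts, (a[valid], b[valid]), 1.0)
        counts = counts + counts.T  # symmetric
        acc += counts / counts.sum()
        n_used += 1
    if n_used == 0:
        return {s: np.nan for s in HARALICK_STATS}
    P = acc / n_used
    return _haralick_from_glcm(P)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    px = P.sum(axis=1)
    mu = float((np.arange(L) * px).sum())
    var = float(((np.arange(L) - mu) ** 2 * px).sum())

    out: dict[str, float] = {}
    out["asm"] = float((P**2).sum())
    out["contrast"] = float(((i - j) ** 2 * P).sum())
    if var > 1e-12:
        out["correlation"] = float((((i - mu) * (j - mu)) * P).sum() / var)
    else:
        out["correlation"] = 0.0  # zero-variance convention
    out["variance"] = var
    out["idm"] = float((P / (1.0 + (i - j) ** 2)).sum())

    # sum / difference distributions
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (i + j).ravel(), P.ravel())
    k = np.arange(2 * L - 1)
    out["sum_avg"] = float((k * psum).sum())
    out["sum_var"] = float(((k - out["sum_avg"]) ** 2 * psum).sum())
    out["sum_entropy"] = _entropy(psum)
    out["entropy"] = _entropy(P.ravel())

    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(i - j).ravel(), P.ravel())
    kd = np.arange(L)
    dmean = float((kd * pdiff).sum())
    out["diff_var"] = float(((kd - dmean) ** 2 * pdiff).sum())
    out["diff_entropy"] = _entropy(pdiff)

    hxy = out["entropy"]
    hx = _entropy(px)
    outer = np.outer(px, px)
    pos = (P > 0) & (outer > 0)
    hxy1 = float(-(P[pos] * np.log(outer[pos])).sum())
    opos = outer > 0
    hxy2 = float(-(outer[opos] * np.log(outer[opos])).sum())
    out["imc1"] = (hxy - hxy1) / hx if hx > 1e-12 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


def shape_descriptors(mask: np.ndarray) -> dict[str, float]:
    """15 shape descriptors of a single binary object.

    Perimeter follows the Crofton 4-direction approximation (unbiased on
    smooth digital shapes, so the form factor of a digitized disc stays
    near 1); orientation is in radians, row-major axes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {s: np.nan for s in SHAPE_STATS}
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(props.perimeter_crofton)
    minr, minc, maxr, maxc = props.bbox
    out = {
        "area": area,
        "perimeter": perim,
        "form_factor": 4 * np.pi * area / perim**2 if perim > 0 else np.nan,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "major_axis": float(props.axis_major_length),
        "minor_axis": float(props.axis_minor_length),
        "aspect_ratio": (
            float(props.axis_major_length / props.axis_minor_length)
            if props.axis_minor_length > 0
            else np.nan
        ),
        "orientation": float(props.orientation),
        "equiv_diameter": float(props.equivalent_diameter_area),
        "euler_number": float(props.euler_number),
        "bbox_width": float(maxc - minc),
        "bbox_height": float(maxr - minr),
        "compactness": perim**2 / (4 * np.pi * area),
    }
    return out


def intensity_descriptors(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """13 intensity statistics over one masked region."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {s: np.nan for s in INTENSITY_STATS}
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    med = float(np.median(vals))
    out = {
        "mean": float(vals.mean()),
        "median": med,
        "sd": float(vals.std()),
        "mad": float(np.median(np.abs(vals - med))),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "integrated": float(vals.sum()),
        "q05": float(np.percentile(vals, 5)),
        "q25": float(np.percentile(vals, 25)),
        "q75": float(np.percentile(vals, 75)),
        "q95": float(np.percentile(vals, 95)),
    }
    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    total = vals.sum()
    if total > 0:
        wcentroid = (coords * vals[:, None]).sum(axis=0) / total
        out["mass_disp"] = float(np.linalg.norm(wcentroid - centroid))
    else:
        out["mass_disp"] = np.nan
    edge = mask & ~erosion(mask, footprint=np.ones((3, 3), bool))
    out["edge_mean"] = float(image[edge].mean()) if edge.any() else np.nan
    return out


def cross_channel_corr(
    image_a: np.ndarray, image_b: np.ndarray, mask: np.ndarray
) -> dict[str, float]:
    """Colocalization metrics over masked pixels: Pearson correlation,
    overlap coefficient, and the Manders fraction of A on B-positive."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        return {"pcc": np.nan, "overlap": np.nan, "manders": np.nan}
    a = np.asarray(image_a, dtype=float)[mask]
    b = np.asarray(image_b, dtype=float)[mask]
    if a.std() == 0 or b.std() == 0:
        pcc = np.nan
    else:
        pcc = float(np.corrcoef(a, b)[0, 1])
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    overlap = float((a * b).sum() / denom) if denom > 0 else np.nan
    asum = a.sum()
    manders = float(a[b > 0].sum() / asum) if asum > 0 else np.nan
    return {"pcc": pcc, "overlap": overlap, "manders": manders}


from functools import lru_cache


@lru_cache(maxsize=32)
def _disk_sequence(radius: int):
    return disk(radius, decomposition="sequence")


@lru_cache(maxsize=32)
def _disk_sequence_3d(radius: int):
    # (1, k, k) footprints: apply the 2-D disc independently per stacked plane
    return tuple((fp[None], n) for fp, n in disk(radius, decomposition="sequence"))


def _granularity_multichannel(
    images: dict[str, np.ndarray], mask: np.ndarray, radii=GRANULARITY_RADII
) -> dict[str, dict[int, float]]:
    """Granularity spectra of several channels over one mask, computed with
    a single opening per radius on the stacked channels."""
    names = list(images)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {ch: {r: np.nan for r in radii} for ch in names}
    pad = max(radii) + 1
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    planes = [
        np.pad(np.where(mask[sl], np.asarray(images[ch], dtype=float)[sl], 0.0), pad)
        for ch in names
    ]
    stack = np.stack(planes)
    totals = stack.sum(axis=(1, 2))
    out = {ch: {} for ch in names}
    prev = totals.copy()
    for r in radii:
        remaining = opening(stack, footprint=_disk_sequence_3d(r)).sum(axis=(1, 2))
        loss = (prev - remaining)
        for i, ch in enumerate(names):
            out[ch][r] = float(loss[i] / totals[i]) if totals[i] > 0 else np.nan
        prev = remaining
    return out


def granularity_spectrum(
    image: np.ndarray, mask: np.ndarray, radii=GRANULARITY_RADII
) -> dict[int, float]:
    """Normalized intensity loss under successive morphological openings.

    Value at radius r is the fraction of the initial masked intensity
    removed between openings with discs of radius r-1 and r; once the
    opening radius exceeds the object radius everything is removed and the
    spectrum sums to 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {r: np.nan for r in radii}
    pad = max(radii) + 1
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    crop = np.where(mask[sl], np.asarray(image, dtype=float)[sl], 0.0)
    crop = np.pad(crop, pad)
    total = crop.sum()
    if total <= 0:
        return {r: np.nan for r in radii}
    out = {}
    prev = total
    for r in radii:
        remaining = opening(crop, footprint=_disk_sequence(r)).sum()
        out[r] = float((prev - remaining) / total)
        prev = remaining
    return out


def radial_distribution(
    image: np.ndarray,
    cell_mask: np.ndarray,
    center: tuple[float, float],
    n_bins: int = RADIAL_BINS,
) -> dict[str, float]:
    """Radial intensity statistics over equal-area concentric bins.

    Cell pixels are split into ``n_bins`` equal-population bins by their
    distance from ``center`` (the nucleus centroid); per bin: fraction of
    total intensity (frac_at_d), that fraction normalized by the pixel
    fraction (mean_frac) and the coefficient of variation of pixel
    intensities (radial_cv).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    out = {}
    coords = np.argwhere(cell_mask)
    if len(coords) < n_bins:
        for b in range(1, n_bins + 1):
            for stat in RADIAL_STATS:
                out[f"{stat}_b{b}"] = np.nan
        return out
    vals = np.asarray(image, dtype=float)[cell_mask]
    dist = np.linalg.norm(coords - np.asarray(center), axis=1)
    order = np.argsort(dist, kind="stable")
    bins = np.array_split(order, n_bins)
    total = vals.sum()
    for b, idx in enumerate(bins, start=1):
        v = vals[idx]
        frac = v.sum() / total if total > 0 else np.nan
        pix_frac = len(idx) / len(vals)
        out[f"frac_at_d_b{b}"] = float(frac) if total > 0 else np.nan
        out[f"mean_frac_b{b}"] = float(frac / pix_frac) if total > 0 else np.nan
        m = v.mean()
        out[f"radial_cv_b{b}"] = float(v.std() / m) if m > 0 else np.nan
    return out


def neighbor_metrics(labels: np.ndarray, touch_distance: int = 2) -> pd.DataFrame:
    """Per-object neighbour metrics for one label map.

    n_neighbors counts distinct labels within ``touch_distance`` px of the
    object; percent_touching is the percentage of the object's boundary
    pixels with another label in that range; dist1/dist2 are the first and
    second closest centroid distances, angle the angle (degrees) between
    them at this object, mean_dist the mean centroid distance to all
    other objects.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels[labels > 0])
    rows = []
    centroids = {}
    for lab in ids:
        centroids[lab] = np.argwhere(labels == lab).mean(axis=0)
    fp = disk(touch_distance)
    for lab in ids:
        own = labels == lab
        boundary = own & ~erosion(own, footprint=np.ones((3, 3), bool))
        grown = ndi.binary_dilation(boundary, structure=fp)
        near = np.unique(labels[grown & (labels > 0) & ~own])
        n_nb = len(near)
        if boundary.any():
            # boundary pixels whose dilated footprint meets another label
            other = (labels > 0) & ~own
            other_near = ndi.binary_dilation(other, structure=fp)
            pct = 100.0 * (boundary & other_near).sum() / boundary.sum()
        else:
            pct = 0.0
        others = [o for o in ids if o != lab]
        c = centroids[lab]
        row = {"label": int(lab), "n_neighbors": float(n_nb),
               "percent_touching": float(pct), "dist1": np.nan, "dist2": np.nan,
               "angle": np.nan, "mean_dist": np.nan}
        if others:
            dists = np.array([np.linalg.norm(centroids[o] - c) for o in others])
            order = np.argsort(dists, kind="stable")
            row["dist1"] = float(dists[order[0]])
            row["mean_dist"] = float(dists.mean())
            if len(others) >= 2:
                row["dist2"] = float(dists[order[1]])
                v1 = centroids[others[order[0]]] - c
                v2 = centroids[others[order[1]]] - c
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                row["angle"] = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        rows.append(row)
    return pd.DataFrame(rows, columns=["label"] + list(NEIGHBOR_STATS))


def _crop(arrs: list[np.ndarray], mask: np.ndarray, pad: int = 2):
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    sl = (
        slice(max(0, rows[0] - pad), rows[-1] + 1 + pad),
        slice(max(0, cols[0] - pad), cols[-1] + 1 + pad),
    )
    return [a[sl] for a in arrs], sl


def extract_features(
    stack,
    maps: dict[str, np.ndarray],
    manifest: FeatureManifest | None = None,
    glcm_levels: int = 64,
    glcm_distance: int = 3,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Per-cell feature table with exactly the manifest's columns, in order.

    ``maps`` must carry ``cells``/``nuclei``/``mito`` label maps sharing the
    cell labelling.  Only the families present in the manifest are
    computed; a field with no cells yields an empty table with the full
    header.
    """
    manifest = manifest or default_manifest()
    cells = np.asarray(maps["cells"])
    nuclei = np.asarray(maps["nuclei"])
    mito = np.asarray(maps["mito"])
    comp_maps = {"cell": cells, "nucleus": nuclei, "mito": mito}
    wanted = set(manifest.table["family"])
    names = manifest.names
    ids = np.unique(cells[cells > 0])

    meta_cols = dict(metadata or {})
    if ids.size == 0:
        return pd.DataFrame(columns=["cell_id", *meta_cols, *names])

    channel_images = {ch: np.asarray(stack[ch], dtype=float) for ch in CHANNELS}
    nb_tables = {}
    if "neighbors" in wanted:
        for comp in ("cell", "nucleus"):
            t = neighbor_metrics(comp_maps[comp])
            nb_tables[comp] = t.set_index("label") if len(t) else t

    rows = []
    pairs = [
        (a, b) for idx, a in enumerate(CHANNELS) for b in CHANNELS[idx + 1:]
    ]
    for lab in ids:
        feat: dict[str, float] = {}
        masks = {c: comp_maps[c] == lab for c in comp_maps}
        cell_mask = masks["cell"]
        crop_imgs, sl = _crop(list(channel_images.values()), cell_mask, pad=2)
        crop_imgs = dict(zip(CHANNELS, crop_imgs))
        crop_masks = {c: masks[c][sl] for c in masks}

        if "shape" in wanted:
            for comp in comp_maps:
                for stat, v in shape_descriptors(crop_masks[comp]).items():
                    feat[f"{comp}_shape_{stat}"] = v
        if "intensity" in wanted:
            for comp in comp_maps:
                for ch in CHANNELS:
                    d = intensity_descriptors(crop_imgs[ch], crop_masks[comp])
                    for stat, v in d.items():
                        feat[f"{comp}_{ch}_int_{stat}"] = v
        if "texture" in wanted:
            for comp in comp_maps:
                for ch in CHANNELS:
                    d = glcm_texture(
                        crop_imgs[ch], crop_masks[comp],
                        levels=glcm_levels, distance=glcm_distance,
                    )
                    for stat, v in d.items():
                        feat[f"{comp}_{ch}_tex_{stat}"] = v
        if "correlation" in wanted:
            for comp in ("cell", "nucleus"):
                for a, b in pairs:
                    d = cross_channel_corr(crop_imgs[a], crop_imgs[b], crop_masks[comp])
                    for metric, v in d.items():
                        feat[f"{comp}_corr_{metric}_{a}_{b}"] = v
        if "granularity" in wanted:
            spectra = _granularity_multichannel(crop_imgs, crop_masks["cell"])
            for ch in CHANNELS:
                for r, v in spectra[ch].items():
                    feat[f"cell_{ch}_gran_r{r}"] = v
        if "radial" in wanted:
            nuc_mask = crop_masks["nucleus"]
            if nuc_mask.any():
                center = np.argwhere(nuc_mask).mean(axis=0)
            else:
                center = np.argwhere(crop_masks["cell"]).mean(axis=0)
            for ch in CHANNELS:
                d = radial_distribution(crop_imgs[ch], crop_masks["cell"], center)
                for key, v in d.items():
                    feat[f"cell_{ch}_radial_{key}"] = v
        if "neighbors" in wanted:
            for comp in ("cell", "nucleus"):
                t = nb_tables[comp]
                for stat in NEIGHBOR_STATS:
                    feat[f"{comp}_nb_{stat}"] = (
                        float(t.loc[lab, stat]) if lab in t.index else np.nan
                    )
        if "location" in wanted:
            for comp, chs in (("cell", CHANNELS), ("nucleus", CHANNELS), ("mito", ("mmp",))):
                m = masks[comp]
                if m.any():
                    coords = np.argwhere(m).astype(float)
                    cen = coords.mean(axis=0)
                    feat[f"{comp}_loc_centroid_row"] = cen[0]
                    feat[f"{comp}_loc_centroid_col"] = cen[1]
                    for ch in chs:
                        w = channel_images[ch][m]
                        tot = w.sum()
                        if tot > 0:
                            wc = (coords * w[:, None]).sum(axis=0) / tot
                            feat[f"{comp}_loc_wcentroid_{ch}_row"] = wc[0]
                            feat[f"{comp}_loc_wcentroid_{ch}_col"] = wc[1]
                        else:
                            feat[f"{comp}_loc_wcentroid_{ch}_row"] = np.nan
                            feat[f"{comp}_loc_wcentroid_{ch}_col"] = np.nan
                else:
                    feat[f"{comp}_loc_centroid_row"] = np.nan
                    feat[f"{comp}_loc_centroid_col"] = np.nan
                    for ch in chs:
                        feat[f"{comp}_loc_wcentroid_{ch}_row"] = np.nan
                        feat[f"{comp}_loc_wcentroid_{ch}_col"] = np.nan

        row = {"cell_id": int(lab), **meta_cols}
        row.update({name: feat.get(name, np.nan) for name in names})
        rows.append(row)

    return pd.DataFrame(rows, columns=["cell_id", *meta_cols, *names])


def aggregate_image_profiles(
    table: pd.DataFrame,
    keys: tuple[str, ...] = ("well", "field"),
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-image mean profile: average each feature over all cells of one
    image, skipping missing values; a cell-count column is appended and
    non-feature metadata (cell_line, compound, ...) is carried through."""
    if table.empty:
        raise ValueError("cannot aggregate an empty feature table")
    if feature_names is None:
        skip = set(keys) | {"cell_id"}
        feature_names = [
            c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    grouped = table.groupby(list(keys), sort=True, dropna=False)
    prof = grouped[feature_names].mean()
    prof["n_cells"] = grouped.size()
    meta_cols = [
        c for c in table.columns
        if c not in feature_names and c not in keys and c != "cell_id"
    ]
    for c in meta_cols:
        prof[c] = grouped[c].first()
    return prof.reset_index()
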
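"""Nucleus / cell / mitochondria segmentation.

A classical high-content-screening segmentation stage: nuclei are detected
on the DNA-stain channel (Gaussian smoothing, Otsu threshold, size filter,
optional watershed splitting of touching objects), cell bodies are grown
from the nuclear seeds out to a bounded distance guided by a cytoplasmic
channel, and per-cell mitochondrial masks are extracted from the
membrane-potential channel with a white top-hat plus per-cell threshold.
All label maps are 2-D int32 images with background 0 and labels carried
over from the nuclear seeds; coordinates are 0-based row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.morphology import disk, white_tophat
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "NucleiParams",
    "segment_nuclei",
    "expand_to_cells",
    "segment_mitochondria",
    "segment_field",
]


@dataclass(frozen=True)
class NucleiParams:
    smooth_sigma: float = 2.0
    threshold: float | None = None   # None -> Otsu on the smoothed image
    min_area: int = 40
    split: bool = True
    split_min_distance: int = 7   # ~expected nucleus radius; suppresses neck peaks
    exclude_border: bool = False


def _relabel(labels: np.ndarray) -> np.ndarray:
    return relabel_sequential(labels)[0].astype(np.int32)


def segment_nuclei(hoechst: np.ndarray, params: NucleiParams | None = None) -> np.ndarray:
    """Label nuclei on the DNA-stain channel.

    Pipeline: Gaussian smoothing -> automatic (Otsu) or fixed threshold ->
    connected components -> watershed split of touching objects on the
    distance transform (when ``params.split``) -> area filter -> contiguous
    relabelling 1..K.  A blank (constant) image yields an empty map.
    """
    params = params or NucleiParams()
    img = np.asarray(hoechst, dtype=float)
    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    if params.threshold is not None:
        thr = params.threshold
    else:
        if np.ptp(smoothed) == 0:
            return np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)

    labels, _ = ndi.label(fg)
    if params.split:
        dist = ndi.distance_transform_edt(fg)
        # peak_local_max scans row-major, so plateau ties resolve to the
        # lexicographically first pixel — documented for reproducibility
        peaks = peak_local_max(
            dist, min_distance=params.split_min_distance, labels=labels,
            exclude_border=False,
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if markers.any():
            labels = watershed(-dist, markers, mask=fg)

    if params.min_area > 0:
        sizes = np.bincount(labels.ravel())
        kill = np.flatnonzero(sizes < params.min_area)
        labels[np.isin(labels, kill[kill > 0])] = 0
    if params.exclude_border:
        border = np.unique(
            np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
            )
        )
        labels[np.isin(labels, border[border > 0])] = 0
    return _relabel(labels)


def expand_to_cells(
    nuclei: np.ndarray, guide: np.ndarray, max_distance: float
) -> np.ndarray:
    """Grow cell bodies from nuclear seeds, bounded by ``max_distance``.

    Each background pixel within ``max_distance`` of a nucleus is assigned
    to its nearest nucleus (exact Euclidean distance transform), restricted
    to the guide channel's foreground (Otsu; a flat guide imposes no
    restriction).  Cells are disjoint, keep their seed's label, and with a
    uniform guide an isolated nucleus grows to its morphological dilation
    by a disc of radius ``max_distance``.
    """
    nuclei = np.asarray(nuclei)
    guide = np.asarray(guide, dtype=float)
    if nuclei.shape != guide.shape:
        raise ValueError(f"shape mismatch: nuclei {nuclei.shape} vs guide {guide.shape}")
    if not nuclei.any() or max_distance <= 0:
        return nuclei.astype(np.int32).copy()

    dist, (ir, ic) = ndi.distance_transform_edt(nuclei == 0, return_indices=True)
    if np.ptp(guide) > 0:
        fg = guide > threshold_otsu(guide)
    else:
        fg = np.ones_like(guide, dtype=bool)
    cells = np.where((dist <= max_distance) & (fg | (nuclei > 0)),
                     nuclei[ir, ic], 0)
    return cells.astype(np.int32)


def segment_mitochondria(
    mmp: np.ndarray, cells: np.ndarray, tophat_radius: int = 3,
    threshold: float | None = None,
) -> np.ndarray:
    """Per-cell mitochondrial mask from the membrane-potential channel.

    White top-hat (disc of ``tophat_radius``) isolates thin bright
    structures; each cell is then thresholded independently (Otsu within
    the cell unless a fixed ``threshold`` is given) and the mask labelled
    by its parent cell's label, so containment is guaranteed.
    """
    if tophat_radius < 1:
        raise ValueError("tophat_radius must be >= 1")
    mmp = np.asarray(mmp, dtype=float)
    cells = np.asarray(cells)
    if mmp.shape != cells.shape:
        raise ValueError("mmp image and cell map shapes differ")
    enhanced = white_tophat(mmp, footprint=disk(tophat_radius))
    mito = np.zeros(cells.shape, dtype=np.int32)
    for lab in np.unique(cells[cells > 0]):
        inside = cells == lab
        vals = enhanced[inside]
        if threshold is not None:
            thr = threshold
        else:
            if np.ptp(vals) == 0:
                continue
            thr = threshold_otsu(vals)
        mito[inside & (enhanced > thr)] = lab
    return mito


def segment_field(
    stack, nuclei_params: NucleiParams | None = None,
    max_cell_distance: float = 12.0, tophat_radius: int = 3,
) -> dict[str, np.ndarray]:
    """Convenience wrapper: full segmentation of one ChannelStack."""
    nuclei = segment_nuclei(stack["hoechst"], nuclei_params)
    cells = expand_to_cells(nuclei, stack["ros"], max_cell_distance)
    mito = segment_mitochondria(stack["mmp"], cells, tophat_radius)
    return {"nuclei": nuclei, "cells": cells, "mito": mito}
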
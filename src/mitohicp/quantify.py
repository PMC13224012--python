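"""Per-cell, background-corrected fluorescence quantification.

One row per segmented cell with mean / median / integrated intensity per
channel over the relevant compartment, a scalar per-field background
estimate subtracted (clipped at zero), compartment areas, and
mitochondria-restricted means for the mitochondrial dyes (mmp, mtros).
These per-cell measurements feed the group summaries, the morphological
profiles and the MMP-ROS coupling statistics downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .simgen import CHANNEL_ORDER, ChannelStack

__all__ = ["estimate_background", "measure_cells", "pool_screen"]

#: compartment over which each channel's primary readout is taken
PRIMARY_COMPARTMENT = {"hoechst": "nucleus", "ros": "cell", "mtros": "cell", "mmp": "cell"}


def estimate_background(
    image: np.ndarray, cells: np.ndarray, method: str = "percentile",
    percentile: float = 5.0,
) -> float:
    """Scalar background estimate from non-cell (label 0) pixels.

    Default is the 5th percentile of background pixels; ``method="median"``
    uses their median.  Requires at least 100 background pixels.
    """
    bg = np.asarray(image, dtype=float)[np.asarray(cells) == 0]
    if bg.size < 100:
        raise ValueError(
            f"only {bg.size} background pixels; configure a fixed background instead"
        )
    if method == "percentile":
        return float(np.percentile(bg, percentile))
    if method == "median":
        return float(np.median(bg))
    raise ValueError(f"unknown background method {method!r}")


def _labelled_stats(image: np.ndarray, labels: np.ndarray, index: np.ndarray):
    means = ndi.mean(image, labels, index)
    medians = ndi.median(image, labels, index)
    areas = ndi.sum_labels(np.ones_like(labels), labels, index)
    return means, medians, areas


def measure_cells(
    stack: ChannelStack,
    cells: np.ndarray,
    nuclei: np.ndarray,
    mito: np.ndarray,
    background: dict[str, float] | None = None,
    metadata: dict | None = None,
) -> pd.DataFrame:
    """Measure every cell of one field across all channels.

    For each channel: mean, median and integrated intensity over the
    channel's primary compartment plus a background-corrected mean
    ``max(mean - background, 0)``; mito-restricted (and corrected) means
    for mmp and mtros; areas of the nucleus, cell and mitochondrial masks.
    ``metadata`` key/values (well, field, cell_line, ...) are copied onto
    every row.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    mito = np.asarray(mito)
    if cells.shape != stack.shape:
        raise ValueError("label maps and stack shapes differ")

    cell_labels = np.unique(cells[cells > 0])
    nuc_labels = set(np.unique(nuclei[nuclei > 0]).tolist())
    orphan = nuc_labels - set(cell_labels.tolist())
    if orphan:
        raise ValueError(f"nucleus labels without a cell: {sorted(orphan)}")
    if cell_labels.size == 0:
        return pd.DataFrame()

    background = background or {}
    compartments = {"cell": cells, "nucleus": nuclei, "mito": mito}
    out = pd.DataFrame({"cell_id": cell_labels})
    for key, value in (metadata or {}).items():
        out[key] = value

    for comp_name, comp in compartments.items():
        areas = ndi.sum_labels(np.ones_like(comp), comp, cell_labels)
        out[f"{comp_name}_px"] = areas.astype(int)

    for role in CHANNEL_ORDER:
        img = np.asarray(stack[role], dtype=float)
        comp_name = PRIMARY_COMPARTMENT[role]
        comp = compartments[comp_name]
        present = np.isin(cell_labels, np.unique(comp[comp > 0]))
        means = np.full(cell_labels.shape, np.nan)
        medians = np.full(cell_labels.shape, np.nan)
        areas = np.zeros(cell_labels.shape)
        if present.any():
            idx = cell_labels[present]
            means[present], medians[present], areas[present] = _labelled_stats(img, comp, idx)
        bg = float(background.get(role, 0.0))
        out[f"{role}_mean"] = means
        out[f"{role}_median"] = medians
        out[f"{role}_integrated"] = means * areas
        out[f"{role}_corr_mean"] = np.maximum(means - bg, 0.0)
        if role in ("mmp", "mtros"):
            m_present = np.isin(cell_labels, np.unique(mito[mito > 0]))
            m_means = np.full(cell_labels.shape, np.nan)
            if m_present.any():
                m_means[m_present] = ndi.mean(img, mito, cell_labels[m_present])
            out[f"{role}_mito_mean"] = m_means
            out[f"{role}_mito_corr_mean"] = np.maximum(m_means - bg, 0.0)
    return out


def pool_screen(
    tables: list[pd.DataFrame], experiment_ids: list | None = None
) -> pd.DataFrame:
    """Concatenate per-field cell tables into one screen-level table.

    Column sets must agree; an ``experiment`` column is attached when
    ``experiment_ids`` is given (one id per table).  Duplicate
    (well, field, cell_id) keys are rejected.
    """
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame()
    cols = set(tables[0].columns)
    for t in tables[1:]:
        if set(t.columns) != cols:
            raise ValueError("per-field tables have inconsistent columns")
    if experiment_ids is not None:
        if len(experiment_ids) != len(tables):
            raise ValueError("need one experiment id per table")
        tables = [t.assign(experiment=e) for t, e in zip(tables, experiment_ids)]
    pooled = pd.concat(tables, ignore_index=True)
    keys = [k for k in ("experiment", "well", "field", "cell_id") if k in pooled.columns]
    if len(keys) > 1 and pooled.duplicated(subset=keys).any():
        dups = pooled[pooled.duplicated(subset=keys)][keys].iloc[0].tolist()
        raise ValueError(f"duplicate cell keys, first: {dups}")
    return pooled
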
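"""Redox-coupling statistics: MMP vs (mt)ROS correlation structure.

At single-cell resolution the membrane-potential readout (MMP) correlates
with both the whole-cell ROS and the mitochondrial-superoxide readouts;
the strength of these correlations — and how treatments weaken them — is
the coupling phenotype.  This module computes Pearson correlations per
group (pooled over cells and per image), Fisher r-to-z transforms with
normal-theory confidence intervals, and z-tests comparing correlation
strength between two independent samples:

    Z = (z_r1 - z_r2) / sqrt(1/(n1-3) + 1/(n2-3)),   z_r = atanh(r)

Three contrast families are emitted by :func:`coupling_profile`:
MMP-ROS vs MMP-mtROS within each group, each pair across cell lines,
and each treatment vs control within a cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "pearson_r",
    "fisher_transform",
    "fisher_ci",
    "CouplingResult",
    "CorrelationComparison",
    "compare_independent_correlations",
    "coupling_profile",
]

#: single-cell table columns holding the three readouts, in (M, R, S) order
DEFAULT_READOUTS = {
    "MMP": "mmp_mito_corr_mean",
    "ROS": "ros_corr_mean",
    "mtROS": "mtros_mito_corr_mean",
}
PAIRS = (("MMP", "ROS"), ("MMP", "mtROS"))


def pearson_r(x, y) -> tuple[float, int]:
    """Pearson product-moment correlation after dropping missing pairs.

    Returns (r, n).  Fewer than 3 complete pairs or zero variance in
    either variable yields (nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3 or x.std() == 0 or y.std() == 0:
        return np.nan, n
    return float(sps.pearsonr(x, y).statistic), n


def fisher_transform(r: float) -> float:
    """Fisher r-to-z: z_r = atanh(r) = 0.5*ln((1+r)/(1-r)); requires |r|<1."""
    if not np.abs(r) < 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory CI on r via the Fisher transform (needs n > 3)."""
    if n <= 3:
        return (np.nan, np.nan)
    z = fisher_transform(r)
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass
class CouplingResult:
    group: str
    pair: str
    scope: str              # "pooled" or "per_image"
    n: int
    r: float
    z_r: float
    ci95: tuple[float, float]
    per_image_r: list[float] = field(default_factory=list)

    def violin_summary(self) -> dict:
        """Median / IQR / mean of the per-image r distribution."""
        r = np.asarray([v for v in self.per_image_r if np.isfinite(v)])
        if r.size == 0:
            return {"median": np.nan, "q25": np.nan, "q75": np.nan, "mean": np.nan}
        return {
            "median": float(np.median(r)),
            "q25": float(np.percentile(r, 25)),
            "q75": float(np.percentile(r, 75)),
            "mean": float(r.mean()),
        }


@dataclass
class CorrelationComparison:
    label1: str
    label2: str
    r1: float
    n1: int
    r2: float
    n2: int
    Z: float
    p_one_sided: float
    p_two_sided: float
    note: str = "independent-sample Fisher z"


def compare_independent_correlations(
    r1: float, n1: int, r2: float, n2: int,
    label1: str = "sample1", label2: str = "sample2",
) -> CorrelationComparison:
    """Fisher z-test for the difference of two independent correlations.

    The one-sided p is the standard-normal tail beyond Z in the observed
    direction; the two-sided p is twice that.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both samples need n > 3")
    z1, z2 = fisher_transform(r1), fisher_transform(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    Z = float((z1 - z2) / se)
    p_one = float(sps.norm.sf(abs(Z)))
    return CorrelationComparison(
        label1=label1, label2=label2, r1=float(r1), n1=int(n1),
        r2=float(r2), n2=int(n2), Z=Z, p_one_sided=p_one,
        p_two_sided=min(1.0, 2 * p_one),
    )


def _group_r(sub: pd.DataFrame, xcol: str, ycol: str) -> tuple[float, int]:
    return pearson_r(sub[xcol], sub[ycol])


def coupling_profile(
    table: pd.DataFrame,
    readouts: dict[str, str] | None = None,
    group_keys: tuple[str, ...] = ("cell_line", "compound"),
    image_keys: tuple[str, ...] = ("well", "field"),
    control_label: str = "control",
    min_n: int = 4,
) -> tuple[list[CouplingResult], list[CorrelationComparison]]:
    """Coupling analysis of a pooled single-cell table.

    For every group and readout pair (MMP-ROS, MMP-mtROS): the pooled
    Pearson r over cells with Fisher z and CI, plus the per-image r list.
    Comparisons: (i) MMP-ROS vs MMP-mtROS within each group, (ii) each
    pair between cell lines for the control compound, (iii) each treatment
    vs control within each cell line.  Groups with n < ``min_n`` are
    skipped.
    """
    readouts = readouts or DEFAULT_READOUTS
    results: list[CouplingResult] = []
    by_group: dict[tuple, dict[str, CouplingResult]] = {}

    for gkey, sub in table.groupby(list(group_keys), sort=True):
        gname = ":".join(str(k) for k in gkey)
        if len(sub) < min_n:
            continue
        for a, b in PAIRS:
            r, n = _group_r(sub, readouts[a], readouts[b])
            pair = f"{a}-{b}"
            per_image = [
                _group_r(s, readouts[a], readouts[b])[0]
                for _, s in sub.groupby(list(image_keys), sort=True)
            ]
            res = CouplingResult(
                group=gname, pair=pair, scope="pooled", n=n, r=r,
                z_r=fisher_transform(r) if np.isfinite(r) and abs(r) < 1 else np.nan,
                ci95=fisher_ci(r, n) if np.isfinite(r) else (np.nan, np.nan),
                per_image_r=per_image,
            )
            results.append(res)
            by_group.setdefault(gkey, {})[pair] = res

    comparisons: list[CorrelationComparison] = []

    def _cmp(ra, rb, la, lb):
        if np.isfinite(ra.r) and np.isfinite(rb.r) and ra.n > 3 and rb.n > 3:
            comparisons.append(
                compare_independent_correlations(ra.r, ra.n, rb.r, rb.n, la, lb)
            )

    # (i) MMP-ROS vs MMP-mtROS within each group
    for gkey, pairs in by_group.items():
        if "MMP-ROS" in pairs and "MMP-mtROS" in pairs:
            gname = pairs["MMP-ROS"].group
            _cmp(pairs["MMP-ROS"], pairs["MMP-mtROS"],
                 f"{gname}|MMP-ROS", f"{gname}|MMP-mtROS")

    # (ii) each pair across cell lines (controls)
    line_idx = group_keys.index("cell_line") if "cell_line" in group_keys else 0
    comp_idx = group_keys.index("compound") if "compound" in group_keys else None
    control_groups = [
        g for g in by_group
        if comp_idx is None or g[comp_idx] == control_label
    ]
    for i, g1 in enumerate(control_groups):
        for g2 in control_groups[i + 1:]:
            if g1[line_idx] == g2[line_idx]:
                continue
            for pair in ("MMP-ROS", "MMP-mtROS"):
                if pair in by_group[g1] and pair in by_group[g2]:
                    _cmp(by_group[g1][pair], by_group[g2][pair],
                         f"{by_group[g1][pair].group}|{pair}",
                         f"{by_group[g2][pair].group}|{pair}")

    # (iii) each treatment vs control within cell line
    if comp_idx is not None:
        for gkey, pairs in by_group.items():
            if gkey[comp_idx] == control_label:
                continue
            ctrl_key = tuple(
                control_label if i == comp_idx else v for i, v in enumerate(gkey)
            )
            if ctrl_key not in by_group:
                continue
            for pair, res in pairs.items():
                if pair in by_group[ctrl_key]:
                    _cmp(res, by_group[ctrl_key][pair],
                         f"{res.group}|{pair}",
                         f"{by_group[ctrl_key][pair].group}|{pair}")

    return results, comparisons


def coupling_tables(
    results: list[CouplingResult], comparisons: list[CorrelationComparison]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten coupling results/comparisons into CSV-ready tables."""
    res_rows = []
    for r in results:
        row = {
            "group": r.group, "pair": r.pair, "scope": r.scope, "n": r.n,
            "r": r.r, "z_r": r.z_r, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
            "n_images": len(r.per_image_r),
        }
        row.update({f"violin_{k}": v for k, v in r.violin_summary().items()})
        res_rows.append(row)
    cmp_rows = [vars(c) for c in comparisons]
    return pd.DataFrame(res_rows), pd.DataFrame(cmp_rows)
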
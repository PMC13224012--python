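"""Group-comparison statistics and relative qPCR quantification.

Classic equal-variance (Student's) two-sample t-tests and one-way ANOVA
for treatment-vs-control readouts, star-coded group summaries, and the
ddCt relative-quantification calculator (relative level = 2^-ddCt with
dCt = Ct(target) - Ct(reference), centred on the control-group mean dCt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "unpaired_t",
    "one_way_anova",
    "ddct_quantify",
    "summarize_groups",
    "star_code",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


def unpaired_t(a, b, equal_var: bool = True) -> tuple[float, float, float]:
    """Unpaired two-sample t-test, Student's (equal-variance) by default.

    Returns (t, df, p_two_sided).  Welch's variant via ``equal_var=False``.
    Zero pooled variance with equal means gives (0, df, 1); with unequal
    means it is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if equal_var else np.nan
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def one_way_anova(groups: list) -> tuple[float, int, int, float]:
    """One-way ANOVA; returns (F, df_between, df_within, p).

    All-identical data across all groups gives (F=0, p=1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    allvals = np.concatenate(arrays)
    if np.ptp(allvals) == 0:
        return 0.0, df1, df2, 1.0
    res = sps.f_oneway(*arrays)
    return float(res.statistic), df1, df2, float(res.pvalue)


def ddct_quantify(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
) -> pd.DataFrame:
    """Relative quantification by the ddCt method.

    ``ct`` needs columns sample, group, gene, Ct.  Per sample:
    dCt = Ct(target) - Ct(reference); ddCt = dCt - mean dCt of the control
    group; rel_level = 2^-ddCt.  The control group's mean ddCt is 0 by
    construction.
    """
    required = {"sample", "group", "gene", "Ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    wide = ct.pivot_table(index=["sample", "group"], columns="gene", values="Ct",
                          aggfunc="mean")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
        missing = wide.index[wide[gene].isna()].tolist()
        if missing:
            raise ValueError(f"sample {missing[0][0]!r} lacks a Ct for {gene!r}")
    out = wide.reset_index()[["sample", "group"]]
    out["dct"] = (wide[target_gene] - wide[reference_gene]).to_numpy()
    ctrl = out.loc[out["group"] == control_group, "dct"]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    out["ddct"] = out["dct"] - ctrl.mean()
    out["rel_level"] = 2.0 ** (-out["ddct"])
    return out


def summarize_groups(
    table: pd.DataFrame,
    value: str,
    group: str = "compound",
    control_label: str = "control",
    test: str = "t",
    extra_keys: tuple[str, ...] = (),
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-group mean/median/SEM plus a test against the control group.

    ``test``: "t" (unpaired Student's) or "anova" (one-way over all
    groups; the same omnibus p is reported on every non-control row).
    The control row carries no p and no stars.  ``bonferroni`` multiplies
    each p by the number of treatment-vs-control comparisons (off by
    default: stars are per-comparison).
    """
    if test not in ("t", "anova"):
        raise ValueError(f"unknown test {test!r}; use 't' or 'anova'")
    if control_label not in set(table[group]):
        raise ValueError(f"control label {control_label!r} not present")
    keys = [*extra_keys, group]
    rows = []
    for strat, sub in (
        table.groupby(list(extra_keys), sort=True) if extra_keys else [((), table)]
    ):
        strat = strat if isinstance(strat, tuple) else (strat,)
        ctrl_vals = sub.loc[sub[group] == control_label, value].dropna().to_numpy()
        anova_p = np.nan
        if test == "anova":
            arrays = [
                g[value].dropna().to_numpy() for _, g in sub.groupby(group, sort=True)
            ]
            arrays = [a for a in arrays if a.size >= 2]
            if len(arrays) >= 2:
                _, _, _, anova_p = one_way_anova(arrays)
        for gname, g in sub.groupby(group, sort=True):
            vals = g[value].dropna().to_numpy()
            n = vals.size
            row = dict(zip(extra_keys, strat))
            row.update(
                {
                    group: gname, "n": n,
                    "mean": vals.mean() if n else np.nan,
                    "median": float(np.median(vals)) if n else np.nan,
                    "sem": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                }
            )
            n_tests = sub[group].nunique() - 1 if bonferroni else 1
            if gname == control_label:
                row.update({"statistic": np.nan, "p": np.nan, "stars": ""})
            elif test == "t" and n >= 2 and ctrl_vals.size >= 2:
                t, _, p = unpaired_t(vals, ctrl_vals)
                p = min(1.0, p * n_tests)
                row.update({"statistic": t, "p": p, "stars": star_code(p)})
            else:
                p = min(1.0, anova_p * n_tests) if np.isfinite(anova_p) else anova_p
                row.update(
                    {"statistic": np.nan, "p": p, "stars": star_code(p)}
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=[*keys, "n", "mean", "median", "sem",
                                       "statistic", "p", "stars"])
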
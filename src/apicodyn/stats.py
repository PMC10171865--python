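"""Group-comparison statistics: unpaired two-sided Mann-Whitney U (exact
for small samples), one-way ANOVA, and wild-type vs mutant reporting
tables. No multiple-testing correction is applied by default (raw test
p-values are reported, with an optional Benjamini-Hochberg flag)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "one_way_anova",
    "genotype_report",
    "significance_stars",
]

EXACT_MW_MAX_N = 20  # exact U-distribution up to n_a + n_b of this size


@dataclass
class GroupComparison:
    variable: str
    test: str
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    statistic: float
    p_value: float
    underpowered: bool = False
    degenerate: bool = False


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney(
    sample_a, sample_b, variable: str = "", labels: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Unpaired two-sided Mann-Whitney U test; exact null distribution
    when n_a + n_b <= 20 and there are no ties, tie-corrected normal
    approximation otherwise."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_MW_MAX_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        variable=variable,
        test="mann_whitney",
        group_labels=labels,
        group_sizes=(a.size, b.size),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        underpowered=min(a.size, b.size) < 3,
    )


def one_way_anova(
    *groups, variable: str = "", labels: tuple[str, ...] | None = None
) -> GroupComparison:
    """One-way ANOVA; F = 0 with p = 1 is flagged degenerate (all groups
    identical constants)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("every group needs >= 2 values")
    degenerate = all(np.std(g) == 0 for g in gs) and len({g[0] for g in gs}) == 1
    if degenerate:
        f, p = 0.0, 1.0
    else:
        res = sps.f_oneway(*gs)
        f, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        variable=variable,
        test="one_way_anova",
        group_labels=tuple(labels) if labels else tuple(f"g{i}" for i in range(len(gs))),
        group_sizes=tuple(g.size for g in gs),
        statistic=f,
        p_value=p,
        underpowered=min(g.size for g in gs) < 3,
        degenerate=degenerate,
    )


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def genotype_report(
    wt: pd.DataFrame,
    mutant: pd.DataFrame,
    variables: list[str],
    labels: tuple[str, str] = ("WT", "mutant"),
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Wild-type vs mutant comparison table.

    Both inputs are long tables with a ``variable`` column and a
    ``value`` column (one row per cell/junction measurement, pooled
    across embryos). For each requested variable the report gives group
    means ± s.e.m. and a two-sided Mann-Whitney p-value; an optional
    Benjamini-Hochberg column is appended when ``bh_correct``.
    """
    for name, df in ((labels[0], wt), (labels[1], mutant)):
        if df.empty:
            raise ValueError(f"empty cohort: {name}")
        missing = {"variable", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"cohort {name} lacks columns {sorted(missing)}")
    rows = []
    for var in variables:
        a = wt.loc[wt.variable == var, "value"].to_numpy(dtype=float)
        b = mutant.loc[mutant.variable == var, "value"].to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            rows.append((var, a.size, np.nan, np.nan, b.size, np.nan, np.nan,
                         np.nan, np.nan, ""))
            continue
        cmp = mann_whitney(a, b, variable=var, labels=labels)
        rows.append(
            (var, a.size, a.mean(), _sem(a), b.size, b.mean(), _sem(b),
             cmp.statistic, cmp.p_value, significance_stars(cmp.p_value))
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "variable",
            f"n_{labels[0]}", f"mean_{labels[0]}", f"sem_{labels[0]}",
            f"n_{labels[1]}", f"mean_{labels[1]}", f"sem_{labels[1]}",
            "U", "p_value", "stars",
        ],
    )
    if bh_correct:
        p = out["p_value"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            pv = p[ok]
            order = np.argsort(pv)
            m = pv.size
            ranked = pv[order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            qq = np.empty(m)
            qq[order] = np.minimum(ranked, 1.0)
            q[ok] = qq
        out["p_bh"] = q
    return out
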
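"""Site selection and statistical calling of methyltransferase-dependent
sites.

The dependence design has three conditions: an empty-vector control, a
catalytically dead enzyme (K190M), and the wild-type rescue.  A site is
called enzyme-dependent when its methylation level is significantly
higher in the rescue than in *both* comparators: Welch's unequal-variance
t-test per contrast on per-replicate levels, Benjamini-Hochberg FDR
across sites within each contrast, padj < alpha in both, and a positive
rescue-minus-comparator mean difference.

Sites enter testing only with read coverage strictly above ``min_cov``
(default 10) in every replicate of every tested condition.  A separate
two-condition comparison keeps sites with pooled coverage > 100 and >=20%
methylation in at least one condition, and compares the groups globally
with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VERDICT_DEP = "dependent"
VERDICT_NOT = "not_dependent"
VERDICT_UNTESTED = "not_tested"


def welch_test(levels_a, levels_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Welch df, two-sided p).

    Degenerate zero-variance inputs follow fixed conventions: both groups
    constant and equal -> t=0, p=1; constant but unequal -> the variance
    is replaced by machine epsilon, giving an extreme t (callers can flag
    such sites via the near-zero pooled variance).
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    # constant groups are detected by value range, not by the computed
    # variance, which picks up mean-roundoff noise
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return 0.0, float(a.size + b.size - 2), 1.0
        eps = np.finfo(float).eps
        va = vb = eps
        sa, sb = va / a.size, vb / b.size
        t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
        return float(t), float(df), float(p)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(t), float(df), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_testable_sites(
    matrix: pd.DataFrame,
    min_cov: int = 10,
    conditions: list[str] | None = None,
) -> list[str]:
    """Sites with coverage strictly above ``min_cov`` in every replicate
    of every tested condition.  ``matrix`` is long-format with columns
    site, condition, replicate, coverage (absent rows = zero coverage)."""
    if matrix.empty:
        return []
    df = matrix
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
        n_cond = len(conditions)
    else:
        n_cond = df["condition"].nunique()
    expected = {
        cond: g["replicate"].nunique() for cond, g in df.groupby("condition")
    }
    keep = []
    for site, g in df.groupby("site", sort=True):
        ok = True
        for cond, n_rep in expected.items():
            sub = g[g["condition"] == cond]
            if len(sub) < n_rep or (sub["coverage"] <= min_cov).any():
                ok = False
                break
        ok = ok and g["condition"].nunique() == n_cond
        if ok:
            keep.append(site)
    return keep


def call_dependent_sites(
    matrix: pd.DataFrame,
    comparators: tuple[str, str] = ("ctr", "K190M"),
    rescue: str = "NSUN2",
    alpha: float = 0.05,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Call enzyme-dependent sites from a long-format site matrix.

    Per testable site, Welch's t-test compares each comparator against
    the rescue; BH-FDR is applied across sites within each contrast.  A
    site is ``dependent`` iff padj < alpha in both contrasts and the
    rescue mean exceeds both comparator means.  Sites failing coverage
    selection are reported as ``not_tested``.
    """
    conds = [*comparators, rescue]
    for c in conds:
        if c not in set(matrix["condition"]):
            raise ValueError(f"condition {c!r} missing from matrix")
    testable = select_testable_sites(matrix, min_cov=min_cov, conditions=conds)
    all_sites = sorted(matrix["site"].unique())

    by_site_cond = {
        (site, cond): g["level"].to_numpy()
        for (site, cond), g in matrix.groupby(["site", "condition"])
    }
    rows = []
    pvals: dict[str, list[float]] = {c: [] for c in comparators}
    for site in testable:
        rescue_levels = by_site_cond[(site, rescue)]
        row: dict = {"site": site, "verdict": VERDICT_NOT}
        row[f"mean_{rescue}"] = rescue_levels.mean()
        for comp in comparators:
            comp_levels = by_site_cond[(site, comp)]
            t, df, p = welch_test(comp_levels, rescue_levels)
            row[f"mean_{comp}"] = comp_levels.mean()
            row[f"t_{comp}"] = t
            row[f"df_{comp}"] = df
            row[f"p_{comp}"] = p
            row[f"diff_{comp}"] = rescue_levels.mean() - comp_levels.mean()
            pvals[comp].append(p)
        rows.append(row)

    for comp in comparators:
        padj = bh_fdr(pvals[comp])
        for row, q in zip(rows, padj):
            row[f"padj_{comp}"] = float(q)

    for row in rows:
        sig = all(row[f"padj_{c}"] < alpha for c in comparators)
        up = all(row[f"diff_{c}"] > 0 for c in comparators)
        row["verdict"] = VERDICT_DEP if (sig and up) else VERDICT_NOT

    tested = {r["site"] for r in rows}
    for site in all_sites:
        if site not in tested:
            rows.append({"site": site, "verdict": VERDICT_UNTESTED})

    out = pd.DataFrame(rows).set_index("site").loc[all_sites].reset_index()
    return out


def select_comparison_sites(
    matrix: pd.DataFrame,
    min_cov: int = 100,
    min_level: float = 0.20,
) -> list[str]:
    """Two-condition quantification filter: keep sites whose pooled
    (summed-across-replicates) counts give coverage strictly above
    ``min_cov`` and level >= ``min_level`` in at least one condition."""
    if matrix.empty:
        return []
    pooled = (
        matrix.groupby(["site", "condition"])[["n_meth", "n_unmeth"]]
        .sum()
        .reset_index()
    )
    pooled["coverage"] = pooled["n_meth"] + pooled["n_unmeth"]
    pooled["level"] = np.where(
        pooled["coverage"] > 0, pooled["n_meth"] / pooled["coverage"], 0.0
    )
    ok = pooled[(pooled["coverage"] > min_cov) & (pooled["level"] >= min_level)]
    return sorted(ok["site"].unique())


def global_level_comparison(levels_a, levels_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing per-site methylation levels of
    two conditions (exact null for small tie-free samples, otherwise
    normal approximation with tie correction)."""
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    if method == "exact" and (np.unique(np.concatenate([a, b])).size < a.size + b.size):
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
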
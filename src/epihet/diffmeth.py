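"""Differential promoter methylation across age groups.

The testing chain: per-region Welch-ANOVA (heteroscedasticity-robust one-way
ANOVA) over the age groups, Benjamini-Hochberg step-up correction over all
testable regions, a boundary-inclusive >=5-percentage-point effect gate on
the largest pairwise group-mean difference, Games-Howell pairwise post-hoc
tests for the regions that pass, a compact-letter display summarising the
pairwise pattern, and agglomerative clustering of z-scored profiles into the
two archetypes (cluster I: elevated in the reference/youngest group; cluster
II: the opposite).

Welch's F*:  w_g = n_g/s_g^2,  W = sum w_g,  xbar_w = sum w_g xbar_g / W,
h = sum (1 - w_g/W)^2 / (n_g - 1),
F* = [sum w_g (xbar_g - xbar_w)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) h],
df1 = k-1,  df2 = (k^2-1) / (3h).

Games-Howell for a pair (i, j):
q_ij = |xbar_i - xbar_j| / sqrt((s_i^2/n_i + s_j^2/n_j) / 2),
nu_ij by Welch-Satterthwaite, p from the studentized-range distribution with
k means and nu_ij df.  At k = 2 both tests coincide with Welch's t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methcalls import SampleSheet

VARIANCE_FLOOR = 1e-6  # applied when a group has zero sample variance


@dataclass(frozen=True)
class WelchAnovaResult:
    f_star: float
    df1: float
    df2: float
    p_value: float
    variance_floored: bool = False


def _group_stats(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    n = np.array([len(g) for g in groups], dtype=float)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (n < 2).any():
        raise ValueError("every group needs at least 2 observations")
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    floored = bool((v < VARIANCE_FLOOR).any())
    v = np.maximum(v, VARIANCE_FLOOR)
    return n, m, v, floored


def welch_anova(groups: Sequence[Sequence[float]]) -> WelchAnovaResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Groups with zero sample variance get the variance floor (flagged in the
    result) so the statistic stays defined at, e.g., fully unmethylated
    promoters where every sample reads 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    n, m, v, floored = _group_stats(arrs)
    k = len(arrs)
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    h = ((1.0 - w / W) ** 2 / (n - 1.0)).sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * h
    f_star = num / den
    df2 = (k**2 - 1.0) / (3.0 * h)
    p = float(stats.f.sf(f_star, k - 1, df2))
    return WelchAnovaResult(float(f_star), float(k - 1), float(df2), p, floored)


def welch_anova_rows(
    x: np.ndarray, group_cols: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch-ANOVA over a (regions x samples) matrix.

    NaN entries are ignored per row; rows where any group retains fewer than
    2 values get NaN statistics.  Returns (F*, df2, p) arrays.
    """
    x = np.asarray(x, dtype=float)
    k = len(group_cols)
    R = x.shape[0]
    n = np.empty((R, k))
    m = np.empty((R, k))
    v = np.empty((R, k))
    for j, cols in enumerate(group_cols):
        sub = x[:, cols]
        n[:, j] = np.sum(~np.isnan(sub), axis=1)
        # rows with <2 values in a group are marked untestable below; the
        # nanvar degrees-of-freedom warning for those rows is expected
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m[:, j] = np.nanmean(sub, axis=1)
            v[:, j] = np.nanvar(sub, axis=1, ddof=1)
    ok = (n >= 2).all(axis=1)
    v = np.maximum(v, VARIANCE_FLOOR)
    w = n / v
    W = w.sum(axis=1, keepdims=True)
    mw = (w * m).sum(axis=1, keepdims=True) / W
    h = ((1.0 - w / W) ** 2 / (n - 1.0)).sum(axis=1)
    num = (w * (m - mw) ** 2).sum(axis=1) / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * h
    f_star = num / den
    df2 = (k**2 - 1.0) / (3.0 * h)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(f_star, k - 1, df2)
    f_star = np.where(ok, f_star, np.nan)
    df2 = np.where(ok, df2, np.nan)
    p = np.where(ok, p, np.nan)
    return f_star, df2, p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Standard step-up with enforced monotonicity; ties broken by a stable
    sort on (p, original index); input order preserved in the output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def games_howell(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Games-Howell pairwise comparisons with unequal variances and sizes.

    Returns one row per unordered pair with the mean difference, studentized
    q, Welch-Satterthwaite df and the studentized-range p-value (k = total
    number of groups).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    n, m, v, floored = _group_stats(arrs)
    k = len(arrs)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            diff = m[i] - m[j]
            q = abs(diff) / np.sqrt(se2 / 2.0)
            nu = se2**2 / (
                (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
            )
            if k == 2:
                # the studentized range of 2 means is sqrt(2)|t|; use the
                # exact t tail rather than quadrature
                p = 2.0 * float(stats.t.sf(q / np.sqrt(2.0), nu))
            else:
                p = float(stats.studentized_range.sf(q, k, nu))
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "mean_diff": float(diff),
                    "q": float(q),
                    "df": float(nu),
                    "p_value": min(1.0, p),
                    "variance_floored": floored,
                }
            )
    return pd.DataFrame(rows)


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """Upper tail of the studentized-range distribution (k means, df)."""
    return float(stats.studentized_range.sf(q, k, df))


# ---------------------------------------------------------------------------
# Compact letter display
# ---------------------------------------------------------------------------


def compact_letters(
    pairwise_p: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``pairwise_p`` is a complete symmetric group x group p-value matrix.
    Groups share at least one letter iff their pairwise p >= alpha; the
    letter set is minimal via absorption and deterministic given the group
    order of the matrix.
    """
    labels = list(pairwise_p.index)
    if list(pairwise_p.columns) != labels:
        raise ValueError("pairwise p matrix must have identical row/column labels")
    for a in labels:
        for b in labels:
            if a == b:
                continue
            pab, pba = pairwise_p.loc[a, b], pairwise_p.loc[b, a]
            if np.isnan(pab) or abs(pab - pba) > 1e-12:
                raise ValueError(f"incomplete or asymmetric p matrix at ({a}, {b})")
    # columns = letters, each a set of groups; start with all groups together
    cols: list[set[str]] = [set(labels)]
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if pairwise_p.loc[a, b] >= alpha:
                continue
            new_cols: list[set[str]] = []
            for col in cols:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: drop empties, duplicates, and columns contained in another
            cols = []
            for c in new_cols:
                if not c or c in cols:
                    continue
                if any(c < d for d in new_cols):
                    continue
                cols.append(c)
    # order letters by the first group they contain, then assign a, b, c ...
    cols.sort(key=lambda c: min(labels.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, col in zip(alphabet, cols):
        for g in labels:
            if g in col:
                out[g] += letter
    return out


# ---------------------------------------------------------------------------
# Differential calling and clustering
# ---------------------------------------------------------------------------


def call_differential(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    delta_min: float = 0.05,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Identify differentially methylated regions across age groups.

    ``matrix`` is a region x sample table of mean methylation levels (NaN
    allowed).  A region is testable when every group retains >=2 values.
    Welch-ANOVA p-values over testable regions are BH-corrected; a region is
    called differential iff q < alpha (raw p with ``use_adjusted=False``) and
    the largest absolute pairwise group-mean difference is >= delta_min
    (boundary inclusive).  Games-Howell p-values and compact letters are
    attached for differential regions.
    """
    groups = sheet.groups
    if len(groups) < 2:
        raise ValueError("differential analysis needs >= 2 groups")
    samples = [s for s in sheet.samples if s in matrix.columns]
    x = matrix[samples].to_numpy(dtype=float)
    col_of = {s: i for i, s in enumerate(samples)}
    group_cols = [
        np.array([col_of[s] for s in sheet.samples_in(g) if s in col_of])
        for g in groups
    ]
    f_star, df2, p = welch_anova_rows(x, group_cols)
    gmeans = np.column_stack(
        [np.nanmean(x[:, c], axis=1) if len(c) else np.full(len(x), np.nan) for c in group_cols]
    )
    delta_max = np.nanmax(gmeans, axis=1) - np.nanmin(gmeans, axis=1)

    res = pd.DataFrame(index=matrix.index)
    res.index.name = "region"
    for j, g in enumerate(groups):
        sub = x[:, group_cols[j]]
        n = np.sum(~np.isnan(sub), axis=1)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res[f"mean_{g}"] = np.nanmean(sub, axis=1)
            sd = np.nanstd(sub, axis=1, ddof=1)
        res[f"se_{g}"] = np.where(n > 1, sd / np.sqrt(n), 0.0)
    res["delta_max"] = delta_max
    res["f_star"] = f_star
    res["df2"] = df2
    res["p_value"] = p
    testable = ~np.isnan(p)
    res["testable"] = testable
    q = np.full(len(res), np.nan)
    q[testable] = bh_adjust(p[testable])
    res["q_value"] = q
    crit = q if use_adjusted else p
    # the effect gate is boundary-inclusive; a tiny absolute tolerance keeps
    # group means assembled by floating arithmetic from falling just under it
    with np.errstate(invalid="ignore"):
        res["differential"] = (
            testable & (crit < alpha) & (delta_max >= delta_min - 1e-12)
        )

    pair_labels = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    for a, b in pair_labels:
        res[f"gh_p_{a}_vs_{b}"] = np.nan
    res["letters"] = ""
    for ridx in res.index[res["differential"]]:
        row = matrix.loc[ridx]
        vals = [
            row[[s for s in sheet.samples_in(g) if s in row.index]].dropna().to_numpy()
            for g in groups
        ]
        gh = games_howell(vals, labels=groups)
        pmat = pd.DataFrame(1.0, index=groups, columns=groups)
        for r in gh.itertuples(index=False):
            pmat.loc[r.group_i, r.group_j] = r.p_value
            pmat.loc[r.group_j, r.group_i] = r.p_value
            res.loc[ridx, f"gh_p_{r.group_i}_vs_{r.group_j}"] = r.p_value
        letters = compact_letters(pmat, alpha=alpha)
        res.loc[ridx, "letters"] = ",".join(letters[g] for g in groups)
    return res


def cluster_differential(
    matrix: pd.DataFrame,
    diff_regions: Sequence[str],
    sheet: SampleSheet,
    reference_group: str | None = None,
    k: int = 2,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[pd.Series, list[str]]:
    """Cluster differential regions into the two archetypal patterns.

    Each region's per-sample vector is z-scored (mean 0, sd 1 across
    samples) and the regions are clustered agglomeratively (average linkage,
    Euclidean distance) with the tree cut at ``k``.  The cluster whose mean
    z-score in the reference (youngest) group exceeds its mean z elsewhere is
    labelled "I"; the other "II".  Regions with zero variance across samples
    are excluded (second return value).
    """
    from scipy.cluster import hierarchy

    if reference_group is None:
        reference_group = sheet.groups[0]
    regions = [r for r in diff_regions]
    if len(regions) < 2:
        raise ValueError("need >= 2 differential regions to cluster")
    samples = [s for s in sheet.samples if s in matrix.columns]
    sub = matrix.loc[regions, samples]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    excluded = list(sub.index[(sd == 0) | sd.isna() | sub.isna().any(axis=1)])
    keep = [r for r in regions if r not in excluded]
    if len(keep) < 2:
        raise ValueError("fewer than 2 clusterable regions after excluding flat rows")
    z = sub.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    link = hierarchy.linkage(z.to_numpy(), method=method, metric=metric)
    assign = hierarchy.fcluster(link, t=k, criterion="maxclust")
    ref_cols = [s for s in sheet.samples_in(reference_group) if s in z.columns]
    other_cols = [s for s in z.columns if s not in ref_cols]
    labels = {}
    contrast = {}
    for c in np.unique(assign):
        rows = z.iloc[assign == c]
        contrast[c] = rows[ref_cols].mean().mean() - rows[other_cols].mean().mean()
    ordered = sorted(contrast, key=lambda c: -contrast[c])
    names = ["I", "II"] + [f"C{i}" for i in range(3, k + 1)]
    cluster_name = {c: names[i] for i, c in enumerate(ordered)}
    out = pd.Series(
        [cluster_name[c] for c in assign], index=keep, name="cluster", dtype=object
    )
    return out, excluded
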
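"""Nonparametric statistics used across the analysis.

Correlation matrices (Spearman/Pearson, Holm or Benjamini-Hochberg
adjusted), exact and approximate Wilcoxon tests, Cohen's kappa interrater
agreement, and a dyad-cluster permutation test for group contrasts.

The exact Wilcoxon routines enumerate the permutation null directly:
signed-rank by enumerating the 2^n sign assignments over the observed
(mid-)ranks, rank-sum by dynamic programming over the Mann-Whitney U count
distribution.  Large samples switch to the usual normal approximations
with tie corrections and (for the signed-rank test) a 0.5 continuity
correction.  All results carry a method tag and sidedness so they can be
serialized for reproducibility.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    sidedness: str = "two-sided"
    note: str = ""

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "n": self.n, "method": self.method,
                "sidedness": self.sidedness, "note": self.note}


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrMatrixResult:
    names: list[str]
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    method: str           # "spearman" | "pearson"
    adjust: str           # "holm" | "bh" | "none"
    flagged: list[str] = field(default_factory=list)   # constant columns


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def correlation_matrix(table: pd.DataFrame, method: str = "spearman",
                       adjust: str = "holm") -> CorrMatrixResult:
    """Pairwise correlation matrix with multiplicity-adjusted p values.

    Missing values are handled pairwise-complete.  Spearman's coefficient
    is computed as the product-moment correlation of mid-ranks.  Pairs
    involving a constant column get NaN r and are flagged.  Adjustment is
    applied jointly over the strict upper triangle.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if adjust not in ("holm", "bh", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    names = list(table.columns)
    k = len(names)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    flagged: set[str] = set()

    for i, j in itertools.combinations(range(k), 2):
        xy = table[[names[i], names[j]]].dropna()
        if len(xy) < 3:
            flagged.update((names[i], names[j]))
            continue
        x = xy.iloc[:, 0].to_numpy(dtype=float)
        y = xy.iloc[:, 1].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            if np.ptp(x) == 0:
                flagged.add(names[i])
            if np.ptp(y) == 0:
                flagged.add(names[j])
            continue
        if method == "spearman":
            x, y = _midranks(x), _midranks(y)
        rij, pij = sps.pearsonr(x, y)
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij

    p_adj = p.copy()
    iu = np.triu_indices(k, 1)
    raw = p[iu]
    ok = ~np.isnan(raw)
    if adjust != "none" and ok.any():
        adj = np.full_like(raw, np.nan)
        sm_method = {"holm": "holm", "bh": "fdr_bh"}[adjust]
        adj[ok] = multipletests(raw[ok], method=sm_method)[1]
        p_adj[iu] = adj
        p_adj[(iu[1], iu[0])] = adj

    def frame(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=names, columns=names)

    return CorrMatrixResult(names=names, r=frame(r), p_raw=frame(p),
                            p_adj=frame(p_adj), method=method, adjust=adjust,
                            flagged=sorted(flagged))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p values."""
    return list(multipletests(list(p_values), method="holm")[1])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_exact_tail(ranks: np.ndarray, w_obs: float,
                            sidedness: str) -> float:
    """Exact p over all 2^n sign assignments of the given (mid-)ranks.

    Mid-ranks are half-integers, so doubling them makes every attainable
    W+ an integer and the null distribution is built by convolving
    ``(1 + z^{2 r_i})`` terms -- equivalent to full enumeration but
    polynomial time.
    """
    r2 = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(int)
    max_w = int(r2.sum())
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_w + 1 - r]
        counts = counts + shifted
    total = counts.sum()
    w2 = int(round(2.0 * w_obs))
    count_ge = counts[w2:].sum()
    count_le = counts[: w2 + 1].sum()
    if sidedness == "greater":
        return count_ge / total
    if sidedness == "less":
        return count_le / total
    return min(1.0, 2.0 * min(count_ge, count_le) / total)


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]] | np.ndarray,
                         continuity: bool = True,
                         sidedness: str = "two-sided",
                         exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test on paired observations (or differences).

    Zero differences are dropped; ties get mid-ranks.  Exact enumeration is
    used up to ``exact_max_n`` nonzero differences, otherwise the normal
    approximation with tie-corrected variance and an optional 0.5
    continuity correction.  The statistic is W+, the positive rank sum.
    """
    arr = np.asarray(pairs, dtype=float)
    d = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("wilcoxon_signed_rank: all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        p = _signed_rank_exact_tail(ranks, w_plus, sidedness)
        return TestResult(statistic=w_plus, p_value=p, n=n,
                          method="wilcoxon-signed-rank-exact",
                          sidedness=sidedness)

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        np.sum(counts ** 3 - counts)) / 48.0
    cc = 0.5 if continuity else 0.0
    if sidedness == "greater":
        z = (w_plus - mu - cc) / math.sqrt(var)
        p = sps.norm.sf(z)
    elif sidedness == "less":
        z = (w_plus - mu + cc) / math.sqrt(var)
        p = sps.norm.cdf(z)
    else:
        z = (abs(w_plus - mu) - cc) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(z)
    return TestResult(statistic=w_plus, p_value=float(min(1.0, p)), n=n,
                      method="wilcoxon-signed-rank-normal"
                             + ("-cc" if continuity else ""),
                      sidedness=sidedness)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney) test
# ---------------------------------------------------------------------------

def _mann_whitney_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts[u] = #arrangements with statistic u.

    Recurrence on the largest pooled observation: if it is an x it beats
    all n y's (U gains n), else it is a y; so
    ``N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1)``.
    """
    max_u = n1 * n2
    # table[m] = count polynomial in u for (m, current n)
    table = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
    for m in range(n1 + 1):
        table[m][0] = 1.0           # n = 0: all x's, U is forced to 0
    for n in range(1, n2 + 1):
        new = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
        new[0][0] = 1.0
        for m in range(1, n1 + 1):
            shifted = np.zeros(max_u + 1)
            shifted[n:] = new[m - 1][: max_u + 1 - n]
            new[m] = shifted + table[m]
        table = new
    return table[n1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      sidedness: str = "two-sided",
                      exact_max_n: int = 8) -> TestResult:
    """Wilcoxon rank-sum test of two independent samples.

    The statistic is U for the first sample.  Exact null enumeration when
    the smaller sample has at most ``exact_max_n`` observations and there
    are no cross-sample ties, otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("wilcoxon_rank_sum: both samples must be non-empty")
    n1, n2 = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks = sps.rankdata(allv)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(allv)) < len(allv)

    if min(n1, n2) <= exact_max_n and not has_ties:
        counts = _mann_whitney_counts(n1, n2)
        total = counts.sum()
        u_int = int(round(u1))
        p_le = counts[: u_int + 1].sum() / total
        p_ge = counts[u_int:].sum() / total
        if sidedness == "greater":
            p = p_ge
        elif sidedness == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=u1, p_value=float(p), n=n1 + n2,
                          method="wilcoxon-rank-sum-exact",
                          sidedness=sidedness)

    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, tcounts = np.unique(allv, return_counts=True)
    tie_term = float(np.sum(tcounts ** 3 - tcounts)) / (nt * (nt - 1))
    var = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    if var <= 0:   # all values identical
        return TestResult(statistic=u1, p_value=1.0, n=nt,
                          method="wilcoxon-rank-sum-normal",
                          sidedness=sidedness, note="zero variance")
    cc = 0.5
    if sidedness == "greater":
        p = sps.norm.sf((u1 - mu - cc) / math.sqrt(var))
    elif sidedness == "less":
        p = sps.norm.cdf((u1 - mu + cc) / math.sqrt(var))
    else:
        p = 2.0 * sps.norm.sf((abs(u1 - mu) - cc) / math.sqrt(var))
    return TestResult(statistic=u1, p_value=float(min(1.0, max(0.0, p))),
                      n=nt, method="wilcoxon-rank-sum-normal",
                      sidedness=sidedness)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Interrater agreement kappa = (p_o - p_e) / (1 - p_e).

    Chance agreement p_e comes from the product of the raters' marginal
    label frequencies; chance-level agreement gives kappa = 0.  Raises when
    both raters use one identical category throughout (p_e = 1).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences must have equal length")
    if not a:
        raise ValueError("empty label sequences")
    cats = sorted(set(a) | set(b), key=str)
    n = len(a)
    p_o = sum(1 for u, v in zip(a, b) if u == v) / n
    pa = {c: a.count(c) / n for c in cats}
    pb = {c: b.count(c) / n for c in cats}
    p_e = sum(pa[c] * pb[c] for c in cats)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: a single shared category")
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# cluster permutation test
# ---------------------------------------------------------------------------

def permutation_group_compare(metric: Sequence[float],
                              group_labels: Sequence,
                              cluster_ids: Sequence,
                              n_perm: int = 2000,
                              seed: int = 0) -> TestResult:
    """Two-group mean comparison with dyad-level (cluster) permutation.

    Observations from one cluster always stay together: group labels are
    reassigned at the cluster level, preserving the original counts of
    clusters per group.  This controls the pseudoreplication that repeated
    sessions of the same dyad would otherwise introduce.  The statistic is
    the difference in group means of the observations; two-sided p uses the
    add-one estimator ``(1 + #{|T*| >= |T|}) / (1 + n_perm)``.
    """
    m = np.asarray(metric, dtype=float)
    g = np.asarray(group_labels)
    c = np.asarray(cluster_ids)
    if not (len(m) == len(g) == len(c)):
        raise ValueError("metric, group_labels, cluster_ids must align")
    groups = np.unique(g)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    clusters = pd.unique(c)
    cl_group = {}
    for cl in clusters:
        gs = np.unique(g[c == cl])
        if len(gs) != 1:
            raise ValueError(f"cluster {cl!r} spans both groups")
        cl_group[cl] = gs[0]
    n_a = sum(1 for cl in clusters if cl_group[cl] == groups[0])
    n_b = len(clusters) - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 clusters per group")
    n_distinct = math.comb(len(clusters), n_a)
    note = ""
    if n_distinct < 20:
        note = (f"only {n_distinct} distinct cluster permutations; "
                "p-value resolution is limited")

    def t_stat(assign: dict) -> float:
        ga = np.array([assign[cl] for cl in c])
        return float(m[ga == groups[0]].mean() - m[ga == groups[1]].mean())

    t_obs = t_stat(cl_group)
    rng = np.random.default_rng(seed)
    cl_arr = np.array(clusters, dtype=object)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(cl_arr))
        assign = {cl_arr[i]: (groups[0] if k < n_a else groups[1])
                  for k, i in enumerate(perm)}
        if abs(t_stat(assign)) >= abs(t_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(statistic=t_obs, p_value=p, n=len(m),
                      method=f"cluster-permutation(n_perm={n_perm},seed={seed})",
                      sidedness="two-sided", note=note)


def export_model_matrix(table: pd.DataFrame, response: str,
                        fixed: Sequence[str],
                        cluster: Sequence[str]) -> pd.DataFrame:
    """Tidy model matrix (response, fixed effects, cluster ids) for refitting
    in any mixed-model tool."""
    cols = [response, *fixed, *cluster]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns {missing}")
    return table[cols].dropna().reset_index(drop=True)
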
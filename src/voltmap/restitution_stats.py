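"""APD restitution curves and group statistics.

The restitution curve plots APD80 against the preceding diastolic
interval (DI = CL - APD80) across pacing cycle lengths; its maximum
local slope is the classical arrhythmia-susceptibility index (slopes
approaching 1 promote alternans).  Group comparisons follow the
nonparametric convention for small animal cohorts: Kruskal–Wallis
omnibus test, Dunn's rank-based pairwise post hoc (gated on omnibus
p < 0.05), and a general-linear-model trend test across cycle lengths.
The Teichholz M-mode formula converts ventricular diameters to an
ejection fraction for the echocardiography arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class RestitutionCurve:
    """Ordered (DI, APD80) pairs with an optional fitted slope summary."""

    points: list[tuple[float, float]]  # (di_ms, apd80_ms), DI ascending
    slope_summary: dict = field(default_factory=dict)

    @property
    def di(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def apd(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class GroupTable:
    """Per-CL, per-group summary mirroring a mean +/- SD comparison table.

    ``summary`` has one row per cycle length with columns
    ``{group}_mean / {group}_sd / {group}_n`` plus the Kruskal–Wallis
    ``p_value``; ``pairwise`` maps CL -> symmetric Dunn p-value
    DataFrames; ``trend`` maps group -> (slope_sign, p_for_trend).
    """

    summary: pd.DataFrame
    pairwise: dict[float, pd.DataFrame]
    pairwise_adjusted: dict[float, pd.DataFrame]
    trend: dict[str, tuple[int, float]]
    measure: str = ""


@dataclass(frozen=True)
class EchoMeasures:
    """M-mode echocardiographic measurements (cm) with derived LVEF (%)."""

    lvedd: float
    lvesd: float
    ivsd: float = float("nan")
    pwd: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.lvesd <= self.lvedd):
            raise ValueError("need 0 < LVESD <= LVEDD")

    @property
    def lvef(self) -> float:
        return teichholz_ef(self.lvedd, self.lvesd)


# --------------------------------------------------------------------------
# Restitution
# --------------------------------------------------------------------------

def build_restitution(apd_by_cl: dict[float, float]) -> RestitutionCurve:
    """Assemble (DI, APD80) pairs from per-CL APD80 means, DI ascending.

    DI = CL - APD80; an APD80 at or above its own CL makes the pair
    impossible and raises.
    """
    if len(apd_by_cl) < 2:
        raise ValueError(">= 2 cycle lengths with valid APD required")
    pts = []
    for cl, apd in apd_by_cl.items():
        if not np.isfinite(apd):
            continue
        if apd >= cl:
            raise ValueError(f"APD80 {apd} ms >= cycle length {cl} ms; "
                             "diastolic interval would be non-positive")
        pts.append((float(cl - apd), float(apd)))
    if len(pts) < 2:
        raise ValueError(">= 2 valid (DI, APD) points required")
    pts.sort(key=lambda p: p[0])
    return RestitutionCurve(points=pts)


def restitution_slope(curve: RestitutionCurve,
                      method: str = "segmentwise") -> float:
    """Maximum local slope (dimensionless, ms/ms) of the restitution curve.

    ``segmentwise`` (default): chord slope of each adjacent pair,
    maximum reported — the "slope in each part" reading.
    ``exponential``: least-squares fit of APD = A - B exp(-DI/tau);
    the slope is the fitted derivative (B/tau) exp(-DI/tau) maximized
    over the observed DIs (i.e. at the smallest DI).  A non-convergent
    fit falls back to segmentwise with a warning.
    """
    di, apd = curve.di, curve.apd
    if np.any(np.diff(di) <= 0):
        raise ValueError("DI values must be strictly increasing")
    if method not in ("segmentwise", "exponential"):
        raise ValueError("method must be segmentwise|exponential")

    seg = np.diff(apd) / np.diff(di)
    seg_max = float(seg.max())
    if method == "segmentwise":
        curve.slope_summary = {"max_local_slope": seg_max,
                               "fit_method": "segmentwise"}
        return seg_max

    if len(di) < 3:
        raise ValueError("exponential fit needs >= 3 points")
    try:
        a0 = float(apd.max())
        tau0 = max((di.max() - di.min()) / 2.0, 1.0)
        b0 = max(a0 - float(apd.min()), 1.0) * float(np.exp(di.min() / tau0))
        popt, _ = curve_fit(
            lambda d, a, b, tau: a - b * np.exp(-d / tau),
            di, apd, p0=(a0, b0, tau0), maxfev=20000)
        a, b, tau = popt
        if tau <= 0:
            raise RuntimeError("non-physical time constant")
        slope = float(b / tau * np.exp(-di.min() / tau))
    except (RuntimeError, ValueError):
        warnings.warn("exponential restitution fit did not converge; "
                      "falling back to segmentwise slopes")
        curve.slope_summary = {"max_local_slope": seg_max,
                               "fit_method": "segmentwise_fallback"}
        return seg_max
    curve.slope_summary = {"max_local_slope": slope,
                           "fit_method": "exponential",
                           "A": float(a), "B": float(b), "tau": float(tau)}
    return slope


# --------------------------------------------------------------------------
# Nonparametric group statistics
# --------------------------------------------------------------------------

#: Largest total sample size for which the exact permutation null of the
#: Kruskal–Wallis H is enumerated instead of approximated.
KW_EXACT_MAX_N = 8
#: Up to this total n (and tie-free data) the null is sampled by Monte
#: Carlo permutation instead of the chi-square approximation, which is
#: conservative at small-animal cohort sizes (true size ~0.035 at
#: nominal 0.05 for groups of 5/5/4/4).
KW_PERMUTATION_MAX_N = 30
#: Permutation draws for the sampled null (cached per group-size tuple).
KW_PERMUTATION_DRAWS = 100_000


def kruskal_wallis(groups: list, method: str = "auto") -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its p-value.

    ``method="chi2"`` uses the chi-square approximation with k-1 df;
    ``"exact"`` enumerates every permutation of group labels (exact
    null, feasible for small cohorts); ``"permutation"`` samples the
    permutation null (seeded, cached by group sizes).  ``"auto"``
    (default) picks exact for total n <= 8 — where the chi-square
    approximation is off by up to ~0.1 — permutation for tie-free data
    up to n = 30 where chi-square is still conservative, and chi-square
    otherwise.  All-identical observations are a degenerate but legal
    input: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError(">= 2 groups required")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs >= 1 observation")
    n_total = sum(len(g) for g in groups)
    if n_total < 3:
        raise ValueError("total n must be >= 3")
    if method not in ("auto", "chi2", "exact", "permutation"):
        raise ValueError("method must be auto|chi2|exact|permutation")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p_chi2 = stats.kruskal(*groups)
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        if n_total <= KW_EXACT_MAX_N:
            method = "exact"
        elif n_total <= KW_PERMUTATION_MAX_N and not has_ties:
            method = "permutation"
        else:
            method = "chi2"
    if method == "chi2":
        return float(h), float(p_chi2)
    if method == "permutation":
        return float(h), _kw_permutation_p(groups, float(h))
    return float(h), _kw_exact_p(groups, float(h))


_KW_NULL_CACHE: dict[tuple[int, ...], np.ndarray] = {}


def _kw_permutation_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Monte-Carlo permutation p for tie-free data.

    Without ties the ranks are always a permutation of 1..N, so the
    null distribution of H depends only on the group sizes: it is
    sampled once per size tuple (fixed internal seed, so results are
    reproducible) and cached sorted for O(log K) lookup.
    """
    sizes = tuple(len(g) for g in groups)
    null = _KW_NULL_CACHE.get(sizes)
    if null is None:
        n = sum(sizes)
        rng = np.random.default_rng(abs(hash(sizes)) % (2**31))
        ranks = np.tile(np.arange(1.0, n + 1.0), (KW_PERMUTATION_DRAWS, 1))
        perm = rng.permuted(ranks, axis=1)
        s = 0.0
        start = 0
        for sz in sizes:
            means = perm[:, start:start + sz].mean(axis=1)
            s = s + sz * means ** 2
            start += sz
        null = np.sort(12.0 / (n * (n + 1)) * s - 3.0 * (n + 1))
        _KW_NULL_CACHE[sizes] = null
    k = null.size
    n_ge = k - np.searchsorted(null, h_obs - 1e-12, side="left")
    return float((1 + n_ge) / (1 + k))


def _kw_h(ranks_by_group: list[np.ndarray], n: int, tie_term: float) -> float:
    """Tie-corrected H from pooled-rank slices."""
    s = sum(len(r) * r.mean() ** 2 for r in ranks_by_group)
    h = 12.0 / (n * (n + 1)) * s - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _kw_exact_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p: fraction of group-label permutations with
    H >= the observed H (ties handled through pooled ranks)."""
    from itertools import combinations

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    sizes = [len(g) for g in groups]

    hits = total = 0

    def rec(remaining: tuple, szs: list[int], acc: list[np.ndarray]):
        nonlocal hits, total
        if not szs:
            h = _kw_h(acc, n, tie_term)
            total += 1
            if h >= h_obs - 1e-12:
                hits += 1
            return
        for combo in combinations(remaining, szs[0]):
            cset = set(combo)
            rest = tuple(i for i in remaining if i not in cset)
            rec(rest, szs[1:], acc + [ranks[list(combo)]])

    rec(tuple(range(n)), sizes, [])
    return hits / total


def dunn_posthoc(groups: list, labels: list[str] | None = None,
                 alpha: float = 0.05,
                 omnibus_p: float | None = None,
                 force: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn's rank-based pairwise comparisons after Kruskal–Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    on pooled ranks, with tie correction T = sum(t^3 - t)/(12(N-1));
    two-sided normal p-values.  Returns ``(unadjusted, holm_adjusted)``
    symmetric DataFrames.  The post hoc is conventionally gated on the
    omnibus p < alpha; if ``omnibus_p`` is given and not significant the
    test refuses unless ``force=True``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs >= 1 observation")
    k = len(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if omnibus_p is not None and omnibus_p >= alpha and not force:
        raise ValueError(
            f"omnibus p = {omnibus_p:.3g} >= {alpha}: post hoc gated off "
            "(pass force=True to run anyway)")

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction on pooled ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts) / (12.0 * (n - 1)) if n > 1 else 0.0

    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)

    var_base = n * (n + 1) / 12.0 - tie
    punadj = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * stats.norm.sf(abs(z))
            punadj[i, j] = punadj[j, i] = p

    iu = np.triu_indices(k, 1)
    flat = punadj[iu]
    adj = multipletests(flat, method="holm")[1]
    padj = np.ones((k, k))
    padj[iu] = adj
    padj.T[iu] = adj

    unadj_df = pd.DataFrame(punadj, index=labels, columns=labels)
    adj_df = pd.DataFrame(padj, index=labels, columns=labels)
    return unadj_df, adj_df


def trend_test(values_by_level: dict[float, list],
               descending_levels: bool = True) -> tuple[int, float, float]:
    """Linear-trend test across ordered cycle-length levels.

    Fits an ordinary least-squares general linear model of the
    measurement on the CL rank (equally spaced ordinal scores, ordered
    from the longest CL by default), subjects as replicates.  Returns
    ``(slope_sign, p_for_trend, slope)`` with a two-sided p for the
    slope term.  Levels with no observations are dropped with a
    warning; fewer than three remaining levels is an error.
    """
    levels = sorted(values_by_level, reverse=descending_levels)
    kept = []
    for lv in levels:
        obs = [v for v in values_by_level[lv] if np.isfinite(v)]
        if obs:
            kept.append((lv, obs))
        else:
            warnings.warn(f"level {lv} has no observations; dropped")
    if len(kept) < 3:
        raise ValueError(">= 3 levels with observations required for trend")

    x, y = [], []
    for rank, (_, obs) in enumerate(kept):
        x.extend([rank] * len(obs))
        y.extend(obs)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    p = float(model.pvalues[1])
    if np.isnan(p):  # zero residual variance: perfect linear trend
        p = 0.0 if abs(slope) > 0 else 1.0
    return int(np.sign(slope)), p, slope


# --------------------------------------------------------------------------
# Teichholz ejection fraction
# --------------------------------------------------------------------------

def teichholz_volume(d_cm: float) -> float:
    """Teichholz M-mode ventricular volume (mL): V = 7.0/(2.4 + D) * D^3."""
    if d_cm < 0:
        raise ValueError("diameter must be >= 0")
    return 7.0 / (2.4 + d_cm) * d_cm ** 3


def teichholz_ef(lvedd: float, lvesd: float) -> float:
    """LV ejection fraction (%) from end-diastolic and end-systolic
    diameters (cm) via the Teichholz volume formula."""
    if not 0 < lvedd:
        raise ValueError("LVEDD must be > 0")
    if lvesd < 0 or lvesd > lvedd:
        raise ValueError("need 0 <= LVESD <= LVEDD (negative EF impossible)")
    ved = teichholz_volume(lvedd)
    ves = teichholz_volume(lvesd)
    return 100.0 * (ved - ves) / ved


# --------------------------------------------------------------------------
# Cohort summaries
# --------------------------------------------------------------------------

def summarize_groups(df: pd.DataFrame, measure: str,
                     group_order: list[str] | None = None,
                     alpha: float = 0.05) -> GroupTable:
    """Per-CL group summary with omnibus, post hoc, and trend statistics.

    ``df`` holds one row per subject per CL with columns
    ``subject_id, group, cl_ms`` and the measurement column ``measure``.
    For each CL: group means, sample SDs (n-1 denominator; missing for
    n = 1), n, and the Kruskal–Wallis p across groups; Dunn pairwise
    p-values (unadjusted and Holm-adjusted) where the omnibus is
    significant; per-group linear trend across CLs.
    """
    required = {"subject_id", "group", "cl_ms", measure}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")
    if group_order is None:
        group_order = list(pd.unique(df["group"]))

    rows = []
    pairwise: dict[float, pd.DataFrame] = {}
    pairwise_adj: dict[float, pd.DataFrame] = {}
    cls_sorted = sorted(df["cl_ms"].unique(), reverse=True)
    for cl in cls_sorted:
        sub = df[df["cl_ms"] == cl]
        row: dict = {"cl_ms": cl}
        samples, present = [], []
        for g in group_order:
            vals = sub.loc[sub["group"] == g, measure].dropna().to_numpy()
            row[f"{g}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{g}_sd"] = (float(np.std(vals, ddof=1)) if len(vals) > 1
                              else np.nan)
            row[f"{g}_n"] = int(len(vals))
            if len(vals):
                samples.append(vals)
                present.append(g)
        if len(samples) >= 2 and sum(len(s) for s in samples) >= 3:
            h, p = kruskal_wallis(samples)
            row["kw_h"], row["p_value"] = h, p
            if p < alpha:
                unadj, adj = dunn_posthoc(samples, labels=present,
                                          omnibus_p=p, alpha=alpha)
                pairwise[cl] = unadj
                pairwise_adj[cl] = adj
        else:
            row["kw_h"] = row["p_value"] = np.nan
        rows.append(row)

    trend: dict[str, tuple[int, float]] = {}
    for g in group_order:
        by_level = {
            cl: df.loc[(df["group"] == g) & (df["cl_ms"] == cl), measure]
                  .dropna().tolist()
            for cl in cls_sorted}
        by_level = {cl: v for cl, v in by_level.items() if v}
        if len(by_level) >= 3:
            sign, p, _ = trend_test(by_level)
            trend[g] = (sign, p)

    return GroupTable(summary=pd.DataFrame(rows), pairwise=pairwise,
                      pairwise_adjusted=pairwise_adj, trend=trend,
                      measure=measure)
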
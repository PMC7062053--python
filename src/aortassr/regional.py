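"""Regional SSR analysis and cohort statistics.

Quadrant means, along-centerline SSR profiles, cumulative frequency (ECDF)
with percentile summaries, Kruskal-Wallis group comparison (chi-square or
exact-permutation p) with a Scheffe post hoc on the original values, and the
cohort report tables (group mean +/- s.e.m.).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import VesselGeometry
from .markers import WallShearField

__all__ = [
    "RegionalSummary",
    "GroupTestResult",
    "quadrant_mean_ssr",
    "ssr_profile",
    "cumulative_frequency",
    "percentile",
    "kruskal_wallis",
    "scheffe_posthoc",
    "dunn_posthoc",
    "cohort_report",
]


@dataclass
class RegionalSummary:
    """Per-case regional SSR summary."""

    case: str
    group: str
    quadrant_means: dict  # quadrant label -> mean peak-systolic SSR (or NaN)
    percentile_90: float  # within the analysis segment
    ecdf_x: np.ndarray
    ecdf_f: np.ndarray


def _valid_ssr(wss: WallShearField) -> np.ndarray:
    if wss.ssr is None:
        raise ValueError("run ssr() on the wall shear field first")
    return wss.valid & ~wss.ssr_flagged


def quadrant_mean_ssr(
    wss: WallShearField,
    quadrants: np.ndarray,
    segments: np.ndarray | None = None,
    segment: str | tuple | None = None,
) -> dict:
    """Mean SSR over valid vertices per quadrant, within an optional segment.

    ``segment`` may be a single label or a tuple of labels; quadrants left
    empty after validity filtering get NaN (marked missing, not an error).
    """
    ok = _valid_ssr(wss)
    if segment is not None:
        if segments is None:
            raise ValueError("segment filter requires per-vertex segment labels")
        wanted = (segment,) if isinstance(segment, str) else tuple(segment)
        ok = ok & np.isin(segments, wanted)
    out = {}
    for q in pd.unique(quadrants):
        sel = ok & (quadrants == q)
        out[q] = float(wss.ssr[sel].mean()) if sel.any() else float("nan")
    return out


def ssr_profile(
    wss: WallShearField,
    geometry: VesselGeometry,
    segments: np.ndarray | None = None,
    segment: str | tuple | None = None,
) -> pd.DataFrame:
    """Circumferential mean and max of SSR per station vs arc length.

    Returns a DataFrame (arclength_mm, ssr_mean, ssr_max, n_valid); stations
    without valid vertices get NaN.
    """
    ok = _valid_ssr(wss)
    if segment is not None:
        wanted = (segment,) if isinstance(segment, str) else tuple(segment)
        ok = ok & np.isin(segments, wanted)
    rows = []
    stations = np.unique(geometry.vertex_station[ok]) if ok.any() else []
    for st in stations:
        sel = ok & (geometry.vertex_station == st)
        vals = wss.ssr[sel]
        rows.append(
            {
                "arclength_mm": geometry.arclength[st],
                "ssr_mean": vals.mean(),
                "ssr_max": vals.max(),
                "n_valid": len(vals),
            }
        )
    return pd.DataFrame(rows, columns=["arclength_mm", "ssr_mean", "ssr_max", "n_valid"])


def cumulative_frequency(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of finite values: returns (sorted x, F(x)).

    F steps to k/n at the k-th order statistic; F(max) = 1.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cumulative frequency of an empty sample")
    x = np.sort(v)
    f = np.arange(1, len(x) + 1) / len(x)
    return x, f


def percentile(values, q: float) -> float:
    """Percentile by linear interpolation between closest ranks."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("percentile of an empty sample")
    return float(np.percentile(v, q, method="linear"))


@dataclass
class GroupTestResult:
    """Kruskal-Wallis (or post hoc) outcome."""

    H: float
    p: float
    method: str
    pairwise: list = field(default_factory=list)  # (i, j, statistic, p, significant)
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _kw_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction (direct rank-sum formula)."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


@lru_cache(maxsize=8)
def _partition_indices(sizes: tuple) -> tuple:
    """All partitions of range(sum(sizes)) into groups of the given sizes.

    Returns one (n_partitions, size_g) integer index array per group. The
    structure depends only on the sizes, so it is cached and reused across
    repeated tests (e.g. null simulations).
    """

    def partitions(free: tuple, remaining: tuple):
        if len(remaining) == 1:
            yield (free,)
            return
        k = remaining[0]
        for pick in combinations(free, k):
            rest = tuple(i for i in free if i not in pick)
            for tail in partitions(rest, remaining[1:]):
                yield (pick,) + tail

    idx_groups = [[] for _ in sizes]
    for part in partitions(tuple(range(sum(sizes))), tuple(sizes)):
        for gi, pick in enumerate(part):
            idx_groups[gi].append(pick)
    return tuple(np.asarray(idx, dtype=np.intp) for idx in idx_groups)


def _exact_permutation_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p-value by enumerating group reassignments.

    H depends on the ranks only through the per-group rank sums, so all
    partitions of the pooled sample into the observed group sizes are
    enumerated with vectorised rank-sum gathers.
    """
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    idx_groups = _partition_indices(sizes)
    h_all = np.zeros(len(idx_groups[0]))
    for gi, idx in enumerate(idx_groups):
        h_all += ranks[idx].sum(axis=1) ** 2 / sizes[gi]
    h_all = 12.0 / (n * (n + 1)) * h_all - 3 * (n + 1)
    if tie > 0:
        h_all /= tie
    return float(np.mean(h_all >= h_obs - 1e-12))


def kruskal_wallis(groups, method: str = "chi2", alpha: float = 0.05) -> GroupTestResult:
    """Non-parametric Kruskal-Wallis test across >= 2 samples.

    method="chi2": H with tie correction, p from the chi-square
    approximation with k-1 degrees of freedom (delegated to scipy).
    method="permutation": exact permutation p by enumerating all group
    reassignments (feasible for the small per-group sizes used here).
    All-identical values return H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(H=0.0, p=1.0, method=method, alpha=alpha, degenerate=True)
    if method == "chi2":
        h, p = sps.kruskal(*groups)
        return GroupTestResult(H=float(h), p=float(p), method=method, alpha=alpha)
    if method == "permutation":
        h = _kw_h(groups)
        p = _exact_permutation_p(groups, h)
        return GroupTestResult(H=float(h), p=float(p), method=method, alpha=alpha)
    raise ValueError("method must be 'chi2' or 'permutation'")


def scheffe_posthoc(groups, alpha: float = 0.05) -> GroupTestResult:
    """Scheffe simultaneous pairwise contrasts on the original values.

    For each pair (i, j) the contrast F-statistic
    (mean_i - mean_j)^2 / (MSW*(1/n_i + 1/n_j)) is compared against
    (k-1)*F_{alpha; k-1, N-k}; the reported p is the Scheffe-adjusted
    P[(k-1) F_{k-1, N-k} >= F_stat]. Zero within-group variance everywhere
    sets the degenerate flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("Scheffe post hoc needs >= 3 groups")
    ns = np.array([len(g) for g in groups])
    N = ns.sum()
    if N - k <= 0:
        raise ValueError("not enough observations for a within-group variance")
    means = np.array([g.mean() for g in groups])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ssw / (N - k)
    overall = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - overall) ** 2))
    if msw == 0:
        return GroupTestResult(
            H=float("inf") if ssb > 0 else 0.0,
            p=0.0 if ssb > 0 else 1.0,
            method="scheffe",
            alpha=alpha,
            degenerate=True,
        )
    f_crit = sps.f.ppf(1 - alpha, k - 1, N - k)
    pairwise = []
    for i, j in combinations(range(k), 2):
        f_stat = (means[i] - means[j]) ** 2 / (msw * (1 / ns[i] + 1 / ns[j]))
        p = float(sps.f.sf(f_stat / (k - 1), k - 1, N - k))
        pairwise.append((i, j, float(f_stat), p, bool(f_stat > (k - 1) * f_crit)))
    f_omni = (ssb / (k - 1)) / msw
    return GroupTestResult(
        H=float(f_omni),
        p=float(sps.f.sf(f_omni, k - 1, N - k)),
        method="scheffe",
        pairwise=pairwise,
        alpha=alpha,
    )


def dunn_posthoc(groups, alpha: float = 0.05, adjust: str = "bonferroni") -> GroupTestResult:
    """Dunn's rank-based pairwise test (Bonferroni-adjusted by default).

    The rank-based alternative to a Scheffe-on-original-values post hoc.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12 * (n - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    m = k * (k - 1) // 2
    pairwise = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(
            (n * (n + 1) / 12 - tie_term) * (1 / len(groups[i]) + 1 / len(groups[j]))
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        pairwise.append((i, j, float(z), float(p), bool(p < alpha)))
    h = _kw_h(groups)
    return GroupTestResult(
        H=float(h),
        p=float(sps.chi2.sf(h, k - 1)),
        method="dunn",
        pairwise=pairwise,
        alpha=alpha,
    )


def cohort_report(
    marker_table: pd.DataFrame | None = None,
    regional_summaries: list[RegionalSummary] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Assemble cohort report tables.

    marker_table: long DataFrame with columns (case, group, plane, marker,
    value_fine, value_mri, value_truth). Produces a per-group percentage
    error table for the fine ("simulation") and MRI-like values against the
    generator truth, plus the per-case error-reduction column (reductions are
    averaged per case, then per group).

    regional_summaries: quadrant-mean and 90th-percentile SSR tables per
    group (mean +/- s.e.m.), plus ECDF overlay points per case.
    """
    out: dict[str, pd.DataFrame] = {}
    if marker_table is not None and len(marker_table):
        df = marker_table.copy()
        mode = np.where(df["marker"] == "jet_angle_deg", "absolute", "relative")
        for col, src in (("err_fine", "value_fine"), ("err_mri", "value_mri")):
            err = []
            for m, s, r in zip(mode, df[src], df["value_truth"]):
                if m == "relative":
                    err.append(abs(s - r) / abs(r) * 100.0 if r != 0 else np.nan)
                else:
                    err.append(abs(s - r))
            df[col] = err
        with np.errstate(divide="ignore", invalid="ignore"):
            df["reduction_pct"] = np.where(
                df["err_mri"] > 0, (df["err_mri"] - df["err_fine"]) / df["err_mri"] * 100.0, np.nan
            )
        agg = (
            df.groupby(["plane", "marker"])[["err_fine", "err_mri", "reduction_pct"]]
            .agg(["mean", "sem", "count"])
        )
        out["marker_errors_by_case"] = df
        out["marker_errors"] = agg
    if regional_summaries:
        rows = []
        for rs in regional_summaries:
            row = {"case": rs.case, "group": rs.group, "p90_ssr": rs.percentile_90}
            row.update({f"ssr_{q}": v for q, v in rs.quadrant_means.items()})
            rows.append(row)
        per_case = pd.DataFrame(rows)
        value_cols = [c for c in per_case.columns if c not in ("case", "group")]
        out["regional_by_case"] = per_case
        out["regional_by_group"] = per_case.groupby("group")[value_cols].agg(["mean", "sem", "count"])
        out["ecdf_points"] = pd.concat(
            [
                pd.DataFrame(
                    {"case": rs.case, "group": rs.group, "ssr": rs.ecdf_x, "cumfreq": rs.ecdf_f}
                )
                for rs in regional_summaries
            ],
            ignore_index=True,
        )
    return out
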
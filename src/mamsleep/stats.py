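"""Group contrasts and the study's auxiliary arithmetic.

Covers: percent-change estimation with a seeded bootstrap standard error,
two-sample tests (Student/Welch t, Mann-Whitney), Kruskal-Wallis with
Dunn's post-hoc z-tests (Bonferroni-corrected) and optional paired
Wilcoxon follow-ups, density-ranked top-k tables, flagging of cells above
the comparison group's maximum, and total-protein lane normalization for
western-blot densitometry.

Ties take mid-ranks throughout; ranking ties are broken by cell id for
determinism; undefined (NaN) metric values are excluded per metric, never
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedMetricError

TWO_SAMPLE_TESTS = ("welch_t", "student_t", "mann_whitney")
EXACT_MW_MAX_N = 20


@dataclass
class GroupComparison:
    """Result of one contrast between groups on one metric."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    percent_change: float
    percent_change_se: float
    test: str
    statistic: float
    p_value: float
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class BlotLane:
    """One western-blot lane: target-band densitometry plus the Ponceau
    total-protein signal used for loading normalization."""

    lane_id: str
    group: str
    signal: float
    total_protein: float

    def __post_init__(self) -> None:
        if self.signal <= 0 or self.total_protein <= 0:
            raise ValueError(f"lane {self.lane_id}: signals must be positive")


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[np.isfinite(a)]


def percent_change(
    values_a,
    values_b,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percent change of group B relative to group A, with bootstrap SE.

    The point estimate is ``(mean_B - mean_A) / mean_A * 100``.  The SE is
    the standard deviation of the estimate over ``n_boot`` seeded
    with-replacement resamples of both groups.
    """
    a, b = _clean(values_a), _clean(values_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 finite values per group")
    if a.mean() == 0:
        raise UndefinedMetricError("baseline group mean is zero; percent change undefined")
    point = (b.mean() - a.mean()) / a.mean() * 100.0
    if n_boot <= 0:
        return float(point), math.nan
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    ma = a[ia].mean(axis=1)
    mb = b[ib].mean(axis=1)
    ok = ma != 0
    reps = (mb[ok] - ma[ok]) / ma[ok] * 100.0
    return float(point), float(reps.std(ddof=1))


def compare_two(
    values_a,
    values_b,
    test: str = "student_t",
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
    n_boot: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Two-sided two-sample contrast with the requested test.

    ``welch_t`` uses unpooled variances (Welch-Satterthwaite df);
    ``mann_whitney`` uses the exact null for combined n <= 20 without ties
    and the tie-corrected normal approximation otherwise.  Two identical
    constant groups under ``mann_whitney`` yield p = 1 with a
    ``zero-variance`` flag.
    """
    if test not in TWO_SAMPLE_TESTS:
        raise ValueError(f"unknown test {test!r}")
    a, b = _clean(values_a), _clean(values_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 finite values per group")
    flags: set[str] = set()
    if a.mean() != 0:
        pc, pc_se = percent_change(a, b, n_boot=n_boot, seed=seed)
    else:
        pc, pc_se = math.nan, math.nan
        flags.add("undefined-percent-change")

    if test in ("welch_t", "student_t"):
        res = sps.ttest_ind(b, a, equal_var=(test == "student_t"))
        stat, p = float(res.statistic), float(res.pvalue)
        if not math.isfinite(stat):  # both groups constant and equal
            stat, p = 0.0, 1.0
            flags.add("zero-variance")
    else:
        if a.std() == 0 and b.std() == 0 and a[0] == b[0]:
            stat, p = a.size * b.size / 2.0, 1.0
            flags.add("zero-variance")
        else:
            combined = np.concatenate([a, b])
            has_ties = np.unique(combined).size < combined.size
            method = "exact" if (combined.size <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
            res = sps.mannwhitneyu(b, a, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        percent_change=pc, percent_change_se=pc_se,
        test=test, statistic=stat, p_value=min(p, 1.0), flags=flags,
    )


def _dunn_pairwise(groups: dict[str, np.ndarray], correction: str) -> list[tuple[str, str, float, float]]:
    """Dunn's z-tests on rank means after a Kruskal-Wallis omnibus.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) * (1/n_i + 1/n_j) )
    where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [groups[g].size for g in labels])
    rank_means = {
        g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(labels)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            se = math.sqrt(var_base * (1 / groups[gi].size + 1 / groups[gj].size))
            z = (rank_means[gj] - rank_means[gi]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            if correction == "bonferroni":
                p = min(1.0, p * n_pairs)
            out.append((gi, gj, z, p))
    return out


def compare_multi(
    groups: dict[str, object],
    posthoc: str = "dunn",
    paired_followup: str = "none",
    paired: dict[str, tuple[object, object]] | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    metric: str = "",
    n_boot: int = 10_000,
    seed: int = 0,
) -> list[GroupComparison]:
    """Kruskal-Wallis omnibus, Dunn's corrected pairwise z-tests, and
    optional paired Wilcoxon signed-rank follow-ups.

    ``paired`` maps a group label to its (baseline, after) paired samples
    for the within-group Wilcoxon contrasts (used for baseline-vs-post-SD
    sleep).  Returns the omnibus comparison first, then one entry per Dunn
    pair, then any Wilcoxon entries.
    """
    clean = {g: _clean(v) for g, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in clean.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 finite values")

    pooled = np.concatenate(list(clean.values()))
    if np.unique(pooled).size == 1:
        h_stat, h_p, degenerate = 0.0, 1.0, True
    else:
        h_stat, h_p = sps.kruskal(*clean.values())
        degenerate = False
    labels = list(clean)
    results = [
        GroupComparison(
            metric=metric, group_a="|".join(labels), group_b="",
            n_a=int(pooled.size), n_b=0,
            mean_a=float(pooled.mean()), mean_b=math.nan,
            sd_a=float(pooled.std(ddof=1)), sd_b=math.nan,
            percent_change=math.nan, percent_change_se=math.nan,
            test="kruskal_wallis", statistic=float(h_stat), p_value=float(h_p),
            flags={"zero-variance"} if degenerate else set(),
        )
    ]
    if posthoc == "dunn" and not degenerate:
        for gi, gj, z, p in _dunn_pairwise(clean, correction):
            a, b = clean[gi], clean[gj]
            pc, pc_se = (
                percent_change(a, b, n_boot=n_boot, seed=seed)
                if a.mean() != 0 else (math.nan, math.nan)
            )
            results.append(
                GroupComparison(
                    metric=metric, group_a=gi, group_b=gj,
                    n_a=a.size, n_b=b.size,
                    mean_a=float(a.mean()), mean_b=float(b.mean()),
                    sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                    percent_change=pc, percent_change_se=pc_se,
                    test="dunn", statistic=float(z), p_value=float(p),
                )
            )
    if paired_followup == "wilcoxon" and paired:
        n_tests = len(paired)
        for g, (before, after) in paired.items():
            x, y = np.asarray(before, float), np.asarray(after, float)
            diffs = y - x
            if np.all(diffs == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(y, x)
            if correction == "bonferroni":
                p = min(1.0, p * n_tests)
            results.append(
                GroupComparison(
                    metric=metric, group_a=f"{g}:baseline", group_b=f"{g}:after",
                    n_a=x.size, n_b=y.size,
                    mean_a=float(x.mean()), mean_b=float(y.mean()),
                    sd_a=float(x.std(ddof=1)), sd_b=float(y.std(ddof=1)),
                    percent_change=(float((y.mean() - x.mean()) / x.mean() * 100)
                                    if x.mean() != 0 else math.nan),
                    percent_change_se=math.nan,
                    test="wilcoxon", statistic=float(stat), p_value=float(p),
                )
            )
    return results


def rank_top_density(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    metric: str,
    k: int = 20,
) -> pd.DataFrame:
    """Top-k descending values of ``metric`` per group with rank indices.

    Ties are broken by ``cell_id`` for a stable, reproducible order.  If a
    group has fewer than ``k`` defined values, k shrinks to the minimum
    available (warned via the ``k`` column of the result)."""
    frames = []
    k_eff = k
    for label, df in (("A", records_a), ("B", records_b)):
        sub = df[["cell_id", metric]].dropna(subset=[metric])
        k_eff = min(k_eff, len(sub))
    for label, df in (("A", records_a), ("B", records_b)):
        sub = df[["cell_id", metric]].dropna(subset=[metric])
        sub = sub.sort_values([metric, "cell_id"], ascending=[False, True], kind="stable")
        sub = sub.head(k_eff).reset_index(drop=True)
        sub.insert(0, "rank", np.arange(1, len(sub) + 1))
        sub.insert(0, "group", label)
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out["k"] = k_eff
    return out


def flag_above_max(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    metric: str,
) -> tuple[int, list[str]]:
    """Count (and list ids of) group-B cells whose metric strictly exceeds
    the group-A maximum (the 'above the highest S value' rule)."""
    a = records_a[metric].dropna()
    b = records_b[["cell_id", metric]].dropna(subset=[metric])
    if a.empty or b.empty:
        raise ValueError("both groups must have defined values")
    max_a = a.max()
    hits = b[b[metric] > max_a].sort_values("cell_id")
    return len(hits), hits["cell_id"].tolist()


def normalize_blot(lanes: list[BlotLane]) -> pd.DataFrame:
    """Total-protein loading normalization.

    lane normalization factor = lane total-protein signal / highest
    total-protein signal on the blot; normalized signal = observed signal /
    factor.  The lane with the maximal total is unchanged."""
    if not lanes:
        raise ValueError("need at least one lane")
    totals = np.array([l.total_protein for l in lanes], float)
    max_total = totals.max()
    factors = totals / max_total
    normalized = np.array([l.signal for l in lanes], float) / factors
    return pd.DataFrame(
        {
            "lane_id": [l.lane_id for l in lanes],
            "group": [l.group for l in lanes],
            "signal": [l.signal for l in lanes],
            "total_protein": totals,
            "norm_factor": factors,
            "normalized_signal": normalized,
        }
    )
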
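"""Distributional analyses of mutation-accumulation profiles.

Under a uniform molecular clock the number of (synonymous) mutations a
haplotype accumulates since the lineage MRCA is a Poisson count, so clades
evolving at a common rate should show Poisson-distributed distances and
indistinguishable group means. The tests here quantify departures from
that: a one-sample Kolmogorov–Smirnov test against Poisson(mean), group
summaries and contrasts, histogram chi-square tests, and a paired test over
replicate posterior root-to-tip means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .haplotree import DistanceProfile


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("empty group")


def _poisson_ks_d(counts: np.ndarray, lam: float) -> float:
    # ECDF and Poisson CDF are both step functions jumping only at integers,
    # so the sup gap is attained on the integer support.
    n = counts.size
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    ecdf = np.searchsorted(np.sort(counts), ks, side="right") / n
    cdf = stats.poisson.cdf(ks, lam)
    return float(np.max(np.abs(ecdf - cdf)))


def poisson_ks_test(
    counts: Sequence[int],
    method: str = "asymptotic",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sample KS test of integer counts against Poisson(sample mean).

    ``method="asymptotic"`` evaluates the classical Kolmogorov asymptotic
    p-value on the sup-gap d — the continuous-sample recipe applied to
    discrete counts with an estimated rate, which is conservative (the
    nominal type-I rate overstates the true one). ``method="bootstrap"``
    instead calibrates d by parametric bootstrap (re-estimating the rate in
    each resample), giving an exact discrete reference distribution.

    Returns (d, p). Requires n >= 8 and a non-degenerate mean.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size < 8:
        raise ValueError("need at least 8 observations")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    lam = float(arr.mean())
    if lam == 0:
        raise ValueError("degenerate all-zero sample: Poisson rate estimate is 0")
    d = _poisson_ks_d(arr.astype(int), lam)
    if method == "asymptotic":
        p = float(special.kolmogorov(np.sqrt(arr.size) * d))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            sim = rng.poisson(lam, arr.size)
            mu = sim.mean()
            boots[i] = _poisson_ks_d(sim, mu) if mu > 0 else 0.0
        p = float((np.sum(boots >= d) + 1) / (n_boot + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return d, p


def group_summaries(
    profile: DistanceProfile | Mapping[str, int],
    partition: Mapping[str, Sequence[str]],
) -> list[GroupSummary]:
    """Per-group n/mean/sd of a distance profile under a tip partition.

    Groups with no profiled tips are excluded (a warning is logged rather
    than raised, matching how sparse clades are dropped from summary
    tables). Sample standard deviation (ddof=1); NaN for singleton groups.
    """
    counts = profile.counts if isinstance(profile, DistanceProfile) else dict(profile)
    out: list[GroupSummary] = []
    for group, tips in partition.items():
        vals = [counts[t] for t in tips if t in counts]
        if not vals:
            import logging

            logging.getLogger("mitoclock").warning("empty group %s excluded", group)
            continue
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
        out.append(GroupSummary(group, arr.size, float(arr.mean()), sd))
    return out


def union_summary(parts: Sequence[GroupSummary], label: str = "GLOBAL") -> GroupSummary:
    """Size-weighted composite of disjoint groups (mean only; sd undefined
    without the raw values, reported as NaN)."""
    n = sum(p.n for p in parts)
    mean = sum(p.n * p.mean for p in parts) / n
    return GroupSummary(label, n, mean, float("nan"))


def nonsyn_percentage(total_mean: float, syn_mean: float) -> float:
    """Percentage of non-synonymous mutations, 100*(total - syn)/total."""
    if not (total_mean >= syn_mean >= 0) or total_mean <= 0:
        raise ValueError("need total_mean >= syn_mean >= 0 and total_mean > 0")
    return 100.0 * (total_mean - syn_mean) / total_mean


def compare_group_means(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t test (unequal variances). Returns (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def chi2_histogram_test(
    counts_by_group: Mapping[str, Sequence[int]],
    min_expected: float = 1.0,
) -> tuple[float, int, float]:
    """Contingency chi-square of group x distance-bin.

    Unit-width bins from 0 to the pooled maximum; the right tail is pooled
    until every expected cell count reaches ``min_expected`` (the published
    degrees of freedom are data-dependent, so binning is configurable).
    Returns (chi2, df, p).
    """
    groups = list(counts_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    kmax = max(max(v) for v in counts_by_group.values())
    table = np.zeros((len(groups), kmax + 1))
    for i, g in enumerate(groups):
        vals, cnts = np.unique(np.asarray(counts_by_group[g], dtype=int), return_counts=True)
        table[i, vals] = cnts
    # drop empty bins, then pool the right tail until all expected counts
    # clear the floor
    table = table[:, table.sum(axis=0) > 0]
    while table.shape[1] > 2:
        colsum = table.sum(axis=0)
        rowsum = table.sum(axis=1)
        expected = np.outer(rowsum, colsum) / table.sum()
        if expected.min() >= min_expected:
            break
        table = np.hstack([table[:, :-2], table[:, -2:].sum(axis=1, keepdims=True)])
    props = table / table.sum(axis=1, keepdims=True)
    if np.allclose(props, props[0]):
        # identical normalized histograms -> chi2 exactly 0
        df = (table.shape[0] - 1) * (table.shape[1] - 1)
        return 0.0, df, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def paired_rate_test(
    per_set_group_means: pd.DataFrame,
    focal: str,
    reference: str,
) -> dict:
    """Paired t test of per-replicate-set (focal - reference) mean distances.

    ``per_set_group_means`` has one row per replicate set and one column per
    group (the layout of posterior root-to-tip mean tables). Returns the t
    statistic, two-sided p, the mean difference, and both interval
    conventions for the per-group means: +/-1 SE and the 95% t interval.
    """
    if len(per_set_group_means) < 2:
        raise ValueError("need at least 2 replicate sets")
    x = per_set_group_means[focal].to_numpy(dtype=float)
    y = per_set_group_means[reference].to_numpy(dtype=float)
    diff = x - y
    if np.allclose(diff, diff[0]) and np.isclose(diff.std(), 0):
        if np.isclose(diff[0], 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(np.sign(diff[0]) * np.inf), 0.0
    else:
        t_stat, p = stats.ttest_rel(x, y)
    n = diff.size
    summaries = {}
    for col in per_set_group_means.columns:
        v = per_set_group_means[col].to_numpy(dtype=float)
        se = v.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        summaries[col] = {
            "mean": float(v.mean()),
            "se": float(se),
            "ci95_halfwidth": float(tcrit * se),
        }
    return {
        "t": float(t_stat),
        "p": float(p),
        "mean_difference": float(diff.mean()),
        "n_sets": int(n),
        "group_summaries": summaries,
    }


def summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": s.group, "n": s.n, "mean": s.mean, "sd": s.sd} for s in summaries]
    )


def histogram_frame(counts_by_group: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    kmax = max(max(v) for v in counts_by_group.values())
    data = {"distance": np.arange(kmax + 1)}
    for g, v in counts_by_group.items():
        vals, cnts = np.unique(np.asarray(v, dtype=int), return_counts=True)
        col = np.zeros(kmax + 1, dtype=int)
        col[vals] = cnts
        data[g] = col
    return pd.DataFrame(data)
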
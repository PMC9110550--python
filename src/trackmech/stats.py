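"""Nonparametric group comparisons and summary statistics.

Measurements from microtrack experiments (speeds, widths, nuclear shape
indices) are non-Gaussian, so comparisons use rank-based tests: the
Kruskal–Wallis omnibus test with Dunn's pairwise post hoc comparisons for
three or more groups, and the Mann–Whitney U test for two groups.  Dunn's
test is implemented here directly (pooled-rank z statistics with tie
correction, Bonferroni-adjusted by default).  Summaries report medians
with 25/75th and 5/95th percentiles, matching standard box–whisker plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupedMeasurements:
    """Named numeric samples grouped by condition."""

    groups: dict[str, np.ndarray]
    name: str = "measurement"
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {str(k): np.asarray(v, dtype=float).ravel()
                       for k, v in self.groups.items()}
        for k, v in self.groups.items():
            if len(v) < 1:
                raise ValueError(f"group {k!r} is empty")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str = "group",
                   value_col: str = "value", **kwargs) -> "GroupedMeasurements":
        return cls({k: g[value_col].to_numpy() for k, g in df.groupby(group_col)},
                   **kwargs)

    def labels(self) -> list[str]:
        return list(self.groups)


@dataclass
class TestResult:
    """Outcome of a hypothesis test (optionally with post hoc pairs)."""

    method: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None  # group_a, group_b, z, p_raw, p_adj


def _dunn_posthoc(samples: list[np.ndarray], labels: list[str],
                  adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's z tests on pooled ranks with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − ΣT/(12(N−1))]·(1/n_i + 1/n_j)),
    ΣT = Σ(t³ − t) over tie groups; two-sided normal p values adjusted for
    the k(k−1)/2 comparisons.
    """
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start:start + len(s)].mean())
        start += len(s)
    pairs = list(combinations(range(len(samples)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, p_raw))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(1.0, df["p_raw"] * m)
    elif adjust == "sidak":
        df["p_adj"] = 1.0 - (1.0 - df["p_raw"]) ** m
    elif adjust == "holm":
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def kruskal_wallis_dunn(data: GroupedMeasurements,
                        adjust: str = "bonferroni") -> TestResult:
    """Kruskal–Wallis omnibus test with Dunn's post hoc comparisons.

    Requires at least three groups of n ≥ 2 each; for two groups use
    :func:`mann_whitney` instead.  Returns the tie-corrected H statistic
    with its chi-square p value and a table of pairwise Dunn z tests with
    adjusted p values.
    """
    samples = list(data.groups.values())
    labels = data.labels()
    if len(samples) < 3:
        raise ValueError(
            "Kruskal–Wallis post hoc analysis needs >= 3 groups; "
            "for two groups use the Mann–Whitney test")
    for k, v in data.groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    if np.ptp(np.concatenate(samples)) == 0:
        # all observations identical: H = 0 by definition, nothing to rank
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    posthoc = _dunn_posthoc(samples, labels, adjust=adjust)
    return TestResult(method=f"Kruskal–Wallis + Dunn ({adjust})",
                      statistic=float(h), p_value=float(p), posthoc=posthoc)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the smaller sample has n ≤ 8
    and the data contain no ties, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(method=f"Mann–Whitney ({method})",
                      statistic=float(res.statistic), p_value=float(res.pvalue))


def summarize(data: GroupedMeasurements) -> pd.DataFrame:
    """Median, quartiles, 5/95th percentiles and n per group.

    Percentiles use linear interpolation (numpy's default, R type 7).
    """
    rows = []
    for label, v in data.groups.items():
        q = np.percentile(v, [5, 25, 50, 75, 95])
        rows.append((label, q[2], q[1], q[3], q[0], q[4], len(v)))
    return pd.DataFrame(rows, columns=["group", "median", "p25", "p75",
                                       "p05", "p95", "n"])


def boxplot(data: GroupedMeasurements, path=None, ax=None):
    """Box–whisker plot: median, 25/75 box, 5/95 whiskers, outlier dots."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(data.groups) + 1.5, 3.5))
    ax.boxplot(list(data.groups.values()), tick_labels=data.labels(),
               whis=(5, 95), showfliers=True,
               flierprops={"marker": ".", "markersize": 4})
    label = data.name + (f" ({data.units})" if data.units else "")
    ax.set_ylabel(label)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
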
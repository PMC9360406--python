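"""Reference ranges and non-parametric cohort comparisons.

Clinical reference intervals are the 2.5th and 97.5th percentiles of the
healthy-cohort distribution; percentiles use linear interpolation of the
order statistics at position 1 + (n-1)p, the convention fixed here for
reproducibility.

Comparisons follow standard practice for skewed laboratory data:
Shapiro-Wilk normality screening, the Friedman test for paired
(within-subject, across-condition) designs, the Kruskal-Wallis test for
independent groups, each followed by Dunn's post-hoc pairwise z-tests on
mean ranks with Bonferroni family adjustment over the tested pairs.
Paired tests use complete-case rows (Friedman requires complete blocks);
counts of dropped rows are reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceRange",
    "TestReport",
    "reference_range",
    "compare_paired",
    "compare_groups",
    "normality_check",
    "dunn_paired",
    "dunn_independent",
]


@dataclass(frozen=True)
class ReferenceRange:
    median: float
    p2_5: float
    p97_5: float
    n: int

    def to_dict(self) -> dict:
        return {"median": self.median, "p2_5": self.p2_5, "p97_5": self.p97_5, "n": self.n}


@dataclass
class TestReport:
    """Omnibus test plus Dunn post-hoc pairwise p-values and per-group
    descriptives."""

    test: str
    statistic: float
    p_value: float
    n: int
    groups: dict = field(default_factory=dict)  # name -> {median, iqr, n}
    pairwise: dict = field(default_factory=dict)  # (a, b) -> adjusted p
    dropped: int = 0  # incomplete rows removed (paired designs)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "groups": self.groups,
            "pairwise": {f"{a} vs {b}": p for (a, b), p in self.pairwise.items()},
            "dropped": self.dropped,
        }


def reference_range(values) -> ReferenceRange:
    """Median and 2.5th/97.5th percentile of a healthy-cohort sample.

    Missing values are dropped; percentiles interpolate linearly between
    order statistics (position 1 + (n-1)p).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"need >= 2 non-missing values, got {x.size}")
    lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5], method="linear")
    return ReferenceRange(median=float(med), p2_5=float(lo), p97_5=float(hi), n=int(x.size))


def _describe(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return {"median": float(med), "iqr": (float(q1), float(q3)), "n": int(x.size)}


def compare_paired(table: pd.DataFrame, columns: list[str] | None = None) -> TestReport:
    """Friedman omnibus + Dunn post-hoc across paired columns.

    ``table`` has one row per subject and one column per condition;
    incomplete rows are dropped (complete-block requirement).
    """
    if columns is not None:
        table = table[list(columns)]
    if table.shape[1] < 3:
        raise ValueError("paired omnibus needs >= 3 conditions (use a sign/Wilcoxon test for 2)")
    complete = table.dropna()
    dropped = len(table) - len(complete)
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete subjects, got {len(complete)}")
    cols = [complete[c].to_numpy(dtype=float) for c in complete.columns]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        stat, p = 0.0, 1.0  # identical conditions: all rank sums equal
    else:
        stat, p = stats.friedmanchisquare(*cols)
    pairwise = dunn_paired(complete)
    return TestReport(
        test="friedman",
        statistic=float(stat),
        p_value=float(p),
        n=len(complete),
        groups={c: _describe(complete[c].to_numpy(dtype=float)) for c in complete.columns},
        pairwise=pairwise,
        dropped=dropped,
    )


def dunn_paired(table: pd.DataFrame, pairs=None) -> dict:
    """Dunn's z-tests on within-block mean ranks (Friedman follow-up),
    Bonferroni-adjusted over the tested pairs."""
    ranks = table.rank(axis=1)  # average ranks on ties
    n, k = table.shape
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    if pairs is None:
        pairs = list(itertools.combinations(table.columns, 2))
    m = len(pairs)
    out = {}
    for a, b in pairs:
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = float(min(1.0, m * p))
    return out


def compare_groups(values, labels) -> TestReport:
    """Kruskal-Wallis omnibus + Dunn post-hoc for independent groups
    (e.g. men / women without OC / women with OC)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = np.isfinite(values)
    values, labels = values[mask], labels[mask]
    names = [str(g) for g in pd.unique(labels)]
    groups = {g: values[labels == g] for g in names}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, x in groups.items():
        if x.size < 2:
            raise ValueError(f"group {g!r} has < 2 observations")
    samples = list(groups.values())
    if all(np.allclose(s, samples[0][0]) for s in samples) and all(
        np.ptp(s) == 0 for s in samples
    ):
        stat, p = 0.0, 1.0  # every observation identical: H = 0
    else:
        stat, p = stats.kruskal(*samples)
    pairwise = dunn_independent(groups)
    return TestReport(
        test="kruskal-wallis",
        statistic=float(stat),
        p_value=float(p),
        n=int(values.size),
        groups={g: _describe(x) for g, x in groups.items()},
        pairwise=pairwise,
    )


def dunn_independent(groups: dict) -> dict:
    """Dunn's z-tests on pooled mean ranks with tie correction
    (Kruskal-Wallis follow-up), Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    mean_ranks = {}
    start = 0
    for g in names:
        size = groups[g].size
        mean_ranks[g] = ranks[start : start + size].mean()
        start += size
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = {}
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out[(a, b)] = float(min(1.0, m * p))
    return out


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p.  Valid for 3 <= n <= 5000; a constant
    vector has undefined W and is rejected."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: Shapiro-Wilk W undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)
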
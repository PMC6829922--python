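"""Replicate aggregation, Welch comparisons and observed-vs-predicted reports.

Per-replicate editing frequencies (percent) are aggregated per gRNA x
homoeoallele into mean and standard error of the mean (SEM, sd/sqrt(n) with
the n-1 sample standard deviation; the emulated experiment used n = 3
biological replicates).  Group comparisons use the two-sample t-test assuming
unequal variances (Welch, Satterthwaite degrees of freedom).  The
observed-vs-predicted report relates mean on-target frequencies to external
in-silico activity scores via Spearman rank correlation (censored scores such
as "< 50" are treated as missing, never imputed) and counts gRNAs in the
conventional activity bands (< 3%, 3-10%, > 10%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "WelchResult",
    "ComparisonReport",
    "UndefinedRatioError",
    "aggregate",
    "welch_test",
    "on_off_ratio",
    "table1_report",
    "parse_score",
    "pooled_on_target_mean",
]


class UndefinedRatioError(ValueError):
    """Off/on ratio requested with a non-positive on-target mean."""


@dataclass
class GroupSummary:
    """Replicate values (percent) with mean and SEM for one gRNA x allele."""

    guide_id: str
    allele_id: str
    values: tuple
    mean: float
    sem: Optional[float]  # None when n == 1
    n: int


@dataclass
class WelchResult:
    """Welch two-sample t-test: statistic, Satterthwaite df, two-sided p."""

    t: float
    df: float
    p: float


@dataclass
class ComparisonReport:
    """Observed mean activities vs external score columns.

    ``rho`` maps score-column name to Spearman rho (None when fewer than
    three usable pairs).  ``band_counts`` counts gRNAs with observed activity
    < 3% (low), in [3%, 10%] (moderate) and > 10% (high).
    """

    observed: dict
    scores: dict
    rho: dict
    band_counts: dict


def aggregate(
    replicates: Sequence[float], guide_id: str = "", allele_id: str = ""
) -> GroupSummary:
    """Mean and SEM (sd/sqrt(n), n-1 denominator) of replicate percentages."""
    values = tuple(float(v) for v in replicates)
    if not values:
        raise ValueError("need at least one replicate value")
    n = len(values)
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else None
    return GroupSummary(guide_id, allele_id, values, mean, sem, n)


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sample t-test assuming unequal variances (Welch).

    Requires n >= 2 per group and nonzero variance in at least one group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two replicates")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; test is degenerate")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def on_off_ratio(on: GroupSummary, off: GroupSummary) -> float:
    """Off-target activity as a percent of on-target activity."""
    if on.mean <= 0:
        raise UndefinedRatioError("on-target mean must be positive")
    return 100.0 * off.mean / on.mean


def parse_score(value: Union[float, str, None]) -> Optional[float]:
    """Parse an external activity score; censored values ("< 50") and blanks
    become missing (None)."""
    if value is None:
        return None
    if isinstance(value, str):
        v = value.strip()
        if not v or v.startswith("<") or v.startswith(">"):
            return None
        return float(v)
    value = float(value)
    return None if math.isnan(value) else value


def pooled_on_target_mean(
    per_allele_means: Mapping[str, float], weights: Optional[Mapping[str, int]] = None
) -> float:
    """Pool per-target-homoeoallele mean frequencies into one gRNA activity.

    Default is the unweighted average over target homoeoalleles; passing read
    counts as ``weights`` switches to read-weighted pooling.
    """
    if not per_allele_means:
        raise ValueError("no per-allele means to pool")
    if weights is None:
        return float(np.mean(list(per_allele_means.values())))
    total = sum(weights[a] for a in per_allele_means)
    if total <= 0:
        raise ValueError("weights must sum to a positive total")
    return float(
        sum(per_allele_means[a] * weights[a] for a in per_allele_means) / total
    )


def _spearman(pairs: list[tuple[float, float]]) -> Optional[float]:
    if len(pairs) < 3:
        return None
    obs, sc = zip(*pairs)
    rho = stats.spearmanr(obs, sc).statistic
    return float(rho)


def table1_report(
    observed: Mapping[str, float],
    scores: Optional[Mapping[str, Mapping[str, Union[float, str, None]]]] = None,
    bands: tuple[float, float] = (3.0, 10.0),
) -> ComparisonReport:
    """Observed-vs-predicted comparison over a panel of gRNAs.

    Parameters
    ----------
    observed
        gRNA id -> mean on-target indel frequency (percent).
    scores
        Score-column name -> {gRNA id -> score or censored string}; censored
        entries are excluded pairwise from each correlation.
    bands
        (low, high) thresholds for the activity bands: low < bands[0],
        moderate in [bands[0], bands[1]], high > bands[1].
    """
    if len(observed) < 3:
        raise ValueError("need observed values for at least three gRNAs")
    obs = {g: float(v) for g, v in observed.items()}
    parsed: dict = {}
    rho: dict = {}
    for col, col_scores in (scores or {}).items():
        parsed[col] = {g: parse_score(col_scores.get(g)) for g in obs}
        pairs = [(obs[g], s) for g, s in parsed[col].items() if s is not None]
        rho[col] = _spearman(pairs)
    lo, hi = bands
    band_counts = {
        "low": sum(v < lo for v in obs.values()),
        "moderate": sum(lo <= v <= hi for v in obs.values()),
        "high": sum(v > hi for v in obs.values()),
    }
    return ComparisonReport(obs, parsed, rho, band_counts)


def plot_editing_summary(summaries: Sequence[GroupSummary], ax=None):
    """Bar chart of mean +/- SEM per gRNA x allele (requires matplotlib)."""
    import matplotlib.pyplot as plt  # lazy: plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(summaries), 3.2))
    labels = [f"{s.guide_id}\n{s.allele_id}" for s in summaries]
    means = [s.mean for s in summaries]
    errs = [s.sem or 0.0 for s in summaries]
    ax.bar(range(len(summaries)), means, yerr=errs, capsize=3)
    ax.set_xticks(range(len(summaries)), labels, fontsize=8)
    ax.set_ylabel("indel frequency (%)")
    return ax
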
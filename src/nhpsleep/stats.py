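"""The study-level statistical battery.

Disease states are compared as unpaired groups: Shapiro-Wilk normality
check, Kruskal-Wallis omnibus followed by Dunn's multiple comparisons
(Bonferroni-adjusted two-sided z tests on mean ranks with pooled
tie-corrected variance), Mann-Whitney rank-sum for two-group contrasts,
per-bin one-way ANOVA for spectra, and mean +/- SEM summaries with
t-based 95% confidence intervals.

Pairwise Dunn results are reported whether or not the omnibus rejects
(the layout convention of the usual GraphPad-style tables); a flag gates
them on the omnibus if preferred.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as spstats


@dataclasses.dataclass(frozen=True)
class GroupedSamples:
    """Named groups of observations of one metric."""

    groups: dict[str, np.ndarray]
    metric: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        clean = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for name, v in clean.items():
            if len(v) == 0:
                raise ValueError(f"group {name!r} is empty")
        object.__setattr__(self, "groups", clean)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.groups)


@dataclasses.dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_unadjusted: float
    p_adjusted: float
    significant: bool


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    pairwise: tuple[PairwiseResult, ...] | None = None
    name: str = ""


def _rank_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and the tie-group sizes of the pooled sample."""
    ranks = spstats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return ranks, counts


def kruskal_dunn(
    samples: GroupedSamples, alpha: float = 0.05, gate_on_omnibus: bool = False
) -> TestResult:
    """Kruskal-Wallis omnibus plus Dunn's pairwise multiple comparisons.

    H is tie-corrected with a chi-square (k-1 df) approximation.  Dunn's z
    for groups i, j is (Ri - Rj) / sqrt(S2 * (1/ni + 1/nj)) with
    S2 = N(N+1)/12 - sum(t^3 - t)/(12(N-1)); two-sided p-values are
    Bonferroni-adjusted over all k(k-1)/2 pairs.
    """
    groups = samples.groups
    names = samples.names
    ns = {k: len(v) for k, v in groups.items()}
    pooled = np.concatenate([groups[k] for k in names])
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")

    ranks, tie_counts = _rank_with_ties(pooled)
    mean_ranks = {}
    offset = 0
    for k in names:
        mean_ranks[k] = float(ranks[offset : offset + ns[k]].mean())
        offset += ns[k]

    # Omnibus H with tie correction.
    h = (12.0 / (n_total * (n_total + 1))) * sum(
        ns[k] * mean_ranks[k] ** 2 for k in names
    ) - 3.0 * (n_total + 1)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total) if n_total > 1 else 1.0
    if correction <= 0:  # all observations identical
        h, p_omni = 0.0, 1.0
    else:
        h = h / correction
        p_omni = float(spstats.chi2.sf(h, df=len(names) - 1))

    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    s2 = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairwise = []
    for a, b in pairs:
        if s2 <= 0:
            z, p_un = 0.0, 1.0
        else:
            se = math.sqrt(s2 * (1.0 / ns[a] + 1.0 / ns[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p_un = float(2.0 * spstats.norm.sf(abs(z)))
        p_adj = min(1.0, p_un * m)
        sig = p_adj <= alpha and (not gate_on_omnibus or p_omni <= alpha)
        pairwise.append(PairwiseResult((a, b), z, p_un, p_adj, sig))

    return TestResult(statistic=float(h), p=p_omni, pairwise=tuple(pairwise),
                      name=f"kruskal_dunn[{samples.metric}]")


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U; exact enumeration when both n <= 8
    (tie-free), tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                      name="mann_whitney")


def shapiro(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk supports 3 <= n <= 5000, got n={len(x)}")
    res = spstats.shapiro(x)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), name="shapiro")


def anova_oneway(samples: GroupedSamples) -> TestResult:
    """One-way fixed-effects ANOVA across the groups."""
    arrays = list(samples.groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:  # identical groups -> F = 0
        return TestResult(statistic=0.0, p=1.0, name=f"anova[{samples.metric}]")
    f, p = spstats.f_oneway(*arrays)
    return TestResult(statistic=float(f), p=float(p), name=f"anova[{samples.metric}]")


def summarize(x: Sequence[float]) -> tuple[float, float, tuple[float, float]]:
    """(mean, SEM, t-based 95% CI) of one sample."""
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    if len(x) < 2:
        return mean, 0.0, (mean, mean)
    sem = float(x.std(ddof=1) / math.sqrt(len(x)))
    half = sem * float(spstats.t.ppf(0.975, df=len(x) - 1))
    return mean, sem, (mean - half, mean + half)
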
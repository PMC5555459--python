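"""Population-level statistics on per-nucleus trait tables.

Covers per-line aggregation with outlier removal, broad-sense heritability
from one-way ANOVA variance components, trait-trait Pearson correlation
networks, transgression ratios, Welch two-sample tests, a 2x2 chi-square on
size classes, and a normality check.

Broad-sense heritability is the between-line share of the total trait
variance, H2 = s2_between / (s2_between + s2_within), estimated by
method-of-moments from a one-way ANOVA with the unbalanced-design
correction n0 = (N - sum(n_i^2)/N) / (k - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LineSummary", "HeritabilityResult", "CorrelationEdge",
           "remove_outliers", "line_summary", "line_means", "heritability",
           "correlation_network", "transgression_ratio", "welch_test",
           "chi2_size_classes", "test_normality", "compact_letter_display"]

log = logging.getLogger(__name__)

ID_COLUMNS = ("line_id", "plant_id", "nucleus_id")

#: significance star levels, most to least permissive
STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class LineSummary:
    line_id: object
    trait: str
    mean: float
    sd: float
    n_used: int       # nuclei remaining after outlier removal
    n_nuclei: int     # nuclei observed for the line
    n_plants: int


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    sigma2_between: float
    sigma2_within: float
    H2: float
    n_lines: int
    N_total: int


@dataclass(frozen=True)
class CorrelationEdge:
    trait_a: str
    trait_b: str
    pearson_r: float
    p_value: float
    stars: str          # '', '*', '**', '***' or '****'
    significant: bool


def remove_outliers(values, rule: str = "percentile95") -> np.ndarray:
    """Drop outlying trait values by one of the two published rules.

    'percentile95' keeps values inside the central 95% empirical interval
    (2.5th-97.5th percentile, inclusive); 'sd2' keeps values within two
    standard deviations of the mean, with mean and SD computed once on the
    input (single pass, hence idempotent given the original mean/SD).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for outlier removal")
    if rule == "percentile95":
        lo, hi = np.percentile(values, [2.5, 97.5])
        keep = (values >= lo) & (values <= hi)
    elif rule == "sd2":
        m, s = values.mean(), values.std(ddof=1)
        keep = np.abs(values - m) <= 2.0 * s
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    return values[keep]


def _trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def line_summary(trait_table: pd.DataFrame, min_nuclei: int = 26,
                 min_plants: int = 2, outlier_rule: str = "percentile95"
                 ) -> list[LineSummary]:
    """Per-line, per-trait mean and SD after outlier removal.

    Lines with fewer than ``min_nuclei`` nuclei or ``min_plants`` plants are
    excluded with a logged warning.
    """
    if trait_table.empty:
        raise ValueError("empty trait table")
    traits = _trait_columns(trait_table)
    out: list[LineSummary] = []
    for line_id, sub in trait_table.groupby("line_id", sort=False):
        n_nuclei = len(sub)
        n_plants = sub["plant_id"].nunique() if "plant_id" in sub else 1
        if n_nuclei < min_nuclei or n_plants < min_plants:
            log.warning("line %s excluded: %d nuclei from %d plants "
                        "(need >=%d nuclei, >=%d plants)",
                        line_id, n_nuclei, n_plants, min_nuclei, min_plants)
            continue
        for trait in traits:
            vals = sub[trait].to_numpy(dtype=float)
            kept = remove_outliers(vals, outlier_rule) if len(vals) >= 3 else vals
            out.append(LineSummary(line_id=line_id, trait=trait,
                                   mean=float(kept.mean()),
                                   sd=float(kept.std(ddof=1)) if len(kept) > 1 else 0.0,
                                   n_used=len(kept), n_nuclei=n_nuclei,
                                   n_plants=n_plants))
    return out


def line_means(summaries: Sequence[LineSummary]) -> pd.DataFrame:
    """Pivot LineSummary records into a lines x traits matrix of means."""
    df = pd.DataFrame([{"line_id": s.line_id, "trait": s.trait, "mean": s.mean}
                       for s in summaries])
    if df.empty:
        raise ValueError("no line summaries")
    return df.pivot(index="line_id", columns="trait", values="mean")


def heritability(trait_table: pd.DataFrame, trait: Optional[str] = None) -> HeritabilityResult:
    """Broad-sense heritability of one trait from the per-nucleus table."""
    if trait is None:
        traits = _trait_columns(trait_table)
        if len(traits) != 1:
            raise ValueError(f"specify the trait; table has {traits}")
        trait = traits[0]
    groups = [g.to_numpy(dtype=float)
              for _, g in trait_table.groupby("line_id", sort=False)[trait]]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 lines")
    n_i = np.array([len(g) for g in groups], dtype=float)
    N = n_i.sum()
    if not np.any(n_i >= 2):
        raise ValueError("need at least 2 observations in some line")
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - np.sum(n_i ** 2) / N) / (k - 1)
    sigma2_between = max(0.0, (msb - msw) / n0)
    sigma2_within = msw
    total = sigma2_between + sigma2_within
    h2 = sigma2_between / total if total > 0 else 0.0
    return HeritabilityResult(trait=trait, sigma2_between=sigma2_between,
                              sigma2_within=sigma2_within, H2=float(h2),
                              n_lines=k, N_total=int(N))


def _stars(p: float, alpha_levels: Sequence[float] = STAR_LEVELS) -> str:
    return "*" * sum(p < a for a in sorted(alpha_levels, reverse=True))


def correlation_network(means: pd.DataFrame, traits: Optional[Sequence[str]] = None,
                        alpha_levels: Sequence[float] = STAR_LEVELS,
                        significant_only: bool = True) -> list[CorrelationEdge]:
    """Pairwise Pearson correlations between per-line trait means.

    ``means`` is a lines x traits matrix (parental lines and the F1 may be
    included as additional rows, each contributing one averaged value).
    Returns the edge list; by default only pairs significant at the most
    permissive alpha level.  A trait constant across lines yields NaN edges,
    reported but never significant.
    """
    if traits is None:
        traits = list(means.columns)
    if len(means) < 4:
        raise ValueError("need at least 4 lines for the correlation network")
    alpha_max = max(alpha_levels)
    edges = []
    for a, b in combinations(traits, 2):
        x = means[a].to_numpy(dtype=float)
        y = means[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 4 or np.std(x) == 0 or np.std(y) == 0:
            edge = CorrelationEdge(a, b, float("nan"), float("nan"), "", False)
        else:
            r, p = stats.pearsonr(x, y)
            edge = CorrelationEdge(a, b, float(r), float(p),
                                   _stars(p, alpha_levels), bool(p < alpha_max))
        if edge.significant or not significant_only:
            edges.append(edge)
    return edges


def network_graph(edges: Sequence[CorrelationEdge]):
    """CorrelationEdge list as a networkx graph (for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(e.trait_a, e.trait_b, r=e.pearson_r, p=e.p_value, stars=e.stars)
    return g


def transgression_ratio(means: pd.DataFrame | Sequence[float], trait: Optional[str] = None) -> float:
    """100 * min / max over per-line trait means (all means must be > 0).

    A low percentage means wide transgressive variation among the lines.
    """
    if isinstance(means, pd.DataFrame):
        vals = means[trait].to_numpy(dtype=float)
    else:
        vals = np.asarray(means, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or np.any(vals <= 0):
        raise ValueError("transgression ratio requires strictly positive line means")
    return float(100.0 * vals.min() / vals.max())


def welch_test(values_a, values_b) -> tuple[float, float, int]:
    """Two-sided Welch t-test; returns (t, p, sign of mean_a - mean_b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, 0
        raise ValueError("both groups are constant; Welch statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), int(np.sign(a.mean() - b.mean()))


def chi2_size_classes(values_a, values_b, cutoff: float,
                      continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square comparing the above/below-cutoff split of two groups.

    Builds the 2x2 table (group x size class, 'above' meaning value >
    cutoff); continuity correction off by default.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    table = np.array([[np.sum(a <= cutoff), np.sum(a > cutoff)],
                      [np.sum(b <= cutoff), np.sum(b > cutoff)]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty margin in the 2x2 size-class table")
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def test_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; requires n >= 8 and non-constant input."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 8:
        raise ValueError("need at least 8 values for the normality test")
    if vals.std() == 0:
        raise ValueError("constant input")
    res = stats.shapiro(vals)
    return float(res.statistic), float(res.pvalue)


def compact_letter_display(groups: dict[object, Sequence[float]],
                           alpha: float = 0.01) -> dict[object, str]:
    """Significance letters from all pairwise Welch tests (reporting utility).

    Groups sharing a letter are not significantly different at ``alpha``.
    Uses the insert-and-absorb construction on groups ordered by mean.
    """
    names = sorted(groups, key=lambda k: np.mean(groups[k]))
    differ = {(x, y): welch_test(groups[x], groups[y])[1] < alpha
              for x, y in combinations(names, 2)}

    def ns(x, y):
        return not differ.get((x, y), differ.get((y, x), False))

    letter_sets: list[set] = []
    for g in names:
        placed = False
        for s in letter_sets:
            if all(ns(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    out = {g: "" for g in names}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += chr(ord("a") + i)
    return out
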
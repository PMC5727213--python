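"""Univariate marker filters and the three-criterion intersection.

Each array feature is scored between the two extreme bulks by

* Fisher's ratio ``(M1 - M2)^2 / (V1 + V2)`` — separation of the bulk means
  against the summed bulk variances; features are ranked and the top K
  (default 10) retained;
* an independent two-sample t-test on the 12 + 12 data points, either the
  pooled (equal-variance) or the Welch form, significant at p < 0.01 by
  default;
* membership of the stepwise-DFA model for the compound.

A putative marker must satisfy all three criteria; the three-way Venn
region counts are reported alongside the intersection.  Because Levene's
variance test needs raw data, automatic pooled/Welch selection is offered
only for raw groups; from summary statistics the caller picks the variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, UndefinedStatisticError

DEFAULT_ALPHA = 0.01
DEFAULT_TOP_K = 10


# ---------------------------------------------------------------------------
# Fisher's ratio
# ---------------------------------------------------------------------------

def fishers_ratio(m1: float, v1: float, m2: float, v2: float) -> float:
    """Fisher's ratio (M1 - M2)^2 / (V1 + V2) of two group summaries.

    Degenerate zero-variance input: equal means give 0; distinct means give
    ``inf`` (infinite separation).
    """
    if v1 < 0 or v2 < 0:
        raise ValueError("variances must be nonnegative")
    diff = m1 - m2
    denom = v1 + v2
    if denom == 0:
        return 0.0 if diff == 0 else math.inf
    return diff * diff / denom


@dataclass(frozen=True)
class FisherRanking:
    """Features ordered by non-increasing Fisher's ratio, with a top-K cut."""

    compound: str
    ranking: tuple[tuple[str, float], ...]
    k: int

    @property
    def top_features(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.ranking[: self.k])


def rank_top_k(
    group_stats: pd.DataFrame,
    k: int = DEFAULT_TOP_K,
    compound: str = "",
) -> FisherRanking:
    """Rank features by Fisher's ratio computed from group statistics.

    ``group_stats`` needs columns feature, mean_h, var_h (or sd_h), mean_l,
    var_l (or sd_l).  Ties break lexicographically by feature id.
    """
    if group_stats.empty:
        raise DegenerateInputError("empty group statistics")
    gs = group_stats.copy()
    if "var_h" not in gs.columns:
        gs["var_h"] = gs["sd_h"] ** 2
    if "var_l" not in gs.columns:
        gs["var_l"] = gs["sd_l"] ** 2
    ratios = [
        (row.feature,
         fishers_ratio(row.mean_h, row.var_h, row.mean_l, row.var_l))
        for row in gs.itertuples()
    ]
    ratios.sort(key=lambda fr: (-fr[1], fr[0]))
    return FisherRanking(compound=compound, ranking=tuple(ratios), k=k)


# ---------------------------------------------------------------------------
# Two-sample t-tests from summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    """Two-sided two-sample t-test computed from group summaries."""

    feature: str
    t: float
    df: float
    p: float
    variant: str  # "pooled" | "welch"

    @property
    def significance(self) -> str:
        if self.p > 0.05:
            return "ns"
        if self.p > 0.01:
            return "*"
        return "**"

    @property
    def df_display(self) -> float:
        """df rounded to 1 decimal, the conventional display precision."""
        return round(self.df, 1)


def two_sample_t(
    m1: float, sd1: float, n1: int,
    m2: float, sd2: float, n2: int,
    variant: str = "pooled",
    feature: str = "",
) -> TTestResult:
    """Independent two-sample t-test from means, SDs and group sizes.

    pooled: ``t = (M1-M2) / (s_p sqrt(1/n1 + 1/n2))`` with the pooled SD
    ``s_p`` and ``df = n1 + n2 - 2``.  welch: ``t = (M1-M2) /
    sqrt(SD1^2/n1 + SD2^2/n2)`` with the Welch-Satterthwaite df.  p is
    two-sided.  Both SDs zero with equal means raises
    :class:`UndefinedStatisticError`; with distinct means t is infinite and
    p = 0.
    """
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    diff = m1 - m2
    if sd1 == 0 and sd2 == 0:
        if diff == 0:
            raise UndefinedStatisticError(
                "t undefined: zero spread and equal means")
        df = float(n1 + n2 - 2)
        return TTestResult(feature, math.copysign(math.inf, diff), df, 0.0,
                           variant)
    v1, v2 = sd1 * sd1, sd2 * sd2
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(feature, t, df, p, variant)


def levene_test(*groups: Sequence[float]) -> tuple[float, float, bool]:
    """Mean-centred Levene test for equal variances on raw group values.

    Returns ``(F, p, fallback)``.  ``fallback`` is True when some group has
    zero spread, in which case the test statistic is undefined and callers
    should use the Welch form directly.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise DegenerateInputError("each group needs n >= 2")
    if any(np.ptp(a) == 0 for a in arrays):
        return math.nan, math.nan, True
    f, p = stats.levene(*arrays, center="mean")
    return float(f), float(p), False


def choose_variant(
    group1: Sequence[float],
    group2: Sequence[float],
    alpha: float = 0.05,
) -> str:
    """Pick pooled vs Welch from raw data via the mean-centred Levene test.

    Pooled when Levene's p > alpha (variances compatible), otherwise Welch;
    zero-spread groups fall back to Welch directly.
    """
    _, p, fallback = levene_test(group1, group2)
    if fallback:
        return "welch"
    return "pooled" if p > alpha else "welch"


def t_tests_from_group_stats(
    group_stats: pd.DataFrame,
    variant: str | Mapping[str, str] = "pooled",
) -> list[TTestResult]:
    """Per-feature t-tests over a group-statistics frame.

    ``variant`` is a single form for every feature or a mapping
    feature -> form.
    """
    results = []
    for row in group_stats.itertuples():
        form = variant if isinstance(variant, str) else variant[row.feature]
        results.append(two_sample_t(
            row.mean_h, row.sd_h, int(row.n_h),
            row.mean_l, row.sd_l, int(row.n_l),
            variant=form, feature=row.feature,
        ))
    return results


# ---------------------------------------------------------------------------
# Three-criterion intersection
# ---------------------------------------------------------------------------

VENN_REGIONS = (
    "dfa_only", "fisher_only", "ttest_only",
    "dfa_fisher", "dfa_ttest", "fisher_ttest",
    "dfa_fisher_ttest",
)


@dataclass(frozen=True)
class MarkerSelection:
    """Per-compound marker sets from the three criteria."""

    compound: str
    dfa_set: frozenset[str]
    fisher_set: frozenset[str]
    ttest_set: frozenset[str]

    @property
    def intersection(self) -> frozenset[str]:
        return self.dfa_set & self.fisher_set & self.ttest_set

    @property
    def venn_regions(self) -> dict[str, int]:
        """Cardinalities of the seven exclusive Venn regions."""
        d, f, t = self.dfa_set, self.fisher_set, self.ttest_set
        return {
            "dfa_only": len(d - f - t),
            "fisher_only": len(f - d - t),
            "ttest_only": len(t - d - f),
            "dfa_fisher": len((d & f) - t),
            "dfa_ttest": len((d & t) - f),
            "fisher_ttest": len((f & t) - d),
            "dfa_fisher_ttest": len(d & f & t),
        }

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "dfa": sorted(self.dfa_set),
            "fisher_topk": sorted(self.fisher_set),
            "ttest": sorted(self.ttest_set),
            "intersection": sorted(self.intersection),
            "venn_regions": self.venn_regions,
        }


def three_way_intersection(
    dfa_set: Iterable[str],
    fisher_set: Iterable[str],
    ttest_set: Iterable[str],
    compound: str = "",
) -> MarkerSelection:
    """Combine the three criterion sets into a marker selection."""
    return MarkerSelection(
        compound=compound,
        dfa_set=frozenset(dfa_set),
        fisher_set=frozenset(fisher_set),
        ttest_set=frozenset(ttest_set),
    )


def filter_markers(
    group_stats: pd.DataFrame,
    dfa_features: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_TOP_K,
    variant: str | Mapping[str, str] = "pooled",
    compound: str = "",
    bonferroni: bool = False,
) -> MarkerSelection:
    """Apply all three marker criteria for one compound and intersect.

    The t-test criterion is two-sided p < ``alpha`` (default 0.01); with
    ``bonferroni`` the threshold becomes alpha divided by the number of
    features tested.  The Fisher criterion is membership of the top-``k``
    ranking; the DFA criterion is membership of ``dfa_features``.
    """
    ranking = rank_top_k(group_stats, k=k, compound=compound)
    tests = t_tests_from_group_stats(group_stats, variant=variant)
    cut = alpha / len(tests) if bonferroni else alpha
    ttest_set = {r.feature for r in tests if r.p < cut}
    return three_way_intersection(
        dfa_features, ranking.top_features, ttest_set, compound=compound,
    )
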
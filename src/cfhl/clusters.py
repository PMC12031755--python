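"""Supervised EBV/SOCS1 clustering and cohort statistics.

Patients are grouped by two oncogenic drivers: tumor-cell EBV status and
the presence of at least one PASS SOCS1 variant in plasma.  Three
clusters occur in practice — EBV+ & SOCS1-mutated, EBV- & SOCS1-mutated
and EBV- & SOCS1-wild-type — and samples with no detectable ctDNA (or
unknown EBV status) remain unassigned.

Group comparisons use the Wilcoxon rank-sum test (two groups) and the
Kruskal-Wallis test (three groups); correlations use Spearman's rho;
p < 0.05 is the significance level and no multiplicity correction is
applied.  To compare SNV load between clusters without circularity,
SOCS1 variants themselves can be excluded from the load, and a median-VAF
overlap-matching step restricts the SOCS1m/SOCS1wt comparison to samples
with comparable ctDNA levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .quantify import SampleRecord
from .variants import AnnotatedVariant

__all__ = [
    "CLUSTER_LABELS",
    "ComparisonResult",
    "assign_cluster",
    "snv_load",
    "vaf_overlap_match",
    "compare_groups",
    "correlate",
]

CLUSTER_LABELS = (
    "EBV_pos_SOCS1m",
    "EBV_neg_SOCS1m",
    "EBV_neg_SOCS1wt",
    "EBV_pos_SOCS1wt",  # robustness only, never observed in practice
    "unassigned",
)

SIGNIFICANCE_LEVEL = 0.05

# exact rank statistics up to this group size, normal approximation beyond
EXACT_TEST_MAX_N = 25


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # wilcoxon_rank_sum | kruskal_wallis | spearman
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def assign_cluster(sample: SampleRecord, pass_variants: Sequence[AnnotatedVariant]) -> str:
    """Deterministic cluster label from EBV status and SOCS1 PASS variants.

    Samples without any PASS variant carry no detectable ctDNA and are
    unassigned, as are samples with unknown EBV status.
    """
    passed = [v for v in pass_variants if v.passed]
    if not passed or sample.ebv_status not in ("positive", "negative"):
        return "unassigned"
    socs1 = any(v.gene == "SOCS1" for v in passed)
    ebv = "pos" if sample.ebv_status == "positive" else "neg"
    return f"EBV_{ebv}_SOCS1{'m' if socs1 else 'wt'}"


def snv_load(pass_variants: Sequence[AnnotatedVariant], exclude_socs1: bool = True) -> int:
    """Number of PASS SNVs in one sample, optionally excluding SOCS1.

    SOCS1 variants are excluded by default when comparing clusters that
    were themselves defined by SOCS1 status.
    """
    return sum(
        1
        for v in pass_variants
        if v.passed
        and v.variant_class == "SNV"
        and not (exclude_socs1 and v.gene == "SOCS1")
    )


def vaf_overlap_match(
    medians_m: Mapping[str, float], medians_wt: Mapping[str, float]
) -> tuple[list[str], list[str]]:
    """Match SOCS1m and SOCS1wt samples on overlapping median VAF.

    The overlap window runs from the lowest median VAF in the mutated
    cluster to the highest median VAF in the wild-type cluster, endpoints
    inclusive; samples of either cluster inside the window are returned.
    An empty window (clusters with disjoint, reversed ranges) yields empty
    matched subsets with a warning.
    """
    if not medians_m or not medians_wt:
        raise ValueError("both clusters need at least one defined median VAF")
    lo = min(medians_m.values())
    hi = max(medians_wt.values())
    if lo > hi:
        warnings.warn("median-VAF ranges do not overlap; matched subsets are empty",
                      stacklevel=2)
        return [], []
    matched_m = sorted(s for s, v in medians_m.items() if lo <= v <= hi)
    matched_wt = sorted(s for s, v in medians_wt.items() if lo <= v <= hi)
    return matched_m, matched_wt


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    test: Literal["auto", "wilcoxon_rank_sum", "kruskal_wallis"] = "auto",
) -> ComparisonResult:
    """Rank-based comparison of 2 (Wilcoxon rank-sum) or 3+ (Kruskal-Wallis)
    groups, two-sided, ties mid-ranked.

    The rank-sum statistic reported is the Mann-Whitney U of the first
    group; it is computed exactly for groups of up to 25 observations
    without ties and by normal approximation (tie-corrected) otherwise.
    """
    names = tuple(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    if test == "auto":
        test = "wilcoxon_rank_sum" if len(groups) == 2 else "kruskal_wallis"
    if test == "wilcoxon_rank_sum":
        if len(groups) != 2:
            raise ValueError("wilcoxon_rank_sum compares exactly two groups")
        x, y = groups
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= EXACT_TEST_MAX_N and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if len(groups) < 3:
            raise ValueError("kruskal_wallis compares three or more groups")
        res = stats.kruskal(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        test=test, statistic=stat, p_value=min(p, 1.0),
        groups=names, n=tuple(len(g) for g in groups),
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Spearman rank correlation with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 complete pairs")
    rho, p = stats.spearmanr(x, y)
    return ComparisonResult(
        test="spearman", statistic=float(rho), p_value=float(min(p, 1.0)),
        groups=("x", "y"), n=(len(x), len(x)),
    )
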
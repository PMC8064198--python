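"""Genotype-sTIL and clinical-sTIL association statistics.

Because the sTIL percentage is not normally distributed, all group
comparisons of sTIL use rank tests: the tie-corrected Kruskal-Wallis H
across genotypes, with unadjusted pairwise Mann-Whitney post-hoc
comparisons. Genotype-by-clinical contingency tables use the chi-square
independence test. The per-SNP sweep reports unadjusted p-values against
a 0.05 threshold by default (an optional Benjamini-Hochberg adjustment is
available but off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    name: str
    n: int
    mean: float
    ci_lower: float
    ci_upper: float


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis H test result with group summaries.

    The confidence interval reported per group is the normal-approximation
    CI of the mean (mean +/- 1.96 sd/sqrt(n))."""

    H: float
    df: int
    p: float
    tie_correction_factor: float
    groups: list[GroupSummary] = field(default_factory=list)


def _tie_correction(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    denom = n**3 - n
    if denom == 0:
        return 1.0
    return 1.0 - float(((counts**3 - counts).sum()) / denom)


def _summaries(groups: Sequence[np.ndarray], names: Sequence[str]) -> list[GroupSummary]:
    out = []
    for name, g in zip(names, groups):
        m = float(np.mean(g))
        half = 1.96 * float(np.std(g, ddof=1)) / np.sqrt(len(g)) if len(g) > 1 else 0.0
        out.append(GroupSummary(name=name, n=len(g), mean=m, ci_lower=m - half, ci_upper=m + half))
    return out


def kruskal_wallis(groups: Sequence[np.ndarray], names: Optional[Sequence[str]] = None) -> KWResult:
    """Tie-corrected Kruskal-Wallis H across k groups.

    When every pooled value is identical the correction denominator is
    zero and the test is vacuous: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    names = list(names) if names is not None else [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    tie = _tie_correction(pooled)
    if np.all(pooled == pooled[0]):
        return KWResult(H=0.0, df=len(groups) - 1, p=1.0, tie_correction_factor=0.0,
                        groups=_summaries(groups, names))
    H, p = stats.kruskal(*groups)
    return KWResult(
        H=float(H),
        df=len(groups) - 1,
        p=float(p),
        tie_correction_factor=tie,
        groups=_summaries(groups, names),
    )


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    U: float
    p: float
    significant: bool
    testable: bool = True


def pairwise_posthoc(
    groups: Sequence[np.ndarray],
    names: Optional[Sequence[str]] = None,
    alpha: float = 0.01,
    method: str = "mannwhitney",
) -> list[PairwiseResult]:
    """All unordered pairwise two-group rank comparisons, unadjusted.

    The default is the Mann-Whitney U test with normal approximation and
    tie correction; ``method="dunn"`` uses Dunn's z statistic on the
    pooled ranks instead. Pairs containing a group of size < 2 are
    flagged untestable.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    names = list(names) if names is not None else [f"group{i}" for i in range(len(groups))]
    if method == "dunn":
        return _dunn_posthoc(groups, names, alpha)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            if len(a) < 2 or len(b) < 2:
                out.append(PairwiseResult(names[i], names[j], float("nan"), float("nan"), False, False))
                continue
            if np.all(np.concatenate([a, b]) == a[0]):
                out.append(PairwiseResult(names[i], names[j], len(a) * len(b) / 2.0, 1.0, False))
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                     use_continuity=False)
            out.append(
                PairwiseResult(names[i], names[j], float(res.statistic), float(res.pvalue),
                               bool(res.pvalue < alpha))
            )
    return out


def _dunn_posthoc(groups: list[np.ndarray], names: list[str], alpha: float) -> list[PairwiseResult]:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    tie = ((lambda c: (c**3 - c).sum())(np.unique(pooled, return_counts=True)[1])) / (12.0 * (N - 1))
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = rank_groups[i], rank_groups[j]
            if len(a) < 2 or len(b) < 2:
                out.append(PairwiseResult(names[i], names[j], float("nan"), float("nan"), False, False))
                continue
            se = np.sqrt((N * (N + 1) / 12.0 - tie) * (1.0 / len(a) + 1.0 / len(b)))
            z = (a.mean() - b.mean()) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            out.append(PairwiseResult(names[i], names[j], float(z), float(p), bool(p < alpha)))
    return out


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table
    (no continuity correction). Expected counts below 5 are logged."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        log.warning("chi-square: %d expected cell(s) below 5", int((expected < 5).sum()))
    return float(stat), int(df), float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class SNPSweepResult:
    table: pd.DataFrame  # genotype-level rows in the layout of a per-SNP report
    results: dict[str, KWResult]
    skipped: dict[str, str]
    significant: list[str]


def snp_sweep(
    cohort: pd.DataFrame,
    snp_columns: Sequence[str],
    stil_column: str = "stil",
    alpha: float = 0.05,
    adjust: bool = False,
) -> SNPSweepResult:
    """Kruskal-Wallis sweep of sTIL across genotypes for every SNP.

    Complete-case per SNP: missing genotypes are dropped for that SNP only
    and reported. SNPs with fewer than two observed genotype classes are
    skipped with a reason. No multiplicity correction by default;
    ``adjust=True`` adds Benjamini-Hochberg-adjusted p-values.
    """
    rows = []
    results: dict[str, KWResult] = {}
    skipped: dict[str, str] = {}
    for snp in snp_columns:
        sub = cohort[[snp, stil_column]].dropna()
        n_missing = len(cohort) - len(sub)
        classes = sorted(sub[snp].unique())
        if len(classes) < 2:
            skipped[snp] = f"only {len(classes)} observed genotype class(es)"
            continue
        groups = [sub.loc[sub[snp] == g, stil_column].to_numpy() for g in classes]
        res = kruskal_wallis(groups, names=classes)
        results[snp] = res
        for summ in res.groups:
            rows.append(
                {
                    "snp": snp,
                    "genotype": summ.name,
                    "n": summ.n,
                    "percent": round(100.0 * summ.n / len(cohort), 1),
                    "stil_mean": summ.mean,
                    "ci_lower": summ.ci_lower,
                    "ci_upper": summ.ci_upper,
                    "H": res.H,
                    "p": res.p,
                }
            )
        if n_missing:
            rows.append(
                {
                    "snp": snp,
                    "genotype": "missing",
                    "n": n_missing,
                    "percent": round(100.0 * n_missing / len(cohort), 1),
                    "stil_mean": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "H": res.H,
                    "p": res.p,
                }
            )
    table = pd.DataFrame(rows)
    if adjust and results:
        adj = benjamini_hochberg([results[s].p for s in results])
        adj_map = dict(zip(results, adj))
        table["p_adjusted"] = table["snp"].map(adj_map)
    significant = [s for s, r in results.items() if r.p < alpha]
    return SNPSweepResult(table=table, results=results, skipped=skipped, significant=significant)
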
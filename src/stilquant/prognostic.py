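"""Combined prognostic model: train/test split, Cox risk scores, ROC/AUC
at a fixed horizon, and DeLong's test for paired AUC comparison.

The outcome for the ROC analysis is the DFS event status by a fixed
horizon (default three years); patients censored before the horizon
carry no outcome information and are excluded (their count is
reported). The combined model (clinical + sTIL + SNP dummies) and the
clinical-only model are fitted on the training split and compared on
the held-out test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import CoxFit, cox_fit, design_matrix


def split_cohort(
    cohort: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seeded split; floor(n * fraction) rows train.

    A part without any DFS event cannot support the downstream models, so
    it raises with a suggestion to reseed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cohort))
    n_train = int(np.floor(len(cohort) * train_fraction))
    train = cohort.iloc[perm[:n_train]]
    test = cohort.iloc[perm[n_train:]]
    if train["dfs_event"].sum() == 0 or test["dfs_event"].sum() == 0:
        raise ValueError("a split part has zero events; try another seed")
    return train, test


def risk_score(fit: CoxFit, records: pd.DataFrame) -> pd.Series:
    """Linear predictor sum(coef * covariate); higher = higher hazard.

    Rows missing any model covariate are excluded (count available from
    the length difference)."""
    missing_cols = [c for c in fit.covariates if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records lack model covariates: {missing_cols}")
    X = records[fit.covariates].dropna()
    return pd.Series(X.to_numpy(dtype=float) @ fit.coef, index=X.index, name="risk_score")


def horizon_outcome(
    time: np.ndarray, event: np.ndarray, horizon_days: float
) -> tuple[np.ndarray, np.ndarray]:
    """Binary DFS-event-by-horizon outcome and the usable-record mask.

    Event before/at the horizon -> 1; followed beyond the horizon without
    an event -> 0; censored before the horizon -> excluded.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    usable = (time > horizon_days) | (event == 1) & (time <= horizon_days)
    outcome = ((event == 1) & (time <= horizon_days)).astype(int)
    return outcome[usable], usable


def roc_auc(scores: np.ndarray, outcomes: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Tie-adjusted AUC (Mann-Whitney U / (n1 n0), ties count one half)
    with the ROC coordinates."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes are required")
    ranks = stats.rankdata(scores)
    auc = (ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [(scores[outcomes == 1] >= t).mean() for t in thresholds]
    fpr = [(scores[outcomes == 0] >= t).mean() for t in thresholds]
    coords = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return float(auc), coords


def _structural_components(scores: np.ndarray, outcomes: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, outcomes: np.ndarray
) -> tuple[float, float, float]:
    """DeLong's test for two paired AUCs.

    Returns (delta_auc = AUC_a - AUC_b, variance of the difference,
    two-sided p). Structural-component covariance estimate; a degenerate
    variance (e.g. identical score vectors) yields p = 1.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    v10a, v01a, auc_a = _structural_components(np.asarray(scores_a, float), outcomes)
    v10b, v01b, auc_b = _structural_components(np.asarray(scores_b, float), outcomes)
    m, n = len(v10a), len(v01a)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 records in each outcome class")
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        return 0.0 if delta == 0 else float(delta), max(var, 0.0), 1.0
    z = delta / np.sqrt(var)
    return float(delta), float(var), float(2.0 * stats.norm.sf(abs(z)))


def auc_variance(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """DeLong variance of a single AUC."""
    v10, v01, _ = _structural_components(np.asarray(scores, float), np.asarray(outcomes, int))
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


@dataclass
class ROCComparison:
    auc_combined: float
    auc_clinical: float
    delta_auc: float
    delong_p: float
    n_test: int
    n_excluded: int
    horizon_days: float
    roc_combined: pd.DataFrame = field(repr=False, default=None)
    roc_clinical: pd.DataFrame = field(repr=False, default=None)


DEFAULT_CLINICAL = ("age", "sex", "grade", "treatment", "bmi", "tea")


def compare_models(
    cohort: pd.DataFrame,
    clinical_covariates: Sequence[str] = DEFAULT_CLINICAL,
    extra_covariates: Sequence[str] = ("stil",),
    snp_columns: Sequence[str] = (),
    horizon_days: float = 1095.0,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> ROCComparison:
    """Fit the combined and clinical-only Cox models on the training split
    and compare their test-set AUCs for DFS-by-horizon with DeLong's test.

    SNP columns are expanded to reference-coded dummies (most common
    genotype as reference) before fitting.
    """
    working = cohort.copy()
    snp_dummy_cols: list[str] = []
    for snp in snp_columns:
        from .survival import genotype_coding

        ref = working[snp].value_counts().idxmax()
        dummies = genotype_coding(working[snp], model="reference", reference=ref)
        working = pd.concat([working, dummies], axis=1)
        snp_dummy_cols.extend(dummies.columns)

    clin = design_matrix(working, clinical_covariates)
    extra = working[list(extra_covariates)] if extra_covariates else None
    pieces = [working[["dfs_time", "dfs_event"]], clin]
    if extra is not None:
        pieces.append(extra)
    if snp_dummy_cols:
        pieces.append(working[snp_dummy_cols])
    model_df = pd.concat(pieces, axis=1).dropna()

    clinical_cols = list(clin.columns)
    full_cols = clinical_cols + (list(extra_covariates) if extra_covariates else []) + snp_dummy_cols

    train, test = split_cohort(model_df, train_fraction, seed)
    fit_full = cox_fit(train, covariates=full_cols)
    fit_clin = cox_fit(train, covariates=clinical_cols)

    outcome, usable = horizon_outcome(
        test["dfs_time"].to_numpy(), test["dfs_event"].to_numpy(), horizon_days
    )
    test_usable = test.loc[usable]
    s_full = risk_score(fit_full, test_usable).to_numpy()
    s_clin = risk_score(fit_clin, test_usable).to_numpy()
    auc_full, roc_full = roc_auc(s_full, outcome)
    auc_clin, roc_clin = roc_auc(s_clin, outcome)
    delta, _var, p = delong_test(s_full, s_clin, outcome)
    return ROCComparison(
        auc_combined=auc_full,
        auc_clinical=auc_clin,
        delta_auc=delta,
        delong_p=p,
        n_test=int(usable.sum()),
        n_excluded=int(len(test) - usable.sum()),
        horizon_days=horizon_days,
        roc_combined=roc_full,
        roc_clinical=roc_clin,
    )
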
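"""Disease-free survival construction, Kaplan-Meier/log-rank, and Cox
proportional-hazards fitting.

DFS runs from diagnosis to the earliest of recurrence or death (event)
or last follow-up (censored); a same-day event and censoring resolves to
the event. The Cox model maximizes the partial likelihood by
Newton-Raphson with step-halving, Efron's correction for tied event
times by default (Breslow available for cross-checks), standard errors
from the inverse observed information, and Wald tests per coefficient.
Genotypes enter either through reference coding (two indicator columns
against a reference homozygote) or a dominant coding that pools the
declared combined class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


# ---------------------------------------------------------------------------
# DFS construction


def derive_dfs(
    diagnosis,
    recurrence=None,
    death=None,
    last_followup=None,
) -> tuple[float, int]:
    """(time in days, event indicator) from the landmark dates.

    Accepts datetimes or plain day numbers. The clock stops at the
    earliest of recurrence, death or last follow-up; the event fires when
    that earliest landmark is recurrence or death (ties with censoring
    resolve to the event).
    """

    def days(x) -> Optional[float]:
        if x is None:
            return None
        if hasattr(x, "toordinal"):
            return float(x.toordinal() - diagnosis.toordinal())
        return float(x - diagnosis)

    candidates = [(days(recurrence), 1), (days(death), 1), (days(last_followup), 0)]
    candidates = [(t, e) for t, e in candidates if t is not None]
    if not candidates:
        raise ValueError("at least one follow-up landmark is required")
    if any(t < 0 for t, _ in candidates):
        raise ValueError("event date precedes diagnosis")
    t_min = min(t for t, _ in candidates)
    event = int(any(e == 1 for t, e in candidates if t == t_min))
    return t_min, event


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KMEstimate:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each time
    median: Optional[float]  # None when S never reaches 0.5


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> KMEstimate:
    """Product-limit estimate and the median survival time (smallest t
    with S(t) <= 0.5; None when the curve never reaches 0.5)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("at least one record is required")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(times=times, survival=surv, median=median)


def log_rank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, int, float]:
    """Log-rank test across 2+ groups (O-E with hypergeometric variance)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson, Efron/Breslow ties)


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class CoxFit:
    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    ties: str = "efron"
    dropped: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> np.ndarray:
        """(k, 2) array of 95% CI bounds for the hazard ratios."""
        return np.stack(
            [np.exp(self.coef - 1.96 * self.se), np.exp(self.coef + 1.96 * self.se)], axis=1
        )

    @property
    def p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_lower": self.ci[:, 0],
                "hr_ci_upper": self.ci[:, 1],
                "p": self.p,
            },
            index=self.covariates,
        )


def cox_partial_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score and observed information.

    Efron's or Breslow's handling of tied event times.
    """
    order = np.argsort(-time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order]
    n, k = X.shape
    eta = X @ beta
    w = np.exp(eta)

    loglik = 0.0
    score = np.zeros(k)
    info = np.zeros((k, k))

    s0 = 0.0
    s1 = np.zeros(k)
    s2 = np.zeros((k, k))
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            s0 += w[j]
            s1 += w[j] * X[j]
            s2 += w[j] * np.outer(X[j], X[j])
            j += 1
        died = [idx for idx in range(i, j) if event[idx] == 1]
        d = len(died)
        if d > 0:
            xd = X[died]
            wd = w[died]
            loglik += eta[died].sum()
            d0 = wd.sum()
            d1 = (wd[:, None] * xd).sum(axis=0)
            d2 = np.einsum("i,ij,ik->jk", wd, xd, xd)
            score += xd.sum(axis=0)
            for ell in range(d):
                frac = ell / d if ties == "efron" else 0.0
                z0 = s0 - frac * d0
                z1 = s1 - frac * d1
                z2 = s2 - frac * d2
                loglik -= np.log(z0)
                score -= z1 / z0
                info += z2 / z0 - np.outer(z1, z1) / z0**2
        i = j
    return loglik, score, info


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "dfs_time",
    event_col: str = "dfs_event",
    covariates: Optional[Sequence[str]] = None,
    ties: str = "efron",
    max_iter: int = 100,
    score_tol: float = 1e-6,
    step_tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox model on complete cases of the requested covariates.

    Constant covariates are dropped with a warning entry; non-convergence
    within ``max_iter`` Newton steps raises :class:`ConvergenceError`
    carrying the log-likelihood trace.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    covariates = list(covariates) if covariates is not None else [
        c for c in data.columns if c not in (duration_col, event_col)
    ]
    sub = data[[duration_col, event_col] + covariates].dropna()
    X = sub[covariates].to_numpy(dtype=float)
    time = sub[duration_col].to_numpy(dtype=float)
    event = sub[event_col].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("at least one event is required")

    dropped = [c for c, v in zip(covariates, X.var(axis=0)) if v == 0.0]
    keep = [i for i, c in enumerate(covariates) if c not in dropped]
    covariates = [covariates[i] for i in keep]
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no usable (non-constant) covariates")
    # standardize for numerical stability; coefficients are mapped back
    X = X - X.mean(axis=0)
    x_scale = X.std(axis=0)
    X = X / x_scale

    beta = np.zeros(X.shape[1])
    loglik, score, info = cox_partial_loglik(beta, X, time, event, ties)
    trace = [loglik]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}", trace) from exc
        big = np.abs(step).max()
        if big > 10.0:  # cap the proposal; keeps exp(eta) finite pre-halving
            step = step * (10.0 / big)
        # step-halving keeps the partial likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_loglik, new_score, new_info = cox_partial_loglik(new_beta, X, time, event, ties)
            if np.isfinite(new_loglik) and new_loglik >= loglik - 1e-12:
                break
            scale /= 2.0
        beta, loglik, score, info = new_beta, new_loglik, new_score, new_info
        trace.append(loglik)
        if np.abs(beta).max() > 20.0:  # standardized scale
            raise ConvergenceError(
                "coefficients diverging (possible complete separation)", trace
            )
        if np.abs(score).max() < score_tol or np.abs(scale * step).max() < step_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} Newton iterations (max |score| = {np.abs(score).max():.3g})",
            trace,
        )
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxFit(
        covariates=covariates,
        coef=beta / x_scale,
        se=se / x_scale,
        loglik=loglik,
        n=len(sub),
        n_events=int(event.sum()),
        n_iter=it,
        converged=converged,
        ties=ties,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# genotype codings and model wrappers


def genotype_coding(
    genotypes: pd.Series,
    model: str = "reference",
    reference: Optional[str] = None,
    combined: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Dummy covariates for a genotype column.

    ``reference`` coding: one indicator per non-reference genotype class.
    ``dominant`` coding: a single indicator for membership of the declared
    ``combined`` class set (e.g. pooling one homozygote with the
    heterozygote against the rest). Missing genotypes stay missing.
    """
    observed = sorted(x for x in genotypes.dropna().unique())
    if len(observed) < 2:
        raise ValueError("genotype column has fewer than 2 observed classes")
    if len(observed) > 3:
        raise ValueError("more than 3 genotype classes observed")
    name = genotypes.name or "genotype"
    if model == "reference":
        if reference is None:
            raise ValueError("reference class required for reference coding")
        if reference not in observed:
            raise ValueError(f"reference class {reference!r} not observed")
        out = {}
        for g in observed:
            if g == reference:
                continue
            col = genotypes.map(lambda x: np.nan if pd.isna(x) else float(x == g))
            out[f"{name}[{g}]"] = col
        return pd.DataFrame(out)
    if model == "dominant":
        if not combined:
            raise ValueError("dominant coding requires the combined class set")
        unknown = set(combined) - set(observed)
        if unknown:
            raise ValueError(f"combined classes not observed: {sorted(unknown)}")
        col = genotypes.map(lambda x: np.nan if pd.isna(x) else float(x in set(combined)))
        return pd.DataFrame({f"{name}[{'+'.join(combined)}]": col})
    raise ValueError("model must be 'reference' or 'dominant'")


DEFAULT_ADJUSTMENT = ("stil", "age", "sex", "treatment", "bmi")


def design_matrix(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: categorical columns become treatment-coded
    dummies (first class alphabetically is the reference)."""
    cols = []
    for c in covariates:
        s = cohort[c]
        if s.dtype.kind in "biufc":
            cols.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            dummies[s.isna()] = np.nan
            cols.append(dummies)
    return pd.concat(cols, axis=1)


def adjusted_snp_analysis(
    cohort: pd.DataFrame,
    snp: str,
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
    model: str = "reference",
    reference: Optional[str] = None,
    combined: Optional[Sequence[str]] = None,
    ties: str = "efron",
) -> CoxFit:
    """Multivariable Cox fit of one SNP with the adjustment covariates.

    With an empty adjustment set this is the univariable genotype fit.
    Complete-case: patients missing any analyzed predictor are excluded.
    """
    if reference is None and model == "reference":
        reference = sorted(cohort[snp].dropna().unique())[0]
    geno = genotype_coding(cohort[snp], model=model, reference=reference, combined=combined)
    parts = [cohort[["dfs_time", "dfs_event"]], geno]
    if adjustment:
        parts.append(design_matrix(cohort, adjustment))
    df = pd.concat(parts, axis=1)
    n_cov = df.shape[1] - 2
    n_complete = len(df.dropna())
    if n_complete < 10 * n_cov:
        import logging

        logging.getLogger(__name__).warning(
            "%s: only %d complete cases for %d covariates", snp, n_complete, n_cov
        )
    return cox_fit(df, covariates=[c for c in df.columns if c not in ("dfs_time", "dfs_event")],
                   ties=ties)


@dataclass
class StratumFit:
    stratum: str
    fit: Optional[CoxFit]
    reason: Optional[str] = None


def stratified_univariable(
    cohort: pd.DataFrame,
    snp: str,
    stratum_col: str = "treatment",
    model: str = "reference",
    reference: Optional[str] = None,
    combined: Optional[Sequence[str]] = None,
) -> list[StratumFit]:
    """Independent univariable genotype fits within each stratum.

    Strata without events or with a single observed genotype class are
    reported untestable; the remaining strata are unaffected.
    """
    out = []
    for stratum, sub in cohort.groupby(stratum_col):
        if sub["dfs_event"].sum() < 1:
            out.append(StratumFit(str(stratum), None, "no events"))
            continue
        try:
            fit = adjusted_snp_analysis(
                sub, snp, adjustment=(), model=model, reference=reference, combined=combined
            )
        except (ValueError, ConvergenceError) as err:
            out.append(StratumFit(str(stratum), None, str(err)))
            continue
        out.append(StratumFit(str(stratum), fit))
    return out
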
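"""Outcome statistics for imaging clusters: odds ratios, logistic
regression, chi-square proportion tests, Kaplan-Meier / log-rank, and
Cox proportional hazards.

Conventions: odds-ratio confidence intervals are Wald on the log scale;
zero cells take the Haldane-Anscombe +0.5 correction (tagged in the
result); Cox ties are handled by the Efron approximation (monthly
follow-up granularity produces ties); strata without events lead to
monotone partial likelihood and are flagged, not silently estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
import statsmodels.api as sm

Z_95 = 1.96  # conventional Wald coefficient for 95% intervals


class DegenerateOutcomeError(ValueError):
    """Outcome has no variation; the model cannot be fit."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed & event, b = exposed & no event,
    c = unexposed & event, d = unexposed & no event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table is empty")


@dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str  # "2x2" | "2x2+0.5" | "logistic" | "logistic:separation"
    term: str = ""


def odds_ratio_2x2(t: ContingencyTable2x2) -> ORResult:
    """Closed-form odds ratio with Wald 95% CI on the log scale.

    Any zero cell triggers the Haldane-Anscombe +0.5 continuity
    correction, recorded in the method tag.  A row or column that is
    entirely zero leaves the OR undefined and raises ``ValueError``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a zero row or column leaves the odds ratio undefined")
    method = "2x2"
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "2x2+0.5"
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return ORResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z_95 * se)),
        ci_high=float(np.exp(log_or + Z_95 * se)),
        p_value=float(p),
        method=method,
    )


def logistic_fit(
    cohort: pd.DataFrame,
    outcome: str = "pcr",
    covariates: list[str] | None = None,
    mode: str = "univariate",
) -> list[ORResult]:
    """Maximum-likelihood logistic regression for a binary outcome.

    ``mode='univariate'`` fits one single-covariate model per covariate;
    ``'multivariate'`` fits one joint model.  For a single binary
    covariate the fitted OR equals the closed-form 2x2 OR.  Complete or
    quasi-complete separation is flagged in the method tag rather than
    silently reported.
    """
    if covariates is None or not covariates:
        raise ValueError("covariates must be a non-empty list")
    y = cohort[outcome].astype(float)
    if y.nunique() < 2:
        raise DegenerateOutcomeError(f"outcome {outcome!r} is constant")

    def _fit(cols: list[str]) -> list[ORResult]:
        x = sm.add_constant(cohort[cols].astype(float), has_constant="add")
        flagged = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(y, x).fit(disp=0, maxiter=200)
            except Exception:
                # perfect separation aborts Newton; quasi-Newton converges
                # to a finite (huge-beta) optimum we can flag
                flagged = True
                res = sm.Logit(y, x).fit(disp=0, method="bfgs", maxiter=500)
            flagged = flagged or any(
                "separation" in str(w.message).lower() or "converge" in str(w.message).lower()
                for w in caught
            )
        if not flagged and hasattr(res, "mle_retvals"):
            flagged = not res.mle_retvals.get("converged", True)
        if not flagged:
            flagged = bool(np.any(np.abs(res.params[cols]) > 15))
        out = []
        ci = res.conf_int()
        for col in cols:
            beta = float(res.params[col])
            out.append(
                ORResult(
                    odds_ratio=float(np.exp(min(beta, 700.0))),
                    ci_low=float(np.exp(np.clip(ci.loc[col, 0], -700.0, 700.0))),
                    ci_high=float(np.exp(min(ci.loc[col, 1], 700.0))),
                    p_value=float(res.pvalues[col]),
                    method="logistic:separation" if flagged else "logistic",
                    term=col,
                )
            )
        return out

    if mode == "univariate":
        results: list[ORResult] = []
        for cov in covariates:
            results.extend(_fit([cov]))
        return results
    if mode == "multivariate":
        return _fit(list(covariates))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def proportions_test(
    cohort: pd.DataFrame, group: str = "cluster", trait: str = "pcr"
) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on the group x trait table."""
    table = pd.crosstab(cohort[group], cohort[trait])
    if (table.sum(axis=1) == 0).any() or table.shape[0] < 2:
        raise ValueError("need at least two non-empty groups")
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ChiSquareResult(
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        observed=table.to_numpy(),
        expected=expected,
    )


@dataclass
class SurvivalFit:
    curves: dict  # group -> KaplanMeierFitter
    logrank_statistic: float | None
    logrank_p: float | None
    n_events: int
    note: str = ""


def km_logrank(
    cohort: pd.DataFrame,
    group: str = "cluster",
    time_col: str = "dfs_months",
    event_col: str = "event",
) -> SurvivalFit:
    """Per-group Kaplan-Meier product-limit curves and the log-rank test.

    With zero events everywhere the survival functions are identically 1
    and the log-rank statistic is undefined; an explicit "no events"
    result is returned instead of a spurious p-value.
    """
    curves: dict = {}
    for g, sub in cohort.groupby(group):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no subjects")
        km = KaplanMeierFitter(label=str(g))
        km.fit(sub[time_col], event_observed=sub[event_col])
        curves[g] = km
    n_events = int(cohort[event_col].sum())
    if n_events == 0:
        return SurvivalFit(
            curves=curves, logrank_statistic=None, logrank_p=None,
            n_events=0, note="no events: log-rank undefined",
        )
    res = multivariate_logrank_test(
        cohort[time_col], cohort[group], cohort[event_col]
    )
    return SurvivalFit(
        curves=curves,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        n_events=n_events,
    )


@dataclass
class HRResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    term: str
    flagged: bool = False  # monotone likelihood / no-event stratum


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    mode: str = "univariate",
    time_col: str = "dfs_months",
    event_col: str = "event",
) -> list[HRResult]:
    """Cox proportional-hazards fit (Efron ties), hazard ratios with 95% CI.

    A binary covariate whose one stratum has no events gives a monotone
    partial likelihood; such terms are flagged (absurdly wide CI) rather
    than suppressed.
    """
    if int(cohort[event_col].sum()) == 0:
        raise DegenerateOutcomeError("zero events: Cox model undefined")

    def _fit(cols: list[str]) -> list[HRResult]:
        df = cohort[[time_col, event_col] + cols].astype(float)
        forced_flag = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph = CoxPHFitter()
                cph.fit(df, duration_col=time_col, event_col=event_col)
            except Exception:
                # monotone likelihood (e.g. a no-event stratum): stabilize
                # with a small ridge penalty and flag the result
                forced_flag = True
                cph = CoxPHFitter(penalizer=0.1)
                cph.fit(df, duration_col=time_col, event_col=event_col)
        out = []
        for col in cols:
            beta = float(cph.params_[col])
            se = float(cph.standard_errors_[col])
            flagged = forced_flag or abs(beta) > 15 or se > 10
            # clip exponents: monotone-likelihood fits produce huge betas/SEs
            out.append(
                HRResult(
                    hazard_ratio=float(np.exp(min(beta, 700.0))),
                    ci_low=float(np.exp(np.clip(beta - Z_95 * se, -700.0, 700.0))),
                    ci_high=float(np.exp(min(beta + Z_95 * se, 700.0))),
                    p_value=float(cph.summary.loc[col, "p"]),
                    term=col,
                    flagged=flagged,
                )
            )
        return out

    if mode == "univariate":
        results: list[HRResult] = []
        for cov in covariates:
            results.extend(_fit([cov]))
        return results
    if mode == "multivariate":
        return _fit(list(covariates))
    raise ValueError(f"unknown mode {mode!r}")
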
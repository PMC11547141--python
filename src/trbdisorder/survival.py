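"""Median-split survival stratification: Kaplan-Meier, log-rank, Cox.

Cases carrying both a case-level parameter value and a clinical record are
ranked by the parameter and split at the 50th percentile (lower group =
first ceil(n/2) cases; ties broken by case id for determinism).  Group
survival is summarised by the Kaplan-Meier product-limit estimator and
compared with the two-group log-rank test; multivariate Cox proportional-
hazards models (Efron tie handling) admit only covariates passing a
univariate screen at p <= 0.1.

Estimation is delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .reference_io import ClinicalRecord, clinical_frame
from .scoring import CaseScore

logger = logging.getLogger(__name__)

DEFAULT_GATE_P = 0.1

#: reported alongside every stratified comparison
MULTIPLE_TESTING_CAVEAT = (
    "p-values are two-sided and uncorrected for multiple testing across parameters"
)


class SurvivalAnalysisError(ValueError):
    """Raised for degenerate inputs (too few cases, non-convergence...)."""


@dataclass
class StratifiedCohort:
    """A two-group split of cases at the median of one parameter."""

    parameter: str
    lower_group: list[str]
    upper_group: list[str]
    threshold: float
    excluded_without_score: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.lower_group) + len(self.upper_group)


@dataclass
class KMCurve:
    """A product-limit survival curve; ``median_os`` is None when S(t) never
    reaches 0.5."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_os: Optional[float]


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    df: int = 1
    defined: bool = True


@dataclass(frozen=True)
class CovariateEffect:
    covariate: str
    coefficient: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass
class CoxResult:
    effects: dict[str, CovariateEffect]
    dropped: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0


def median_split(case_scores: Iterable[CaseScore],
                 clinical: Iterable[ClinicalRecord],
                 parameter: str) -> StratifiedCohort:
    """Split joined cases into lower/upper 50th-percentile groups.

    Cases are sorted ascending by score (ties by case id); the lower group is
    the first ceil(n/2) cases, so n = 64 gives 32/32 and n = 53 gives 27/26.
    Clinical cases with no score (e.g. no recovered TRB reads) are excluded
    and recorded.
    """
    scores = {s.case_id: s.value for s in case_scores if s.parameter == parameter}
    clinical_ids = {r.case_id for r in clinical}
    joined = sorted(
        ((scores[cid], cid) for cid in clinical_ids if cid in scores),
        key=lambda t: (t[0], t[1]),
    )
    if len(joined) < 2:
        raise SurvivalAnalysisError(
            f"median split needs >= 2 joined cases, got {len(joined)}"
        )
    excluded = sorted(clinical_ids - set(scores))
    if excluded:
        logger.info("excluding %d clinical cases without a %s score",
                    len(excluded), parameter)
    n_lower = math.ceil(len(joined) / 2)
    return StratifiedCohort(
        parameter=parameter,
        lower_group=[cid for _, cid in joined[:n_lower]],
        upper_group=[cid for _, cid in joined[n_lower:]],
        threshold=float(np.median([v for v, _ in joined])),
        excluded_without_score=excluded,
    )


def km_estimate(durations: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    ``median_os`` is the smallest time with S(t) <= 0.5, or None if the curve
    never reaches 0.5.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(durations) == 0:
        raise SurvivalAnalysisError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times, fill_value=0).to_numpy()
    median = kmf.median_survival_time_
    return KMCurve(
        times=times, survival=survival, at_risk=at_risk,
        median_os=None if np.isinf(median) else float(median),
    )


def logrank(durations_a: Sequence[float], events_a: Sequence[int],
            durations_b: Sequence[float], events_b: Sequence[int]) -> LogRankResult:
    """Two-group log-rank test (chi-square, df = 1, two-sided p)."""
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if len(durations_a) == 0 or len(durations_b) == 0:
        raise SurvivalAnalysisError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        logger.warning("log-rank undefined: no events in either group")
        return LogRankResult(chi_square=float("nan"), p_value=float("nan"),
                             defined=False)
    result = logrank_test(durations_a, durations_b,
                          event_observed_A=events_a, event_observed_B=events_b)
    return LogRankResult(chi_square=float(result.test_statistic),
                         p_value=float(result.p_value))


def _survival_frame(clinical: Iterable[ClinicalRecord],
                    covariates: Sequence[str]) -> pd.DataFrame:
    df = clinical_frame(clinical)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise SurvivalAnalysisError(f"missing covariates {missing}")
    return df[["case_id", "os_months", "event", *covariates]]


def cox_fit(clinical: Iterable[ClinicalRecord],
            covariates: Sequence[str]) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties), Wald 95% CIs and p-values.

    Covariates with zero variance cannot be estimated; they are dropped with
    a warning rather than fit.  Non-convergence raises
    :class:`SurvivalAnalysisError`.
    """
    covariates = list(covariates)
    if not covariates:
        raise SurvivalAnalysisError("no covariates requested")
    df = _survival_frame(clinical, covariates)
    if df["event"].sum() < 1:
        raise SurvivalAnalysisError("Cox fit needs at least one event")
    usable, dropped = [], []
    for cov in covariates:
        if df[cov].nunique() < 2:
            logger.warning("dropping constant covariate %r from Cox model", cov)
            dropped.append(cov)
        else:
            usable.append(cov)
    if not usable:
        raise SurvivalAnalysisError("no non-constant covariates to fit")
    cph = CoxPHFitter()
    try:
        cph.fit(df[["os_months", "event", *usable]],
                duration_col="os_months", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise SurvivalAnalysisError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    effects = {
        cov: CovariateEffect(
            covariate=cov,
            coefficient=float(summary.loc[cov, "coef"]),
            hazard_ratio=float(summary.loc[cov, "exp(coef)"]),
            ci_lower=float(summary.loc[cov, "exp(coef) lower 95%"]),
            ci_upper=float(summary.loc[cov, "exp(coef) upper 95%"]),
            p_value=float(summary.loc[cov, "p"]),
        )
        for cov in usable
    }
    return CoxResult(effects=effects, dropped=dropped,
                     n=len(df), n_events=int(df["event"].sum()))


def univariate_gate(clinical: Iterable[ClinicalRecord],
                    candidates: Sequence[str],
                    gate_p: float = DEFAULT_GATE_P) -> list[str]:
    """Admit covariates whose single-covariate Cox p-value is <= ``gate_p``."""
    records = list(clinical)
    admitted = []
    for cov in candidates:
        try:
            result = cox_fit(records, [cov])
        except SurvivalAnalysisError as exc:
            logger.warning("gate: skipping %r (%s)", cov, exc)
            continue
        if result.effects[cov].p_value <= gate_p:
            admitted.append(cov)
    return admitted


@dataclass
class StratificationReport:
    """Summary of one parameter's median-split survival comparison."""

    parameter: str
    n_lower: int
    n_upper: int
    threshold: float
    median_os_lower: Optional[float]
    median_os_upper: Optional[float]
    chi_square: float
    p_value: float
    lower_curve: KMCurve
    upper_curve: KMCurve
    caveat: str = MULTIPLE_TESTING_CAVEAT


def stratify_and_test(case_scores: Iterable[CaseScore],
                      clinical: Iterable[ClinicalRecord],
                      parameter: str) -> StratificationReport:
    """Median split + KM estimates + log-rank for one parameter."""
    clinical = list(clinical)
    cohort = median_split(case_scores, clinical, parameter)
    by_case = {r.case_id: r for r in clinical}

    def group_arrays(ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        recs = [by_case[cid] for cid in ids]
        return (np.array([r.os_months for r in recs]),
                np.array([r.event for r in recs]))

    t_lo, e_lo = group_arrays(cohort.lower_group)
    t_up, e_up = group_arrays(cohort.upper_group)
    lower_curve = km_estimate(t_lo, e_lo)
    upper_curve = km_estimate(t_up, e_up)
    lr = logrank(t_lo, e_lo, t_up, e_up)
    return StratificationReport(
        parameter=parameter,
        n_lower=len(cohort.lower_group), n_upper=len(cohort.upper_group),
        threshold=cohort.threshold,
        median_os_lower=lower_curve.median_os,
        median_os_upper=upper_curve.median_os,
        chi_square=lr.chi_square, p_value=lr.p_value,
        lower_curve=lower_curve, upper_curve=upper_curve,
    )


def report_frame(reports: Iterable[StratificationReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "parameter": r.parameter,
            "n_lower": r.n_lower, "n_upper": r.n_upper,
            "threshold": r.threshold,
            "median_os_lower": np.nan if r.median_os_lower is None else r.median_os_lower,
            "median_os_upper": np.nan if r.median_os_upper is None else r.median_os_upper,
            "chi_square": r.chi_square, "p_value": r.p_value,
            "caveat": r.caveat,
        })
    return pd.DataFrame(rows)


def cox_table(result: CoxResult) -> pd.DataFrame:
    """Cox summary with hazard ratios (Exp(B)) and Wald 95% CI bounds."""
    return pd.DataFrame(
        [(e.covariate, e.hazard_ratio, e.p_value, e.ci_lower, e.ci_upper)
         for e in result.effects.values()],
        columns=["covariate", "exp_b", "significance", "ci_lower_95", "ci_upper_95"],
    )


def plot_km(report: StratificationReport, path: str) -> None:
    """Save a two-arm KM plot for one stratified parameter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(report.lower_curve.times, report.lower_curve.survival, where="post",
            color="black", label=f"lower 50% (n={report.n_lower})")
    ax.step(report.upper_curve.times, report.upper_curve.survival, where="post",
            color="grey", label=f"upper 50% (n={report.n_upper})")
    ax.set_xlabel("overall survival (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{report.parameter} (log-rank p = {report.p_value:.3g})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
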
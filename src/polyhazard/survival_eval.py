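"""Age-specific risk evaluation of polygenic scores.

A standardized score enters a Cox model on the age axis together with sex
and three principal components.  Model comparisons against the APOE-only
baseline use the nested likelihood-ratio test (the anova() workflow for
coxph models); the proportional-hazards assumption is checked with the
scaled-Schoenfeld score test; risk stratification is visualized with
Kaplan–Meier curves for the 0–5 / 5–25 / 25–75 / 75–95 / 95–100% score
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from ._cox import SurvData, cox_fit, zph_test
from .gwas_scan import COVARIATE_COLUMNS
from .polygenic_scores import ScoreSet
from .synthetic_cohort import CohortData

__all__ = ["KM_GROUP_EDGES", "CoxEvalResult", "KMCurves", "evaluate_score",
           "lr_nested_test", "ph_assumption_test", "km_quantile_curves",
           "subgroup_e33"]

#: score-distribution percentiles bounding the five Kaplan–Meier groups
KM_GROUP_EDGES = (5, 25, 75, 95)
KM_GROUP_LABELS = ("0-5%", "5-25%", "25-75%", "75-95%", "95-100%")


@dataclass
class CoxEvalResult:
    """Cox fit of score term(s) + covariates on age-specific risk."""

    terms: str
    beta_score: float = np.nan
    se: float = np.nan
    p: float = np.nan
    beta_apoe: float = np.nan
    se_apoe: float = np.nan
    p_apoe: float = np.nan
    loglik_full: float = np.nan
    loglik_null: float = np.nan
    lr_stat: float = np.nan
    lr_df: int = 0
    lr_p: float = np.nan
    ph_test_p: dict = field(default_factory=dict)
    n: int = 0
    n_events: int = 0
    term_names: tuple = ()
    converged: bool = False


@dataclass
class KMCurves:
    """Kaplan–Meier step functions per score-quantile group."""

    curves: dict  # label -> DataFrame(age, survival)
    group_n: dict

    def survival_at(self, label: str, age: float) -> float:
        c = self.curves[label]
        idx = np.searchsorted(c["age"].to_numpy(), age, side="right") - 1
        return 1.0 if idx < 0 else float(c["survival"].iat[idx])


def _design(cohort: CohortData, scores: ScoreSet, terms: str):
    std = scores.standardized
    if std is None:
        raise ValueError("scores must be standardized before evaluation")
    term_map = {
        "apoe_only": ["score_apoe"],
        "score_only": ["score_snps"],
        "apoe_plus_score": ["score_apoe", "score_snps"],
        "combined_only": ["score_combined"],
    }
    if terms not in term_map:
        raise ValueError(f"unknown terms {terms!r}")
    names = term_map[terms]
    for c in names:
        if c not in std.columns:
            raise ValueError(f"score set lacks {c}")
    S = std[names].to_numpy(float)
    covs = cohort.phenotype[list(COVARIATE_COLUMNS)].to_numpy(float)
    X = np.column_stack([S, covs])
    ok = ~np.isnan(X).any(axis=1)
    if np.any(np.std(X[ok], axis=0) == 0):
        raise ValueError("degenerate (constant) term in the Cox design")
    rank = np.linalg.matrix_rank(X[ok] - X[ok].mean(axis=0))
    if rank < X.shape[1]:
        raise ValueError("collinear terms in the Cox design")
    return X, ok, tuple(names) + tuple(COVARIATE_COLUMNS)


def evaluate_score(cohort: CohortData, scores: ScoreSet, terms: str = "combined_only",
                   ph_test: bool = True) -> CoxEvalResult:
    """Cox fit of age-specific risk on the requested score term(s).

    ``terms`` is one of apoe_only / score_only / apoe_plus_score /
    combined_only; sex and pc1..pc3 are always included.  The result
    stores the maximized partial log-likelihood so nested models can be
    compared with :func:`lr_nested_test`.
    """
    X, ok, names = _design(cohort, scores, terms)
    time, event = cohort.survival_arrays()
    fit = cox_fit(X[ok], time[ok], event[ok])
    res = CoxEvalResult(terms=terms, n=int(ok.sum()),
                        n_events=int(event[ok].sum()),
                        loglik_full=fit.loglik, loglik_null=fit.loglik_null,
                        term_names=names, converged=fit.converged)
    score_ix = 1 if terms == "apoe_plus_score" else 0
    res.beta_score = float(fit.beta[score_ix])
    res.se = float(fit.se[score_ix])
    res.p = float(fit.p[score_ix])
    if terms in ("apoe_only", "apoe_plus_score"):
        res.beta_apoe = float(fit.beta[0])
        res.se_apoe = float(fit.se[0])
        res.p_apoe = float(fit.p[0])
    if ph_test:
        sd = SurvData(time[ok], event[ok])
        z = zph_test(fit, sd, X[ok])
        res.ph_test_p = dict(zip(names, z["p"]))
        res.ph_test_p["GLOBAL"] = z["global_p"]
    return res


def lr_nested_test(full: CoxEvalResult, reduced: CoxEvalResult):
    """Likelihood-ratio test of nested Cox models fit on the same rows.

    Returns ``(lr_stat, df, p)`` with lr_stat = 2·(ll_full − ll_reduced)
    and a chi-square reference on the parameter-count difference.
    """
    if not set(reduced.term_names) <= set(full.term_names):
        raise ValueError("reduced model terms must nest within the full model")
    if full.n != reduced.n or full.n_events != reduced.n_events:
        raise ValueError("nested comparison requires identical rows")
    df = len(full.term_names) - len(reduced.term_names)
    lr = 2.0 * (full.loglik_full - reduced.loglik_full)
    if lr < -1e-6:
        raise ValueError("full-model loglik below reduced-model loglik: fit failure")
    lr = max(lr, 0.0)
    if df == 0:  # identical models: no evidence either way
        return lr, 0, 1.0
    return lr, df, float(stats.chi2.sf(lr, df))


def ph_assumption_test(cohort: CohortData, scores: ScoreSet,
                       terms: str = "combined_only", transform: str = "km") -> dict:
    """Proportional-hazards diagnostic for an evaluation model.

    Scaled-Schoenfeld score test per term plus a global test, using the
    Kaplan–Meier time transform (the cox.zph default).  Returns
    {term: p, ..., "GLOBAL": p}.
    """
    X, ok, names = _design(cohort, scores, terms)
    time, event = cohort.survival_arrays()
    sd = SurvData(time[ok], event[ok])
    fit = cox_fit(X[ok], data=sd)
    z = zph_test(fit, sd, X[ok], transform=transform)
    out = dict(zip(names, z["p"]))
    out["GLOBAL"] = z["global_p"]
    return out


def km_quantile_curves(cohort: CohortData, scores: ScoreSet,
                       column: str = "score_combined") -> KMCurves:
    """Kaplan–Meier curves for the five score-quantile groups.

    Individuals are binned at the 5th/25th/75th/95th percentiles of the
    standardized score (right-closed: a score equal to an edge falls in
    the lower bin).  Empty bins are omitted with a warning.
    """
    std = scores.standardized
    if std is None or column not in std.columns:
        raise ValueError("standardized score column required")
    s = std[column].to_numpy(float)
    ok = ~np.isnan(s)
    time, event = cohort.survival_arrays()
    s, time, event = s[ok], time[ok], event[ok]
    edges = np.percentile(s, KM_GROUP_EDGES)
    bins = np.searchsorted(edges, s, side="left")  # == edge -> lower bin

    curves, group_n = {}, {}
    kmf = KaplanMeierFitter()
    for b, label in enumerate(KM_GROUP_LABELS):
        sel = bins == b
        group_n[label] = int(sel.sum())
        if not sel.any():
            warnings.warn(f"score group {label} is empty; curve omitted")
            continue
        kmf.fit(time[sel], event_observed=event[sel])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame({
            "age": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
        })
    return KMCurves(curves=curves, group_n=group_n)


def subgroup_e33(cohort: CohortData) -> CohortData:
    """Restrict to APOE ε3 homozygotes (zero ε2 and ε4 copies)."""
    ph = cohort.phenotype
    miss = ph["apoe_e2_count"].isna() | ph["apoe_e4_count"].isna()
    if miss.any():
        raise ValueError(
            f"{int(miss.sum())} individual(s) lack APOE allele counts; "
            "exclude them before subsetting")
    keep = (ph["apoe_e2_count"] == 0) & (ph["apoe_e4_count"] == 0)
    if not keep.any():
        raise ValueError("no APOE e3/e3 homozygotes in the cohort")
    return cohort.subset_individuals(np.flatnonzero(keep.to_numpy()))
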
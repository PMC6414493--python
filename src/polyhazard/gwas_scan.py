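"""Variant QC and per-variant association scans.

Two models per SNP, each adjusted for sex and three principal components:
logistic regression of case/control status (no age term) giving log odds
ratios, and Cox proportional-hazards regression on the age axis (onset age
for cases, assessment age as the censoring age for controls) giving log
hazard ratios.  Summary statistics from either scan feed score
construction downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._cox import SurvData, cox_fit
from .synthetic_cohort import CohortData

log = logging.getLogger(__name__)

__all__ = [
    "QC_DEFAULTS", "QCReport", "hwe_test", "qc_filter",
    "fit_logistic", "fit_cox", "scan", "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ["sex", "pc1", "pc2", "pc3"]

#: QC thresholds: drop if MAF < maf_min, missingness >= miss_max,
#: HWE p < hwe_min, or (when an INFO column exists) INFO < info_min.
QC_DEFAULTS = {"maf_min": 0.1, "miss_max": 0.05, "hwe_min": 1e-6, "info_min": 0.4}


def hwe_test(genotype_counts) -> tuple[float, float]:
    """Hardy–Weinberg 1-df chi-square goodness-of-fit test.

    Parameters
    ----------
    genotype_counts : (n_AA, n_Aa, n_aa)
        Counts of the three genotype classes.

    Returns
    -------
    (chi2, p); a monomorphic variant returns (0.0, 1.0).
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise ValueError("genotype_counts must be three non-negative numbers")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


@dataclass
class QCReport:
    """Per-variant QC metrics and pass/fail verdicts."""

    table: pd.DataFrame  # id, maf, missing_rate, hwe_p, info, pass, fail_reasons
    hwe_on_controls: bool = True

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum())


def _dosage_maf(d):
    freq = np.nanmean(d) / 2.0
    return min(freq, 1 - freq)


def _hwe_from_dosage(d):
    # round to hard calls for the chi-square test; dosages from GT are integral
    calls = np.round(d[~np.isnan(d)])
    counts = [(calls == 2).sum(), (calls == 1).sum(), (calls == 0).sum()]
    return hwe_test(counts)[1]


def qc_filter(cohort: CohortData, thresholds: dict | None = None,
              info: np.ndarray | None = None) -> tuple[CohortData, QCReport]:
    """Apply the four-rule variant QC and return the filtered cohort.

    HWE is computed on controls only (cases are enriched for true
    association, which inflates HWE departures at causal loci); this choice
    is recorded on the report.  ``info`` optionally supplies per-variant
    imputation INFO scores.
    """
    th = dict(QC_DEFAULTS)
    if thresholds:
        th.update(thresholds)
    D = cohort.dosages
    n, m = D.shape
    if info is not None and len(info) != m:
        raise ValueError("info length != number of variants")

    if cohort.phenotype is not None:
        ctrl_rows = (cohort.phenotype["status"] == "control").to_numpy()
        hwe_rows = ctrl_rows if ctrl_rows.any() else np.ones(n, bool)
        on_controls = ctrl_rows.any()
    else:
        hwe_rows = np.ones(n, bool)
        on_controls = False

    recs = []
    for j in range(m):
        d = D[:, j]
        maf = _dosage_maf(d)
        miss = float(np.isnan(d).mean())
        hwe_p = _hwe_from_dosage(d[hwe_rows]) if not np.all(np.isnan(d[hwe_rows])) else 1.0
        inf = float(info[j]) if info is not None else np.nan
        reasons = []
        if maf < th["maf_min"]:
            reasons.append("maf")
        if miss >= th["miss_max"]:
            reasons.append("missingness")
        if hwe_p < th["hwe_min"]:
            reasons.append("hwe")
        if info is not None and inf < th["info_min"]:
            reasons.append("info")
        recs.append((cohort.variant_meta["id"].iat[j], maf, miss, hwe_p, inf,
                     not reasons, ",".join(reasons)))
    table = pd.DataFrame(recs, columns=["id", "maf", "missing_rate", "hwe_p",
                                        "info", "pass", "fail_reasons"])
    keep = np.flatnonzero(table["pass"].to_numpy())
    if keep.size == 0:
        raise ValueError("QC removed every variant")
    for reason in ("maf", "missingness", "hwe", "info"):
        c = table["fail_reasons"].str.contains(reason).sum()
        if c:
            log.info("QC: %d variant(s) failed %s", c, reason)
    return cohort.subset_variants(keep), QCReport(table, hwe_on_controls=on_controls)


def fit_logistic(y, x, covariates=None, *, tol: float = 1e-8, max_iter: int = 50):
    """Logistic regression of y on x (+ intercept and covariates).

    Maximum likelihood via Newton/IRLS (statsmodels backend).  Returns
    ``(beta, se, p, converged)`` for the coefficient on ``x``; separation
    or non-convergence yields ``converged = False`` so the caller can
    exclude the variant from score weights.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y has a single class")
    if np.nanstd(x) == 0:
        raise ValueError("x is constant")
    cols = [x[:, None]]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    X = sm.add_constant(np.hstack(cols), prepend=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=max_iter,
                                     tol=tol, disp=0, warn_convergence=False)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            return np.nan, np.nan, np.nan, False
    beta = float(res.params[0])
    se = float(res.bse[0])
    converged = bool(res.mle_retvals.get("converged", False))
    if not np.isfinite(se) or se > 100 or abs(beta) > 30:
        converged = False  # quasi-separation
    p = float(2 * stats.norm.sf(abs(beta / se))) if np.isfinite(se) and se > 0 else np.nan
    return beta, se, p, converged


def fit_cox(time, event, x, covariates=None, *, ties: str = "efron",
            tol: float = 1e-8, max_iter: int = 50, data: SurvData | None = None):
    """Cox regression of (time, event) on x (+ covariates).

    Returns ``(beta, se, p, loglik, converged)`` for the coefficient on
    ``x``; ``loglik`` is the maximized partial log-likelihood of the whole
    model (used by nested likelihood-ratio tests).
    """
    x = np.asarray(x, dtype=float)
    cols = [x[:, None]]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    X = np.hstack(cols)
    fit = cox_fit(X, time, event, data=data, ties=ties, tol=tol, max_iter=max_iter)
    return (float(fit.beta[0]), float(fit.se[0]), float(fit.p[0]),
            float(fit.loglik), fit.converged)


def scan(cohort: CohortData, model: str = "cox",
         covariate_columns=COVARIATE_COLUMNS, ties: str = "efron") -> pd.DataFrame:
    """Per-variant association scan; returns summary statistics.

    Missing dosages are mean-imputed per variant.  Variants whose fit
    fails carry NaN beta (excluded from downstream selection).  Output is
    sorted by (chromosome, position) with columns id, chromosome,
    position, effect_allele, other_allele, beta, se, p, n_used, model.
    """
    if model not in ("logistic", "cox"):
        raise ValueError(f"unknown model {model!r}")
    ph = cohort.phenotype
    if ph is None:
        raise ValueError("phenotype required for association scan")
    covs = ph[list(covariate_columns)].to_numpy(float) if covariate_columns else None

    if model == "cox":
        time, event = cohort.survival_arrays()
        sdata = SurvData(time, event)
    else:
        y = (ph["status"] == "case").to_numpy(float)

    D = cohort.dosages
    n, m = D.shape
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.full(m, n)
    for j in range(m):
        d = D[:, j]
        nan = np.isnan(d)
        if nan.any():
            d = np.where(nan, np.nanmean(d), d)
        if np.std(d) == 0:
            continue
        try:
            if model == "cox":
                b, s, p, _, ok = fit_cox(None, None, d, covs, ties=ties, data=sdata)
            else:
                b, s, p, ok = fit_logistic(y, d, covs)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if ok:
            beta[j], se[j], pval[j] = b, s, p
    n_failed = int(np.isnan(beta).sum())
    if n_failed:
        log.info("%s scan: %d of %d variants failed or were skipped",
                 model, n_failed, m)

    out = cohort.variant_meta[["id", "chromosome", "position",
                               "effect_allele", "other_allele"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = pval
    out["n_used"] = n_used
    out["model"] = model
    return (out.sort_values(["chromosome", "position"], kind="stable")
               .reset_index(drop=True))
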
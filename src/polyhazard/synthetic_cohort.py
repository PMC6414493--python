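"""Simulated case/control cohorts with genotypes, LD structure and
age-at-onset under a Weibull proportional-hazards model.

The generator emulates the statistical shape of a late-onset Alzheimer's
case/control genotyping study: many small-effect SNPs arranged in LD
blocks, one large-effect bi-allelic locus with a protective and a risk
allele entered as allele counts (APOE ε2 / ε4 style), onset ages from a
proportional-hazards model on the age scale, right-censored controls
including a block assessed at exactly age 45 (a birth-cohort panel), and a
fraction of cases whose onset age is known only through their age at last
assessment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ApoeConfig",
    "CohortConfig",
    "CohortData",
    "simulate_genotypes",
    "simulate_onset",
    "simulate_cohort",
    "simulate_times_weibull_ph",
    "simulate_times_sign_reversal",
    "impute_age_at_onset",
    "filter_min_age",
]

PHENOTYPE_COLUMNS = [
    "id", "status", "age_at_onset", "age_last_assessment", "sex",
    "pc1", "pc2", "pc3", "apoe_e2_count", "apoe_e4_count",
]


@dataclass(frozen=True)
class ApoeConfig:
    """Large-effect bi-allelic locus with separate protective/risk alleles.

    Default allele frequencies and per-allele log hazard ratios are in the
    range reported for APOE ε2 (protective) and ε4 (risk) in European
    ancestry samples.
    """

    protective_freq: float = 0.08
    protective_beta: float = -0.47
    risk_freq: float = 0.15
    risk_beta: float = 1.03


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one simulated cohort.

    Defaults give roughly a quarter of the sample affected before their
    assessment age, onset ages concentrated in the 60s–80s, and most
    controls censored at 45 (the birth-cohort panel) — the regime the
    analyses in this package are designed for.
    """

    n_individuals: int = 6000
    n_snps: int = 2000
    n_blocks: int = 100
    within_block_corr: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_causal: int = 40
    causal_effect_sd: float = 0.12
    apoe_like: bool = True
    apoe: ApoeConfig = field(default_factory=ApoeConfig)
    baseline_weibull: tuple[float, float] = (6.0, 90.0)  # (shape k, scale λ years)
    assessment_age_mean: float = 72.0
    assessment_age_sd: float = 8.0
    birth_cohort_fraction: float = 0.765
    birth_cohort_age: float = 45.0
    onset_missing_fraction: float = 0.08
    sex_beta: float = 0.2
    pc_betas: tuple[float, float, float] = (0.1, 0.05, 0.02)
    snp_spacing_bp: int = 10_000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must be in [0, 1)")
        k, lam = self.baseline_weibull
        if k <= 0 or lam <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.n_blocks > self.n_snps:
            raise ValueError("n_blocks may not exceed n_snps")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal may not exceed n_snps")
        for name in ("birth_cohort_fraction", "onset_missing_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.apoe_like:
            a = self.apoe
            for f in (a.protective_freq, a.risk_freq):
                if not (0 < f <= 0.5):
                    raise ValueError("APOE-like allele frequencies must be in (0, 0.5]")
            if a.protective_freq + a.risk_freq >= 1:
                raise ValueError("APOE-like allele frequencies must sum to < 1")


@dataclass
class CohortData:
    """Genotype dosages plus per-individual phenotype/survival table.

    ``dosages`` is an individuals × variants float matrix with entries in
    [0, 2] (NaN = missing).  ``variant_meta`` has one row per variant
    (id, chromosome, position, effect_allele, other_allele, true_beta);
    positions are 1-based and strictly increasing within a chromosome.
    ``phenotype`` has one row per individual (see PHENOTYPE_COLUMNS);
    status is "case" or "control".
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    phenotype: pd.DataFrame | None = None

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def validate(self):
        vm = self.variant_meta
        if len(vm) != self.n_variants:
            raise ValueError("variant_meta row count != dosage columns")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise ValueError("dosages outside [0, 2]")
        for _, grp in vm.groupby("chromosome"):
            if not grp["position"].is_monotonic_increasing or grp["position"].duplicated().any():
                raise ValueError("positions must be strictly increasing within a chromosome")
        ph = self.phenotype
        if ph is not None:
            if len(ph) != self.n_individuals:
                raise ValueError("phenotype row count != dosage rows")
            cases = ph["status"] == "case"
            no_age = cases & ph["age_at_onset"].isna() & ph["age_last_assessment"].isna()
            if no_age.any():
                raise ValueError("cases must have age_at_onset or age_last_assessment")
            if (~cases & ph["age_last_assessment"].isna()).any():
                raise ValueError("controls must have age_last_assessment")
            both = ph[["apoe_e2_count", "apoe_e4_count"]].sum(axis=1, skipna=False)
            if (both.dropna() > 2).any():
                raise ValueError("apoe_e2_count + apoe_e4_count must be <= 2")
        return self

    def subset_individuals(self, index) -> "CohortData":
        index = np.asarray(index)
        ph = None
        if self.phenotype is not None:
            ph = self.phenotype.iloc[index].reset_index(drop=True)
        return CohortData(self.dosages[index], self.variant_meta.copy(), ph)

    def subset_variants(self, index) -> "CohortData":
        index = np.asarray(index)
        return CohortData(
            self.dosages[:, index],
            self.variant_meta.iloc[index].reset_index(drop=True),
            None if self.phenotype is None else self.phenotype.copy(),
        )

    def survival_arrays(self):
        """(time, event) on the age axis: onset age for cases (event=1),
        assessment age for controls (event=0)."""
        ph = self.phenotype
        if ph is None:
            raise ValueError("phenotype not filled")
        event = (ph["status"] == "case").to_numpy()
        time = np.where(event, ph["age_at_onset"].to_numpy(float),
                        ph["age_last_assessment"].to_numpy(float))
        if np.isnan(time).any():
            raise ValueError(
                "missing survival times; run impute_age_at_onset first")
        return time, event.astype(int)


def _child_rngs(config: CohortConfig):
    ss = np.random.SeedSequence(config.seed)
    geno, pheno = ss.spawn(2)
    return np.random.default_rng(geno), np.random.default_rng(pheno)


def simulate_genotypes(config: CohortConfig, rng: np.random.Generator | None = None) -> CohortData:
    """Draw dosages with block LD structure; phenotype left unfilled.

    Per block, two haplotypes per individual come from a latent AR(1)
    Gaussian process (lag-1 correlation ``within_block_corr``) thresholded
    at each variant's MAF quantile; the dosage is the haplotype sum, so
    within-block dosage correlation decays geometrically with SNP distance
    and across-block correlation is zero in expectation.
    """
    if rng is None:
        rng, _ = _child_rngs(config)
    n, m = config.n_individuals, config.n_snps
    rho = config.within_block_corr

    mafs = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(mafs)

    # block sizes as equal as possible
    sizes = np.full(config.n_blocks, m // config.n_blocks)
    sizes[: m % config.n_blocks] += 1

    dosages = np.empty((n, m), dtype=float)
    col = 0
    for size in sizes:
        z = np.empty((2 * n, size))
        z[:, 0] = rng.standard_normal(2 * n)
        innov = rng.standard_normal((2 * n, size - 1)) if size > 1 else None
        for j in range(1, size):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * innov[:, j - 1]
        hap = (z < thresholds[col: col + size]).astype(float)
        dosages[:, col: col + size] = hap[0::2] + hap[1::2]
        col += size

    causal = rng.choice(m, size=config.n_causal, replace=False)
    true_beta = np.zeros(m)
    true_beta[causal] = rng.normal(0.0, config.causal_effect_sd, size=config.n_causal)

    width = len(str(m))
    meta = pd.DataFrame({
        "id": [f"snp{j + 1:0{width}d}" for j in range(m)],
        "chromosome": "1",
        "position": config.snp_spacing_bp * (np.arange(m) + 1),
        "effect_allele": "A",
        "other_allele": "G",
        "true_beta": true_beta,
        "maf_target": mafs,
    })
    return CohortData(dosages, meta)


def simulate_times_weibull_ph(eta, shape, scale, rng):
    """Inverse-transform Weibull proportional-hazards onset times:
    T = λ (−ln U / exp(η))^{1/k}."""
    u = rng.uniform(size=np.shape(eta))
    return scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)


def simulate_times_sign_reversal(eta, shape, scale, rng, tau=None):
    """Onset times whose covariate effect flips sign at age ``tau``.

    Hazard is h0(t)·exp(η) before ``tau`` and h0(t)·exp(−η) after — a
    built-in proportional-hazards violation for power studies of the
    Schoenfeld-residual test.  ``tau`` defaults to the baseline median
    λ·(ln 2)^{1/k}.
    """
    eta = np.asarray(eta, dtype=float)
    if tau is None:
        tau = scale * np.log(2.0) ** (1.0 / shape)
    e = rng.exponential(size=eta.shape)          # E ~ Exp(1), T solves H(T)=E
    h_tau = (tau / scale) ** shape * np.exp(eta)
    early = e < h_tau
    t = np.empty_like(eta)
    t[early] = scale * (e[early] / np.exp(eta[early])) ** (1.0 / shape)
    rest = ~early
    base = (tau / scale) ** shape
    t[rest] = scale * (base + (e[rest] - h_tau[rest]) * np.exp(eta[rest])) ** (1.0 / shape)
    return t


def simulate_onset(cohort: CohortData, config: CohortConfig,
                   rng: np.random.Generator | None = None) -> CohortData:
    """Fill the phenotype table: covariates, APOE-like counts, onset vs
    censoring, the fixed-age birth-cohort block and missing onsets.

    Case iff the Weibull-PH onset time falls at or before the assessment
    age; controls are right-censored at assessment.  A
    ``birth_cohort_fraction`` of controls is re-assessed at exactly
    ``birth_cohort_age`` (only controls whose latent onset lies beyond that
    age are eligible, so status is preserved).  An
    ``onset_missing_fraction`` of cases has onset blanked, keeping only the
    age at last assessment.
    """
    if cohort.dosages is None:
        raise ValueError("dosages must be simulated first")
    if rng is None:
        _, rng = _child_rngs(config)
    n = cohort.n_individuals
    k, lam = config.baseline_weibull

    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 3))

    if config.apoe_like:
        a = config.apoe
        probs = [a.protective_freq, a.risk_freq, 1 - a.protective_freq - a.risk_freq]
        haps = rng.choice(3, size=(n, 2), p=probs)   # 0=protective,1=risk,2=neutral
        e2 = (haps == 0).sum(axis=1).astype(float)
        e4 = (haps == 1).sum(axis=1).astype(float)
        eta_apoe = a.protective_beta * e2 + a.risk_beta * e4
    else:
        e2 = e4 = np.zeros(n)
        eta_apoe = 0.0

    beta = cohort.variant_meta["true_beta"].to_numpy()
    causal = np.flatnonzero(beta != 0)
    G = cohort.dosages[:, causal]
    if np.isnan(G).any():
        log.info("mean-imputing missing dosages in the causal set")
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean, G)
    eta = (G @ beta[causal] + eta_apoe + config.sex_beta * sex
           + pcs @ np.asarray(config.pc_betas))

    onset = simulate_times_weibull_ph(eta, k, lam, rng)
    a_lo = (0.0 - config.assessment_age_mean) / config.assessment_age_sd
    assess = stats.truncnorm.rvs(a_lo, np.inf, loc=config.assessment_age_mean,
                                 scale=config.assessment_age_sd, size=n,
                                 random_state=rng)

    is_case = onset <= assess
    controls = np.flatnonzero(~is_case)
    n_bc = int(round(config.birth_cohort_fraction * controls.size))
    if n_bc > 0:
        eligible = controls[onset[controls] > config.birth_cohort_age]
        if eligible.size < n_bc:
            warnings.warn(
                "birth-cohort block truncated: only "
                f"{eligible.size}/{n_bc} controls have latent onset beyond "
                f"age {config.birth_cohort_age}")
            n_bc = eligible.size
        chosen = rng.choice(eligible, size=n_bc, replace=False)
        assess[chosen] = config.birth_cohort_age

    age_onset = np.where(is_case, onset, np.nan)
    case_idx = np.flatnonzero(is_case)
    n_blank = int(round(config.onset_missing_fraction * case_idx.size))
    if n_blank > 0:
        blank = rng.choice(case_idx, size=n_blank, replace=False)
        age_onset[blank] = np.nan

    width = len(str(n))
    phenotype = pd.DataFrame({
        "id": [f"ind{i + 1:0{width}d}" for i in range(n)],
        "status": np.where(is_case, "case", "control"),
        "age_at_onset": age_onset,
        "age_last_assessment": assess,
        "sex": sex.astype(int),
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2],
        "apoe_e2_count": e2, "apoe_e4_count": e4,
        "true_eta": eta,
    })
    return CohortData(cohort.dosages, cohort.variant_meta, phenotype).validate()


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Genotypes + phenotypes in one call, fully determined by config.seed."""
    g_rng, p_rng = _child_rngs(config)
    cohort = simulate_genotypes(config, g_rng)
    return simulate_onset(cohort, config, p_rng)


def impute_age_at_onset(phenotype: pd.DataFrame, years_before: float = 5.0) -> pd.DataFrame:
    """Impute missing case onset as (age at last assessment − 5 years).

    Cases with neither age are dropped with a warning; controls and cases
    with known onset pass through unchanged.  Adds a boolean
    ``onset_imputed`` column.
    """
    out = phenotype.copy()
    cases = out["status"] == "case"
    missing = cases & out["age_at_onset"].isna()
    hopeless = missing & out["age_last_assessment"].isna()
    if hopeless.any():
        warnings.warn(f"dropping {int(hopeless.sum())} case(s) with no age information")
        out = out[~hopeless].reset_index(drop=True)
        cases = out["status"] == "case"
        missing = cases & out["age_at_onset"].isna()
    out["onset_imputed"] = False
    out.loc[missing, "age_at_onset"] = out.loc[missing, "age_last_assessment"] - years_before
    out.loc[missing, "onset_imputed"] = True
    return out


def filter_min_age(cohort: CohortData, min_age: float) -> CohortData:
    """Keep cases with onset ≥ min_age and controls censored at ≥ min_age."""
    ph = cohort.phenotype
    if ph is None:
        raise ValueError("phenotype not filled")
    cases = ph["status"] == "case"
    if (cases & ph["age_at_onset"].isna()).any():
        raise ValueError("cases with missing onset; run impute_age_at_onset first")
    keep = np.where(cases, ph["age_at_onset"] >= min_age,
                    ph["age_last_assessment"] >= min_age)
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(f"min-age filter at {min_age} removed every individual")
    log.info("min-age filter at %s dropped %d of %d individuals",
             min_age, n_drop, len(ph))
    return cohort.subset_individuals(np.flatnonzero(keep))
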
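"""Polygenic score construction.

A polygenic risk score (PRS) is a weighted sum of effect-allele dosages
with log odds-ratio weights from case/control regression; a polygenic
hazard score (PHS) is the same sum with log hazard-ratio weights from Cox
regression.  The APOE ε2/ε4 alleles enter as allele counts with their own
weights.  Scores come in three variants — APOE-only, SNPs-only and
combined — and are residualized on covariates and z-standardized before
survival evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_scan import COVARIATE_COLUMNS
from .synthetic_cohort import CohortData

__all__ = ["APOE_IDS", "SCORE_VARIANTS", "WeightTable", "ScoreSet",
           "align_alleles", "compute_score", "build_score_set",
           "adjust_and_standardize", "score_correlation",
           "weights_from_summary_stats"]

APOE_IDS = ("APOE_e2", "APOE_e4")
SCORE_VARIANTS = ("apoe", "snps", "combined")


@dataclass
class WeightTable:
    """Variant → effect-allele weight map.

    ``table`` columns: id, chromosome, position, effect_allele, weight,
    source, and (after :func:`align_alleles`) flip.  Rows with id
    ``APOE_e2`` / ``APOE_e4`` are keyed to the phenotype allele-count
    columns rather than to dosage variants.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame | None = None  # alignment rejects, for reporting

    def __post_init__(self):
        t = self.table
        required = {"id", "effect_allele", "weight"}
        if missing := required - set(t.columns):
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate weight ids: {dups}")
        if not np.all(np.isfinite(t["weight"].to_numpy(float))):
            raise ValueError("weights must be finite")

    @property
    def apoe_rows(self) -> pd.DataFrame:
        return self.table[self.table["id"].isin(APOE_IDS)]

    @property
    def snp_rows(self) -> pd.DataFrame:
        return self.table[~self.table["id"].isin(APOE_IDS)]

    def __len__(self):
        return len(self.table)


@dataclass
class ScoreSet:
    """Per-individual polygenic scores.

    ``raw`` and ``standardized`` are DataFrames indexed like the cohort's
    phenotype table with columns among score_apoe / score_snps /
    score_combined.  Individuals excluded from a variant (e.g. missing
    APOE counts) carry NaN.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame | None = None
    source: str = ""
    threshold: float | None = None
    n_snps_used: dict = field(default_factory=dict)


def weights_from_summary_stats(stats: pd.DataFrame, source: str) -> WeightTable:
    """Turn a scan's summary statistics into a SNP weight table."""
    ok = stats[stats["beta"].notna()]
    return WeightTable(pd.DataFrame({
        "id": ok["id"].to_numpy(),
        "chromosome": ok["chromosome"].to_numpy(),
        "position": ok["position"].to_numpy(),
        "effect_allele": ok["effect_allele"].to_numpy(),
        "weight": ok["beta"].to_numpy(float),
        "source": source,
    }))


def align_alleles(weights: WeightTable, variant_meta: pd.DataFrame) -> WeightTable:
    """Match weight effect alleles to the cohort's dosage coding.

    Where the weight's effect allele equals the cohort's coded allele the
    dosage is used as-is; where it equals the other allele the variant is
    marked ``flip`` and contributes ``2 − dosage``; anything else is
    dropped with a warning.  APOE allele-count rows pass through
    unflipped.
    """
    meta = variant_meta.set_index("id")
    if meta.index.duplicated().any():
        raise ValueError("duplicate variant ids in cohort metadata")
    rows, dropped = [], []
    for rec in weights.table.to_dict("records"):
        vid = rec["id"]
        if vid in APOE_IDS:
            rows.append({**rec, "flip": False})
            continue
        if vid not in meta.index:
            dropped.append({**rec, "reason": "absent"})
            continue
        coded, other = meta.at[vid, "effect_allele"], meta.at[vid, "other_allele"]
        if rec["effect_allele"] == coded:
            rows.append({**rec, "flip": False})
        elif rec["effect_allele"] == other:
            rows.append({**rec, "flip": True})
        else:
            dropped.append({**rec, "reason": "allele_mismatch"})
    if dropped:
        warnings.warn(f"align_alleles dropped {len(dropped)} weight row(s)")
    if not rows:
        raise ValueError("no weight rows align to the cohort")
    return WeightTable(pd.DataFrame(rows),
                       dropped=pd.DataFrame(dropped) if dropped else None)


def _snp_component(cohort: CohortData, weights: pd.DataFrame) -> tuple[np.ndarray, int]:
    idx = {v: j for j, v in enumerate(cohort.variant_meta["id"])}
    score = np.zeros(cohort.n_individuals)
    used = 0
    for rec in weights.to_dict("records"):
        j = idx.get(rec["id"])
        if j is None:
            continue
        d = cohort.dosages[:, j].astype(float)
        if bool(rec.get("flip", False)):
            d = 2.0 - d
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)  # mean-dosage fill
        score += rec["weight"] * d
        used += 1
    return score, used


def _apoe_component(cohort: CohortData, weights: pd.DataFrame) -> np.ndarray:
    ph = cohort.phenotype
    counts = {"APOE_e2": ph["apoe_e2_count"].to_numpy(float),
              "APOE_e4": ph["apoe_e4_count"].to_numpy(float)}
    score = np.zeros(cohort.n_individuals)
    for rec in weights.to_dict("records"):
        score = score + rec["weight"] * counts[rec["id"]]
    # NaN counts propagate: individuals without APOE genotypes are excluded
    return score


def compute_score(cohort: CohortData, weights: WeightTable,
                  variant: str = "combined") -> ScoreSet:
    """Raw weighted-sum score for one variant (apoe | snps | combined).

    Missing dosages contribute the variant's mean dosage; individuals with
    missing APOE allele counts get NaN for apoe/combined scores.
    """
    if variant not in SCORE_VARIANTS:
        raise ValueError(f"unknown score variant {variant!r}")
    if len(weights) == 0:
        raise ValueError("empty weight table")
    out = pd.DataFrame(index=pd.RangeIndex(cohort.n_individuals))
    used = {}
    if variant in ("snps", "combined"):
        snp_score, n_used = _snp_component(cohort, weights.snp_rows)
        used["snps"] = n_used
        if variant == "snps" and n_used == 0:
            raise ValueError("no SNP weight rows usable for this cohort")
        out["score_snps"] = snp_score
    if variant in ("apoe", "combined"):
        if weights.apoe_rows.empty:
            raise ValueError("weight table has no APOE rows")
        out["score_apoe"] = _apoe_component(cohort, weights.apoe_rows)
    if variant == "combined":
        out["score_combined"] = out["score_apoe"] + out["score_snps"]
        out = out[["score_combined"]]
    src = weights.table["source"].iloc[0] if "source" in weights.table else ""
    return ScoreSet(raw=out, source=str(src), n_snps_used=used)


def build_score_set(cohort: CohortData, weights: WeightTable) -> ScoreSet:
    """All three score variants (raw) in one ScoreSet."""
    apoe = compute_score(cohort, weights, "apoe")
    snps = compute_score(cohort, weights, "snps")
    raw = pd.concat([apoe.raw, snps.raw], axis=1)
    raw["score_combined"] = raw["score_apoe"] + raw["score_snps"]
    return ScoreSet(raw=raw, source=apoe.source, n_snps_used=snps.n_snps_used)


def adjust_and_standardize(scores: ScoreSet, covariates) -> ScoreSet:
    """Residualize each raw score on covariates, then z-standardize.

    Covariates (sex + 3 PCs by convention) plus an intercept are regressed
    out by least squares over the individuals with a non-missing score;
    the residual is scaled to mean 0, SD 1.  Raises if a score has zero
    residual variance.
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != len(scores.raw):
        raise ValueError("covariate rows != scored individuals")
    X = np.column_stack([np.ones(C.shape[0]), C])
    std = pd.DataFrame(index=scores.raw.index)
    for col in scores.raw.columns:
        y = scores.raw[col].to_numpy(float)
        ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
        resid = np.full_like(y, np.nan)
        coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        resid[ok] = y[ok] - X[ok] @ coef
        sd = np.nanstd(resid)
        scale = max(1.0, float(np.nanstd(y)))
        if not np.isfinite(sd) or sd <= 1e-10 * scale:
            raise ValueError(f"{col} has zero residual variance after adjustment")
        std[col] = (resid - np.nanmean(resid)) / sd
    return ScoreSet(raw=scores.raw, standardized=std, source=scores.source,
                    threshold=scores.threshold, n_snps_used=scores.n_snps_used)


def score_correlation(s1: ScoreSet, s2: ScoreSet, column: str | None = None) -> float:
    """Pearson correlation between two standardized score sets.

    Defaults to the combined score when present, otherwise the single
    shared column.  Requires at least 3 jointly scored individuals.
    """
    a = s1.standardized if s1.standardized is not None else s1.raw
    b = s2.standardized if s2.standardized is not None else s2.raw
    if column is None:
        shared = [c for c in a.columns if c in b.columns]
        column = "score_combined" if "score_combined" in shared else shared[0]
    x, y = a[column].to_numpy(float), b[column].to_numpy(float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 individuals for a correlation")
    return float(sps.pearsonr(x[ok], y[ok])[0])
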
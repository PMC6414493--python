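"""Orchestration: discovery/validation splits, repeated cross-validation
over the P-value threshold grid, and the subsample stability analysis.

One repetition = a seeded stratified 75/25 split of the cohort; logistic
and Cox scans in the discovery part give the PRS and PHS weights; scores
are built, adjusted and standardized in the held-out validation part and
evaluated with a Cox model on the age axis.  Reported per threshold:
mean/SD of the validation effect size, mean P-value, and the mean Pearson
correlation between the two scores.  Five repeated random splits are the
default; a strict disjoint 5-fold mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas_scan, variant_selection
from .io import (load_cohort, load_published_weights, load_weight_table,
                 read_summary_stats, write_summary_stats)
from .polygenic_scores import (WeightTable, adjust_and_standardize,
                               align_alleles, build_score_set, compute_score,
                               score_correlation, weights_from_summary_stats)
from .survival_eval import evaluate_score
from .synthetic_cohort import CohortData
from .variant_selection import DEFAULT_THRESHOLDS, SelectionConfig

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "CVReport", "split_discovery_validation",
           "kfold_splits", "run_comparison", "subsample_analysis",
           "load_cohort", "load_weight_table", "load_published_weights",
           "read_summary_stats", "write_summary_stats"]

DEFAULT_SUBSAMPLE_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    split_fraction: float = 0.75
    n_repeats: int = 5
    thresholds: tuple = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    qc_thresholds: dict | None = None
    min_age: float | None = None
    strict_kfold: bool = False
    subsample_fractions: tuple = DEFAULT_SUBSAMPLE_FRACTIONS

    def __post_init__(self):
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")
        if any(not (0 < f <= 1) for f in self.subsample_fractions):
            raise ValueError("subsample fractions must be in (0, 1]")


@dataclass
class CVReport:
    """Aggregated cross-validation results plus the per-fold detail."""

    summary: pd.DataFrame
    folds: pd.DataFrame
    fold_results: list = field(default_factory=list)

    def to_tsv(self, path):
        self.summary.to_csv(path, sep="\t", index=False, na_rep="NA",
                            float_format="%.6g")
        return path


def _stratum_indices(phenotype: pd.DataFrame):
    status = phenotype["status"].to_numpy()
    return [np.flatnonzero(status == s) for s in ("case", "control")]


def split_discovery_validation(cohort: CohortData, fraction: float,
                               seed: int) -> tuple[CohortData, CohortData]:
    """Seeded stratified split by case/control status.

    ``fraction`` of each stratum goes to discovery, the rest to
    validation; both parts of both strata must keep at least 2 members.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    disc_parts, valid_parts = [], []
    for idx in _stratum_indices(cohort.phenotype):
        n_disc = int(round(fraction * idx.size))
        perm = rng.permutation(idx)
        disc, valid = perm[:n_disc], perm[n_disc:]
        if min(disc.size, valid.size) < 2:
            raise ValueError(
                f"split at fraction {fraction} leaves a stratum with "
                f"{min(disc.size, valid.size)} member(s)")
        disc_parts.append(disc)
        valid_parts.append(valid)
    return (cohort.subset_individuals(np.sort(np.concatenate(disc_parts))),
            cohort.subset_individuals(np.sort(np.concatenate(valid_parts))))


def kfold_splits(cohort: CohortData, k: int, seed: int):
    """Strict disjoint stratified k-fold: yields (discovery, validation)
    pairs whose validation parts partition the cohort."""
    rng = np.random.default_rng(seed)
    strata = [rng.permutation(idx) for idx in _stratum_indices(cohort.phenotype)]
    for fold in range(k):
        val_parts, disc_parts = [], []
        for perm in strata:
            chunks = np.array_split(perm, k)
            val_parts.append(chunks[fold])
            disc_parts.extend(chunks[i] for i in range(k) if i != fold)
        val = np.sort(np.concatenate(val_parts))
        disc = np.sort(np.concatenate(disc_parts))
        if min(val.size, disc.size) < 2:
            raise ValueError("fold too small")
        yield cohort.subset_individuals(disc), cohort.subset_individuals(val)


def _fold_seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _selection_pvalues(logit_stats: pd.DataFrame,
                       external_stats: pd.DataFrame | None) -> pd.DataFrame:
    """Stats table whose p column drives pruning priority and thresholds."""
    if external_stats is None:
        return logit_stats
    sel = logit_stats.drop(columns=["p"]).merge(
        external_stats[["id", "p"]], on="id", how="left")
    return sel[logit_stats.columns]


def run_comparison(cohort: CohortData, config: RunConfig,
                   external_stats: pd.DataFrame | None = None) -> CVReport:
    """The full PRS-vs-PHS cross-validated threshold-grid comparison.

    Per repetition: scan the discovery part with both models, LD-prune
    (priority P-values from ``external_stats`` when given, else the
    discovery logistic scan), then per threshold build the PHS (Cox
    weights) and PRS (logistic weights) in the validation part, adjust,
    standardize and evaluate each with a Cox model.  Thresholds with no
    SNPs in a fold are reported as NA for that fold.
    """
    seeds = _fold_seeds(config.seed, config.n_repeats)
    records = []
    fold_results = []
    if config.strict_kfold:
        splits = kfold_splits(cohort, config.n_repeats, seeds[0])
    else:
        splits = (split_discovery_validation(cohort, config.split_fraction, s)
                  for s in seeds)

    for rep, (disc, valid) in enumerate(splits):
        logit = gwas_scan.scan(disc, "logistic")
        cox = gwas_scan.scan(disc, "cox")
        sel_stats = _selection_pvalues(logit, external_stats)
        # scan output is coordinate-sorted like variant_meta, so discovery
        # dosage columns line up with the stats rows
        assert list(sel_stats["id"]) == list(disc.variant_meta["id"])
        pruned = variant_selection.prune(sel_stats, disc.dosages, config.selection)
        cov_cols = valid.phenotype[gwas_scan.COVARIATE_COLUMNS].to_numpy(float)

        for threshold in config.thresholds:
            chosen = variant_selection.select_by_threshold(pruned, threshold)
            rec = {"repeat": rep, "threshold": threshold, "n_snps": len(chosen)}
            if len(chosen) == 0:
                records.append(rec)
                continue
            ids = chosen["id"]
            res = {}
            for tag, stats in (("phs", cox), ("prs", logit)):
                w = weights_from_summary_stats(
                    stats[stats["id"].isin(ids)], f"discovery_{stats['model'].iat[0]}")
                w = align_alleles(w, valid.variant_meta)
                sc = compute_score(valid, w, "snps")
                sc = adjust_and_standardize(sc, cov_cols)
                ev = evaluate_score(valid, sc, "score_only", ph_test=False)
                rec[f"{tag}_beta"] = ev.beta_score
                rec[f"{tag}_se"] = ev.se
                rec[f"{tag}_p"] = ev.p
                res[tag] = (sc, ev)
            rec["corr"] = score_correlation(res["phs"][0], res["prs"][0],
                                            column="score_snps")
            records.append(rec)
            fold_results.append({"repeat": rep, "threshold": threshold,
                                 "phs": res["phs"][1], "prs": res["prs"][1]})
        log.info("repeat %d/%d done", rep + 1, config.n_repeats)

    folds = pd.DataFrame(records)
    for col in ("phs_beta", "phs_se", "phs_p", "prs_beta", "prs_se", "prs_p", "corr"):
        if col not in folds:
            folds[col] = np.nan
    rows = []
    for threshold in config.thresholds:
        all_sub = folds[folds["threshold"] == threshold]
        sub = all_sub[all_sub["phs_beta"].notna()]
        row = {"threshold": threshold,
               "n_snps": all_sub["n_snps"].mean(),
               "n_folds_used": len(sub)}
        for tag in ("phs", "prs"):
            row[f"{tag}_beta_mean"] = sub[f"{tag}_beta"].mean() if len(sub) else np.nan
            row[f"{tag}_beta_sd"] = sub[f"{tag}_beta"].std(ddof=1) if len(sub) > 1 else np.nan
            row[f"{tag}_p_mean"] = sub[f"{tag}_p"].mean() if len(sub) else np.nan
        row["corr_mean"] = sub["corr"].mean() if len(sub) else np.nan
        rows.append(row)
    return CVReport(summary=pd.DataFrame(rows), folds=folds,
                    fold_results=fold_results)


def subsample_analysis(cohort: CohortData, weights: WeightTable,
                       fractions=DEFAULT_SUBSAMPLE_FRACTIONS, n_reps: int = 1,
                       seed: int = 0, variant: str = "snps") -> pd.DataFrame:
    """Score-effect stability across stratified subsamples of the cohort.

    For each sample fraction (and repetition) a case/control-stratified
    subsample is drawn, the fixed weight table is applied, and the
    standardized score is evaluated with the Cox model.  Returns one row
    per (fraction, repetition) with beta, SE and P; fraction 1.0
    reproduces the full-sample evaluation.
    """
    aligned = align_alleles(weights, cohort.variant_meta)
    seeds = _fold_seeds(seed, n_reps)
    terms = {"snps": "score_only", "apoe": "apoe_only",
             "combined": "combined_only"}[variant]
    rows = []
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        for frac in fractions:
            if frac == 1.0:
                sub = cohort
            else:
                parts = []
                for idx in _stratum_indices(cohort.phenotype):
                    take = max(int(round(frac * idx.size)), 1)
                    parts.append(rng.choice(idx, size=take, replace=False))
                sel = np.sort(np.concatenate(parts))
                sub = cohort.subset_individuals(sel)
            if sub.n_individuals < 50:
                log.warning("subsample at fraction %.2f has only %d individuals",
                            frac, sub.n_individuals)
            sc = compute_score(sub, aligned, variant)
            sc = adjust_and_standardize(
                sc, sub.phenotype[gwas_scan.COVARIATE_COLUMNS].to_numpy(float))
            ev = evaluate_score(sub, sc, terms, ph_test=False)
            rows.append({"fraction": frac, "repeat": rep, "n": ev.n,
                         "n_events": ev.n_events, "beta": ev.beta_score,
                         "se": ev.se, "p": ev.p})
    return pd.DataFrame(rows)
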
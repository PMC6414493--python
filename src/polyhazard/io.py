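"""File interfaces: weight tables, summary statistics, cohorts (VCF or TSV).

All tabular formats are TSV with ``NA`` for missing values and 1-based
genomic positions.  Genotypes come either from a VCF (v4.x; the DS FORMAT
field when present, otherwise GT converted to an alternate-allele dosage)
or from a sample × variant dosage TSV accompanied by a variant metadata
TSV.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .polygenic_scores import APOE_IDS, WeightTable
from .synthetic_cohort import PHENOTYPE_COLUMNS, CohortData

__all__ = [
    "load_published_weights", "load_weight_table", "write_weight_table",
    "read_summary_stats", "write_summary_stats",
    "load_cohort", "write_cohort", "write_vcf",
    "build_synthetic_published_cohort",
]

_SUMMARY_COLS = {"id": "id", "chr": "chromosome", "pos": "position",
                 "a1": "effect_allele", "a2": "other_allele", "beta": "beta",
                 "se": "se", "p": "p", "n": "n_used", "model": "model"}

#: published per-allele weights: APOE ε2/ε4 plus 31 AD risk SNPs, with log
#: hazard-ratio and log odds-ratio columns from the source GWAS
PUBLISHED_WEIGHT_SOURCES = {
    "phs": "log_hr",
    "igap": "log_or_igap",
    "igap_nogerad": "log_or_igap_nogerad",
}


def load_published_weights(source: str = "phs") -> WeightTable:
    """Load the packaged APOE + 31-SNP weight fixture.

    ``source`` selects the weight column: ``phs`` (log hazard ratios used
    for polygenic hazard scores), ``igap`` or ``igap_nogerad`` (log odds
    ratios from the case/control meta-analyses).  The effect-allele column
    follows the ``igap_nogerad`` coding as published; sign conventions between
    the odds-ratio columns are preserved verbatim, so allele alignment is
    the consumer's responsibility.
    """
    if source not in PUBLISHED_WEIGHT_SOURCES:
        raise ValueError(f"unknown weight source {source!r}; "
                         f"choose from {sorted(PUBLISHED_WEIGHT_SOURCES)}")
    col = PUBLISHED_WEIGHT_SOURCES[source]
    ref = resources.files("polyhazard") / "data" / "ad_phs_weights.tsv"
    with resources.as_file(ref) as path:
        raw = pd.read_csv(path, sep="\t", na_values="NA")
    apoe = raw["snp"].isin(APOE_IDS)
    if apoe.sum() != 2 or (~apoe).sum() != 31:
        raise ValueError("packaged weight fixture corrupted: expected 2 APOE "
                         f"rows + 31 SNP rows, found {apoe.sum()} + {(~apoe).sum()}")
    table = pd.DataFrame({
        "id": raw["snp"],
        "chromosome": raw["chr"].astype(str),
        "position": raw["pos"],
        "effect_allele": raw["a1"],
        "weight": raw[col].astype(float),
        "source": f"published_{source}",
    })
    return WeightTable(table)


def load_weight_table(path) -> WeightTable:
    """Read a weight TSV (id, chr, pos, effect_allele, weight, source)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str}, na_values="NA")
    need = {"id", "chr", "pos", "effect_allele", "weight"}
    if missing := need - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = pd.to_numeric(df["weight"], errors="coerce").isna() & df["weight"].notna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: non-numeric weight on line(s) {lines}")
    if df["weight"].isna().any():
        lines = (df.index[df["weight"].isna()] + 2).tolist()
        raise ValueError(f"{path}: missing weight on line(s) {lines}")
    table = df.rename(columns={"chr": "chromosome", "pos": "position"})
    if "source" not in table:
        table["source"] = str(path)
    return WeightTable(table[["id", "chromosome", "position", "effect_allele",
                              "weight", "source"]])


def write_weight_table(weights: WeightTable, path):
    out = weights.table.rename(columns={"chromosome": "chr", "pos": "position"})
    out = out.rename(columns={"position": "pos"})
    cols = ["id", "chr", "pos", "effect_allele", "weight", "source"]
    out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def write_summary_stats(stats: pd.DataFrame, path):
    """Write scan output as TSV (id, chr, pos, a1, a2, beta, se, p, n, model)."""
    inv = {v: k for k, v in _SUMMARY_COLS.items()}
    out = stats.rename(columns=inv)
    out[list(_SUMMARY_COLS)].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str}, na_values="NA")
    if missing := set(_SUMMARY_COLS) - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df.rename(columns=_SUMMARY_COLS)


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    dosage_rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # bi-allelic variants only
        fmts = v.FORMAT
        if "DS" in fmts:
            d = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        else:
            gt = np.asarray(v.gt_types, dtype=float)  # 0/1/3 calls, 2 unknown
            d = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        dosage_rows.append(d)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if not dosage_rows:
        raise ValueError(f"{path}: no usable bi-allelic variants")
    meta = pd.DataFrame({
        "id": ids, "chromosome": chroms, "position": poss,
        "effect_allele": alts, "other_allele": refs,  # dosage counts ALT
        "true_beta": np.nan,
    })
    return np.column_stack(dosage_rows), meta, samples


def load_cohort(phenotypes, vcf=None, genotypes=None, variants=None) -> CohortData:
    """Assemble a cohort from a phenotype TSV plus genotypes.

    Genotypes come from ``vcf`` or from a dosage TSV (``genotypes``, rows =
    individuals with an ``id`` first column) with a variant TSV
    (``variants``: id, chr, pos, effect_allele, other_allele).  Phenotype
    rows are matched to genotype samples by id and must cover them all.
    """
    ph = pd.read_csv(phenotypes, sep="\t", na_values="NA", dtype={"id": str})
    if missing := set(PHENOTYPE_COLUMNS) - set(ph.columns):
        raise ValueError(f"{phenotypes}: missing columns {sorted(missing)}")
    if vcf is not None:
        D, meta, samples = _read_vcf(vcf)
    elif genotypes is not None and variants is not None:
        g = pd.read_csv(genotypes, sep="\t", na_values="NA", dtype={"id": str})
        samples = g["id"].tolist()
        D = g.drop(columns="id").to_numpy(float)
        vm = pd.read_csv(variants, sep="\t", dtype={"chr": str}, na_values="NA")
        need = {"id", "chr", "pos", "effect_allele", "other_allele"}
        if missing := need - set(vm.columns):
            raise ValueError(f"{variants}: missing columns {sorted(missing)}")
        meta = vm.rename(columns={"chr": "chromosome", "pos": "position"})
        if "true_beta" not in meta:
            meta["true_beta"] = np.nan
        if list(g.columns[1:]) != list(meta["id"]):
            raise ValueError("genotype columns and variant ids disagree")
    else:
        raise ValueError("provide either vcf= or genotypes= and variants=")
    ph = ph.set_index("id").reindex(samples)
    if ph["status"].isna().any():
        lost = ph.index[ph["status"].isna()].tolist()[:5]
        raise ValueError(f"phenotype table lacks genotyped individuals, e.g. {lost}")
    ph = ph.reset_index()
    order = meta.sort_values(["chromosome", "position"], kind="stable").index.to_numpy()
    return CohortData(D[:, order], meta.iloc[order].reset_index(drop=True), ph).validate()


def write_cohort(cohort: CohortData, out_dir):
    """Write phenotype.tsv, genotypes.tsv and variants.tsv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ph = cohort.phenotype
    if ph is not None:
        cols = [c for c in ph.columns if c != "true_eta"]
        ph[cols].to_csv(out / "phenotype.tsv", sep="\t", index=False, na_rep="NA")
    vm = cohort.variant_meta.rename(columns={"chromosome": "chr", "position": "pos"})
    keep = [c for c in ["id", "chr", "pos", "effect_allele", "other_allele", "true_beta"]
            if c in vm.columns]
    vm[keep].to_csv(out / "variants.tsv", sep="\t", index=False, na_rep="NA")
    g = pd.DataFrame(cohort.dosages, columns=cohort.variant_meta["id"])
    ids = ph["id"] if ph is not None else pd.RangeIndex(cohort.n_individuals).astype(str)
    g.insert(0, "id", list(ids))
    g.to_csv(out / "genotypes.tsv", sep="\t", index=False, na_rep="NA",
             float_format="%.6g")
    return out


def write_vcf(cohort: CohortData, path):
    """Minimal VCF 4.2 with DS (dosage) genotype fields."""
    ph = cohort.phenotype
    ids = list(ph["id"]) if ph is not None else [
        f"s{i}" for i in range(cohort.n_individuals)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        vm = cohort.variant_meta
        for j in range(cohort.n_variants):
            row = [str(vm["chromosome"].iat[j]), str(int(vm["position"].iat[j])),
                   str(vm["id"].iat[j]), str(vm["other_allele"].iat[j]),
                   str(vm["effect_allele"].iat[j]), ".", "PASS", ".", "GT:DS"]
            for d in cohort.dosages[:, j]:
                if np.isnan(d):
                    row.append("./.:.")
                else:
                    gt = "0/0" if d < 0.5 else ("0/1" if d < 1.5 else "1/1")
                    row.append(f"{gt}:{d:.3f}")
            fh.write("\t".join(row) + "\n")
    return path


def build_synthetic_published_cohort(n_individuals: int = 8000, seed: int = 0,
                                     **config_overrides):
    """Synthetic cohort whose variants mirror the packaged weight table.

    Generates independent genotypes for the 31 published SNPs (ids,
    chromosomes, positions and effect alleles taken from the packaged
    table, dosages counting the table's effect allele) and draws onset
    ages under the published log hazard-ratio weights, APOE ε2/ε4
    included.  This is a synthetic stand-in for an access-controlled
    case/control cohort: it lets the published-weight analyses run end to
    end, but its LD structure (none) and allele frequencies are invented.
    """
    from .synthetic_cohort import (CohortConfig, CohortData,
                                   simulate_genotypes, simulate_onset)

    w = load_published_weights("phs")
    snps = w.snp_rows.sort_values(["chromosome", "position"]).reset_index(drop=True)
    m = len(snps)
    cfg = CohortConfig(n_individuals=n_individuals, n_snps=m, n_blocks=m,
                       n_causal=0, seed=seed, **config_overrides)
    geno = simulate_genotypes(cfg)
    meta = geno.variant_meta
    meta["id"] = snps["id"].to_numpy()
    meta["chromosome"] = snps["chromosome"].astype(str).to_numpy()
    meta["position"] = snps["position"].astype(int).to_numpy()
    meta["effect_allele"] = snps["effect_allele"].to_numpy()
    meta["other_allele"] = np.where(snps["effect_allele"] == "G", "T", "G")
    meta["true_beta"] = snps["weight"].to_numpy(float)
    return simulate_onset(CohortData(geno.dosages, meta), cfg)
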
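"""File formats and quality control.

Reads genotype dosages from VCF (DS preferred, GT fallback) or a
tab-delimited matrix, writes both back, and applies the marker/individual
filters used before sequence-level imputation: call rate >= 0.95,
MAF >= 0.01, Hardy-Weinberg chi-square p >= 0.001, at most 10 Mendelian
inconsistencies per marker, individual genotyping rate >= 0.90, and the
post-imputation filters MAF >= 0.02 and imputation accuracy >= 0.80.
Phenotypes are pre-corrected for age with a quadratic regression and for
contemporary-group effects by group-mean removal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationTable, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Per-filter counts of removed variants/individuals plus thresholds."""

    thresholds: dict = field(default_factory=dict)
    removed_variants: dict = field(default_factory=dict)
    removed_individuals: dict = field(default_factory=dict)
    skipped_filters: list[str] = field(default_factory=list)
    input_variants: int = 0
    retained_variants: int = 0
    input_individuals: int = 0
    retained_individuals: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=int)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _read_vcf(path: str) -> tuple[GenotypeMatrix, int]:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    rows, meta = [], []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            logger.warning("multi-allelic record excluded at %s:%d", rec.CHROM, rec.POS)
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = np.array(ds, dtype=float).reshape(-1)
            dos = np.where((dos < -0.5) | (dos > 2.5), np.nan, dos)
        else:
            gt = rec.genotype.array()  # (n, ploidy+1)
            alleles = gt[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            dos = alleles.sum(axis=1)
        acc = rec.INFO.get("R2")
        rows.append(dos)
        meta.append(
            {
                "variant_id": rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "accuracy": float(acc) if acc is not None else np.nan,
            }
        )
    if not rows:
        raise ValueError(f"{path}: no biallelic records")
    dosages = np.vstack(rows).T
    variants = pd.DataFrame(meta)
    variants["alt_freq"] = np.nanmean(dosages, axis=0) / 2.0
    variants = variants[["variant_id", "chrom", "pos", "ref", "alt", "alt_freq", "accuracy"]]
    return (
        GenotypeMatrix(dosages=dosages, variants=variants, individual_ids=samples),
        n_multiallelic,
    )


def _read_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["variant_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in required + ["accuracy"]]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    dosages = df[sample_cols].to_numpy(dtype=float).T
    variants = df[required].copy()
    variants["alt_freq"] = np.nanmean(dosages, axis=0) / 2.0
    variants["accuracy"] = df["accuracy"] if "accuracy" in df.columns else np.nan
    return GenotypeMatrix(dosages=dosages, variants=variants, individual_ids=sample_cols)


def read_genotypes(path: str, format: str = "vcf") -> tuple[GenotypeMatrix, QcReport]:
    """Read a dosage matrix; multi-allelic VCF records are excluded and counted."""
    report = QcReport()
    if format == "vcf":
        geno, n_multi = _read_vcf(path)
        report.removed_variants["multiallelic"] = n_multi
    elif format == "tsv":
        geno = _read_tsv(path)
    else:
        raise ValueError(f"unknown format: {format}")
    report.input_variants = geno.n_variants + report.removed_variants.get("multiallelic", 0)
    report.retained_variants = geno.n_variants
    report.input_individuals = report.retained_individuals = geno.n_individuals
    return geno, report


def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write an uncompressed VCF 4.2 with GT (rounded) and DS fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation accuracy">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        for chrom in geno.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids) + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in geno.variants.iterrows():
            acc = row["accuracy"]
            info = f"R2={acc:.4f}" if np.isfinite(acc) else "."
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["variant_id"]),
                str(row["ref"]), str(row["alt"]), ".", "PASS", info, "GT:DS",
            ]
            for d in geno.dosages[:, j]:
                if not np.isfinite(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(np.clip(d, 0, 2)))]}:{d:.4f}")
            fh.write("\t".join(fields) + "\n")


def write_tsv(geno: GenotypeMatrix, path: str) -> None:
    df = geno.variants[["variant_id", "chrom", "pos", "ref", "alt", "accuracy"]].copy()
    body = pd.DataFrame(
        geno.dosages.T, columns=geno.individual_ids, index=df.index
    ).round(4)
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False, na_rep="")


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    df = pheno.to_frame()
    df.insert(0, "individual_id", df.index)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_phenotypes(path: str) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    ids = df["individual_id"].astype(str).tolist()
    value_cols = [c for c in df.columns if c not in ("individual_id", "age", "group")]
    raw_cols = [c for c in ("age", "group") if c in df.columns]
    return PhenotypeTable(
        individual_ids=ids,
        trait_names=value_cols,
        values=df[value_cols].to_numpy(dtype=float),
        raw=df[["individual_id"] + raw_cols] if raw_cols else None,
    )


def write_annotations(annot: AnnotationTable, path: str) -> None:
    annot.table.to_csv(path, sep="\t", index=False, na_rep="")


def read_annotations(path: str) -> AnnotationTable:
    return AnnotationTable(table=pd.read_csv(path, sep="\t"))


def read_bed(path: str) -> pd.DataFrame:
    """Parse a BED file (0-based half-open) into chrom/start/end."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer BED coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{ln}: end < start")
            rows.append({"chrom": parts[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def hwe_chisq_p(n_ref: int, n_het: int, n_alt: int) -> float:
    """1-df chi-square Hardy-Weinberg test on hard genotype counts."""
    n = n_ref + n_het + n_alt
    if n == 0:
        return 1.0
    p = (2 * n_alt + n_het) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_ref, n_het, n_alt], dtype=float)
    ok = exp > 0
    chi2 = float(np.sum((obs[ok] - exp[ok]) ** 2 / exp[ok]))
    return float(stats.chi2.sf(chi2, df=1))


def mendelian_inconsistencies(
    geno: GenotypeMatrix, trios: list[tuple[str, str]]
) -> np.ndarray:
    """Count opposite-homozygote parent/offspring conflicts per variant."""
    id_index = {s: i for i, s in enumerate(geno.individual_ids)}
    for pair in trios:
        for s in pair:
            if s not in id_index:
                raise ValueError(f"trio references unknown individual: {s}")
    hard = np.round(geno.dosages)
    counts = np.zeros(geno.n_variants, dtype=int)
    for parent, child in trios:
        a = hard[id_index[parent]]
        b = hard[id_index[child]]
        conflict = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
        counts += np.where(np.isfinite(a) & np.isfinite(b), conflict, False)
    return counts


def qc_variants(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    hwe_p_min: float = 0.001,
    max_mendel: int = 10,
    trios: list[tuple[str, str]] | None = None,
    min_imputed_maf: float = 0.02,
    min_accuracy: float = 0.80,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply marker filters; a variant is retained iff it passes all applicable ones.

    Filters needing absent metadata (accuracy, trios) are skipped and logged.
    Thresholds follow "lower than" wording: the boundary value is retained.
    """
    report = QcReport(
        thresholds={
            "min_call_rate": min_call_rate,
            "min_maf": min_maf,
            "hwe_p_min": hwe_p_min,
            "max_mendel": max_mendel,
            "min_imputed_maf": min_imputed_maf,
            "min_accuracy": min_accuracy,
        },
        input_variants=geno.n_variants,
        input_individuals=geno.n_individuals,
        retained_individuals=geno.n_individuals,
    )
    keep = np.ones(geno.n_variants, dtype=bool)

    def apply(name: str, fail_mask: np.ndarray) -> None:
        newly = fail_mask & keep
        report.removed_variants[name] = int(newly.sum())
        keep[newly] = False

    apply("call_rate", geno.call_rate() < min_call_rate)
    maf = geno.maf()
    apply("maf", maf < min_maf)

    hard = np.round(geno.dosages)
    n_ref = np.nansum(hard == 0, axis=0)
    n_het = np.nansum(hard == 1, axis=0)
    n_alt = np.nansum(hard == 2, axis=0)
    hwe = np.array([hwe_chisq_p(a, b, c) for a, b, c in zip(n_ref, n_het, n_alt)])
    apply("hwe", hwe < hwe_p_min)

    if trios:
        apply("mendel", mendelian_inconsistencies(geno, trios) > max_mendel)
    else:
        report.skipped_filters.append("mendel (no trios supplied)")

    acc = geno.variants["accuracy"].to_numpy(dtype=float)
    if np.any(np.isfinite(acc)):
        apply("imputed_maf", maf < min_imputed_maf)
        apply("accuracy", ~np.isnan(acc) & (acc < min_accuracy))
    else:
        report.skipped_filters.append("imputation accuracy (no scores present)")

    out = geno.subset_variants(keep)
    report.retained_variants = out.n_variants
    return out, report


def qc_individuals(
    geno: GenotypeMatrix, min_genotyping_rate: float = 0.90
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop individuals whose genotyping rate is lower than the threshold."""
    rate = np.mean(np.isfinite(geno.dosages), axis=1)
    keep = rate >= min_genotyping_rate
    if not keep.any():
        raise ValueError("all individuals removed by genotyping-rate filter")
    report = QcReport(
        thresholds={"min_genotyping_rate": min_genotyping_rate},
        input_variants=geno.n_variants,
        retained_variants=geno.n_variants,
        input_individuals=geno.n_individuals,
        retained_individuals=int(keep.sum()),
        removed_individuals={"genotyping_rate": int((~keep).sum())},
    )
    return geno.subset_individuals(keep), report


def precorrect_phenotypes(raw: PhenotypeTable) -> PhenotypeTable:
    """Residualize each trait on (age, age^2), then remove group means.

    Output deviations have zero mean within every contemporary group.
    Groups with a single record are logged; their deviation is exactly 0.
    """
    if raw.raw is None or "age" not in raw.raw.columns:
        raise ValueError("raw table must carry an 'age' column for pre-correction")
    age = raw.raw["age"].to_numpy(dtype=float)
    groups = (
        raw.raw["group"].to_numpy()
        if "group" in raw.raw.columns
        else np.zeros(len(age), dtype=int)
    )
    X = np.column_stack([np.ones_like(age), age, age**2])
    corrected = np.empty_like(raw.values)
    for t in range(raw.n_traits):
        y = raw.values[:, t]
        ok = np.isfinite(y) & np.isfinite(age)
        resid = np.full_like(y, np.nan)
        if ok.sum() >= 3:
            beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
            resid[ok] = y[ok] - X[ok] @ beta
        else:
            resid[ok] = y[ok] - np.nanmean(y[ok])
        for grp in pd.unique(groups):
            sel = (groups == grp) & np.isfinite(resid)
            if sel.sum() == 1:
                logger.info("contemporary group %r has a single record", grp)
            if sel.any():
                resid[sel] -= resid[sel].mean()
        corrected[:, t] = resid
    return PhenotypeTable(
        individual_ids=list(raw.individual_ids),
        trait_names=list(raw.trait_names),
        values=corrected,
        raw=raw.raw,
    )
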
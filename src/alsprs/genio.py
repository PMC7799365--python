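"""Genotype and tabular I/O plus small genotype-prep plumbing.

Dosage orientation is panel-driven: the SNP panel file (columns
``snp_id, chrom, pos, ref, alt, effect_allele, maf``) — not the VCF —
decides which allele is counted, so additive coding stays stable across
cohorts.  A VCF site whose alleles do not match the panel is a hard error.

TSV dialect: tab-separated, header row, UTF-8, ``.`` for missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_tsv",
    "write_tsv",
    "synthetic_panel",
    "read_panel",
    "read_genotypes",
    "write_vcf",
    "compute_pcs",
]

MISSING = "."


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def synthetic_panel(snp_ids: list[str], maf: np.ndarray) -> pd.DataFrame:
    """Panel table for simulator SNPs: synthetic chr/pos, ALT is the minor
    (effect) allele."""
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, len(snp_ids) + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "effect_allele": "G",
            "maf": np.asarray(maf, float),
        }
    )


def read_panel(path) -> pd.DataFrame:
    panel = read_tsv(path)
    required = {"snp_id", "ref", "alt", "effect_allele"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must provide columns {sorted(required)}")
    if panel["snp_id"].duplicated().any():
        dups = panel.loc[panel["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate panel SNP ids: {dups}")
    return panel


def _dosage_from_vcf(path, panel: pd.DataFrame) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = panel.set_index("snp_id")
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        vid = variant.ID
        if vid is None or vid not in wanted.index:
            continue
        row = wanted.loc[vid]
        if len(variant.ALT) != 1:
            raise ValueError(f"site {vid}: panel sites must be bi-allelic, got ALT={variant.ALT}")
        ref, alt = variant.REF, variant.ALT[0]
        if {ref, alt} != {row["ref"], row["alt"]}:
            raise ValueError(
                f"site {vid}: VCF alleles {ref}/{alt} do not match panel {row['ref']}/{row['alt']}"
            )
        eff = row["effect_allele"]
        if eff not in (ref, alt):
            raise ValueError(f"site {vid}: effect allele {eff} matches neither REF nor ALT")
        dose = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):  # half-missing counts as missing
                continue
            alt_count = sum(1 for a in alleles if a == 1)
            dose[i] = alt_count if eff == alt else len(alleles) - alt_count
        data[vid] = dose
    missing_sites = [s for s in wanted.index if s not in data]
    if missing_sites:
        raise ValueError(f"panel sites absent from VCF: {missing_sites}")
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))[list(wanted.index)]


def read_genotypes(
    path,
    panel: pd.DataFrame | str | Path,
    max_sample_missing: float = 0.2,
    max_snp_missing: float = 0.2,
) -> pd.DataFrame:
    """Subjects x SNPs effect-allele dosage matrix from a VCF or dosage TSV.

    TSV input must already be 0/1/2 coded with a ``subject_id`` column and
    is validated against the panel's SNP list.  Missingness above the
    configured per-sample / per-SNP thresholds raises, listing offenders;
    surviving missing entries stay NaN for downstream complete-case
    handling.
    """
    if not isinstance(panel, pd.DataFrame):
        panel = read_panel(panel)
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        dose = _dosage_from_vcf(path, panel)
    else:
        df = read_tsv(path)
        if "subject_id" not in df.columns:
            raise ValueError("dosage TSV must have a subject_id column")
        dose = df.set_index("subject_id")
        absent = [s for s in panel["snp_id"] if s not in dose.columns]
        if absent:
            raise ValueError(f"panel sites absent from dosage table: {absent}")
        dose = dose[list(panel["snp_id"])].astype(float)
        bad = dose.stack().dropna()
        if not bad.isin([0.0, 1.0, 2.0]).all():
            raise ValueError("dosage table contains values outside {0, 1, 2}")
    snp_missing = dose.isna().mean(axis=0)
    bad_snps = snp_missing[snp_missing > max_snp_missing]
    if len(bad_snps):
        raise ValueError(f"SNPs above missingness threshold: {dict(bad_snps.round(3))}")
    sample_missing = dose.isna().mean(axis=1)
    bad_samples = sample_missing[sample_missing > max_sample_missing]
    if len(bad_samples):
        raise ValueError(f"samples above missingness threshold: {dict(bad_samples.round(3))}")
    flagged = dose.index[dose.isna().any(axis=1)]
    if len(flagged):
        logger.info("%d subject(s) carry missing genotypes", len(flagged))
    return dose


def write_vcf(dosages: pd.DataFrame, panel: pd.DataFrame, path) -> None:
    """Minimal VCF 4.2 with one GT record per panel SNP.

    Dosage counts the panel's effect allele; genotypes are emitted as
    unphased ALT-allele counts.
    """
    panel = panel.set_index("snp_id")
    samples = list(dosages.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_by_alt_count = {0: "0/0", 1: "0/1", 2: "1/1"}
    for snp in dosages.columns:
        row = panel.loc[snp]
        eff_is_alt = row["effect_allele"] == row["alt"]
        fields = [str(row.get("chrom", "1")), str(row.get("pos", 0)), snp, row["ref"], row["alt"], ".", "PASS", ".", "GT"]
        for s in samples:
            d = dosages.loc[s, snp]
            if np.isnan(d):
                fields.append("./.")
            else:
                alt_count = int(d) if eff_is_alt else 2 - int(d)
                fields.append(gt_by_alt_count[alt_count])
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def compute_pcs(dosages: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """First ``k`` principal-component scores of the genotype matrix.

    Columns are mean-imputed then z-scored (constant columns contribute
    nothing); scores come from the SVD of the standardised matrix.  Sign
    convention: each component is flipped so its largest-magnitude loading
    is positive.
    """
    if len(dosages) < k + 1:
        raise ValueError(f"need at least {k + 1} subjects for {k} components")
    m = dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(m, axis=0)
    idx = np.where(np.isnan(m))
    m[idx] = np.take(col_mean, idx[1])
    sd = m.std(axis=0, ddof=1)
    keep_sd = np.where(sd == 0, 1.0, sd)
    zs = (m - m.mean(axis=0)) / keep_sd
    zs[:, sd == 0] = 0.0
    u, s, vt = np.linalg.svd(zs, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(scores, index=dosages.index, columns=[f"PC{i + 1}" for i in range(k)])
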
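"""Genotype-panel file formats: PLINK bed/bim/fam, VCF, phenotype TSV.

The PLINK codec is self-contained: .bed is the standard SNP-major 2-bit
encoding (magic ``6c 1b 01``). Within this package dosages count copies of
``allele_b``, which is written as the .bim A2 column, so 2-bit code 0b00
(hom A1) maps to dosage 0 and 0b11 (hom A2) to dosage 2; 0b01 is missing.
"""

from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd

from transprs.synthetic_data import GenotypePanel

__all__ = ["write_plink", "read_plink", "write_vcf", "read_vcf", "write_phenotype", "read_phenotype"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of A2 (allele_b); 1 is the missing sentinel
_CODE_TO_DOSAGE = np.array([0.0, np.nan, 1.0, 2.0], dtype=np.float32)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write .bed/.bim/.fam; phenotype (if any) goes to the .fam column 6."""
    prefix = Path(prefix)
    vm = panel.variant_meta
    bim = pd.DataFrame(
        {
            "chrom": vm["chrom"],
            "id": vm["variant_id"],
            "cm": 0,
            "pos": vm["pos"],
            "a1": vm["allele_a"],
            "a2": vm["allele_b"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    pheno = panel.phenotype if panel.phenotype is not None else np.full(panel.n_samples, -9)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_meta["sample_id"],
            "iid": panel.sample_meta["sample_id"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": pheno,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = panel.dosages.shape
    d = panel.dosages
    codes = np.where(np.isnan(d), 1, np.where(d < 0.5, 0, np.where(d < 1.5, 2, 3))).astype(np.uint8)
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypePanel:
    """Read .bed/.bim/.fam back into a GenotypePanel (dosage counts A2)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "allele_a", "allele_b"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise ValueError("bed file size inconsistent with bim/fam dimensions")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    pheno = fam["pheno"].to_numpy(dtype=float)
    phenotype = None if np.all(pheno == -9) else pheno
    sample_meta = pd.DataFrame({"sample_id": fam["sample_id"], "population": "NA"})
    return GenotypePanel(
        dosages=dosages,
        variant_meta=bim[["variant_id", "chrom", "pos", "allele_a", "allele_b"]],
        sample_meta=sample_meta,
        phenotype=phenotype,
    )


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with GT and DS (dosage of ALT = allele_b)."""
    vm = panel.variant_meta
    samples = panel.sample_meta["sample_id"].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(panel.n_variants):
            col = panel.dosages[:, j]
            fields = []
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[int(round(d))]}:{d:g}")
            fh.write(
                f"{vm['chrom'].iloc[j]}\t{vm['pos'].iloc[j]}\t{vm['variant_id'].iloc[j]}\t"
                f"{vm['allele_a'].iloc[j]}\t{vm['allele_b'].iloc[j]}\t.\t.\t.\tGT:DS\t"
                + "\t".join(fields)
                + "\n"
            )


def read_vcf(path) -> GenotypePanel:
    """Read a VCF into a GenotypePanel; DS is preferred over GT when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    records, rows = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "N"
        records.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), var.POS, var.REF, alt))
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = ds[:, 0].astype(np.float32)
            row[row < 0] = np.nan
        else:
            gts = np.asarray(var.gt_types, dtype=np.float32)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            row = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts)).astype(np.float32)
        rows.append(row)
    vm = pd.DataFrame(records, columns=["variant_id", "chrom", "pos", "allele_a", "allele_b"])
    dosages = np.vstack(rows).T if rows else np.zeros((len(samples), 0), dtype=np.float32)
    sm = pd.DataFrame({"sample_id": samples, "population": "NA"})
    return GenotypePanel(dosages=dosages, variant_meta=vm, sample_meta=sm)


def write_phenotype(panel: GenotypePanel, path) -> None:
    """Two-column TSV: sample_id, phenotype value."""
    if panel.phenotype is None:
        raise ValueError("panel has no phenotype")
    pd.DataFrame(
        {"sample_id": panel.sample_meta["sample_id"], "value": panel.phenotype}
    ).to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "value"} <= set(df.columns):
        raise ValueError("phenotype TSV needs columns: sample_id, value")
    return df
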
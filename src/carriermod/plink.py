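"""PLINK genotype file I/O: text .ped/.map and binary .bed/.bim/.fam.

Positions are 1-based (.bim/.map convention).  The binary codec follows the
standard SNP-major .bed layout (magic bytes 0x6c 0x1b 0x01; two bits per
call: 00 = homozygous A1, 10 = heterozygous, 11 = homozygous A2,
01 = missing); dosages count the A1 allele.  The .ped format records no
allele registry, so the text reader takes A1 as the lexicographically
smaller allele observed at each marker — lossless for matrices written by
:func:`write_ped_map` (alleles A/B) except for markers monomorphic in the
file, where the unseen allele is unrecoverable and dosages read as 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ValidationError
from .genotypes import MISSING, GenotypeMatrix

__all__ = ["write_ped_map", "read_ped_map", "write_bed_bim_fam", "read_bed_bim_fam"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def write_ped_map(
    gm: GenotypeMatrix, prefix: str | Path, phenotype: np.ndarray | None = None
) -> None:
    prefix = Path(prefix)
    snps = gm.snps
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")
    a1 = snps["a1"].to_numpy()
    a2 = snps["a2"].to_numpy()
    pheno = (
        np.full(gm.n_samples, -9)
        if phenotype is None
        else np.where(np.asarray(phenotype, dtype=bool), 2, 1)
    )
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(gm.n_samples):
            fields = [gm.family_ids[i], gm.sample_ids[i], "0", "0", "2", str(int(pheno[i]))]
            row = gm.calls[i]
            for j in range(gm.n_snps):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a2[j], a2[j]]
                elif g == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write("\t".join(map(str, fields)) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    snps = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"snp_id": str},
    )
    m = len(snps)
    sample_ids: list[str] = []
    family_ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_pairs: list[list[str]] = [[] for _ in range(m)]
    raw: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValidationError(
                    f"{prefix.with_suffix('.ped')}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            family_ids.append(parts[0])
            sample_ids.append(parts[1])
            raw.append(parts[6:])
    for alleles in raw:
        for j in range(m):
            for a in alleles[2 * j : 2 * j + 2]:
                if a != "0" and a not in allele_pairs[j]:
                    allele_pairs[j].append(a)
    a1_list, a2_list = [], []
    for j in range(m):
        seen = sorted(allele_pairs[j])
        if len(seen) > 2:
            raise ValidationError(f"marker {snps['snp_id'][j]} has >2 alleles")
        if len(seen) == 2:
            a1, a2 = seen
        elif len(seen) == 1:
            # monomorphic in the file: the unseen allele is unrecoverable, so
            # the seen allele is taken as A2 and all dosages read as 0
            a1, a2 = "0", seen[0]
        else:
            a1, a2 = "0", "0"
        a1_list.append(a1)
        a2_list.append(a2)
    calls = np.empty((len(sample_ids), m), dtype=np.int8)
    for i, alleles in enumerate(raw):
        for j in range(m):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                calls[i, j] = MISSING
            else:
                calls[i, j] = (a == a1_list[j]) + (b == a1_list[j])
    snps = snps.drop(columns=["cm"])
    snps["a1"] = a1_list
    snps["a2"] = a2_list
    return GenotypeMatrix(sample_ids, snps, calls, family_ids)


def write_bed_bim_fam(
    gm: GenotypeMatrix, prefix: str | Path, phenotype: np.ndarray | None = None
) -> None:
    prefix = Path(prefix)
    gm.snps.assign(cm=0)[["chrom", "snp_id", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    pheno = (
        np.full(gm.n_samples, -9)
        if phenotype is None
        else np.where(np.asarray(phenotype, dtype=bool), 2, 1)
    )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(gm.n_samples):
            fh.write(f"{gm.family_ids[i]}\t{gm.sample_ids[i]}\t0\t0\t2\t{int(pheno[i])}\n")
    # SNP-major 2-bit encoding
    code = np.empty(gm.calls.shape, dtype=np.uint8)  # (samples, snps)
    code[gm.calls == 2] = 0b00
    code[gm.calls == MISSING] = 0b01
    code[gm.calls == 1] = 0b10
    code[gm.calls == 0] = 0b11
    n = gm.n_samples
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.zeros((pad, gm.n_snps), dtype=np.uint8)])
    quads = code.T.reshape(gm.n_snps, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_bed_bim_fam(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    ).drop(columns=["cm"])
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise ValidationError(f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major .bed)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(data) != expected:
        raise ValidationError(
            f"{prefix.with_suffix('.bed')}: size {len(data)} != expected {expected} "
            f"for {n} samples x {m} SNPs"
        )
    packed = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    quads = np.stack(
        [packed & 0b11, (packed >> 2) & 0b11, (packed >> 4) & 0b11, (packed >> 6) & 0b11], axis=2
    ).reshape(m, -1)[:, :n]
    calls = np.empty((n, m), dtype=np.int8)
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    calls[:] = lut[quads].T
    return GenotypeMatrix(list(fam["iid"]), bim, calls, list(fam["fid"]))
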
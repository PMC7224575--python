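"""File I/O: delimited genotype/phenotype/kinship tables and PLINK 1 binary.

Delimited conventions (tab-separated): genotype files have a header row of SNP
ids and the sample id in the first column; phenotype files have columns
``sample_id`` and ``phenotype``; kinship files are square with sample ids as
both header row and first column. PLINK .bed is the standard SNP-major 2-bit
encoding; dosages count the A1 allele, missing calls become NaN.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_genotypes_text(path: str):
    """Read a samples x SNPs dosage table; returns (G, sample_ids, snp_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(s) for s in df.index], list(df.columns)


def write_genotypes_text(path: str, G, sample_ids, snp_ids) -> None:
    df = pd.DataFrame(np.asarray(G), index=sample_ids, columns=snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_phenotype(path: str):
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError(f"{path}: expected columns 'sample_id' and 'phenotype'")
    return df["phenotype"].to_numpy(dtype=float), [str(s) for s in df["sample_id"]]


def write_phenotype(path: str, y, sample_ids) -> None:
    pd.DataFrame({"sample_id": sample_ids, "phenotype": np.asarray(y)}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_kinship_text(path: str):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: kinship table must be square")
    return df.to_numpy(dtype=float), [str(s) for s in df.index]


def write_kinship_text(path: str, phi, sample_ids) -> None:
    df = pd.DataFrame(np.asarray(phi), index=sample_ids, columns=sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def align_samples(target_ids, ids, what: str) -> np.ndarray:
    """Index of each target id inside ``ids``; errors list the missing ids."""
    pos = {s: i for i, s in enumerate(ids)}
    missing = [s for s in target_ids if s not in pos]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(f"{what}: missing sample ids: {shown}"
                         + ("..." if len(missing) > 10 else ""))
    return np.array([pos[s] for s in target_ids], dtype=int)


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet


def read_plink(prefix: str):
    """Read ``prefix``.bed/.bim/.fam; returns (G, sample_ids, snp_ids).

    G is samples x SNPs with A1-allele dosages in {0, 1, 2} and NaN for
    missing calls.
    """
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    sample_ids = list(fam[1])
    snp_ids = list(bim[1])
    n, m = len(sample_ids), len(snp_ids)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _PLINK_MAGIC:
            raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1 .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bpv = (n + 3) // 4  # bytes per variant
    if raw.size != bpv * m:
        raise ValueError(f"{prefix}.bed: size does not match .fam/.bim")
    raw = raw.reshape(m, bpv)
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    G = _BED_DECODE[codes[:, :n]].T
    return G, sample_ids, snp_ids


def write_plink(prefix: str, G, sample_ids, snp_ids) -> None:
    """Write a dosage matrix as a PLINK 1 triplet (chromosome 1, dummy map)."""
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    fam = pd.DataFrame({0: sample_ids, 1: sample_ids, 2: 0, 3: 0, 4: 0, 5: -9})
    fam.to_csv(prefix + ".fam", sep=" ", header=False, index=False)
    bim = pd.DataFrame({0: 1, 1: snp_ids, 2: 0, 3: np.arange(1, m + 1),
                        4: "A", 5: "B"})
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    # dosage -> 2-bit code (inverse of _BED_DECODE)
    code = np.full(G.shape, 0b01, dtype=np.uint8)  # missing
    code[G == 2.0] = 0b00
    code[G == 1.0] = 0b10
    code[G == 0.0] = 0b11
    bpv = (n + 3) // 4
    padded = np.zeros((m, bpv * 4), dtype=np.uint8)
    padded[:, :n] = code.T
    packed = np.zeros((m, bpv), dtype=np.uint8)
    for shift in range(4):
        packed |= padded[:, shift::4] << (2 * shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


def read_genotypes_any(path: str):
    """Dispatch on path: PLINK prefix (``.bed`` exists) or delimited text."""
    if os.path.exists(path + ".bed"):
        return read_plink(path)
    if path.endswith(".bed"):
        return read_plink(path[:-4])
    return read_genotypes_text(path)
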
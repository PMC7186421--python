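"""PLINK 1 binary (.bed/.bim/.fam) and GCTA binary GRM triplet I/O.

The .bed writer emits SNP-major v1.00 files (magic bytes 0x6c 0x1b 0x01) with
the standard 2-bit codes: 00 = homozygous A1 (dosage 2 of allele 1),
10 = heterozygous, 11 = homozygous A2 (dosage 0), 01 = missing.  Dosages in
this package count copies of allele 1 (the reference allele).

The GCTA GRM triplet is ``prefix.grm.bin`` (float32 lower triangle including
the diagonal, row by row), ``prefix.grm.N.bin`` (float32 SNP count per pair)
and ``prefix.grm.id`` (FID / IID, tab separated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grm import GRMatrix
from .synthpop import GenotypeMatrix

__all__ = ["write_plink", "read_plink", "write_grm_gcta", "read_grm_gcta",
           "write_pheno_table", "read_pheno_table"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage of allele1 -> 2-bit code, and back
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def write_plink(G: GenotypeMatrix, prefix: str) -> None:
    """Write a GenotypeMatrix as a PLINK .bed/.bim/.fam triplet."""
    n, L = G.dosages.shape
    vm = G.variant_meta
    sm = G.sample_meta

    with open(f"{prefix}.bim", "w") as fh:
        for row in vm.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")

    with open(f"{prefix}.fam", "w") as fh:
        for row in sm.itertuples(index=False):
            fh.write(f"{row.fid}\t{row.iid}\t0\t0\t0\t-9\n")

    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.empty(n_bytes, dtype=np.uint8)
        for l in range(L):
            buf[:] = 0
            col = G.dosages[:, l]
            for i in range(n):
                v = col[i]
                code = 0b01 if np.isnan(v) else _DOSAGE_TO_CODE[v]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(buf.tobytes())


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet into a GenotypeMatrix."""
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"a1": str, "a2": str})
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    n, L = len(fam), len(bim)

    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK v1.00 file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)

    n_bytes = (n + 3) // 4
    if raw.size != n_bytes * L:
        raise ValueError(f"{prefix}.bed has unexpected size")
    raw = raw.reshape(L, n_bytes)

    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((L, n_bytes * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T          # n x L

    variant_meta = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    sample_meta = fam[["fid", "iid"]].copy()
    sample_meta["pop"] = "NA"
    return GenotypeMatrix(dosages, variant_meta, sample_meta)


def write_grm_gcta(A: GRMatrix, prefix: str) -> None:
    """Write a GRM as the GCTA binary triplet (float32 lower triangle)."""
    n = A.n
    iu = np.tril_indices(n)
    # GCTA stores row i, columns 0..i — tril_indices already yields that order
    vals = A.values[iu].astype(np.float32)
    vals.tofile(f"{prefix}.grm.bin")
    np.full(vals.shape, A.n_snps_used, dtype=np.float32).tofile(f"{prefix}.grm.N.bin")
    A.sample_ids.to_csv(f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(prefix: str) -> GRMatrix:
    """Read a GCTA binary GRM triplet."""
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32)
    if vals.size != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin has unexpected size for n={n}")
    A = np.zeros((n, n))
    iu = np.tril_indices(n)
    A[iu] = vals
    A = A + A.T - np.diag(np.diag(A))
    nsnp = np.fromfile(f"{prefix}.grm.N.bin", dtype=np.float32)
    n_snps = int(nsnp[0]) if nsnp.size else 0
    return GRMatrix(A, n_snps, ids)


def write_pheno_table(df: pd.DataFrame, path: str) -> None:
    """Write an FID/IID-keyed phenotype or covariate table as TSV."""
    if list(df.columns[:2]) != ["fid", "iid"]:
        raise ValueError("table must start with fid, iid columns")
    df.to_csv(path, sep="\t", index=False)


def read_pheno_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() if c.lower() in ("fid", "iid") else c
                  for c in df.columns]
    if list(df.columns[:2]) != ["fid", "iid"]:
        raise ValueError(f"{path} must start with FID and IID columns")
    return df
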
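"""Readers and writers for the formats the pipeline touches.

PLINK 1 binary (bed/bim/fam, SNP-major), tab-separated expression matrices
and probe annotation, GMT gene-set collections, and YAML-style key-value
configuration.  The bed codec follows the documented 2-bit dialect: per
sample, ``00`` = homozygous allele1, ``01`` = missing, ``10`` = heterozygous,
``11`` = homozygous allele2, packed low bits first; dosages count copies of
the ``.bim`` first allele.  Writing then reading reproduces the bed file
byte-for-byte (padding bits are written as zero).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd
import yaml

from .types import MISSING, ExpressionDataset, FormatError, GenotypeDataset

_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# 2-bit code -> allele1 dosage
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}

# byte value -> the four dosages it packs (low bit-pair = first sample)
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


def read_plink(prefix: Union[str, Path]) -> GenotypeDataset:
    """Read a PLINK 1 bed/bim/fam triple given its shared path prefix."""
    prefix = str(prefix)
    return read_plink_files(prefix + ".bed", prefix + ".bim", prefix + ".fam")


def read_plink_files(bed_path, bim_path, fam_path) -> GenotypeDataset:
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK bed file (bad magic bytes)")
    if raw[2:3] != _SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major mode (0x01) is supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise FormatError(
            f"{bed_path}: truncated or oversized body "
            f"({body.size} bytes, expected {bytes_per_snp * m})"
        )
    # (m, bytes_per_snp, 4) -> drop padding -> (n, m)
    dosages = _BYTE_LUT[body.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n].T

    # fam phenotype: 1 = control, 2 = case; anything else treated as control
    phenotype = (fam["pheno"].to_numpy() == 2).astype(np.int64)
    samples = pd.DataFrame(
        {"sample_id": fam["iid"], "cohort": fam["fid"], "phenotype": phenotype}
    )
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeDataset(genotypes=np.ascontiguousarray(dosages), samples=samples, snps=snps)


def write_plink(dataset: GenotypeDataset, out_prefix: Union[str, Path]) -> None:
    """Write a bed/bim/fam triple; bit-exact round trip with :func:`read_plink`."""
    out_prefix = str(out_prefix)
    os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
    n, m = dataset.genotypes.shape
    bytes_per_snp = (n + 3) // 4

    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)  # pad code 00
    geno = dataset.genotypes.T  # (m, n)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][geno == dosage] = code
    shifted = codes.reshape(m, bytes_per_snp, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    body = np.bitwise_or.reduce(shifted, axis=2).astype(np.uint8)

    with open(out_prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC + _SNP_MAJOR)
        fh.write(body.tobytes())

    fam = pd.DataFrame(
        {
            "fid": dataset.samples["cohort"],
            "iid": dataset.samples["sample_id"],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": dataset.samples["phenotype"].map({0: 1, 1: 2}),
        }
    )
    fam.to_csv(out_prefix + ".fam", sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": dataset.snps["chrom"],
            "snp_id": dataset.snps["snp_id"],
            "cm": 0,
            "pos": dataset.snps["pos"],
            "a1": dataset.snps["a1"],
            "a2": dataset.snps["a2"],
        }
    )
    bim.to_csv(out_prefix + ".bim", sep="\t", header=False, index=False)


def write_expression(expr: ExpressionDataset, values_path, probes_path) -> None:
    """Write the log2 matrix (probes x samples) and probe annotation as TSV."""
    mat = pd.DataFrame(expr.values, index=expr.probes["probe_id"], columns=expr.samples)
    mat.to_csv(values_path, sep="\t", index_label="probe_id")
    expr.probes.to_csv(probes_path, sep="\t", index=False)


def read_expression(values_path, probes_path) -> ExpressionDataset:
    mat = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    probes = pd.read_csv(probes_path, sep="\t", dtype={"probe_id": str, "chrom": str})
    probes = probes.set_index("probe_id").loc[mat.index].reset_index()
    return ExpressionDataset(
        values=mat.to_numpy(dtype=float),
        probes=probes,
        samples=list(mat.columns),
    )


def read_gmt(path) -> Dict[str, List[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line with fewer than 3 fields: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Dict[str, List[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def load_config(path) -> dict:
    """Load a flat key-value (YAML-compatible) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
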
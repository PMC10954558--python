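"""Readers for the package's on-disk formats.

Matrix Market counts with barcode/feature sidecars, donor genotypes (long
TSV or VCF), per-nucleus SNP allele observations, the ground-truth JSON
written by the simulator, and GMT gene-set collections.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import sparse
from scipy.io import mmread

__all__ = [
    "read_counts_dir",
    "read_genotypes",
    "read_snp_observations",
    "read_ground_truth",
    "read_gmt",
]


def read_counts_dir(directory: str | Path):
    """Read one village's counts: (csr genes x cells, gene_ids, barcodes)."""
    directory = Path(directory)
    counts = sparse.csr_matrix(mmread(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "features.tsv", header=None)[0].tolist()
    barcodes = pd.read_csv(directory / "barcodes.tsv", header=None)[0].tolist()
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError("matrix dimensions do not match features/barcodes")
    return counts, genes, barcodes


def _read_genotypes_vcf(path: Path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF genotypes requires cyvcf2") from exc
    vcf = VCF(str(path))
    donors = list(vcf.samples)
    snp_ids, rows = [], []
    for variant in vcf:
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        rows.append([g[0] + g[1] for g in variant.genotypes])
    vcf.close()
    return pd.DataFrame(rows, index=snp_ids, columns=donors).T.astype("int8")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Donor x SNP dosage matrix from a long TSV (snp_id, donor_id, dosage)
    or a VCF with GT fields (dosage = alt allele count)."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"}:
        return _read_genotypes_vcf(path)
    long = pd.read_csv(path, sep="\t")
    expected = {"snp_id", "donor_id", "dosage"}
    if not expected.issubset(long.columns):
        raise ValueError(f"genotype TSV needs columns {sorted(expected)}")
    wide = long.pivot(index="donor_id", columns="snp_id", values="dosage")
    if wide.isna().any().any():
        raise ValueError("genotype TSV is not a complete donor x SNP grid")
    # preserve first-appearance SNP order rather than alphabetical
    snp_order = long["snp_id"].drop_duplicates().tolist()
    donor_order = long["donor_id"].drop_duplicates().tolist()
    return wide.loc[donor_order, snp_order].astype("int8")


def read_snp_observations(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path, sep="\t")
    expected = {"barcode", "snp_id", "allele", "count"}
    if not expected.issubset(obs.columns):
        raise ValueError(f"SNP observation TSV needs columns {sorted(expected)}")
    return obs


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: tab-separated lines of (set name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
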
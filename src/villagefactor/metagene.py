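"""Metagene discovery and joint quantification of high-homology paralogs.

Reads from highly homologous gene families (the canonical example being the
complement genes C4A/C4B) map to multiple gene models at low mapping
quality, so their UMIs cannot be confidently assigned to a single member.
A UMI is associated with a single gene if at least one of its reads maps
uniquely at high quality; otherwise it is associated with the union of the
genes its low-quality reads hit.  Families of genes whose UMIs are
consistently co-ambiguous are discovered from these association sets and
quantified jointly as one "metagene" row (feature id "GENE1+GENE2"),
because the data give no basis for distributing the ambiguous UMIs among
members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetaGeneFamily",
    "umi_associations",
    "discover_metagenes",
    "count_metagene_umis",
    "validate_single_copy",
]

UNIQUE = "unique-high-quality"
MULTI = "multi-low-quality"


@dataclass(frozen=True)
class MetaGeneFamily:
    member_genes: tuple[str, ...]  # sorted, size >= 2
    supporting_umis: int
    purity: float

    @property
    def feature_id(self) -> str:
        return "+".join(self.member_genes)


def _norm_class(c: str) -> str:
    c = str(c).lower()
    if c.startswith("unique"):
        return UNIQUE
    if c.startswith("multi"):
        return MULTI
    raise ValueError(f"unknown mapq class {c!r}")


def umi_associations(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse read-level records to one association set per (cell, UMI).

    A UMI with at least one unique-high-quality read is associated with
    that single gene; unique reads to two or more different genes mark the
    UMI inconsistent (dropped to the discard bucket downstream).  A UMI
    with only multi-low-quality reads is associated with the union of the
    genes hit.

    Returns a DataFrame (cell_barcode, umi, genes, ambiguous) where
    ``genes`` is a sorted tuple; inconsistent UMIs have genes == ().
    """
    required = {"cell_barcode", "umi", "gene_id", "mapq_class"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if len(records) == 0:
        return pd.DataFrame(columns=["cell_barcode", "umi", "genes", "ambiguous"])
    rec = records.copy()
    rec["mapq_class"] = rec["mapq_class"].map(_norm_class)
    rows = []
    for (cell, umi), grp in rec.groupby(["cell_barcode", "umi"], sort=True):
        unique_genes = sorted(set(grp.loc[grp["mapq_class"] == UNIQUE, "gene_id"]))
        if len(unique_genes) == 1:
            rows.append((cell, umi, (unique_genes[0],), False))
        elif len(unique_genes) > 1:
            rows.append((cell, umi, (), False))  # chimeric evidence, discarded
        else:
            genes = tuple(sorted(set(grp["gene_id"])))
            rows.append((cell, umi, genes, len(genes) > 1))
    return pd.DataFrame(rows, columns=["cell_barcode", "umi", "genes", "ambiguous"])


def discover_metagenes(
    records: pd.DataFrame,
    min_support: int = 50,
    min_purity: float = 0.95,
) -> list[MetaGeneFamily]:
    """Find gene families from consistently co-ambiguous UMIs.

    A candidate family is a gene set S (|S| >= 2) observed as an
    association set with at least ``min_support`` supporting UMIs and
    purity >= ``min_purity``, where purity is the fraction of ambiguous
    UMIs touching any member of S whose association set equals S exactly.
    Overlapping candidates are resolved deterministically: higher purity
    wins, then larger support, then lexicographic member order.
    """
    assoc = umi_associations(records)
    if len(assoc) == 0:
        return []
    amb = assoc[assoc["ambiguous"]]
    set_counts = amb["genes"].value_counts()

    candidates = []
    for genes, n in set_counts.items():
        n = int(n)
        if n < min_support:
            continue
        # ambiguous UMIs touching any member of the candidate set
        touching = int(
            sum(int(c) for s, c in set_counts.items() if set(s) & set(genes))
        )
        purity = n / touching if touching else 0.0
        if purity >= min_purity:
            candidates.append(MetaGeneFamily(tuple(genes), n, purity))

    candidates.sort(key=lambda f: (-f.purity, -f.supporting_umis, f.member_genes))
    kept: list[MetaGeneFamily] = []
    used: set[str] = set()
    for fam in candidates:
        if used & set(fam.member_genes):
            continue
        kept.append(fam)
        used |= set(fam.member_genes)
    kept.sort(key=lambda f: f.member_genes)
    return kept


def count_metagene_umis(
    records: pd.DataFrame,
    families: list[MetaGeneFamily],
):
    """Count UMIs per gene and per metagene family, per cell.

    Unambiguous UMIs count to their single gene.  Ambiguous UMIs whose
    association set equals a family count once to that family's joint row.
    All remaining ambiguous or inconsistent UMIs fall into a discard
    bucket, so that

        sum(gene counts) + sum(metagene counts) + discarded == total UMIs.

    Returns (gene_counts, metagene_counts, discarded) with cells as
    columns; ``discarded`` is a per-cell Series.
    """
    fam_sets = {f.member_genes: f.feature_id for f in families}
    members = [g for f in families for g in f.member_genes]
    if len(set(members)) != len(members):
        raise ValueError("resolve overlaps first")

    assoc = umi_associations(records)
    cells = sorted(assoc["cell_barcode"].unique()) if len(assoc) else []
    gene_rows: dict[str, dict[str, int]] = {}
    meta_rows: dict[str, dict[str, int]] = {fid: {} for fid in fam_sets.values()}
    discarded: dict[str, int] = {c: 0 for c in cells}

    for row in assoc.itertuples(index=False):
        cell = row.cell_barcode
        if not row.ambiguous and len(row.genes) == 1:
            g = row.genes[0]
            gene_rows.setdefault(g, {})
            gene_rows[g][cell] = gene_rows[g].get(cell, 0) + 1
        elif row.genes in fam_sets:
            fid = fam_sets[row.genes]
            meta_rows[fid][cell] = meta_rows[fid].get(cell, 0) + 1
        else:
            discarded[cell] += 1

    gene_counts = pd.DataFrame(gene_rows).T.reindex(columns=cells).fillna(0).astype(int)
    gene_counts = gene_counts.sort_index()
    metagene_counts = (
        pd.DataFrame(meta_rows).T.reindex(columns=cells).fillna(0).astype(int)
    )
    metagene_counts = metagene_counts.sort_index()
    return gene_counts, metagene_counts, pd.Series(discarded, name="discarded")


def validate_single_copy(
    joint_counts: pd.DataFrame,
    oracle_counts: pd.DataFrame,
) -> dict:
    """Compare joint metagene counts to a collapsed single-copy oracle.

    The oracle is the per-cell count obtained by mapping the same reads to
    a reference with only one family copy, so every UMI maps uniquely.
    Returns a concordance report: fraction of cells where every shared
    family row agrees exactly, plus the discordant cells.
    """
    shared_cells = [c for c in joint_counts.columns if c in oracle_counts.columns]
    if not shared_cells:
        raise ValueError("no shared cell barcodes between joint and oracle counts")
    shared_rows = [r for r in joint_counts.index if r in oracle_counts.index]
    j = joint_counts.loc[shared_rows, shared_cells]
    o = oracle_counts.loc[shared_rows, shared_cells]
    equal = (j.to_numpy() == o.to_numpy()).all(axis=0)
    discordant = [c for c, ok in zip(shared_cells, equal) if not ok]
    return {
        "cells_total": len(shared_cells),
        "cells_concordant": int(equal.sum()),
        "concordance": float(equal.mean()),
        "discordant_cells": discordant,
    }
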
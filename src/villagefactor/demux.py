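"""SNP-based donor demultiplexing for pooled ("village") libraries.

Each nucleus carries allele observations at transcribed SNPs; combined over
hundreds of sites these identify the donor of origin.  Because most droplet
doublets in a 20-donor pool combine nuclei from two different donors, they
are recognizable as mixtures of two genotypes.

The allele model is linear error contamination:

    P(alt | dosage g, error eps) = (1 - 2 eps) * g / 2 + eps

which is exact at g in {0, 2} and unbiased at g = 1, and extends to the
50/50 doublet mixture by substituting the mean dosage (g1 + g2) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "DonorAssignment",
    "expected_cross_donor_fraction",
    "allele_loglik_matrix",
    "assign_nucleus",
    "classify_doublet",
    "demux_all",
]


@dataclass
class DonorAssignment:
    """Per-nucleus demultiplexing verdict."""

    barcode: str
    log_likelihoods: pd.Series  # per-donor singlet log-likelihoods
    best_donor: str | None
    margin: float  # best minus second-best, natural-log units
    status: str  # "singlet" | "doublet" | "ambiguous"
    best_pair: tuple[str, str] | None = None
    flags: list[str] = field(default_factory=list)


def expected_cross_donor_fraction(donor_proportions) -> float:
    """Expected fraction of doublets whose two nuclei come from distinct
    donors: 1 - sum_d p_d^2.  For 20 equal donors this is 0.95."""
    p = np.asarray(donor_proportions, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    return float(1.0 - np.sum(p**2))


def _p_alt(dosage: np.ndarray, error_rate: float) -> np.ndarray:
    return (1.0 - 2.0 * error_rate) * np.asarray(dosage, float) / 2.0 + error_rate


def _collapse_observations(
    obs: pd.DataFrame, max_count_per_snp: int | None
) -> pd.DataFrame:
    grouped = (
        obs.groupby(["snp_id", "allele"], sort=True)["count"].sum().reset_index()
    )
    if max_count_per_snp is not None:
        grouped["count"] = grouped["count"].clip(upper=max_count_per_snp)
    return grouped


def allele_loglik_matrix(
    obs: pd.DataFrame,
    genotypes: pd.DataFrame,
    error_rate: float,
    max_count_per_snp: int | None = 1,
) -> pd.Series:
    """Per-donor singlet log-likelihood of one nucleus's observations.

    ``obs`` has columns (snp_id, allele, count); ``genotypes`` is the
    donor x SNP dosage matrix.  Multi-read evidence at one SNP is capped at
    ``max_count_per_snp`` (default 1) to avoid pseudo-replication.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    collapsed = _collapse_observations(obs, max_count_per_snp)
    missing = set(collapsed["snp_id"]) - set(genotypes.columns)
    if missing:
        raise ValueError(f"observed SNPs absent from genotype panel: {sorted(missing)}")
    snp_pos = {s: j for j, s in enumerate(genotypes.columns)}
    idx = collapsed["snp_id"].map(snp_pos).to_numpy()
    is_alt = (collapsed["allele"] == "alt").to_numpy()
    counts = collapsed["count"].to_numpy(dtype=float)
    G = genotypes.to_numpy(dtype=float)[:, idx]  # donors x obs
    p_alt = _p_alt(G, error_rate)
    p = np.where(is_alt[None, :], p_alt, 1.0 - p_alt)
    ll = (counts[None, :] * np.log(p)).sum(axis=1)
    return pd.Series(ll, index=genotypes.index)


def assign_nucleus(
    obs: pd.DataFrame,
    genotypes: pd.DataFrame,
    error_rate: float = 0.01,
    margin_threshold: float = 2.0,
    max_count_per_snp: int | None = 1,
    barcode: str = "",
) -> DonorAssignment:
    """Assign one nucleus to its most likely donor.

    Status is "ambiguous" when the log-likelihood margin between the best
    and second-best donor falls below ``margin_threshold`` (natural-log
    units), or when there is no evidence at all.
    """
    if len(obs) == 0:
        ll = pd.Series(0.0, index=genotypes.index)
        return DonorAssignment(
            barcode=barcode, log_likelihoods=ll, best_donor=None,
            margin=0.0, status="ambiguous", flags=["no evidence"],
        )
    ll = allele_loglik_matrix(obs, genotypes, error_rate, max_count_per_snp)
    order = ll.sort_values(ascending=False)
    best = order.index[0]
    margin = (
        float(order.iloc[0] - order.iloc[1]) if len(order) > 1 else float("inf")
    )
    status = "singlet" if margin >= margin_threshold else "ambiguous"
    return DonorAssignment(
        barcode=barcode, log_likelihoods=ll,
        best_donor=best if status == "singlet" else best,
        margin=margin, status=status,
    )


def _pair_loglik(
    obs: pd.DataFrame,
    genotypes: pd.DataFrame,
    error_rate: float,
    max_count_per_snp: int | None,
) -> pd.DataFrame:
    """Log-likelihood of every ordered-free donor pair under a 50/50 mixture
    (mixture dosage (g1 + g2) / 2)."""
    collapsed = _collapse_observations(obs, max_count_per_snp)
    donors = list(genotypes.index)
    pairs = list(combinations(range(len(donors)), 2))
    G = genotypes.to_numpy(dtype=float)
    i1 = np.array([a for a, _ in pairs])
    i2 = np.array([b for _, b in pairs])
    snp_pos = {s: j for j, s in enumerate(genotypes.columns)}
    idx = collapsed["snp_id"].map(snp_pos).to_numpy()
    is_alt = (collapsed["allele"] == "alt").to_numpy()
    counts = collapsed["count"].to_numpy(dtype=float)
    g_mix = 0.5 * (G[i1][:, idx] + G[i2][:, idx])  # pairs x obs
    p_alt = _p_alt(g_mix, error_rate)
    p = np.where(is_alt[None, :], p_alt, 1.0 - p_alt)
    ll = (counts[None, :] * np.log(p)).sum(axis=1)
    return pd.DataFrame(
        {"donor1": [donors[a] for a in i1], "donor2": [donors[b] for b in i2],
         "loglik": ll}
    )


def classify_doublet(
    obs: pd.DataFrame,
    genotypes: pd.DataFrame,
    error_rate: float = 0.01,
    doublet_margin: float = 5.0,
    margin_threshold: float = 2.0,
    max_count_per_snp: int | None = 1,
    barcode: str = "",
) -> DonorAssignment:
    """Resolve singlet vs cross-donor doublet status for one nucleus.

    Evaluates the 50/50 two-donor mixture likelihood over all donor pairs;
    the nucleus is a doublet when the best pair beats the best singlet by at
    least ``doublet_margin`` log units.  Doublets of genotype-identical
    donors are indistinguishable from singlets by construction and are
    reported as singlet/ambiguous.
    """
    assignment = assign_nucleus(
        obs, genotypes, error_rate, margin_threshold, max_count_per_snp, barcode
    )
    if "no evidence" in assignment.flags or len(genotypes.index) < 2:
        return assignment
    pair_ll = _pair_loglik(obs, genotypes, error_rate, max_count_per_snp)
    best_pair_row = pair_ll.loc[pair_ll["loglik"].idxmax()]
    best_singlet_ll = float(assignment.log_likelihoods.max())
    if float(best_pair_row["loglik"]) - best_singlet_ll >= doublet_margin:
        assignment.status = "doublet"
        assignment.best_pair = (
            str(best_pair_row["donor1"]), str(best_pair_row["donor2"])
        )
    return assignment


def demux_all(
    snp_obs: pd.DataFrame,
    genotypes: pd.DataFrame,
    error_rate: float = 0.01,
    margin_threshold: float = 2.0,
    doublet_margin: float = 5.0,
    detect_doublets: bool = True,
    max_count_per_snp: int | None = 1,
) -> pd.DataFrame:
    """Demultiplex every barcode in a long SNP-observation table.

    Returns a DataFrame (barcode, best_donor, status, margin, best_pair).
    """
    rows = []
    for barcode, obs in snp_obs.groupby("barcode", sort=True):
        if detect_doublets:
            a = classify_doublet(
                obs, genotypes, error_rate, doublet_margin, margin_threshold,
                max_count_per_snp, barcode=barcode,
            )
        else:
            a = assign_nucleus(
                obs, genotypes, error_rate, margin_threshold,
                max_count_per_snp, barcode=barcode,
            )
        rows.append(
            (a.barcode, a.best_donor, a.status, a.margin,
             "+".join(a.best_pair) if a.best_pair else "")
        )
    return pd.DataFrame(
        rows, columns=["barcode", "best_donor", "status", "margin", "best_pair"]
    )
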
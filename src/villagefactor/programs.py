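"""Within-cell-type gene-expression program discovery by consensus NMF.

Repeated NMF restarts from random initializations are run on (variance-
normalized) counts for each candidate factor number k; the component
spectra from all restarts are L2-normalized, outlier components discarded,
and the remainder clustered into k consensus groups whose medians are the
consensus spectra.  Per-cell usages are refit by non-negative least
squares and normalized so each cell's usages sum to 1.  The per-k
stability (silhouette of the component clustering) and reconstruction
error guide the choice of k.  Donor-level program scores are the mean
normalized usage of each donor's cells, with an optional per-program sign
orientation so all related analyses read in the same direction.

Model/Results usage::

    model = ConsensusNMF(counts)
    res = model.fit(k_values=range(3, 31), restarts=20, seed=0)
    res.selection_report
    res.spectra(k=11)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import non_negative_factorization
from sklearn.metrics import silhouette_score

__all__ = [
    "filter_cells_genes",
    "ConsensusNMF",
    "ProgramResults",
    "usage_normalize",
    "donor_program_scores",
]


def filter_cells_genes(
    counts: pd.DataFrame,
    min_genes: int = 200,
    min_umis: int = 200,
    min_cells: int = 10,
):
    """Standard single-cell count filtering before factorization.

    Cells with fewer than ``min_genes`` detected genes or fewer than
    ``min_umis`` total UMIs are removed first; genes detected in fewer
    than ``min_cells`` of the surviving cells are then removed.  Returns
    (filtered counts, report dict).
    """
    X = counts.to_numpy()
    if np.any(X < 0) or np.any(X != np.round(X)):
        raise ValueError("counts must be non-negative integers")
    genes_per_cell = (X > 0).sum(axis=0)
    umis_per_cell = X.sum(axis=0)
    keep_cells = (genes_per_cell >= min_genes) & (umis_per_cell >= min_umis)
    sub = counts.loc[:, keep_cells]
    cells_per_gene = (sub.to_numpy() > 0).sum(axis=1)
    keep_genes = cells_per_gene >= min_cells
    out = sub.loc[keep_genes]
    if out.shape[0] == 0 or out.shape[1] == 0:
        raise ValueError("no cells survive filters")
    report = {
        "cells_removed": int((~keep_cells).sum()),
        "genes_removed": int((~keep_genes).sum()),
        "cells_kept": out.shape[1],
        "genes_kept": out.shape[0],
    }
    return out, report


def usage_normalize(usages: pd.DataFrame):
    """Scale each cell's total usage across all programs to 1.

    All-zero rows are flagged and left at zero.  Idempotent.
    """
    U = usages.to_numpy(dtype=float)
    if np.any(U < 0):
        raise ValueError("usages must be non-negative")
    sums = U.sum(axis=1)
    zero = sums == 0
    out = U.copy()
    out[~zero] = U[~zero] / sums[~zero, None]
    return (
        pd.DataFrame(out, index=usages.index, columns=usages.columns),
        list(usages.index[zero]),
    )


def donor_program_scores(
    usages: pd.DataFrame,
    cell_to_donor,
    orientation=None,
):
    """Mean normalized usage per donor and program, sign-oriented.

    ``orientation`` is +1/-1 per program (Series, dict or array), applied
    after averaging; programs whose natural NMF direction reads opposite
    to the rest of an analysis can be flipped (the "take the negative"
    convention).  Donors with zero cells are absent from the result and
    listed in the returned report.
    """
    donor_map = pd.Series(cell_to_donor)
    unmapped = [c for c in usages.index if c not in donor_map.index]
    if unmapped:
        raise ValueError(f"cells without a donor: {unmapped[:10]}")
    normalized, zero_rows = usage_normalize(usages)
    groups = donor_map.loc[normalized.index]
    means = normalized.groupby(groups.values).mean()
    means.index.name = "donor_id"
    if orientation is not None:
        orient = pd.Series(orientation, index=usages.columns) \
            if not isinstance(orientation, pd.Series) else orientation
        means = means * orient.reindex(usages.columns).to_numpy()[None, :]
    absent = sorted(set(donor_map.unique()) - set(means.index))
    return means, {"absent_donors": absent, "zero_usage_cells": zero_rows}


@dataclass
class _KFit:
    k: int
    spectra: pd.DataFrame  # programs x genes, rows L2-normalized medians
    usages: pd.DataFrame  # cells x programs (normalized, rows sum to 1)
    stability: float
    error: float
    n_components_pooled: int
    n_outliers_dropped: int


@dataclass
class ProgramResults:
    """Consensus NMF results over a scan of factor numbers k."""

    model: "ConsensusNMF"
    fits: dict[int, _KFit]
    selection_report: pd.DataFrame  # (k, stability, error)
    chosen_k: int

    def spectra(self, k: int | None = None) -> pd.DataFrame:
        return self.fits[k or self.chosen_k].spectra

    def usages(self, k: int | None = None) -> pd.DataFrame:
        return self.fits[k or self.chosen_k].usages

    def stability(self, k: int | None = None) -> float:
        return self.fits[k or self.chosen_k].stability

    def reconstruction_error(self, k: int | None = None) -> float:
        return self.fits[k or self.chosen_k].error

    def donor_scores(self, cell_to_donor, orientation=None, k: int | None = None):
        return donor_program_scores(
            self.usages(k), cell_to_donor, orientation=orientation
        )

    def explained_variance(self, k: int | None = None) -> float:
        """1 - ||X - WH||^2 / ||X - mean||^2 on the factorized matrix."""
        fit = self.fits[k or self.chosen_k]
        X = self.model._norm.T  # cells x genes
        W = self._refit_weights(fit)
        rec = W @ fit.spectra.to_numpy()
        denom = ((X - X.mean(axis=0)) ** 2).sum()
        return float(1.0 - ((X - rec) ** 2).sum() / denom)

    def _refit_weights(self, fit: _KFit) -> np.ndarray:
        X = self.model._norm.T
        W, _, _ = non_negative_factorization(
            X, H=fit.spectra.to_numpy(), n_components=fit.k,
            update_H=False, max_iter=500, tol=1e-6,
        )
        return W

    def summary(self) -> str:
        lines = [
            "Consensus NMF results",
            "=====================",
            f"cells: {self.model._norm.shape[1]}    "
            f"genes: {self.model._norm.shape[0]}",
            f"k scanned: {sorted(self.fits)}    chosen k: {self.chosen_k} "
            "(max stability)",
            "",
            self.selection_report.to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)


class ConsensusNMF:
    """Consensus non-negative matrix factorization of a gene x cell matrix.

    ``counts`` is a genes x cells DataFrame (raw UMIs).  With
    ``variance_normalize`` (default) each gene is scaled to unit variance
    before factorization; spectra are reported on that scale.
    """

    def __init__(self, counts, gene_ids=None, cell_ids=None,
                 variance_normalize: bool = True):
        if sparse.issparse(counts):
            counts = pd.DataFrame(
                counts.toarray(), index=gene_ids, columns=cell_ids
            )
        elif not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(np.asarray(counts), index=gene_ids,
                                  columns=cell_ids)
        self.counts = counts
        X = counts.to_numpy(dtype=float)
        if variance_normalize:
            sd = X.std(axis=1)
            sd[sd == 0] = 1.0
            X = X / sd[:, None]
            self._gene_scale = sd
        else:
            self._gene_scale = np.ones(X.shape[0])
        self._norm = X  # genes x cells

    def fit(
        self,
        k_values=range(3, 31),
        restarts: int = 20,
        outlier_distance: float = 0.3,
        seed: int = 0,
        max_iter: int = 1000,
        nmf_tol: float = 1e-7,
    ) -> ProgramResults:
        k_values = sorted(set(int(k) for k in k_values))
        if any(k < 2 for k in k_values):
            raise ValueError("each k must be >= 2")
        if restarts < 3:
            raise ValueError("need at least 3 restarts")
        fits = {}
        rng = np.random.default_rng(seed)
        for k in k_values:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            fits[k] = self._fit_one_k(
                k, restarts, outlier_distance, sub_seed, max_iter, nmf_tol
            )
        report = pd.DataFrame(
            {
                "k": list(fits),
                "stability": [fits[k].stability for k in fits],
                "error": [fits[k].error for k in fits],
            }
        )
        chosen = int(report.loc[report["stability"].idxmax(), "k"])
        return ProgramResults(
            model=self, fits=fits, selection_report=report, chosen_k=chosen
        )

    def _fit_one_k(self, k, restarts, outlier_distance, seed, max_iter, nmf_tol):
        X = self._norm.T  # cells x genes (samples x features for sklearn)
        n_cells, n_genes = X.shape
        components = []
        ok = 0
        for r in range(restarts):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    W, H, _ = non_negative_factorization(
                        X, n_components=k, init="random",
                        random_state=seed + r, max_iter=max_iter, tol=nmf_tol,
                    )
            except Exception:
                continue  # failed restart is discarded
            norms = np.linalg.norm(H, axis=1)
            norms[norms == 0] = 1.0
            components.append(H / norms[:, None])
            ok += 1
        if ok == 0:
            raise RuntimeError("all NMF restarts failed")
        pooled = np.vstack(components)  # (ok*k) x genes, L2-normalized rows

        # drop outlier components: mean distance to nearest neighbours
        n_neighbors = max(2, int(round(0.3 * ok)))
        from scipy.spatial.distance import cdist

        D = cdist(pooled, pooled)
        np.fill_diagonal(D, np.inf)
        D.sort(axis=1)
        mean_nn = D[:, :n_neighbors].mean(axis=1)
        keep = mean_nn <= outlier_distance
        if keep.sum() < k:  # too aggressive for this dataset; keep everything
            keep = np.ones(len(pooled), dtype=bool)
        kept = pooled[keep]
        n_dropped = int((~keep).sum())

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(kept)
        if len(set(labels)) > 1 and kept.shape[0] > k:
            stability = float(silhouette_score(kept, labels))
        else:
            stability = float("nan")
        spectra = np.vstack([
            np.median(kept[labels == c], axis=0) for c in range(k)
        ])
        norms = np.linalg.norm(spectra, axis=1)
        norms[norms == 0] = 1.0
        spectra = spectra / norms[:, None]

        W, _, _ = non_negative_factorization(
            X, H=spectra, n_components=k, update_H=False,
            max_iter=max_iter, tol=nmf_tol,
        )
        error = float(
            np.linalg.norm(X - W @ spectra) / max(np.linalg.norm(X), 1e-300)
        )
        prog_names = [f"cNMF{i + 1}" for i in range(k)]
        usages, _ = usage_normalize(
            pd.DataFrame(W, index=self.counts.columns, columns=prog_names)
        )
        spectra_df = pd.DataFrame(
            spectra, index=prog_names, columns=self.counts.index
        )
        return _KFit(
            k=k, spectra=spectra_df, usages=usages, stability=stability,
            error=error, n_components_pooled=len(pooled),
            n_outliers_dropped=n_dropped,
        )
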
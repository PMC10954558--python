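"""Cross-cell-type latent factor analysis of donor pseudobulk expression.

Per-cell-type gene-by-donor residual matrices are concatenated into a single
donor x (gene, cell type) matrix — each gene appears once per cell type,
with a ``_celltype`` suffix — and a Bayesian factor model is fitted to it:

    x_ij ~ Normal(s_i . l_j, 1 / tau_j)
    s_ik ~ Normal(0, 1)
    l_jk ~ Normal(0, 1 / alpha_k),  alpha_k ~ Gamma(a0, b0)
    tau_j ~ Gamma(c0, d0)

The per-factor precision alpha_k is an automatic-relevance-determination
(ARD) prior: factors not supported by the data have their loadings shrunk
toward zero, so the number of requested factors k is an upper bound rather
than a hard model choice.  Inference is coordinate-ascent variational Bayes
with a monotone evidence lower bound.  A deterministic truncated-PCA mode
is provided as an oracle for testing.

Usage follows the statsmodels Model/Results convention::

    model = LatentFactorAnalysis.from_pseudobulks(residual_pbs, raw_pbs)
    res = model.fit(k=10)
    res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln
from scipy.stats import norm, rankdata

__all__ = [
    "ConcatenatedMatrix",
    "concatenate_celltypes",
    "LatentFactorAnalysis",
    "LatentFactorResults",
    "FactorSummary",
    "summarize_factors",
    "quantile_normalize",
    "adjust_for_age",
]


@dataclass
class ConcatenatedMatrix:
    """Donor x (gene, cell type) expression matrix.

    Features are named ``GENE_celltype``; every feature passed its cell
    type's top-expression filter.  ``dropped_donors`` lists donors removed
    because they lacked one or more cell types.
    """

    donors: list[str]
    features: list[str]
    values: pd.DataFrame  # donors x features
    dropped_donors: list[str] = field(default_factory=list)


def concatenate_celltypes(
    residual_pseudobulks,
    raw_pseudobulks,
    top_fraction: float = 0.5,
) -> ConcatenatedMatrix:
    """Filter each cell type to its most expressed genes and column-bind.

    Gene ranking uses the companion raw-sum matrices with donor columns
    scaled to 100,000 UMIs (mean across donors); the top ``top_fraction``
    of genes per cell type are kept, suffixed with the cell type, and the
    per-type residual-sum blocks are concatenated along features.  Donors
    missing any cell type are dropped with a warning.
    """
    if not residual_pseudobulks:
        raise ValueError("empty pseudobulk list")
    raw_by_type = {pb.cell_type: pb for pb in raw_pseudobulks}
    donor_sets = []
    for pb in residual_pseudobulks:
        donor_sets.append(set(pb.matrix.columns))
    common = set.intersection(*donor_sets)
    all_donors = sorted(set.union(*donor_sets))
    dropped = sorted(set(all_donors) - common)
    if dropped:
        warnings.warn(f"dropping donors missing a cell type: {dropped}")
    donors = [d for d in all_donors if d in common]

    blocks = []
    for pb in residual_pseudobulks:
        raw = raw_by_type.get(pb.cell_type)
        if raw is None:
            raise ValueError(f"no raw_sum companion for cell type {pb.cell_type!r}")
        scaled = raw.matrix * (1e5 / raw.matrix.sum(axis=0))
        rank_metric = scaled.mean(axis=1)
        n_keep = max(1, int(round(top_fraction * len(rank_metric))))
        keep = rank_metric.sort_values(ascending=False).index[:n_keep]
        keep = [g for g in pb.matrix.index if g in set(keep)]  # stable order
        block = pb.matrix.loc[keep, donors].T
        block.columns = [f"{g}_{pb.cell_type}" for g in keep]
        blocks.append(block)
    values = pd.concat(blocks, axis=1)
    if values.columns.duplicated().any():
        raise ValueError("duplicate features after suffixing")
    return ConcatenatedMatrix(
        donors=donors, features=list(values.columns), values=values,
        dropped_donors=dropped,
    )


def quantile_normalize(values) -> np.ndarray:
    """Rank-based mapping to standard-normal quantiles.

    Returns ``qnorm(rank(x) / (n + 1))`` with average ranks for ties; a
    monotone transform, so rank statistics are unchanged.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return x
    ranks = rankdata(x, method="average")
    return norm.ppf(ranks / (x.size + 1))


def adjust_for_age(scores, ages) -> np.ndarray:
    """Residuals of an OLS regression of donor scores on (intercept, age)."""
    y = np.asarray(scores, dtype=float)
    a = np.asarray(ages, dtype=float)
    if y.shape != a.shape:
        raise ValueError("scores and ages must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 donors")
    if np.ptp(a) == 0:
        raise ValueError("age not identifiable: constant ages")
    design = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


class LatentFactorAnalysis:
    """Latent factor model over a donor x feature matrix.

    Parameters
    ----------
    data
        A :class:`ConcatenatedMatrix` or a donors x features DataFrame with
        features named ``GENE_celltype``.
    center
        Center each feature before fitting (default).  Features are not
        variance-scaled: residual inputs are already variance-stabilized.
    """

    def __init__(self, data, center: bool = True):
        if isinstance(data, ConcatenatedMatrix):
            df = data.values
        else:
            df = pd.DataFrame(data)
        if df.isna().any().any():
            raise ValueError("matrix must be complete (no missing entries)")
        self.data = df
        self.donors = list(df.index)
        self.features = list(df.columns)
        self.center = center
        self._mean = df.to_numpy(dtype=float).mean(axis=0)
        X = df.to_numpy(dtype=float)
        self._X = X - self._mean if center else X.copy()

    @classmethod
    def from_pseudobulks(cls, residual_pseudobulks, raw_pseudobulks,
                         top_fraction: float = 0.5, center: bool = True):
        concat = concatenate_celltypes(
            residual_pseudobulks, raw_pseudobulks, top_fraction
        )
        return cls(concat, center=center)

    # ------------------------------------------------------------------
    def fit(
        self,
        k: int = 10,
        method: str = "vb_ard",
        tol: float = 1e-6,
        max_iter: int = 1000,
        seed: int = 0,
        init: str = "svd",
    ) -> "LatentFactorResults":
        n, p = self._X.shape
        if not 1 <= k < min(n, p):
            raise ValueError(f"k must be in [1, {min(n, p) - 1}]")
        if method == "pca":
            return self._fit_pca(k)
        if method != "vb_ard":
            raise ValueError("method must be 'vb_ard' or 'pca'")
        return self._fit_vb_ard(k, tol, max_iter, seed, init)

    def _fit_pca(self, k: int) -> "LatentFactorResults":
        U, sv, Vt = np.linalg.svd(self._X, full_matrices=False)
        scores = U[:, :k] * sv[:k]
        loadings = Vt[:k].T
        scores, loadings = _orient(scores, loadings)
        return LatentFactorResults(
            model=self, k=k, method="pca",
            scores=self._scores_df(scores, k),
            loadings=self._loadings_df(loadings, k),
            noise_precision=None, relevance=None,
            elbo_trace=np.array([]), converged=True, n_iter=0,
        )

    def _fit_vb_ard(self, k, tol, max_iter, seed, init):
        X = self._X
        n, p = X.shape
        a0 = b0 = c0 = d0 = 1e-3  # broad Gamma hyperpriors
        log2pi = np.log(2.0 * np.pi)

        if init == "svd":
            U, sv, Vt = np.linalg.svd(X, full_matrices=False)
            ML = Vt[:k].T * (sv[:k] / np.sqrt(n))
        elif init == "random":
            rng = np.random.default_rng(seed)
            ML = rng.normal(0.0, 0.1, size=(p, k))
        else:
            raise ValueError("init must be 'svd' or 'random'")
        SigL = np.broadcast_to(np.eye(k) * 1e-6, (p, k, k)).copy()
        E_alpha = np.ones(k)
        E_log_alpha = np.zeros(k)
        col_var = X.var(axis=0)
        E_tau = 1.0 / np.maximum(col_var, 1e-6)
        E_log_tau = np.log(E_tau)
        a_hat = a0 + p / 2.0
        c_hat = c0 + n / 2.0

        elbos: list[float] = []
        converged = False
        x2 = (X**2).sum(axis=0)
        for it in range(max_iter):
            Ell = SigL + ML[:, :, None] * ML[:, None, :]

            # q(S): shared covariance, closed-form means
            prec_s = np.eye(k) + np.einsum("j,jab->ab", E_tau, Ell)
            Sig_s = np.linalg.inv(prec_s)
            MS = (X * E_tau) @ ML @ Sig_s
            A = n * Sig_s + MS.T @ MS

            # q(L): per-feature covariance (noise precision varies by feature)
            prec_l = np.diag(E_alpha)[None, :, :] + E_tau[:, None, None] * A[None, :, :]
            SigL = np.linalg.inv(prec_l)
            B = X.T @ MS
            ML = np.einsum("jab,jb->ja", SigL, B) * E_tau[:, None]
            Ell = SigL + ML[:, :, None] * ML[:, None, :]

            # q(alpha): ARD relevance precisions
            W = np.einsum("jkk->k", Ell)
            b_hat = b0 + 0.5 * W
            E_alpha = a_hat / b_hat
            E_log_alpha = digamma(a_hat) - np.log(b_hat)

            # q(tau): per-feature noise precisions
            cross = np.einsum("ij,ij->j", X, MS @ ML.T)
            trace = np.einsum("ab,jab->j", A, Ell)
            R = np.maximum(x2 - 2.0 * cross + trace, 1e-12)
            d_hat = d0 + 0.5 * R
            E_tau = c_hat / d_hat
            E_log_tau = digamma(c_hat) - np.log(d_hat)

            # evidence lower bound
            ll = 0.5 * n * E_log_tau.sum() - 0.5 * n * p * log2pi \
                - 0.5 * float(E_tau @ R)
            lp_s = -0.5 * n * k * log2pi \
                - 0.5 * (n * np.trace(Sig_s) + (MS**2).sum())
            lp_l = 0.5 * p * E_log_alpha.sum() - 0.5 * p * k * log2pi \
                - 0.5 * float(E_alpha @ W)
            lp_alpha = float(
                np.sum(a0 * np.log(b0) - gammaln(a0)
                       + (a0 - 1.0) * E_log_alpha - b0 * E_alpha)
            )
            lp_tau = float(
                np.sum(c0 * np.log(d0) - gammaln(c0)
                       + (c0 - 1.0) * E_log_tau - d0 * E_tau)
            )
            h_s = 0.5 * n * (k * (1.0 + log2pi) + np.linalg.slogdet(Sig_s)[1])
            h_l = 0.5 * (p * k * (1.0 + log2pi)
                         + np.linalg.slogdet(SigL)[1].sum())
            h_alpha = float(
                np.sum(a_hat - np.log(b_hat) + gammaln(a_hat)
                       + (1.0 - a_hat) * digamma(a_hat))
            )
            h_tau = float(
                np.sum(c_hat - np.log(d_hat) + gammaln(c_hat)
                       + (1.0 - c_hat) * digamma(c_hat))
            )
            elbo = ll + lp_s + lp_l + lp_alpha + lp_tau + h_s + h_l + h_alpha + h_tau
            elbos.append(elbo)
            if it > 0 and abs(elbos[-1] - elbos[-2]) < tol * abs(elbos[-2]):
                converged = True
                break

        if not converged:
            warnings.warn("vb_ard did not converge within max_iter")
        scores, loadings = _orient(MS, ML)
        return LatentFactorResults(
            model=self, k=k, method="vb_ard",
            scores=self._scores_df(scores, k),
            loadings=self._loadings_df(loadings, k),
            noise_precision=pd.Series(E_tau, index=self.features, name="tau"),
            relevance=pd.Series(E_alpha, index=_factor_names(k), name="alpha"),
            elbo_trace=np.asarray(elbos), converged=converged, n_iter=len(elbos),
        )

    def _scores_df(self, scores, k):
        return pd.DataFrame(scores, index=self.donors, columns=_factor_names(k))

    def _loadings_df(self, loadings, k):
        return pd.DataFrame(loadings, index=self.features, columns=_factor_names(k))


def _factor_names(k: int) -> list[str]:
    return [f"LF{i + 1}" for i in range(k)]


def _orient(scores: np.ndarray, loadings: np.ndarray):
    """Sign convention: orient each factor so its maximum-|loading| feature
    loads positively (resolves the global sign ambiguity)."""
    scores = scores.copy()
    loadings = loadings.copy()
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]
    return scores, loadings


@dataclass
class FactorSummary:
    """Variance-explained and independence diagnostics for a fitted model."""

    total_variance_explained: float
    per_factor_variance_explained: pd.Series
    score_correlations: pd.DataFrame
    loading_correlations: pd.DataFrame
    celltype_composition: pd.DataFrame  # factors x cell types, rows sum to 1


@dataclass
class LatentFactorResults:
    """Fitted latent factor model: loadings, donor scores and diagnostics."""

    model: LatentFactorAnalysis
    k: int
    method: str
    scores: pd.DataFrame  # donors x factors
    loadings: pd.DataFrame  # features x factors
    noise_precision: pd.Series | None
    relevance: pd.Series | None
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int

    # -- diagnostics ---------------------------------------------------
    def fitted_values(self) -> np.ndarray:
        return self.scores.to_numpy() @ self.loadings.to_numpy().T

    def variance_explained(self) -> tuple[float, pd.Series]:
        """(total, per-factor) fraction of variance explained.

        Total is 1 - RSS/TSS on the centered matrix; the per-factor value
        is the leave-one-factor-in fraction.
        """
        X = self.model._X
        tss = float((X**2).sum())
        total = 1.0 - float(((X - self.fitted_values()) ** 2).sum()) / tss
        per = {}
        S = self.scores.to_numpy()
        L = self.loadings.to_numpy()
        for i, name in enumerate(self.scores.columns):
            rec = np.outer(S[:, i], L[:, i])
            per[name] = 1.0 - float(((X - rec) ** 2).sum()) / tss
        return total, pd.Series(per, name="variance_explained")

    def factor_variance_shares(self) -> pd.Series:
        """Each factor's share of total fitted score variance (used to see
        which requested factors the ARD prior has shrunk away)."""
        v = self.scores.var(axis=0, ddof=0) * (self.loadings**2).sum(axis=0)
        return v / v.sum()

    def celltype_composition(self, top_n: int = 1000) -> pd.DataFrame:
        """Cell-type histogram of each factor's top-|loading| features."""
        n_feat = self.loadings.shape[0]
        if top_n > n_feat:
            warnings.warn(f"top_n clamped to feature count {n_feat}")
            top_n = n_feat
        types = [f.rsplit("_", 1)[1] if "_" in f else "unknown"
                 for f in self.loadings.index]
        all_types = sorted(set(types))
        rows = {}
        for name in self.loadings.columns:
            top = np.argsort(-self.loadings[name].abs().to_numpy())[:top_n]
            counts = pd.Series([types[i] for i in top]).value_counts()
            rows[name] = [counts.get(t, 0) / top_n for t in all_types]
        return pd.DataFrame.from_dict(rows, orient="index", columns=all_types)

    def quantile_normalized_scores(self) -> pd.DataFrame:
        return self.scores.apply(lambda c: quantile_normalize(c.to_numpy()), axis=0)

    def summarize(self, top_n: int = 1000) -> FactorSummary:
        total, per = self.variance_explained()
        return FactorSummary(
            total_variance_explained=total,
            per_factor_variance_explained=per,
            score_correlations=self.scores.corr(),
            loading_correlations=self.loadings.corr(),
            celltype_composition=self.celltype_composition(top_n),
        )

    def summary(self, top_n: int = 1000) -> str:
        s = self.summarize(top_n=min(top_n, self.loadings.shape[0]))
        lines = [
            "Latent factor analysis results",
            "==============================",
            f"method: {self.method}    k: {self.k}    "
            f"donors: {len(self.scores)}    features: {len(self.loadings)}",
            f"iterations: {self.n_iter}    converged: {self.converged}",
            f"total variance explained: {s.total_variance_explained:.3f}",
            "",
            "Per-factor variance explained:",
            s.per_factor_variance_explained.to_string(float_format="%.4f"),
            "",
            "Cell-type composition of top loading features:",
            s.celltype_composition.to_string(float_format="%.3f"),
        ]
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["k"] = self.k
            f.attrs["method"] = self.method
            f.attrs["converged"] = self.converged
            f.create_dataset("scores", data=self.scores.to_numpy())
            f.create_dataset("loadings", data=self.loadings.to_numpy())
            f.create_dataset(
                "donors", data=np.array(self.scores.index, dtype="S")
            )
            f.create_dataset(
                "features", data=np.array(self.loadings.index, dtype="S")
            )
            f.create_dataset("elbo_trace", data=self.elbo_trace)
            if self.noise_precision is not None:
                f.create_dataset("noise_precision",
                                 data=self.noise_precision.to_numpy())
            if self.relevance is not None:
                f.create_dataset("relevance", data=self.relevance.to_numpy())

    def export_tsv(self, scores_path, loadings_path) -> None:
        """TSV exports: donor scores and gene-by-cell-type loadings."""
        self.scores.rename_axis("donor_id").to_csv(scores_path, sep="\t")
        self.loadings.rename_axis("feature").to_csv(loadings_path, sep="\t")


def summarize_factors(results: LatentFactorResults, top_n: int = 1000) -> FactorSummary:
    """Module-level convenience wrapper for :meth:`LatentFactorResults.summarize`."""
    return results.summarize(top_n=top_n)
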
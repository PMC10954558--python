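"""Pearson-residual normalization, pseudobulk aggregation and donor QC.

Counts are variance-stabilized to Pearson residuals under a negative
binomial mean model, summed within (donor, cell type) into gene-by-donor
pseudobulk matrices, and aberrant donors are excluded by robust conformity
statistics: a donor's conformity score is its median pairwise Pearson
correlation (of log10-scaled expression over the top expressed genes) with
every other donor, converted to a modified z-score

    M_i = 0.6745 * (x_i - median(x)) / MAD(x)

with MAD the (unscaled) median absolute deviation.  Donors are excluded
when |M| > 5 on expression conformity, |M| > 15 on cell-type-proportion
conformity, or when any cell type has fewer than 1,000 total UMIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CellTypePseudobulk",
    "ConformityReport",
    "pearson_residuals",
    "aggregate_pseudobulk",
    "conformity_scores",
    "proportion_conformity_scores",
    "modified_z",
    "flag_outlier_donors",
]

MODIFIED_Z_CONSTANT = 0.6745


@dataclass
class CellTypePseudobulk:
    """Gene x donor matrix for one cell type.

    ``mode`` records whether entries are summed raw counts ("raw_sum") or
    summed Pearson residuals ("residual_sum"); ``donor_umis`` carries each
    donor's total raw UMIs in this cell type (available in raw_sum mode).
    """

    cell_type: str
    matrix: pd.DataFrame
    mode: str  # "raw_sum" | "residual_sum"
    donor_umis: pd.Series | None = None
    absent_donors: list[str] = field(default_factory=list)


@dataclass
class ConformityReport:
    """Per-donor conformity scores and their modified z-scores."""

    scores: pd.Series
    median: float
    mad: float
    modified_z: pd.Series


def _as_dense_df(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    if sparse.issparse(counts):
        return pd.DataFrame(counts.toarray())
    return pd.DataFrame(np.asarray(counts))


def estimate_theta(
    counts: pd.DataFrame,
    window: int = 51,
    min_proportion: float = 1e-4,
    theta_max: float = 1e6,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments, regularized.

    theta_g solves Var = mu + mu^2 / theta pooled over cells at the gene's
    depth-adjusted means.  Raw estimates are smoothed by a rolling median
    over genes ordered by log mean expression; genes below
    ``min_proportion`` of total counts inherit the global median theta.
    Non-overdispersed genes are capped at ``theta_max`` (Poisson-like).
    """
    X = counts.to_numpy(dtype=float)
    depth = X.sum(axis=0)
    total = depth.sum()
    p = X.sum(axis=1) / total if total > 0 else np.zeros(X.shape[0])
    mu = np.outer(p, depth)
    excess = ((X - mu) ** 2 - mu).sum(axis=1)
    denom = (mu**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(excess > 0, denom / np.maximum(excess, 1e-12), theta_max)
    raw = np.clip(raw, 1e-3, theta_max)

    order = np.argsort(p)
    smoothed = pd.Series(raw[order]).rolling(
        window=min(window, len(raw)), center=True, min_periods=1
    ).median().to_numpy()
    theta = np.empty_like(raw)
    theta[order] = smoothed
    global_median = float(np.median(theta)) if len(theta) else theta_max
    theta[p < min_proportion] = global_median
    return pd.Series(theta, index=counts.index)


def pearson_residuals(
    counts,
    theta: pd.Series | float | None = None,
    clip: float | None = None,
) -> pd.DataFrame:
    """Pearson residuals of UMI counts under an NB mean model.

    r_gc = (x_gc - mu_gc) / sqrt(mu_gc + mu_gc^2 / theta_g) with
    mu_gc = depth_c * (gene g's pooled proportion).  ``theta`` may be a
    per-gene Series, a scalar, or None (estimated by
    :func:`estimate_theta`); np.inf gives Poisson residuals.  Residuals are
    clipped to +/- sqrt(n_cells) by default; all-zero genes get zero rows.
    """
    df = _as_dense_df(counts)
    if df.shape[1] < 2:
        raise ValueError("need at least two cells")
    X = df.to_numpy(dtype=float)
    if np.any(X < 0) or np.any(X != np.round(X)):
        raise ValueError("counts must be non-negative integers")
    depth = X.sum(axis=0)
    total = depth.sum()
    p = X.sum(axis=1) / total if total > 0 else np.zeros(X.shape[0])
    mu = np.outer(p, depth)

    if theta is None:
        th = estimate_theta(df).to_numpy()
    elif np.isscalar(theta):
        th = np.full(X.shape[0], float(theta))
    else:
        th = theta.reindex(df.index).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = mu + mu**2 / th[:, None]
        r = np.where(var > 0, (X - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    bound = float(np.sqrt(X.shape[1])) if clip is None else float(clip)
    r = np.clip(r, -bound, bound)
    return pd.DataFrame(r, index=df.index, columns=df.columns)


def aggregate_pseudobulk(
    values: pd.DataFrame,
    cell_to_donor,
    cell_to_type,
    mode: str,
) -> list[CellTypePseudobulk]:
    """Sum per-cell values into gene x donor matrices, one per cell type.

    ``values`` is genes x cells (raw counts for mode "raw_sum", Pearson
    residuals for "residual_sum"); the cell maps are Series/dicts keyed by
    barcode.  Donors with no cells of a type are recorded as absent rather
    than imputed.  Raises on unmapped barcodes, listing the offenders.
    """
    if mode not in {"raw_sum", "residual_sum"}:
        raise ValueError("mode must be raw_sum or residual_sum")
    donor_map = pd.Series(cell_to_donor)
    type_map = pd.Series(cell_to_type)
    cells = list(values.columns)
    unmapped = [c for c in cells if c not in donor_map.index or c not in type_map.index]
    if unmapped:
        raise ValueError(f"unmapped cell barcodes: {unmapped[:10]}"
                         + ("..." if len(unmapped) > 10 else ""))
    donors = sorted(donor_map.loc[cells].unique())
    out = []
    for ct in sorted(type_map.loc[cells].unique()):
        ct_cells = [c for c in cells if type_map[c] == ct]
        groups = donor_map.loc[ct_cells]
        mat = values[ct_cells].T.groupby(groups.values).sum().T
        present = list(mat.columns)
        absent = [d for d in donors if d not in present]
        mat = mat.reindex(columns=[d for d in donors if d in present])
        donor_umis = mat.sum(axis=0) if mode == "raw_sum" else None
        out.append(
            CellTypePseudobulk(
                cell_type=ct, matrix=mat, mode=mode,
                donor_umis=donor_umis, absent_donors=absent,
            )
        )
    return out


def _scale_to_1e5(matrix: pd.DataFrame) -> pd.DataFrame:
    colsum = matrix.sum(axis=0)
    return matrix * (1e5 / colsum.replace(0, np.nan))


def conformity_scores(
    pseudobulks: list[CellTypePseudobulk],
    min_umis_per_1e5: float = 10.0,
) -> ConformityReport:
    """Expression conformity from raw-sum pseudobulk matrices.

    Per cell type, donor columns are scaled to 100,000 UMIs and genes kept
    if they reach ``min_umis_per_1e5`` in at least one donor; the kept rows
    from all cell types are merged and each donor's conformity score is the
    median pairwise Pearson correlation of log10(x + 1) expression with the
    other donors.
    """
    if not pseudobulks:
        raise ValueError("no pseudobulk matrices given")
    blocks = []
    for pb in pseudobulks:
        if pb.mode != "raw_sum":
            raise ValueError("conformity scores require raw_sum pseudobulk")
        scaled = _scale_to_1e5(pb.matrix)
        keep = (scaled.max(axis=1) >= min_umis_per_1e5).to_numpy()
        block = scaled.loc[keep]
        block.index = [f"{g}_{pb.cell_type}" for g in block.index]
        blocks.append(block)
    donors = blocks[0].columns
    for b in blocks[1:]:
        if not b.columns.equals(donors):
            raise ValueError("pseudobulk matrices must share the donor set")
    merged = pd.concat(blocks, axis=0)
    if merged.shape[1] < 3:
        raise ValueError("conformity undefined: fewer than 3 donors")
    logx = np.log10(merged.to_numpy(dtype=float) + 1.0)
    scores = pd.Series(_median_pairwise_corr(logx.T), index=donors,
                       name="conformity")
    return _report_from_scores(scores)


def _median_pairwise_corr(vectors: np.ndarray) -> np.ndarray:
    """Median off-diagonal Pearson correlation per row; rows with zero
    variance (no information) get NaN rather than a warning."""
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(vectors)
        np.fill_diagonal(corr, np.nan)
        return np.nanmedian(corr, axis=1)


def proportion_conformity_scores(proportions: pd.DataFrame) -> ConformityReport:
    """Conformity on per-donor cell-type proportion vectors.

    ``proportions`` is cell types x donors (columns sum to 1); the same
    median-pairwise-Pearson / modified-z machinery as for expression is
    applied to these vectors.
    """
    if proportions.shape[1] < 3:
        raise ValueError("conformity undefined: fewer than 3 donors")
    scores = pd.Series(
        _median_pairwise_corr(proportions.to_numpy(dtype=float).T),
        index=proportions.columns, name="conformity",
    )
    return _report_from_scores(scores)


def _report_from_scores(scores: pd.Series) -> ConformityReport:
    if scores.isna().all():
        # no information (e.g. identical proportion vectors): no flags
        return ConformityReport(
            scores=scores, median=float("nan"), mad=float("nan"),
            modified_z=pd.Series(np.nan, index=scores.index),
        )
    med = float(scores.median())
    mad = float((scores - med).abs().median())
    if mad > 0:
        mz = MODIFIED_Z_CONSTANT * (scores - med) / mad
    else:
        mz = pd.Series(np.nan, index=scores.index)
    return ConformityReport(scores=scores, median=med, mad=mad, modified_z=mz)


def modified_z(scores) -> pd.Series:
    """Modified z-scores M_i = 0.6745 * (x_i - median) / MAD (unscaled MAD).

    A value exactly one MAD above the median maps to 0.6745.
    """
    s = pd.Series(scores, dtype=float)
    med = s.median()
    mad = (s - med).abs().median()
    if mad == 0:
        raise ValueError("degenerate spread: MAD is zero")
    return MODIFIED_Z_CONSTANT * (s - med) / mad


def flag_outlier_donors(
    expr_report: ConformityReport | None,
    prop_report: ConformityReport | None,
    umi_totals: pd.DataFrame | None = None,
    min_umis: float = 1000.0,
    expr_threshold: float = 5.0,
    prop_threshold: float = 15.0,
) -> pd.DataFrame:
    """Union of the three exclusion criteria, each flag with its reason.

    ``umi_totals`` is donors x cell types (total raw UMIs); a donor fails
    the UMI rule when any cell type is below ``min_umis``.  Expression and
    proportion conformity flags use |modified z| above their thresholds.
    Returns a DataFrame (donor, criterion, statistic); empty when no donor
    is flagged.
    """
    rows = []
    if umi_totals is not None:
        worst = umi_totals.min(axis=1)
        for donor, v in worst.items():
            if v < min_umis:
                rows.append((donor, "low_umis", float(v)))
    for report, name, thr in (
        (expr_report, "expression_conformity", expr_threshold),
        (prop_report, "proportion_conformity", prop_threshold),
    ):
        if report is None:
            continue
        for donor, m in report.modified_z.items():
            if np.isfinite(m) and abs(m) > thr:
                rows.append((donor, name, float(m)))
    return pd.DataFrame(rows, columns=["donor", "criterion", "statistic"])
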
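"""Donor-level association statistics for factor and program scores.

Three statistics relate per-donor scores to covariates: Spearman rank
correlation (score vs age), the two-sided Wilcoxon rank-sum test (case vs
control), and a joint OLS regression of scores on age, sex and case-control
status.  Small samples use exact permutation enumeration; larger samples
use the standard t / normal approximations with tie corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "rank_correlation",
    "case_control_test",
    "joint_regression",
]


@dataclass
class AssociationResult:
    statistic_name: str  # "spearman_rho" | "rank_sum_W" | "regression_t"
    estimate: float
    statistic: float
    p_value: float
    n: int
    term: str = ""


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined: constant input")
    return float(np.corrcoef(rx, ry)[0, 1])


def rank_correlation(scores, covariate) -> AssociationResult:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks for ties; for n <= 10 the p-value is the exact
    permutation probability of |rho| at least as large as observed,
    otherwise the t approximation is used.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    rho = _spearman_rho(x, y)
    if n <= 10:
        rxc = stats.rankdata(x) - (n + 1) / 2.0
        ryc = stats.rankdata(y) - (n + 1) / 2.0
        obs = abs(float(rxc @ ryc))
        count = total = 0
        chunk: list[tuple[int, ...]] = []

        def flush(chunk):
            P = np.array(chunk, dtype=np.intp)
            dots = np.abs(rxc[P] @ ryc)
            return int((dots >= obs - 1e-9).sum()), len(chunk)

        for perm in permutations(range(n)):
            chunk.append(perm)
            if len(chunk) == 100_000:
                c, t = flush(chunk)
                count, total = count + c, total + t
                chunk = []
        if chunk:
            c, t = flush(chunk)
            count, total = count + c, total + t
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return AssociationResult(
        "spearman_rho", estimate=rho, statistic=rho,
        p_value=min(1.0, p), n=n, term="covariate",
    )


def _ranksum_W(pooled_ranks: np.ndarray, idx: tuple[int, ...]) -> float:
    return float(pooled_ranks[list(idx)].sum())


def case_control_test(scores, labels) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum test between two groups.

    ``labels`` is a boolean/0-1 vector (or "case"/"control" strings); the
    reported statistic W is the sum of ranks of the first (case) group.
    Exact enumeration over all group assignments is used when both groups
    have at most 8 members; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "biuf":
        grp = lab.astype(bool)
    else:
        grp = np.array([str(v) == "case" for v in lab])
    x1, x2 = x[grp], x[~grp]
    n1, n2 = x1.size, x2.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x1, x2]))
    W = float(ranks[:n1].sum())
    n = n1 + n2
    if n1 <= 8 and n2 <= 8:
        mean_W = n1 * (n + 1) / 2.0
        dev = abs(W - mean_W)
        count = total = 0
        for idx in combinations(range(n), n1):
            w = _ranksum_W(ranks, idx)
            if abs(w - mean_W) >= dev - 1e-12:
                count += 1
            total += 1
        p = count / total
        estimate = float(np.median(x1) - np.median(x2))
    else:
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
        estimate = float(np.median(x1) - np.median(x2))
    return AssociationResult(
        "rank_sum_W", estimate=estimate, statistic=W,
        p_value=min(1.0, p), n=n, term="status",
    )


def joint_regression(scores, age, sex, status) -> list[AssociationResult]:
    """OLS of scores on intercept + age + sex + case-control status.

    Sex is coded female=0/male=1 (or passed 0/1); status case=1.  Returns
    one result per non-intercept term with estimate, t statistic and
    two-sided p; raises on rank-deficient designs naming the collinear
    terms.  Rows with missing values are dropped listwise.
    """
    import statsmodels.api as sm

    y = np.asarray(scores, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex)
    if s.dtype.kind in "biuf":
        s = s.astype(float)
    else:
        s = np.array([1.0 if str(v) == "M" else 0.0 for v in s])
    c = np.asarray(status)
    if c.dtype.kind in "biuf":
        c = c.astype(float)
    else:
        c = np.array([1.0 if str(v) == "case" else 0.0 for v in c])

    df = pd.DataFrame({"score": y, "age": a, "sex": s, "status": c}).dropna()
    n = len(df)
    if n <= 4:
        raise ValueError("need n > number of terms + 1")
    design = sm.add_constant(df[["age", "sex", "status"]])
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = design.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear terms: {worst}")
    fit = sm.OLS(df["score"], design).fit()
    out = []
    for term in ("age", "sex", "status"):
        out.append(
            AssociationResult(
                "regression_t",
                estimate=float(fit.params[term]),
                statistic=float(fit.tvalues[term]),
                p_value=float(fit.pvalues[term]),
                n=n, term=term,
            )
        )
    return out
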
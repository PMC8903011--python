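"""Spearman correlation analyses of splice-event inclusion.

Covers: event-vs-regulator correlations (BH-corrected within study),
all-pairs event cross-correlations, partial Spearman correlations that
remove the effect of covariates (precision-matrix normalization on ranks,
the ppcor-style estimator), the zero-order-vs-partial distribution
comparison, and LOESS trajectory smoothing for developmental plots.

Spearman's rank correlation is used throughout (inclusion values are
bounded and typically skewed, so a rank statistic is the fixed design
choice). Partial correlation p-values use the t-approximation with
n - |Z| - 2 degrees of freedom.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .differential import bh_adjust, ranksum_p

__all__ = [
    "spearman",
    "partial_spearman",
    "partial_spearman_p",
    "psi_regulator_correlations",
    "pairwise_event_correlations",
    "compare_zero_order_vs_partial",
    "loess_smooth",
]


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation and two-sided p (t-approximation, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _rank_matrix(columns: Sequence[np.ndarray]) -> np.ndarray:
    return np.column_stack([stats.rankdata(c) for c in columns])


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    z: Optional[np.ndarray] = None,
) -> float:
    """Partial Spearman correlation of x and y controlling for covariates z.

    All variables are rank-transformed; the partial coefficient comes from
    the inverse of the rank correlation matrix,
    r_xy.Z = -P_xy / sqrt(P_xx * P_yy). With an empty Z this is exactly the
    zero-order Spearman rho; with |Z| = 1 it equals the first-order
    recursion (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if z is None or (hasattr(z, "size") and np.asarray(z).size == 0):
        return spearman(x, y)[0]
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] == x.size and z.shape[1] != x.size:
        z = z.T  # accept samples-by-covariates input
    n_cov = z.shape[0]
    if x.size <= n_cov + 2:
        raise ValueError("need n > |Z| + 2 samples")
    ranks = _rank_matrix([x, y, *z])
    corr = np.corrcoef(ranks, rowvar=False)
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("collinear variables: rank correlation matrix is singular") from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("collinear variables: rank correlation matrix is singular")
    return float(-prec[0, 1] / np.sqrt(denom))


def partial_spearman_p(rho: float, n: int, n_covariates: int) -> float:
    """Two-sided p for a (partial) Spearman coefficient via the t-approximation
    with n - n_covariates - 2 degrees of freedom."""
    df = n - n_covariates - 2
    if df < 1:
        raise ValueError("not enough samples for the requested covariate set")
    rho = min(max(rho, -1.0), 1.0)
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df))


def psi_regulator_correlations(
    psi: pd.DataFrame,
    expression: pd.DataFrame,
    regulators: Sequence[str] = ("CELF1", "MBNL1", "MBNL2"),
    study: str = "",
) -> pd.DataFrame:
    """Spearman correlation of every event's inclusion with each regulator's
    expression, BH-adjusted within the study."""
    shared = [s for s in psi.columns if s in expression.columns]
    if len(shared) < 4:
        raise ValueError(
            f"only {len(shared)} shared samples between PSI and expression matrices"
        )
    rows = []
    for event in psi.index:
        ev = psi.loc[event, shared].to_numpy(dtype=float)
        for gene in regulators:
            if gene not in expression.index:
                raise ValueError(f"regulator {gene!r} absent from expression matrix")
            rho, p = spearman(ev, expression.loc[gene, shared].to_numpy(dtype=float))
            rows.append((event, gene, rho, p))
    out = pd.DataFrame(rows, columns=["event_id", "regulator", "rho", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["study"] = study
    out["controlled_for"] = ""
    return out


def pairwise_event_correlations(psi: pd.DataFrame) -> pd.DataFrame:
    """Zero-order Spearman correlations for all unordered event pairs
    (k events -> k(k-1)/2 rows)."""
    if psi.shape[0] < 2:
        raise ValueError("need at least 2 events for pairwise correlations")
    values = psi.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    corr = np.corrcoef(ranks)
    n = psi.shape[1]
    rows = []
    ids = list(psi.index)
    for i, j in combinations(range(len(ids)), 2):
        rho = float(corr[i, j])
        rows.append((ids[i], ids[j], rho, partial_spearman_p(rho, n, 0)))
    out = pd.DataFrame(rows, columns=["event_a", "event_b", "rho", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["controlled_for"] = ""
    return out


def partial_pairwise_event_correlations(
    psi: pd.DataFrame, covariates: pd.DataFrame, label: str = ""
) -> pd.DataFrame:
    """Partial Spearman correlations for all event pairs controlling for a
    covariate table (samples x covariates, indexed like psi's columns)."""
    cov = covariates.loc[psi.columns].to_numpy(dtype=float).T
    n = psi.shape[1]
    k = cov.shape[0]
    rows = []
    ids = list(psi.index)
    vals = {e: psi.loc[e].to_numpy(dtype=float) for e in ids}
    for a, b in combinations(ids, 2):
        rho = partial_spearman(vals[a], vals[b], cov)
        rows.append((a, b, rho, partial_spearman_p(rho, n, k)))
    out = pd.DataFrame(rows, columns=["event_a", "event_b", "rho", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["controlled_for"] = label
    return out


def compare_zero_order_vs_partial(
    psi: pd.DataFrame, covariate_sets: Dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Compare |rho| distributions before and after controlling covariates.

    For each named covariate set, all-pairs partial Spearman coefficients are
    computed and their absolute values compared with the zero-order |rho|
    distribution by the rank-sum test; p-values are BH-adjusted across the
    covariate sets. Returns one row per set with the medians, the median
    shift (partial minus zero-order), p and q.
    """
    zero = pairwise_event_correlations(psi)
    abs_zero = zero["rho"].abs().to_numpy()
    rows = []
    for name, cov in covariate_sets.items():
        part = partial_pairwise_event_correlations(psi, cov, label=name)
        if len(part) != len(zero):
            raise ValueError("mismatched pair sets between zero-order and partial")
        abs_part = part["rho"].abs().to_numpy()
        p = ranksum_p(abs_zero, abs_part)
        rows.append(
            (
                name,
                float(np.median(abs_zero)),
                float(np.median(abs_part)),
                float(np.median(abs_part) - np.median(abs_zero)),
                p,
            )
        )
    out = pd.DataFrame(
        rows, columns=["controlled_for", "median_abs_zero", "median_abs_partial",
                       "median_shift", "p"]
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def loess_smooth(
    x: Sequence[float],
    y: Sequence[float],
    query: Optional[Sequence[float]] = None,
    span: float = 0.5,
) -> np.ndarray:
    """LOESS fit (tricube-weighted local linear regression, no robustness
    iterations) evaluated at the query points (default: the observed x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if int(np.floor(span * x.size)) < 3:
        raise ValueError("span covers fewer than 3 points; increase span or n")
    xq = x if query is None else np.asarray(query, dtype=float)
    fitted = sm.nonparametric.lowess(
        y, x, frac=span, it=0, xvals=np.sort(xq), is_sorted=False
    )
    order = np.argsort(xq, kind="stable")
    out = np.empty_like(xq)
    out[order] = fitted
    return out
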
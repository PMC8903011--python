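"""Differential exon inclusion between two groups and permutation FDR.

The per-event test is the two-sided Wilcoxon rank-sum (Mann-Whitney) test:
exact by enumeration when the combined sample size is at most 12 and there
are no ties, otherwise the tie-corrected normal approximation with
continuity correction. An event is called significant under the joint rule
p < p_threshold AND |delta PSI| > delta_threshold; in the transcriptome-wide
screen the p-values are deliberately not multiplicity-corrected — instead
the empirical FDR of the joint rule is estimated by re-running the screen on
randomly shuffled group labels.
"""

from __future__ import annotations

import warnings
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ranksum_p", "detect_events", "permutation_fdr", "bh_adjust"]

_EXACT_MAX_N = 12


def ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p-value.

    Exact null enumeration for combined n <= 12 without ties; otherwise
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    n = pooled.size
    exact = n <= _EXACT_MAX_N and np.unique(pooled).size == n
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def _group_columns(
    psi: pd.DataFrame, metadata: pd.DataFrame, group: str
) -> list[str]:
    samples = metadata.loc[metadata["group"] == group, "sample_id"]
    cols = [s for s in samples if s in psi.columns]
    if not cols:
        raise ValueError(f"group {group!r} absent from metadata or PSI matrix")
    return cols


def _pvalues_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise rank-sum p-values for two events x samples blocks."""
    n = a.shape[1] + b.shape[1]
    if n <= _EXACT_MAX_N:
        return np.array([ranksum_p(a[i], b[i]) for i in range(a.shape[0])])
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows produce sd = 0
            res = stats.mannwhitneyu(
                a, b, axis=1, alternative="two-sided",
                method="asymptotic", use_continuity=True,
            )
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))  # constant event -> p = 1


def detect_events(
    psi: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    delta_threshold: float = 0.2,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-event differential inclusion between two groups.

    Returns a table indexed by event with mean PSI per group, delta
    (group_a - group_b), rank-sum p, the joint significance flag and the
    direction (sign of delta). P-values are not FDR-corrected here; use
    :func:`permutation_fdr` to estimate the empirical FDR of the rule.
    """
    cols_a = _group_columns(psi, metadata, group_a)
    cols_b = _group_columns(psi, metadata, group_b)
    a = psi[cols_a].to_numpy(dtype=float)
    b = psi[cols_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    delta = mean_a - mean_b
    p = _pvalues_matrix(a, b)
    significant = (p < p_threshold) & (np.abs(delta) > delta_threshold)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_psi": delta,
            "p": p,
            "significant": significant,
            "direction": np.sign(delta).astype(int),
        },
        index=psi.index.rename("event_id"),
    )


def permutation_fdr(
    psi: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    delta_threshold: float = 0.2,
    p_threshold: float = 0.01,
    n_shuffles: int = 100,
    seed: Optional[int] = None,
) -> float:
    """Empirical FDR of the joint rule by random shuffling of sample labels.

    FDR = mean over shuffles of (#significant under shuffled labels) divided
    by max(#significant observed, 1). Labels are permuted across all samples
    of the two groups, unstratified. Deterministic given ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    cols_a = _group_columns(psi, metadata, group_a)
    cols_b = _group_columns(psi, metadata, group_b)
    values = psi[cols_a + cols_b].to_numpy(dtype=float)
    n_a = len(cols_a)
    n_total = values.shape[1]

    if comb(n_total, n_a) < n_shuffles:
        warnings.warn(
            f"only {comb(n_total, n_a)} distinct label splits exist; "
            f"shuffling with replacement over {n_shuffles} draws"
        )

    observed = int(
        detect_events(psi, metadata, group_a, group_b, delta_threshold, p_threshold)[
            "significant"
        ].sum()
    )

    rng = np.random.default_rng(seed)
    shuffled_counts = np.empty(n_shuffles, dtype=float)
    for k in range(n_shuffles):
        perm = rng.permutation(n_total)
        a = values[:, perm[:n_a]]
        b = values[:, perm[n_a:]]
        delta = a.mean(axis=1) - b.mean(axis=1)
        gate = np.abs(delta) > delta_threshold
        count = 0
        if gate.any():
            p = _pvalues_matrix(a[gate], b[gate])
            count = int((p < p_threshold).sum())
        shuffled_counts[k] = count
    return float(shuffled_counts.mean() / max(observed, 1))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
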
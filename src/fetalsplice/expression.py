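"""Between-sample normalization of gene counts: TMM factors and log2-CPM.

TMM (trimmed mean of M-values) is reimplemented from its published
definition: per sample, gene-wise log2 ratios (M) of library-normalized
proportions against a reference sample are trimmed (30% per M tail, 5% per
A tail), and the scaling factor is two to the power of the precision-weighted
mean of the surviving M values, with delta-method binomial weights. The
reference sample is the one whose 75th count-proportion percentile is
closest to the across-sample mean, and factors are rescaled to have
geometric mean one.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["tmm_factors", "log2_cpm", "group_logfc"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("no genes positive in both samples; TMM factor set to 1")
        return 1.0
    o, r = obs[keep], ref[keep]
    p_o, p_r = o / lib_obs, r / lib_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # delta-method variance of M under binomial sampling
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    if np.max(np.abs(M)) < 1e-6:
        return 1.0

    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(M)
    rank_a = rankdata(A)
    trimmed = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not trimmed.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1")
        return 1.0
    f = np.sum(M[trimmed] / w[trimmed]) / np.sum(1.0 / w[trimmed])
    if not np.isfinite(f):
        warnings.warn("non-finite TMM estimate; factor set to 1")
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: Optional[str] = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    min_count: int = 0,
) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean one) for a genes x
    samples raw count table.

    ``min_count`` optionally drops genes whose total count is below the
    threshold before factor estimation (no filtering by default).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if min_count > 0:
        counts = counts.loc[counts.sum(axis=1) >= min_count]
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"samples with zero library size: {bad}")
    if ref_sample is None:
        f75 = np.quantile(mat / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if ref_sample not in counts.columns:
            raise ValueError(f"unknown reference sample: {ref_sample!r}")
        ref_idx = counts.columns.get_loc(ref_sample)

    factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx],
                      logratio_trim, sum_trim)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2_cpm(
    counts: pd.DataFrame, factors: Optional[pd.Series] = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts per million with TMM-adjusted effective library sizes.

    log2((count + prior) / (library_size * factor + 2 * prior) * 1e6).
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts)
    f = factors.reindex(counts.columns).to_numpy(dtype=float)
    eff = lib * f + 2.0 * prior
    if np.any(eff <= 0):
        raise ValueError("non-positive effective library size")
    out = np.log2((mat + prior) / eff * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def group_logfc(
    log2cpm: pd.DataFrame,
    metadata: pd.DataFrame,
    gene: str,
    group_a: str,
    group_b: str,
) -> float:
    """Mean log2-CPM of ``gene`` over group_a minus its mean over group_b.

    ``metadata`` needs sample_id and group columns; only samples present in
    the expression matrix are used.
    """
    if gene not in log2cpm.index:
        raise ValueError(f"unknown gene: {gene!r}")
    sel = metadata[metadata["sample_id"].isin(log2cpm.columns)]
    means = {}
    for name in (group_a, group_b):
        samples = sel.loc[sel["group"] == name, "sample_id"]
        if samples.empty:
            raise ValueError(f"group {name!r} has no samples in the expression matrix")
        means[name] = log2cpm.loc[gene, samples].mean()
    return float(means[group_a] - means[group_b])
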
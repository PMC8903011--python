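"""Intersection of developmental and disease differential-splicing results.

The sign convention is fixed package-wide: the developmental delta PSI is
prenatal minus postnatal and the disease delta is DM1 minus unaffected, so
an event "changed toward the prenatal inclusion pattern" exactly when the
two deltas share a sign. High-confidence events are significant (joint
p + |delta| rule) in both datasets with a consistent direction. Overlap
enrichment between the two significant sets is the hypergeometric upper
tail (one-sided Fisher exact test).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "classify_direction",
    "intersect_high_confidence",
    "overlap_enrichment",
    "direction_tally",
]

TOWARD_PRENATAL = "toward_prenatal"
TOWARD_POSTNATAL = "toward_postnatal"
UNKNOWN = "unknown"


def classify_direction(
    delta_dev: Optional[float], delta_dm1: Optional[float]
) -> str:
    """Direction of the disease change relative to the fetal program.

    ``toward_prenatal`` when the DM1-vs-unaffected change has the same
    nonzero sign as the prenatal-vs-postnatal change, ``toward_postnatal``
    for opposite nonzero signs, ``unknown`` when either delta is missing or
    exactly zero.
    """
    missing_dev = delta_dev is None or (isinstance(delta_dev, float) and math.isnan(delta_dev))
    missing_dm1 = delta_dm1 is None or (isinstance(delta_dm1, float) and math.isnan(delta_dm1))
    if missing_dev and missing_dm1:
        raise ValueError("both deltas missing: nothing to classify")
    if missing_dev or missing_dm1 or delta_dev == 0 or delta_dm1 == 0:
        return UNKNOWN
    return TOWARD_PRENATAL if (delta_dev > 0) == (delta_dm1 > 0) else TOWARD_POSTNATAL


def intersect_high_confidence(
    dev_results: pd.DataFrame, dm1_results: pd.DataFrame
) -> pd.DataFrame:
    """Join developmental and disease results on event id.

    Inputs are :func:`fetalsplice.differential.detect_events` tables whose
    delta columns follow the package sign convention (prenatal - postnatal
    and DM1 - unaffected respectively). Returns one row per event in the
    union with significance flags, both deltas (NaN where unmeasured), the
    direction class and the high-confidence flag (significant in both with
    same-sign deltas).
    """
    if not dev_results.index.intersection(dm1_results.index).size:
        raise ValueError("developmental and disease results share no event ids")
    dev = dev_results[["delta_psi", "p", "significant"]].rename(
        columns={"delta_psi": "delta_dev", "p": "p_dev", "significant": "sig_dev"}
    )
    dm1 = dm1_results[["delta_psi", "p", "significant"]].rename(
        columns={"delta_psi": "delta_dm1", "p": "p_dm1", "significant": "sig_dm1"}
    )
    joined = dev.join(dm1, how="outer")
    joined["sig_dev"] = joined["sig_dev"].eq(True)  # NaN (unmeasured) -> False
    joined["sig_dm1"] = joined["sig_dm1"].eq(True)
    joined["direction"] = [
        classify_direction(d, m)
        for d, m in zip(joined["delta_dev"], joined["delta_dm1"])
    ]
    joined["high_confidence"] = (
        joined["sig_dev"]
        & joined["sig_dm1"]
        & (joined["direction"] == TOWARD_PRENATAL)
    )
    return joined


def overlap_enrichment(
    n_universe: int, n_set_a: int, n_set_b: int, n_overlap: int
) -> float:
    """One-sided overlap enrichment p-value: P(X >= n_overlap) under the
    hypergeometric null (Fisher exact upper tail), computed via
    log-factorials."""
    if not (0 <= n_overlap <= min(n_set_a, n_set_b) <= max(n_set_a, n_set_b) <= n_universe):
        raise ValueError(
            f"inconsistent counts: universe={n_universe}, A={n_set_a}, "
            f"B={n_set_b}, overlap={n_overlap}"
        )
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_set_a, n_set_b))


def direction_tally(results: pd.DataFrame, criterion: str = "both_p",
                    p_threshold: float = 0.01) -> pd.Series:
    """Counts per direction among events passing a significance criterion.

    ``both_p``: rank-sum p < p_threshold in both datasets (the stricter
    histogram criterion); ``either``: significant under the joint
    p + |delta| rule in at least one dataset.
    """
    if criterion == "both_p":
        mask = (results["p_dev"] < p_threshold) & (results["p_dm1"] < p_threshold)
    elif criterion == "either":
        mask = results["sig_dev"] | results["sig_dm1"]
    else:
        raise ValueError(f"criterion must be 'both_p' or 'either', got {criterion!r}")
    sub = results.loc[mask.fillna(False)]
    return sub["direction"].value_counts().reindex(
        [TOWARD_PRENATAL, TOWARD_POSTNATAL, UNKNOWN], fill_value=0
    )
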
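"""Percent-spliced-in (PSI) estimation from inclusion/exclusion junction counts.

The estimator is a simplified Bayesian point estimate: counts are first
normalized by the number of read positions supporting each isoform (a
skipped-exon event has two inclusion junctions but only one skipping
junction), rescaled to preserve the total read mass, and the posterior mean
under a uniform Beta(1, 1) prior is reported. The posterior mean is bounded
away from 0 and 1, and an event with no informative reads falls back to the
prior mean 0.5 and is flagged undetected.

Dataset-level filtering follows the study design: an event is kept only if
it is detected (>= ``min_reads`` informative reads) in **every** sample of
the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

__all__ = ["PsiMatrix", "estimate_psi", "build_psi_matrix"]


@dataclass
class PsiMatrix:
    """Events x samples inclusion estimates with a detection mask."""

    psi: pd.DataFrame        # events x samples, values in [0, 1]
    detected: pd.DataFrame   # same shape, bool
    dataset: str = ""
    kept_events: List[str] = None
    dropped_events: List[str] = None

    def __post_init__(self) -> None:
        vals = self.psi.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("PSI values must lie in [0, 1]")


def estimate_psi(
    inclusion,
    exclusion,
    inclusion_positions: int = 2,
    exclusion_positions: int = 1,
):
    """Posterior-mean inclusion estimate for one or many events.

    Counts are length-normalized (I~ = inclusion / inclusion_positions,
    E~ = exclusion / exclusion_positions), rescaled so I' + E' equals the
    observed total, and the Beta(1, 1) posterior mean (I' + 1)/(I' + E' + 2)
    is returned. Accepts scalars or arrays. The defaults (2, 1) encode the
    standard skipped-exon junction geometry; counts that are already
    isoform-level effective counts should use (1, 1).
    """
    inc = np.asarray(inclusion, dtype=float)
    exc = np.asarray(exclusion, dtype=float)
    if np.any(inc < 0) or np.any(exc < 0):
        raise ValueError("junction counts must be non-negative")
    if inclusion_positions < 1 or exclusion_positions < 1:
        raise ValueError("position counts must be >= 1")
    i_norm = inc / inclusion_positions
    e_norm = exc / exclusion_positions
    total = inc + exc
    norm_total = i_norm + e_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norm_total > 0, total / np.where(norm_total > 0, norm_total, 1.0), 0.0)
    i_prime = i_norm * scale
    e_prime = e_norm * scale
    out = (i_prime + 1.0) / (i_prime + e_prime + 2.0)
    return out if out.ndim else float(out)


def build_psi_matrix(
    inclusion: pd.DataFrame,
    exclusion: pd.DataFrame,
    min_reads: int = 10,
    dataset: str = "",
    inclusion_positions: int = 1,
    exclusion_positions: int = 1,
) -> PsiMatrix:
    """Assemble a filtered PSI matrix for one dataset.

    ``inclusion`` and ``exclusion`` are events x samples count tables with
    identical indexes. An event is detected in a sample when its informative
    reads (inclusion + exclusion) reach ``min_reads``; events not detected in
    every sample of the dataset are excluded from it. Returns the matrix plus
    the kept/dropped event lists.
    """
    if not inclusion.index.equals(exclusion.index) or not inclusion.columns.equals(
        exclusion.columns
    ):
        raise ValueError("inclusion and exclusion tables must share index and columns")
    inc = inclusion.to_numpy(dtype=float)
    exc = exclusion.to_numpy(dtype=float)
    detected = (inc + exc) >= min_reads
    keep = detected.all(axis=1)
    psi = estimate_psi(
        inc[keep], exc[keep], inclusion_positions, exclusion_positions
    )
    kept = list(inclusion.index[keep])
    dropped = list(inclusion.index[~keep])
    return PsiMatrix(
        psi=pd.DataFrame(psi, index=kept, columns=inclusion.columns),
        detected=pd.DataFrame(
            detected[keep], index=kept, columns=inclusion.columns
        ),
        dataset=dataset,
        kept_events=kept,
        dropped_events=dropped,
    )
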
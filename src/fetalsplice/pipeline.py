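"""End-to-end orchestration: simulate -> PSI -> expression -> differential ->
cross-dataset -> correlations, with all tables written as TSV and a
machine-readable run manifest.

The manifest mirrors the tallies a study of this design reports: number of
significant developmental events, significant disease events, their overlap
with its enrichment p-value, the direction histogram (toward-prenatal vs
toward-postnatal vs unknown), regulator log fold changes, and the
shuffling-based empirical FDR of the detection rule. Runs are idempotent for
a fixed seed.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import (
    compare_zero_order_vs_partial,
    pairwise_event_correlations,
    psi_regulator_correlations,
)
from .cross_dataset import direction_tally, intersect_high_confidence, overlap_enrichment
from .differential import detect_events, permutation_fdr
from .expression import group_logfc, log2_cpm, tmm_factors
from .io import write_junction_counts, write_matrix, write_table
from .psi import build_psi_matrix
from .simulate import REGULATORS, CohortConfig, simulate_gene_counts, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("fetalsplice")

_GROUPS = {
    "development": ("prenatal", "postnatal"),
    "dm1": ("dm1", "unaffected"),
}


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    outdir: str = "fetalsplice_run"
    seed: int = 0
    n_events: int = 500
    frac_true_fetal_shift: float = 0.10
    n_group_a: int = 20
    n_group_b: int = 20
    depth: float = 50.0
    concentration: float = 30.0
    dm1_shift: float = 0.6
    delta_threshold: float = 0.2
    p_threshold: float = 0.01
    fdr_level: float = 0.05
    min_reads: int = 10
    n_shuffles: int = 100
    tally_criterion: str = "both_p"
    max_pairwise_events: int = 40
    run_fdr: bool = True
    run_correlations: bool = True

    def validate(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError(f"p_threshold={self.p_threshold} outside (0, 1)")
        if not 0 <= self.delta_threshold:
            raise ValueError("delta_threshold must be non-negative")
        if self.min_reads < 0 or self.n_shuffles < 1:
            raise ValueError("min_reads must be >= 0 and n_shuffles >= 1")
        self.cohort_config().validate()

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_events=self.n_events,
            frac_true_fetal_shift=self.frac_true_fetal_shift,
            n_group_a=self.n_group_a,
            n_group_b=self.n_group_b,
            depth=self.depth,
            concentration=self.concentration,
            dm1_shift=self.dm1_shift,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage and return the manifest dictionary.

    Writes, under ``config.outdir``: per-cohort metadata, junction counts,
    regulator expression and PSI matrices; differential tables; the
    cross-dataset table and direction tally; correlation tables; and
    ``manifest.json`` holding the resolved config and all stage counts.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "tool": "fetalsplice",
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    cohorts = simulate_study(config.cohort_config())
    for kind, cohort in cohorts.items():
        write_table(cohort.metadata, outdir / f"{kind}_metadata.tsv")
        write_junction_counts(
            cohort.inclusion, cohort.exclusion, outdir / f"{kind}_junction_counts.tsv"
        )
        write_matrix(cohort.regulator_expr, outdir / f"{kind}_regulator_expr.tsv", "gene")
    write_matrix(cohorts["development"].truth, outdir / "truth.tsv", "event_id")
    log.info("simulate: %d events, cohorts %s", config.n_events, list(cohorts))
    manifest["stages"]["simulate"] = {
        "n_events": config.n_events,
        "n_samples": {k: len(c.metadata) for k, c in cohorts.items()},
    }

    # --- psi ---------------------------------------------------------------
    psi_matrices = {}
    for kind, cohort in cohorts.items():
        pm = build_psi_matrix(
            cohort.inclusion, cohort.exclusion, min_reads=config.min_reads, dataset=kind
        )
        psi_matrices[kind] = pm
        write_matrix(pm.psi, outdir / f"{kind}_psi.tsv", "event_id")
        log.info("psi[%s]: kept %d / dropped %d events", kind,
                 len(pm.kept_events), len(pm.dropped_events))
    manifest["stages"]["psi"] = {
        k: {"kept": len(pm.kept_events), "dropped": len(pm.dropped_events)}
        for k, pm in psi_matrices.items()
    }

    # --- expression ---------------------------------------------------------
    logfc = {}
    expr_norm = {}
    for kind, cohort in cohorts.items():
        counts = simulate_gene_counts(cohort)
        factors = tmm_factors(counts)
        cpm = log2_cpm(counts, factors)
        expr_norm[kind] = cpm
        write_matrix(cpm, outdir / f"{kind}_log2cpm.tsv", "gene")
        if kind in _GROUPS:
            hi, lo = ("postnatal", "prenatal") if kind == "development" else (
                "dm1", "unaffected")
            logfc[kind] = {
                g: group_logfc(cpm, cohort.metadata, g, hi, lo) for g in REGULATORS
            }
    manifest["stages"]["expression"] = {"regulator_logfc": logfc}
    log.info("expression: regulator logFC %s", logfc)

    # --- differential -------------------------------------------------------
    diff = {}
    fdr = {}
    for kind in ("development", "dm1"):
        ga, gb = _GROUPS[kind]
        res = detect_events(
            psi_matrices[kind].psi, cohorts[kind].metadata, ga, gb,
            config.delta_threshold, config.p_threshold,
        )
        diff[kind] = res
        write_table(res.reset_index(), outdir / f"{kind}_differential.tsv")
        if config.run_fdr:
            fdr[kind] = permutation_fdr(
                psi_matrices[kind].psi, cohorts[kind].metadata, ga, gb,
                config.delta_threshold, config.p_threshold,
                n_shuffles=config.n_shuffles, seed=config.seed,
            )
        log.info("differential[%s]: %d significant of %d events",
                 kind, int(res["significant"].sum()), len(res))
    manifest["stages"]["differential"] = {
        k: {"n_events": len(v), "n_significant": int(v["significant"].sum())}
        for k, v in diff.items()
    }
    manifest["stages"]["differential"]["empirical_fdr"] = fdr

    # --- cross-dataset ------------------------------------------------------
    cross = intersect_high_confidence(diff["development"], diff["dm1"])
    write_table(cross.reset_index(), outdir / "cross_dataset.tsv")
    universe = len(diff["development"].index.intersection(diff["dm1"].index))
    n_dev = int(diff["development"]["significant"].sum())
    n_dm1 = int(diff["dm1"]["significant"].sum())
    n_overlap = int((cross["sig_dev"] & cross["sig_dm1"]).sum())
    fisher_p = overlap_enrichment(universe, n_dev, n_dm1, n_overlap) if universe else 1.0
    tally = direction_tally(cross, config.tally_criterion, config.p_threshold)
    write_table(tally.rename("count").reset_index(), outdir / "direction_tally.tsv")
    n_high_conf = int(cross["high_confidence"].sum())
    manifest["stages"]["cross_dataset"] = {
        "universe": universe,
        "n_significant_development": n_dev,
        "n_significant_dm1": n_dm1,
        "n_overlap": n_overlap,
        "n_high_confidence": n_high_conf,
        "fisher_p": fisher_p,
        "direction_tally": {k: int(v) for k, v in tally.items()},
    }
    log.info("cross_dataset: dev %d / dm1 %d / overlap %d (p=%.3g), tally %s",
             n_dev, n_dm1, n_overlap, fisher_p, dict(tally))

    # --- correlations -------------------------------------------------------
    if config.run_correlations:
        hc = cross.index[cross["high_confidence"]]
        if len(hc) > config.max_pairwise_events:
            top = cross.loc[hc, "delta_dm1"].abs().nlargest(config.max_pairwise_events)
            hc = top.index
        corr_summary = {}
        for kind, cohort in cohorts.items():
            pm = psi_matrices[kind]
            events = [e for e in hc if e in pm.psi.index]
            if len(events) < 2:
                continue
            sub = pm.psi.loc[events]
            reg = psi_regulator_correlations(sub, expr_norm[kind], REGULATORS, kind)
            write_table(reg, outdir / f"{kind}_event_regulator_corr.tsv")
            pairs = pairwise_event_correlations(sub)
            write_table(pairs, outdir / f"{kind}_pairwise_corr.tsv")
            cov_sets = {
                "age": pd.DataFrame(
                    {"log10_age": np.log10(cohort.metadata["age_days"].to_numpy())},
                    index=cohort.metadata["sample_id"],
                ),
                "regulators": expr_norm[kind].loc[list(REGULATORS)].T,
            }
            if kind == "dm1":
                cov_sets["disease"] = pd.DataFrame(
                    {"dm1": (cohort.metadata["group"] == "dm1").astype(float).to_numpy()},
                    index=cohort.metadata["sample_id"],
                )
            comparison = compare_zero_order_vs_partial(sub, cov_sets)
            write_table(comparison, outdir / f"{kind}_partial_corr_summary.tsv")
            corr_summary[kind] = {
                "n_events": len(events),
                "n_pairs": len(pairs),
                "median_abs_rho": float(pairs["rho"].abs().median()),
                "partial": comparison.set_index("controlled_for")[
                    ["median_abs_partial", "p", "q"]
                ].to_dict("index"),
            }
            log.info("correlation[%s]: %d events, median |rho| %.2f",
                     kind, len(events), corr_summary[kind]["median_abs_rho"])
        manifest["stages"]["correlation"] = corr_summary

    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
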
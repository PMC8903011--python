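"""Splicing-factor balance: expression normalization and correlation analyses.

TMM-normalizes simulated gene counts to log2-CPM, recovers the developmental
fold changes of CELF1/MBNL1/MBNL2, correlates event inclusion with regulator
expression, and shows the zero-order vs partial correlation comparison that
separates age/disease-driven coordination from residual association.
"""

import numpy as np
import pandas as pd

from fetalsplice.correlation import (
    compare_zero_order_vs_partial,
    psi_regulator_correlations,
)
from fetalsplice.expression import group_logfc, log2_cpm, tmm_factors
from fetalsplice.psi import build_psi_matrix
from fetalsplice.simulate import REGULATORS, CohortConfig, simulate_gene_counts, simulate_study

config = CohortConfig(n_events=300, frac_true_fetal_shift=0.12, seed=2)
study = simulate_study(config)
dev, dm1 = study["development"], study["dm1"]

# --- TMM normalization and developmental fold changes ------------------------
counts = simulate_gene_counts(dev)
cpm = log2_cpm(counts, tmm_factors(counts))
print("developmental log2 fold changes (postnatal - prenatal):")
for gene in REGULATORS:
    fc = group_logfc(cpm, dev.metadata, gene, "postnatal", "prenatal")
    print(f"  {gene}: {fc:+.2f}")
# Expected pattern: CELF1 falls (~ -1.2) while MBNL1 (~ +1.6) and MBNL2
# (~ +2.7) rise over development.

# --- event-regulator correlations --------------------------------------------
pm = build_psi_matrix(dev.inclusion, dev.exclusion)
regulated = [e for e in dev.truth.index[dev.truth.regulated] if e in pm.psi.index]
corr = psi_regulator_correlations(pm.psi.loc[regulated[:20]], dev.regulator_expr)
sig = corr[corr["q"] < 0.05]
print(f"\nevent-regulator correlations: {len(sig)}/{len(corr)} significant (q < 0.05)")
print(sig.groupby("regulator")["rho"].median().round(2).to_string())

# --- zero-order vs partial pairwise correlations ------------------------------
for kind in ("development", "dm1"):
    cohort = study[kind]
    pm = build_psi_matrix(cohort.inclusion, cohort.exclusion)
    events = [e for e in cohort.truth.index[cohort.truth.regulated][:20]
              if e in pm.psi.index]
    meta = cohort.metadata.set_index("sample_id")
    covariate_sets = {
        "age": pd.DataFrame({"log10_age": np.log10(meta["age_days"])}),
        "regulators": cohort.regulator_expr.T,
    }
    if kind == "dm1":
        covariate_sets["disease"] = pd.DataFrame(
            {"dm1": (meta["group"] == "dm1").astype(float)}
        )
    comparison = compare_zero_order_vs_partial(pm.psi.loc[events], covariate_sets)
    print(f"\n{kind}: zero-order vs partial |rho| (median)")
    print(comparison.round(3).to_string(index=False))
# In the developmental cohort controlling for age (or regulator expression)
# collapses the pairwise correlations; in the disease cohort only controlling
# for disease state does, showing coordination is driven by the DM1 shift
# rather than by inter-individual regulator mRNA variation.
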
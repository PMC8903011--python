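# fetalsplice

Analysis toolkit for developmentally regulated cassette-exon splicing and its
reversion to the fetal program in the adult brain of myotonic dystrophy
type 1 (DM1) patients.

In DM1, expanded CUG-repeat RNA sequesters MBNL proteins and stabilizes
CELF1, tilting the balance of two antagonistic splicing-regulator families:
MBNL1/2 promote adult exon-inclusion patterns, CELF1 promotes fetal ones.
The expected consequence is that cassette exons whose inclusion changes over
brain development drift back toward their prenatal levels in adult DM1
tissue. `fetalsplice` implements the full analysis that tests this
transcriptome-wide, for anyone who has (or simulates) per-sample
inclusion/exclusion junction counts and gene-level expression counts:

1. **PSI estimation** — percent spliced-in, Ψ ∈ [0, 1], per event and
   sample: junction counts are position-normalized and the Beta(1, 1)
   posterior mean Ψ̂ = (I′+1)/(I′+E′+2) is reported; events not detected
   (≥ `min_reads` informative reads) in every sample of a dataset are
   excluded from that dataset.
2. **Differential inclusion** — two-sided Wilcoxon rank-sum per event;
   an event is significant when *p* < 0.01 **and** |ΔΨ| > 0.2. The screen is
   deliberately not multiplicity-corrected; instead the empirical FDR of the
   joint rule is estimated by re-running it on randomly shuffled sample
   labels: FDR = mean(#discoveries under shuffling) / #observed discoveries.
3. **Cross-dataset intersection** — with ΔΨ_dev = Ψ(prenatal) − Ψ(postnatal)
   and ΔΨ_DM1 = Ψ(DM1) − Ψ(unaffected), an event reverts *toward the
   prenatal pattern* when the two deltas share a sign. Events significant in
   both datasets with consistent direction are the high-confidence set; the
   overlap is tested by the one-sided Fisher exact (hypergeometric) test.
4. **Expression normalization** — TMM scaling factors (trimmed mean of
   M-values, 30%/5% trims, precision-weighted) and log2-CPM, for regulator
   fold changes such as logFC(CELF1), logFC(MBNL1/2) across development.
5. **Correlation analyses** — Spearman correlations of event Ψ with
   CELF1/MBNL1/MBNL2 expression (BH-corrected per study), all-pairs event
   cross-correlations, and partial Spearman correlations (precision-matrix
   normalization on ranks) that remove the effect of age, disease state or
   regulator expression; plus LOESS trajectory smoothing for developmental
   curves.
6. **Synthetic cohorts** — a ground-truthed generator emulating the three
   study designs (developing brain, DM1 vs unaffected, healthy adults) with
   logistic regulator trajectories in log10 post-conceptional age,
   balance-coupled event inclusion, a configurable partial fetal shift in
   DM1 samples, and beta-binomial junction-count noise. The real studies of
   this kind use controlled-access data; the generator makes every stage
   testable without any download.

The package also ships the table of 34 DM1-relevant developmental splice
events in the frontal cortex (hg38 coordinates) with coordinate arithmetic,
reading-frame classification and cassette-exon deduplication.

## Worked example

```bash
python examples/02_simulate_and_detect.py
```

```
PSI matrix: kept 2000 events, dropped 0
significant events (p < 0.01, |dPSI| > 0.2): 200
sensitivity on truly regulated events: 100.0%
false positives among null events: 0
shuffling-based empirical FDR estimate: 2.03%
```

2000 events are simulated at depth 50 with 10% truly coupled to the
MBNL/CELF balance (|ΔΨ| ≥ 0.3 between prenatal and postnatal groups, 20
samples each). The joint rule recovers all 200 regulated events with no
false calls, and the label-shuffling FDR estimate of the rule is ~2%, well
inside the 5% the screen is designed for.

The other examples cover the event-table arithmetic
(`01_event_table.py`), the cross-dataset intersection and direction tally
(`03_cross_dataset.py` — e.g. 35/40 planted fetal-reversion events recovered
as high-confidence, Fisher p ≈ 3e-45), the TMM/correlation analyses
(`04_regulator_balance.py`) and the full pipeline with its run manifest
(`05_full_pipeline.py`). A thin CLI mirrors the stages
(`fetalsplice simulate|psi|expr|diff|cross|corr|run|report|events`).

## Layout

- `src/fetalsplice/` — `events`, `simulate`, `psi`, `expression`,
  `differential`, `cross_dataset`, `correlation`, `io`, `pipeline`, `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests
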
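# mirqc

Quality control and abundance-stratified analysis of high-throughput
qPCR microRNA array data.

## The problem

MicroRNA expression is routinely profiled on 384-well microfluidic qPCR
cards (365 microRNA assays plus duplicated endogenous controls and blank
wells per card). The readout per well is a cycle threshold, Ct: the PCR
cycle at which fluorescence crosses the detection threshold. Lower Ct
means more template; a reaction that never crosses within the 40-cycle
run is reported as "Undetermined" and is a *censored* observation at the
instrument ceiling, not a measurement.

Archival formalin-fixed, paraffin-embedded (FFPE) tissue makes such
profiling attractive for retrospective studies — microRNAs survive
fixation far better than mRNA — but fixation chemistry reduces effective
RNA yield, shifting Ct upward by roughly 1–1.5 cycles relative to paired
fresh-frozen tissue and pushing weakly expressed species over the
detection ceiling. Measurement quality is strongly Ct-dependent:
duplicate plates agree tightly for abundant targets and poorly near the
limit of detection. Analyses that ignore this structure mix reliable and
unreliable signal.

`mirqc` implements the analysis toolkit for this setting, for anyone
running TaqMan-style microRNA cards on FFPE or fresh-frozen material:

* **Ct ingestion** (`mirqc.io`) — long/wide CSV dialects, explicit
  censoring at Ct = 40, plate-layout roles, the all-censored pre-filter,
  and the *equivalent samples* predicate (equal input-RNA concentration
  over cDNA fold-dilution).
* **Abundance strata** (`mirqc.strata`) — high (Ct < 30), medium
  (30 ≤ Ct ≤ 35), low (Ct > 35); duplicate-agreement points
  (|Ct_a − Ct_b| vs mean Ct) and a GCV-selected cubic smoothing spline
  through them; per-stratum count tables.
* **Well failures** (`mirqc.failures`) — the duplicate-based failure
  calls (single / double / not-expressed, arbitrated by reference
  conditions and the Universal RNA positive control) and
  `percent failures = average failures between duplicates /
  microRNAs expressed × 100`.
* **Concordance** (`mirqc.concordance`) — Pearson r with the asymptotic
  t-distribution p-value, computed overall and within each abundance
  stratum (each microRNA assigned once, by its mean Ct); group Ct
  summaries and paired group differences.
* **Abundance shift** (`mirqc.shift`) — stratum-count contingency
  tables, the Pearson chi-square test of independence
  `X² = Σ (O − E)² / E` (no continuity correction, upper-tail p via the
  regularised incomplete gamma function), and 3×3 stratum-migration
  tables between methods.
* **Sample structure** (`mirqc.structure`) — one-minus-Pearson
  correlation distance, agglomerative clustering (complete linkage
  default, Newick export) and PCA of per-assay-centred profiles.
* **Synthetic studies** (`mirqc.simulate`) — a ground-truthed generator
  emulating the card: mixture baseline Cts, concentration/dilution
  effects, the FFPE shift, Ct-dependent replicate noise, logistic well
  failure, censoring at 40 — plus `recover_parameters` to close the
  loop.
* **Pipeline & CLI** (`mirqc.pipeline`, `mirqc` console script) — YAML
  config to a full CSV report bundle; subcommands `simulate`,
  `stratify`, `failures`, `concordance`, `shift`, `cluster`, `report`.

## Worked example

```python
import numpy as np
from mirqc import (SimConfig, simulate_concentration_series,
                   stratified_pairwise_correlations,
                   summarize_duplicate_failures, chi_square_independence)

cfg = SimConfig(seed=1)                      # 365 microRNAs, default study
matrix, truth = simulate_concentration_series(cfg)

# replicate concordance by abundance stratum (duplicate 200 ng/uL plates)
strat = stratified_pairwise_correlations(matrix, ["conc200-r1", "conc200-r2"])
print(strat.table[["stratum", "r", "n"]].round(3).to_string(index=False))

# well-failure rate at the lowest input RNA concentration
summ, _ = summarize_duplicate_failures(
    matrix, "conc10-r1", "conc10-r2",
    reference_conditions=["conc200-r1", "conc200-r2"])
print(f"percent well failures at 10 ng/uL: {summ.percent_failures:.1f}")

# abundance-shift test on a published-style count table
table = np.array([[90, 125], [122, 141], [172, 118]])   # low/medium/high
res = chi_square_independence(table)
print(f"chi-square = {res.statistic:.2f}, df = {res.df}, p = {res.p:.4f}")
```

prints

```
stratum      r   n
    low -0.192  37
 medium  0.527 108
   high  0.996 111
percent well failures at 10 ng/uL: 45.8
chi-square = 17.13, df = 2, p = 0.0002
```

Reading it: duplicate plates are near-interchangeable for abundant
microRNAs (r = 0.996) and close to uninformative near the detection
limit (r ≈ −0.2 on the few pairs that escaped censoring) — the reason
the package stratifies everything. Failures are rampant at 10 ng/µL
input (and fall monotonically as input rises). The contingency test
shows a fresh-frozen vs FFPE panel redistributing microRNAs across
strata far beyond chance.

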
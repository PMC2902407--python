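# Methods

This note documents the statistical procedures `mirqc` implements, the
generative model behind its synthetic studies, the defaults and why they
were chosen, and the limits of what the synthetic tests demonstrate.

## Censoring convention

A qPCR run of 40 cycles can only report Ct ≤ 40. "Undetermined" wells
and literal 40s are stored as `ct = 40, censored = True`; values above
40 are rejected as range errors rather than clamped, because the ceiling
is a hard instrument limit, not a rounding convention. Censored values
are detection *bounds*. They are therefore

* **excluded** from duplicate-agreement points and (by default) from
  Pearson correlations — a pair of 40s would fabricate agreement at the
  ceiling;
* **included at 40** in stratum count tables (an undetected microRNA is
  the extreme of low abundance; this also keeps column totals equal to
  the panel size), in group Ct summaries, and in the per-assay mean Cts
  used for stratum assignment, migration tables, clustering and PCA.

Both choices are switchable (`censor_policy`, `include_censored`)
because published analyses are not always explicit about them.

The pre-filter drops microRNA assays censored in *every* condition; a
single sub-40 value anywhere retains the assay. Endogenous controls and
blank wells are tracked by role and never filtered, never counted among
failures, and never entered into microRNA-level statistics.

## Abundance strata

Cutoffs: high Ct < 30, medium 30 ≤ Ct ≤ 35, low Ct > 35. The medium
stratum is closed on both ends; the cutoffs are configuration, not
re-estimated from data. The supporting diagnostic is the
duplicate-agreement curve: |ΔCt| between duplicate plates against their
mean Ct, smoothed by a cubic smoothing spline whose roughness penalty is
selected by generalised cross-validation
(`scipy.interpolate.make_smoothing_spline`; the selected penalty is not
exposed numerically, so `SplineFit.lam` records `None`). Tied abscissae
are averaged before fitting; fits require ≥ 10 distinct points spanning
more than 2 cycles. Predictions are defined on the observed mean-Ct
range — near the ceiling the apparent drop in spread is a censoring
artifact, since |ΔCt| cannot exceed 40 − mean.

Count-table aggregation across a group of conditions is either
`per_sample_average` (stratify every well, count per condition, average,
round half-up — integer tables are required downstream) or `mean_ct`
(stratify each assay's group-mean Ct, so each assay lands in exactly one
cell).

## Well failures

With duplicate plates, per microRNA: one well at 40 and its duplicate
below 40 is a single failure; both at 40 with the same assay amplifying
at another concentration of the same sample or in the Universal RNA
positive control is a double failure charged to both plates; both at 40
without reference evidence means the microRNA is treated as not
expressed and excluded from the denominator (conservative: no evidence
of expression, no failure charged). The summary statistic is
average-failures-between-duplicates / microRNAs-expressed × 100. The
single-plate variant counts 40s among assays known to be expressed in
that sample from other runs.

## Concordance

Pearson r is computed on pairwise-complete observations, p from
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom (two-sided; |r| = 1 maps
to p = 0); fewer than 3 pairs or zero variance raises rather than
returning NaN. The stratified analysis assigns each microRNA one stratum
from its mean Ct across the compared conditions, then computes all
pairwise correlations within each stratum; strata with < 3 assays are
flagged and skipped without failing the rest. A mixed-model "adjusted"
correlation is deliberately not offered: no model specification exists
to reproduce, so only plain per-pair correlations are reported. The
FFPE-vs-frozen location comparison uses a two-sided paired t-test on
per-assay group-mean Cts; the choice of a paired t-test is an
interpretation, and is labelled as such where reported.

## Abundance-shift tests

Pearson chi-square on strata × groups count tables:
X² = Σ (O−E)²/E with E from the product of margins, df =
(rows−1)(columns−1), p = Q(df/2, X²/2) through the regularised
incomplete gamma function. No Yates correction (tables are 3×2/3×3).
Zero row or column totals are degenerate and raise; expected counts
below 5 warn without aborting, since small synthetic tables can
legitimately reach the test. Migration tables cross-tabulate each
assay's stratum under two methods from group-mean Cts; off-diagonal
asymmetry (e.g. high→medium exceeding medium→high) is the signature of
a directional abundance shift.

## Sample structure

Distance d = 1 − Pearson r between condition profiles over the shared
microRNA panel (optionally restricted to one abundance stratum),
followed by agglomerative clustering — complete linkage by default,
matching the common default of the standard hierarchical-clustering
implementation; linkage is configurable because published analyses
rarely state it. SciPy's implementation is deterministic with
lowest-index tie-breaking; trees export to Newick with branch lengths
from merge-height differences. PCA operates on per-assay-centred
profiles via SVD, with each component's sign fixed so its first nonzero
loading is positive — scores are then reproducible across runs and BLAS
builds. Correlation distance is invariant to any per-condition affine
increasing rescaling of Ct, which is why a uniform FFPE shift does not
separate preservation states in the dendrogram.

## The synthetic-study generator

For assay i in condition c:

    true_ct(i,c) = base_i
                   − slope · log2(conc_c / conc_ref)
                   + penalty · log2(dil_c / dil_min)
                   + shift_i · 1[FFPE] + effect_i · 1[tumour]
                   + b_{s(c), i}
    observed     = true_ct + ε,   ε ~ N(0, σ(true_ct))
    σ(t)         = σ0 + σ1 · max(0, t − knee)
    P(fail)      = logistic((true_ct − m_c) · k)
    m_c          = m0 − coupling · log2(dil_c / dil_min)

Failed wells and observations ≥ 40 are emitted as Ct = 40, censored;
duplicate plates are independent noise/failure draws.

Defaults and their rationale:

* `baseline` mixture: three normal components at Ct 26/32/37, SDs
  2.5/1.5/1.5, weights 0.30/0.34/0.36 — chosen once so that a 200 ng/µL
  plate occupies all three strata at comparable strength (order 100+
  assays each), the regime the analysis is designed for.
* `efficiency_slope` = 1.0 cycle per log2 of input amount: ideal PCR
  doubling per cycle.
* `ffpe_shift` = 1.25 ± 0.25 cycles: centre of the 1.0–1.5-cycle loss
  reported for FFPE against paired fresh-frozen tissue.
* noise: σ0 = 0.15 cycles below the knee at Ct 30, growing by σ1 = 0.25
  cycles per cycle above it — reproduces tight high-abundance
  replication degrading to near-uninformative replication above Ct 35.
* failures: logistic midpoint Ct 38, steepness 1/cycle; cDNA dilution
  lowers the midpoint by 0.5 · log2(dilution/5) rather than shifting Ct
  (`dilution_penalty` defaults to 0), because dilution observably costs
  detection more than location. `failure_midpoint = inf` disables
  failures for deterministic checks.
* `subject_sd` = 0.3 cycles: per-subject-per-assay biological variation
  shared between the FFPE and frozen halves of a specimen. This term is
  an extension of the design-effect formula above; without it all
  subjects of a disease state are clones up to technical noise and
  clustering would be trivially easy.
* differential expression: 60 of 365 microRNAs at ±3 cycles
  (≈ 8-fold), sign randomised — strong tumour/normal biology of the
  kind the clinical comparison is meant to detect, larger than the
  technical FFPE effect.

`recover_parameters` closes the loop: the FFPE shift is re-estimated as
the mean paired FFPE-minus-frozen difference over high-abundance,
fully-uncensored assays (near the ceiling the estimate would be biased
low, because censoring preferentially removes pairs whose FFPE noise
draw was high); the efficiency slope by within-assay least squares over
assays that are high-abundance at the reference concentration; and the
per-stratum noise scale from duplicate differences as √(mean(ΔCt²)/2).

### What the generator does and does not emulate

It reproduces the *structure* of real card data — censoring, abundance
composition, Ct-dependent replicate agreement, concentration/dilution
response, the FFPE shift, stratum migration, tumour/normal separation —
so passing tests demonstrate that the analysis code detects each of
these effects when present and stays calibrated under the null.
It does not emulate extraction-chemistry-specific assay effects,
probe-level cross-reactivity, plate spatial artifacts, or
between-subject heterogeneity beyond a single Gaussian term; synthetic
cross-preservation correlations therefore run higher (~0.96) than the
published real-data values (~0.87), and synthetic per-stratum counts
need not match published tables numerically. Numerical claims about
real data require real data.

One power note, established by simulation: with the default mixture, a
+1.25-cycle FFPE shift moves the 3×2 stratum-count chi-square to only
≈ 4–7 at a 365-assay panel (p ≈ 0.03–0.14, seed-dependent). The
direction of the shift (low counts up, high counts down in FFPE) and
the migration-table asymmetry are robust across seeds and are what the
tests assert; published chi-squares in the high teens reflect real
per-sample count structure the generator does not claim to match.

## Problem sizes in the test suite

Unit and property tests run on small hand-built matrices or
reduced panels (20–80 microRNAs); the end-to-end scientific checks and
`scripts/acceptance.py` use the full default study (365 microRNAs,
duplicate plates over five concentrations, two-method clinical design,
10,000 null tables for calibration), which completes in seconds.
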
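# Methods

## Fragment distribution values

DV_N is mass-weighted: the percentage of total nucleic-acid *mass*
(fluorescence area) in fragments longer than N nt, not the percentage of
molecules. This matches the vendor definition of DV200 that the field
inherits. The threshold comparison is strict (`> N`): mass exactly at the
threshold counts as below. Both conventions are pinned in one place
(`fragment_metrics`) and documented because vendors do not publish them.

Computed profiles are non-increasing in the threshold by construction, DV
values are invariant under any positive rescaling of the mass axis, and
`DVProfile` carries a `failed` status instead of raising when a trace cannot
be evaluated — mirroring how real cohorts end up with NA rows in their QC
tables (14 of the 67 samples in the packaged table).

### Trace pipeline

Raw electropherograms are processed as: rolling-minimum baseline
subtraction → median-filter smoothing with a robust noise floor →
lower-marker detection and excision → integration above each threshold.
Numerical choices, all configurable in `TraceConfig`:

- **Baseline**: rolling minimum of the median-filtered signal; default
  window is the whole trace (a constant-offset model). The minimum statistic
  is biased low under noise, so the residual level — the lower quartile of
  the subtracted signal, exactly zero for a clean trace whose size axis is
  mostly signal-free — is subtracted as a correction. Narrower windows are
  for drifting baselines.
- **Smoothing and noise floor**: a 9-point median filter, then samples
  below 2 estimated noise SDs (MAD-based, so exactly zero on noiseless
  traces) are treated as baseline. Without the floor, rectified noise
  integrated over a several-thousand-nt size axis would swamp the genuine
  mass.
- **Marker handling**: the lower marker (nominal 25 nt) is searched for in
  a 15–35 nt window as an interior local maximum exceeding the window
  median by 5 robust noise units; of two candidates the taller wins, ties
  break toward the smaller size. The excised footprint (walk out from the
  peak to 2% of its height, capped at ±4 nt) is bridged by linear
  interpolation rather than zeroed, so RNA mass co-migrating with the
  marker is not discarded. Detection failure is a value (`None` /
  `failed`), not an exception. A genuine RNA peak sitting inside the marker
  window can masquerade as the marker — the same confusion that defeats the
  instrument software on heavily degraded samples.
- **Integration**: trapezoid. Each sample represents a one-grid-step bin,
  and the strict `>` convention counts the sample at exactly the threshold
  as below, so the integration boundary sits half a grid step above the
  threshold; this keeps the trace route and the discrete-distribution route
  consistent (they agree within 0.3 percentage points on noiseless
  renderings; the test suite enforces 0.5).

## QC table and statistics

Missing is representable and distinct from zero everywhere: "NA" plus a
per-column alias map ("no info" → missing storage time) on input; missing
values never enter statistics or satisfy interval predicates. Replicate
sections are ordinary independent rows — their QC behaves near-independently
in practice, and they are treated that way throughout. Quartiles use the
linear-interpolation convention and the summary object names it, since
1.5×IQR whisker rules depend on the choice. The sample SD of a single value
is reported as 0.

Correlation matrices default to pairwise-complete deletion (each cell uses
every record complete for that pair, maximizing n per cell; the per-cell n
is always reported) with listwise deletion selectable. Cells with fewer than
3 pairs or a constant metric are missing with a recorded reason. Values are
raw by default; a log10 switch exists for yield-type metrics that span
orders of magnitude. Storage time is ceil(elapsed years), minimum 1 — chosen
to match a table whose smallest printed value is well above 1; cohort bins
are the closed integer intervals 7–12 / 13–22 / 23–32 plus "unknown".

**Reported-vs-recomputed cohort means.** Direct re-averaging of the packaged
table does not reproduce the originally reported per-cohort DV means (e.g.
DV100 in 7–12 y recomputes to 60.7 against a reported 53) because the
original inclusion rule is unstated — yet the *yield* means recompute almost
exactly (500.4/86.7/39.1 vs 500/87/41). The pipeline therefore always prints
both columns side by side and never forces agreement. The same applies to
the reported correlation magnitudes (−0.44, −0.39, 0.77): recomputation from
the printed table yields the same signs with smaller magnitudes under every
deletion scheme; the acceptance suite records that discrepancy rather than
hiding it.

## Decision policy

Every inequality direction and boundary is a named threshold in
`PolicyThresholds`: DV100 must strictly exceed 40 to proceed (40.0 itself
fails); below 60, proceed with higher input; DV200 bands follow the printed
"30–50%" / "50–70%" labels with inclusive lower edges, so DV200 = 30 falls
in the 50–100 ng band and anything below 30 is refused. Contamination is
none ≤ 1% < low ≤ 5% < high (strict at both edges); replicate pass is
r ≥ 0.7 inclusive. A missing DV100 yields *indeterminate*, not failure —
such samples have been sequenced successfully; the policy reports rather
than blocks — and all other flags are still evaluated. The library screens
(molarity < 2 nM, yield < 10 ng, genes detected < 1000) separate the
libraries that historically produced near-empty expression data; they are
package defaults, not community constants, and are surfaced in every
decision's reasons list. Verdicts are monotone in DV100 by construction.

## Expression metrics

log2(TPM+1) is the default scale for all correlation, clustering and PCA
(raw TPM switchable). The noise filter drops a gene only when it fails
TPM ≥ 1 *and* count ≥ 5 in every sample; boundary values pass, the
operation is idempotent, and a per-entry mask is available for per-sample
work. "Genes detected" is strictly more than 5 reads; the signature
analysis uses "at least 5 reads" — both constants are separate knobs
because the two rules genuinely differ.

Signature concordance subsets to the signature genes, uses per-sample genes
with ≥ 5 reads (samples with fewer than 3 usable genes are excluded with a
reason and assigned the worst class outright — that is exactly the
"near-empty library" phenotype), correlates against the reference profile,
and clusters the remaining samples by average linkage on 1 − Pearson.
Classes are labelled B, C, … by decreasing median concordance; when
exclusions exist the last label is reserved for them, so the class count
stays at the configured k (default 3). Linkage and distance are package
choices (field practice varies and is rarely stated).

Gene-body bias reduces a 100-bin coverage profile to
bias5 = mean(bins 1–20)/mean(bins 41–60) and bias3 = mean(bins
81–100)/mean(bins 41–60) after unit-mean normalization, flagged above 1.5.
The windows and the 1.5 are package conventions — coverage-bias figures are
traditionally shown without a numeric score. GC profiles flag > 5% of read
mass at ≤ 10% or ≥ 80% GC and report whether the bulk sits in the normal
40–60% band. PCA signs follow the largest-loading-positive convention so
projections are deterministic.

## Synthetic cohorts

The generator's defaults *are* the study conditions: 67 samples, storage
7–32 years with weights (0.22, 0.53, 0.25) over the three cohorts, mean
fragment size a·exp(−b·years) + c with a = 250 nt, b = 0.08/yr, c = 40 nt,
DV missing for 14/67, RIN missing for 6/67, storage unknown for 1/67,
contamination a two-component mixture (clean uniform 0–1% with probability
0.16; otherwise 1% + 47%·Beta(1.2, 2.5)), and library yield lognormal with
median 25 ng decaying in degradation.

Degradation flows through the fragment-size distribution: each sample gets
a lognormal mass-weighted size distribution (shape 0.9) whose mean follows
the decay curve, and DV values are *computed* from it by
`fragment_metrics`, which guarantees DV50 ≥ DV100 ≥ DV200 monotonicity by
construction rather than by rejection. Storage-time correlation targets are
achieved through a shared latent (latent = ρ·standardized-storage + noise
with ρ from the DV100 target); because all DV thresholds derive from one
latent, only the DV100 target is structural and the achieved correlations —
for every metric — are measured on the emitted records and reported, never
assumed. The yield noise SD defaults to √3 times the yield-degradation
slope so the storage/yield correlation lands near its −0.2 target given the
−0.4 latent. |ρ| > 0.95 is rejected as infeasible unless the size jitter is
essentially zero, in which case the monotone noise-free limit is supported.

Expression cohorts plant three quality tiers: B tracks the cohort-wide
gene pattern with a mild shared distortion and small noise; C shows
attenuated signature expression plus a *tier-shared* distortion (so C
samples cohere as a cluster instead of forming a diffuse cloud — diffuse
tiers are not recoverable by correlation-distance clustering, and real
intermediate-quality samples share their artifact structure); D is globally
flattened, noisy, near-zero on the signature, and sequenced at 10⁴ rather
than 3×10⁶ reads. Concordant replicate pairs share a latent component
whose weight is solved from the configured target r = 0.75 on the log2
scale; the 3×10⁶-read default keeps Poisson count noise from attenuating
the measured estimator below its target (at 10⁶ reads the measured r drops
to ≈ 0.71). Discordant pairs couple a B member with a D member and land
near r ≈ 0.1. TPM is recomputed from the emitted Poisson counts and the
configured gene lengths, so the emitted matrix is internally consistent.
Gene-body ramps are planted only where mRNA% falls below 10, and GC
anomalies in a configured fraction of samples (default 15%).

What the generator does *not* emulate: read-level data (no sequences,
alignments or duplication structure), batch effects, GC-dependent
quantification bias, gene–gene correlation beyond the planted tier and pair
structure, and any coupling between contamination and expression content.
Passing tests on synthetic cohorts therefore demonstrate that the analysis
code recovers planted structure of the configured kinds and magnitudes —
not that real FFPE cohorts behave this way.

## Problem sizes

The self-tests use the sizes at which the answers stabilize: 100–200 random
distributions for oracle equivalence, 200 simulated cohorts of n = 67 for
correlation recovery, 50 seeds × 24 samples for tier recovery, 25 seeds ×
7 pairs for the replicate regimes, and 2000-gene expression matrices. The
whole suite runs in well under a minute on one core.

## Known limitations

- DV from traces assumes a size-calibrated axis; ladder/time calibration is
  out of scope, as is RIN (proprietary), which is only an input column.
- The contamination column of the packaged table blends bacterial and mouse
  reads; the originally reported bacterial-only counts (56 samples > 1%,
  41 > 5%) are not recoverable from it and are not asserted anywhere.
- The policy's molarity/yield/gene-count floors are pragmatic defaults, not
  validated cutoffs; flip them per protocol via `PolicyThresholds`.
- A real RNA peak inside the 15–35 nt marker window can be mistaken for the
  marker on markerless traces.
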
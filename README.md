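# ffpeqc

Quality control and feasibility analysis for RNA-Seq of degraded RNA from
formalin-fixed paraffin-embedded (FFPE) tissue.

Archived FFPE blocks are the most widely available clinical specimens, but
fixation and years of storage fragment and chemically modify their RNA. The
standard intactness score (RIN) sits at its floor for such samples and
carries no information; the practical quality currency is the **fragment
distribution value**

DV_N = 100 × (RNA mass in fragments longer than N nt) / (total RNA mass),

read off a size-calibrated capillary electropherogram. DV200 is the industry
metric, but for heavily degraded material almost nothing exceeds 200 nt, so
DV100 and DV50 extend the same definition downward and are the useful
screens there. `ffpeqc` implements, as a tested library plus a thin CLI:

- **`fragment_metrics`** — DV_N from explicit mass-weighted size
  distributions and from raw electropherogram traces (baseline subtraction,
  lower-marker detection and excision, noise-robust integration), with
  marker-detection failure propagated as a missing value rather than an
  exception, as happens on real degraded samples.
- **`sample_qc`** — a per-sample QC table schema (DV values, library size /
  yield / molarity, storage time, contamination %, expression cluster,
  genes detected), delimited-text I/O with explicit missingness, summaries
  and predicate counting. A 67-sample table from archival high-grade ovarian
  serous adenocarcinomas (SEER Residual Tissue Repositories, stored 7–32
  years) ships as a packaged fixture.
- **`cohort_analysis`** — pairwise-complete Pearson matrices over QC
  metrics with per-cell n, storage-time cohort stratification, and the
  storage-time convention (elapsed years rounded up, minimum 1).
- **`qc_policy`** — auditable go/no-go verdicts: proceed when DV100 > 40,
  use more input RNA below DV100 60; Illumina DV200 input bands (>70%:
  from 20 ng, 50–70%: 20–50 ng, 30–50%: 50–100 ng, <30%: not recommended);
  contamination flags (>1% low, >5% high); replicate pass at r ≥ 0.7;
  library molarity / yield / gene-count screens.
- **`expression_metrics`** — noise filtering (drop genes with TPM < 1 or
  count < 5 everywhere), genes-detected counts (> 5 reads), replicate
  concordance on log2(TPM+1), signature-gene concordance clustering into
  quality classes (B/C/D: reference-like, attenuated, near-empty),
  gene-body 3′/5′ coverage-bias scores, GC-profile anomaly flags, and a
  PCA outlier view.
- **`synthetic_cohort`** — a seeded generator of study-shaped cohorts (QC
  tables, traces, expression matrices with replicate pairs, coverage and GC
  profiles) with planted ground truth, so every analysis stage is testable
  end to end without external data.

## Worked example

```
$ ffpeqc table summarize --metric dv200 builtin
dv200: n=53 min=1 q1=11 median=13 mean=17.23 q3=21 max=50 sd=11.05 (linear-interpolation quartiles)
```

Of the 67 archival samples, DV could be computed for 53; the median DV200 of
13% means a typical sample has only 13% of its RNA mass in fragments longer
than 200 nt — far below the 30% floor at which capture-based FFPE kits stop
being recommended, which is why DV100 carries the screening weight here.

```
$ ffpeqc table count --where "dv200 in [30,50]" builtin
8
$ ffpeqc decide builtin
verdicts: {"proceed": 20, "proceed_high_input": 26, "do_not_proceed": 7, "indeterminate": 14}
flags:    {"contamination_low": 16, "contamination_high": 43, "low_yield": 24, "low_molarity": 16, "low_gene_count": 11, "exclude_from_expression": 7}
```

Only 8 samples reach even the lowest vendor DV200 band. The DV100 rule still
lets 46 of 67 proceed (20 outright, 26 with higher input); 14 are
indeterminate because their DV could not be measured at all, and 7 fail.
43 samples carry >5% non-human reads, and 7 combine high contamination with
a near-empty gene count and are marked for exclusion from expression
analysis.

```
$ ffpeqc cohort strata builtin --metrics dv200,dv100,lib_yield
...
recomputed vs originally reported cohort means:
  bin    metric  recomputed_mean  reported_mean   n
 7-12     dv200            22.77           20.0  13
 ...
```

Cohort means are always printed next to the values originally reported for
this table; the two are not forced to agree (see `docs/methods.md`).

Library code mirrors the CLI one-to-one, e.g.:

```python
from ffpeqc import load_table2, pearson_pairwise
records = load_table2()
m = pearson_pairwise(records, ["storage_time", "dv200", "dv100"])
m.get("storage_time", "dv200")   # -0.281 over 52 pairwise-complete samples
```

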
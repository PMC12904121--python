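# Methods

This note documents the statistical procedures, the conventions and defaults
the package commits to, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Coordinates and call representation

All internal coordinates are 1-based inclusive (length = end − start + 1),
the convention of PennCNV-style call tables; BED inputs (0-based half-open)
are converted at the read boundary and back on write. Chromosome labels are
canonicalized by stripping any `chr` prefix; autosomes and X/Y are accepted,
mitochondrial labels rejected (array CNV calling covers the nuclear genome).
A call is a deletion iff copy number < 2 and a duplication iff > 2;
copy-neutral rows are rejected at parse time. Chromosome-X calls are carried
through all analyses but a warning is logged, because the burden models make
no male-hemizygosity adjustment; users studying X specifically should
stratify by sex.

## The QC cascade

Nine stages run in a fixed order, each emitting a report (calls in, calls
out, calls removed) on the primary-caller stream:

1. **Sample metric outliers.** A sample is removed iff any of LRR_SD,
   BAF drift, |WF| strictly exceeds cohort mean + k·SD of that metric
   (default k = 3, sample SD with ddof = 1, computed once over cases and
   controls jointly, one-sided for LRR_SD/BAF drift and two-sided for WF via
   the absolute value). A one-pass rule is deliberately simple; it can mask
   a single extreme outlier at small n (a value among n−1 identical values
   can never exceed mean + 3·SD unless (n−1)/√n > 3, i.e. n ≥ 11), which
   the tests document explicitly.
2. **Call-count cap.** Samples with more than 150 pre-QC primary-caller
   calls are dropped with all their calls (strict >; exactly 150 is kept).
3. **Size/markers.** Keep calls with length ≥ 30 kb *and* ≥ 10 SNP markers
   (both inclusive). Applied to both caller streams so consensus compares
   comparably filtered sets.
4. **Quality score.** Keep calls with |QS| strictly > 0.5; missing QS fails.
5. **Dual-caller consensus.** A primary call is kept iff some secondary-
   caller call from the same sample and of the same type (deletion vs
   duplication, not exact copy number) reciprocally overlaps it at ≥ 50%.
   One secondary call may confirm several primary calls; no stitching of
   fragmented calls is attempted.
6. **Rarity.** A call is removed iff a same-type reference SV with allele
   frequency ≥ 1% reciprocally overlaps it at ≥ 50%; calls matching no
   reference SV count as rare.
7. **Blacklist.** Any shared base with a blacklist region removes the call.
8. **Confidence.** Only calls with a passing high-confidence classifier
   flag survive (the flag is consumed as an input column, not recomputed).
9. **Exon intersection.** Keep calls sharing ≥ 1 bp with ≥ 1 exon of ≥ 1
   protein-coding gene, emitting one gene hit per (call, gene) pair. A
   stricter full-exon-containment mode is available
   (`intervals.exon_containment`); ≥ 1 bp intersection is the default
   because containment discards borderline but real gene disruptions.

Stage order is frozen for reproducibility (rarity before blacklist is
arbitrary); the three pointwise call filters (3, 4, 8) commute, which the
tests check. Every stage is individually toggleable
(`qc.stages_enabled`). Ancestry and relatedness filtering are out of scope:
the sample table is assumed pre-filtered to an unrelated, ancestry-
homogeneous cohort.

## Burden metrics

Per sample and CNV type: event count, summed length in 100-kb units,
number of distinct genes hit; the same per size bin ([30 kb, 100 kb),
[100 kb, 500 kb), [500 kb, 1 MB), ≥ 1 MB — left-closed, right-open on the
lower edges, configurable); per gene set, the count of events hitting ≥ 1
member gene (counting distinct member genes instead is config-selectable);
and per pathogenicity metric, the mean score over the sample's scored calls
of that type (missing scores excluded; no scored calls → missing mean).

## Statistical tests

* **Logistic burden regressions** fit
  `status ~ metric + sex + PC1–10 + LRR_SD` by Newton maximum likelihood
  (tolerance 1e-8, ≤ 100 iterations). Effect = exp(β_metric), 95% CI via
  the Wald normal quantile 1.96, p from the two-sided Wald test. Wald
  rather than likelihood-ratio inference is the convention in array-CNV
  burden work and keeps CIs and p-values mutually consistent. A constant
  metric is untestable; separation or non-convergence (including a fitted
  |β| > 15 on the metric, which at CNV-count scale means a numerically
  infinite odds ratio) yields a *flagged* result with non-finite effect and
  an explanatory note instead of a penalized fit — Firth-type corrections
  are intentionally not applied.
* **Fisher exact tests** sum hypergeometric probabilities of all tables
  with the observed margins that are no more probable than the observed
  table, with a relative tie tolerance of 1e-7 guarding floating-point
  equality. The sum is computed in log space (logsumexp over the full
  support), so cohort-scale margins remain exact; no chi-square fallback
  exists.
* **Odds ratios** use the sample cross-product. When any cell is zero the
  Haldane/Altman correction adds 0.5 to every cell before the cross-product
  and the log-scale Wald CI. The conditional-MLE odds ratio that classical
  Fisher-test software reports is deliberately not used.
* **Counting units** differ by family and are frozen: gene-wise tests count
  *carriers* (samples with ≥ 1 qualifying CNV over the gene); the
  genomic-disorder-region test counts *events*. Deletions and duplications
  are always tested separately; no combined-type tests exist.
* **Multiple testing** uses Bonferroni thresholds α/n with strict p < α/n:
  n = 6 (global), 8 (size bins), number of genes actually tested
  (gene-wise; configurable, e.g. 1891), 30 (gene sets), 12 (pathogenicity
  scores), and 2 for the genomic-disorder family (one test per CNV type;
  no published convention exists for that family, so the package defaults
  to the number of tests it runs).

Degenerate inputs: a gene with zero carriers is skipped, a gene set with no
qualifying CNVs in either cohort is reported untested, a pathogenicity
regression needs ≥ 2 carriers per cohort, and a genomic-disorder table with
all events on one side of the regions carries no information and is
reported with OR 1, p 1 and a "degenerate" note.

## Synthetic cohorts

The generator emits every input the pipeline reads, with known ground
truth. Per-sample truth event counts are Poisson with status-specific
rates; for Poisson counts the log odds of case status is exactly linear in
the count with slope log(rate ratio), so the planted ratio is the
regression's estimand, and any filter that thins events with equal
probability in both arms (QS noise, caller discordance, blacklist/common-SV
relocation, exon misses) leaves that estimand unchanged — this is what
makes the parameter-recovery checks well-posed.

Defaults are chosen to emulate a post-QC array cohort: 1,204 cases and
9,549 controls; 0.14 deletions and 0.15 duplications per control sample
with a planted case duplication rate ratio of 1.7 and no deletion effect;
event sizes log-uniform on [30 kb, 2 Mb]; copy numbers fixed at 1
(deletions) and 3 (duplications); six 30-Mb chromosomes with ~600 genes
(evenly spaced, 4–8 exons of 3 kb; every 10th gene non-coding) — a
desk-scale genome that keeps a full run in seconds while preserving the
geometry the interval filters need. Reserved segments per chromosome hold a
blacklist region, two genomic-disorder regions and common (AF ≥ 1%) and
rare reference SVs; 2% / 5% / 5% of truth events are relocated onto
blacklist / common-SV / disorder segments to exercise those filters, 5%
of primary calls receive a failing quality score and 3% a failing
confidence flag, and the secondary caller drops 5% of events and jitters
endpoints by N(0, 2 kb) truncated so concordant calls stay ≥ 30 kb and at
≥ 50% reciprocal overlap with the truth. Pathogenicity scores are Gaussian
per metric and type (CADD on its native 0–60 scale, the others on [0, 1])
with an optional case shift, 2% missing. Gene-set enrichment is planted by
adding set-targeted case events at a rate calibrated against the cohort's
own control rate of set-hitting events, so the configured multiplier is the
planted rate ratio without geometric bookkeeping.

All randomness derives from one seed via per-component child streams, so
adding a component does not perturb the others and a fixed seed gives
byte-identical output bundles.

What the simulator does **not** emulate: probe-level LRR/BAF signal and the
calling HMMs, linkage disequilibrium and realistic allele-frequency
spectra, population stratification correlated with case status, realistic
gene length/density variation, and breakpoint uncertainty beyond Gaussian
jitter. Passing tests therefore demonstrate the correctness and calibration
of the *statistics and filters*, not the upstream calling pipeline's
behaviour on real intensity data.

The deterministic worked-example fixture plants exactly 95 control and 0
case carriers of a duplication over one designated gene in a 1,204 / 9,549
cohort, giving the corrected carrier-table odds ratio 0.0411 [0.0026,
0.66] and exact p ≈ 2.2 × 10⁻⁵; its array-quality metrics are drawn from
bounded (uniform) distributions so the 3·SD outlier filter provably removes
no sample, and deterministic background calls in both arms keep the global
regressions well-posed.

## Validation performed by the test suite and acceptance script

Computed, not asserted from constants: the worked-example odds ratio, CI
and p through the full pipeline; equality of the Fisher implementation with
exhaustive exact-rational enumeration on random tables; equality of every
interval filter with a per-base set-arithmetic oracle on random small
genomes; 95% CI coverage of the planted duplication effect over 20
simulated cohorts of 5,000 samples; empirical type-I error of the null
regression over 200 cohorts of 2,000 samples (replicate counts and sample
sizes are the package's chosen operating point for a desk-scale run);
byte-level determinism of the end-to-end pipeline; and conservation
(n_in = n_out + n_removed, monotone chaining) of every filter report.

## Known limitations

* Fisher gene-wise tests cannot adjust for covariates; a gene-level signal
  can be confounded by anything the global regressions adjust for.
* The one-pass mean + 3·SD outlier rule is not idempotent in pathological
  configurations and can mask single extreme outliers at very small n.
* Separation in a regression is flagged, not rescued; families with very
  sparse metrics (e.g. a size bin with a handful of events) may be
  systematically untestable at small cohort sizes.
* X-chromosome dosage is not modelled; results for X-linked genes should be
  treated as exploratory.
* The genomic-disorder percentages and counts depend on the reference
  region list supplied; the package ships no curated list.
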
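# Methods

This note documents what `ibcscars` computes, the parameter choices that
matter, and what the synthetic-data generator does and does not emulate.

## Data model

Segments are 0-based half-open intervals carrying a real-valued total
copy number and, when allele-specific calls exist, a minor-allele copy
number. The SEG dialect (1-based, end-inclusive) is converted on read.
All copy-number comparisons use a tolerance of 1e-6. Derived predicates:

* *allelic imbalance* (AI): |total − 2·minor| > tol — the two parental
  alleles have unequal copy counts;
* *LOH*: minor ≈ 0 with total ≥ 1;
* *cnLOH*: LOH with total at the diploid baseline (2). The baseline is
  fixed at 2 throughout; the package does not re-centre by inferred ploidy.

Segments with a missing minor-allele call return "unknown" for these
predicates; TAI and HRD-LOH skip them and report a skipped-segment count
(`n_missing_minor`), since both scores are meaningless without
allele-specific data (they raise if the whole profile lacks it).

Sex chromosomes are kept in the model but excluded from all scar scores
by default (`include_sex_chromosomes=True` to override): a single-copy X
in an unknown-karyotype context would masquerade as terminal allelic
imbalance.

Genome geometry comes from a UCSC-style cytoband file: the centromere is
the bounding interval of the `acen` bands, the chromosome length the
maximal band end. The packaged `cytoband_hg19_synthetic.txt` is a
*synthetic* hg19-like file — true GRCh37 chromosome lengths with
approximate centromere intervals and coarse band structure — suitable
for arm geometry, not for band-level annotation; users with a real
cytoBand.txt(.gz) should point the readers at it.

## Scar scores

* **GII** — altered length / covered length, where altered means total CN
  differs from baseline 2 and covered means the sum of segment lengths
  (not chromosome lengths, so uncovered assay gaps do not dilute the
  index). cnLOH is copy-neutral and does not count.
* **TAI** — AI segments that reach the terminal covered coordinate of
  their chromosome within `telomere_tol` (default 1 kb) and do not
  intersect the centromere; at most one per arm. Telomere-reaching is
  defined against the covered extent rather than the physical chromosome
  end because array segmentation never reaches the physical telomere.
  No minimum segment size by default (`tai_min_size=0`).
* **LST** — per arm, after (a) merging touching equal-state segments and
  (b) absorbing segments shorter than 3 Mb into their larger neighbour,
  the count of junctions whose flanks are both ≥ 10 Mb, differ in
  (total, minor) state, and are separated by ≤ 3 Mb. The 10 Mb flank is
  the method's stated rule; the 3 Mb smoothing and gap values follow the
  original large-scale-transition definition and are configurable. A
  segment belongs to the arm containing its midpoint; a segment spanning
  the whole centromere serves as a flank on both arms (but can never be
  a TAI segment). Junctions across the centromere are not counted.
* **HRD-LOH** — LOH tracts strictly longer than 15 Mb that do not span
  the entire covered extent of their chromosome. The default mode counts
  copy-neutral LOH only, which is how this pipeline's source defines the
  score; `any_loh` mode reproduces the original definition that counts
  every LOH tract. The mode is recorded in the score metadata.
* **HRD-sum** — the unweighted sum, with fixed high cut-offs: LST > 15
  (diploid) / > 20 (polyploid), HRD-LOH ≥ 10, HRD-sum ≥ 42.
* **Ploidy class** — length-weighted mean total CN, polyploid when
  strictly above 2.5. The threshold is this package's choice; the method
  invokes diploid/polyploid without defining them.
* **Median dichotomization** (GII, TAI) — high strictly above the cohort
  median; ties at the median are low.

All scores are invariant under splitting segments into touching
equal-state pieces (the equal-state pre-merge guarantees it) and under
rigid coordinate translation of a chromosome.

## Cohort recurrence

The genome is binned (default 1 Mb); per bin the fraction of samples
with any overlapping gain (total > 2), loss (total < 2) or cnLOH segment
is reported. Gains/losses are flagged recurrent strictly above 50% of
samples, cnLOH at ≥ 25%.

## CTLP detection

Chromothripsis-like patterns are detected per chromosome from
copy-number oscillation: segments < 10 kb are absorbed; a junction is a
breakpoint when the two sides differ by ≥ 0.1 on the log2(total/2)
scale (total CN is floored at 0.05 before the log to handle homozygous
deletions); a candidate region is a maximal run of breakpoint-joined
segments. A region with b breakpoints over length L is scored

    log10 LR = log10 [ Pois(b; b) / Pois(b; λ_bg · L) ]

where λ_bg is the *out-of-region* breakpoint rate of the sample (total
breakpoints minus the region's own, plus one pseudocount, divided by
covered genome length). Using the out-of-region rate is deliberate: a
genome-wide rate would include the cluster itself and mask exactly the
dense events the statistic is meant to find on small or quiet genomes.
Events are reported when b > 10, log10 LR ≥ 8, and the fraction of the
region at non-baseline CN strictly exceeds 0.10 (the "prevalent CNAs
involving ≤ 10% of the region" exclusion, read as an altered-fraction
rule and flagged as an interpretation in the event metadata). Events are
counted per region, so one chromosome may contribute several.

## Variant cascade

Rules fire in a fixed order, exactly one per record:

1. `excluded_class` — synonymous consequence, UTR3/UTR5, intronic or
   intergenic region, or homopolymer flag → drop. Homopolymer status is
   a precomputed input column; the package does not compute sequence
   context.
2. `not_rare` — any available population frequency ≥ 0.01 → drop.
   Known-rare and unobserved variants are treated alike (absence counts
   as rare): the rarity criterion and the absent-in-database criterion
   are one gate.
3. `clinical_pathogenic` — pathogenic or likely pathogenic in any of
   ACMG / ClinVar / Clinvitae → keep.
4. `vus_lof` — ACMG VUS with frameshift, stopgain or canonical-splice
   consequence → keep.
5. `no_evidence` — drop.

The potentially-germline flag implements the printed rule, VAF strictly
below 0.5. That rule is inverted relative to the usual
heterozygous-germline expectation (germline hets cluster *around* 0.5);
the package implements the rule as printed by default and exposes
`direction="above_or_near"` for the conventional reading rather than
guessing intent.

The HR (13 genes) and MMR (6 genes) sets are the published pathway
panels. The surrounding 105-gene panel list is a synthetic stand-in
(the full published panel is supplementary-only): the 19 pathway genes
plus the genes named in the analyses plus representative cancer genes.
All three lists are plain-text config, replaceable per run. Cohort
summaries count distinct cases (a case counts once per gene/pathway no
matter how many variants it carries) and recurrent variants are
identical `hgvs_c` strings in ≥ 2 cases.

## Statistics

Two-sided throughout; significance at p ≤ 0.05. Fisher's exact test for
2×2 tables, chi-square otherwise. Spearman correlation uses average
ranks for ties and the large-sample t approximation for p; a constant
vector yields NaN with a warning. Kaplan–Meier / log-rank use lifelines
with the standard multi-death (hypergeometric-variance) tie correction;
censored observations are right-censored at last contact. The
multivariate overall-survival analysis is ordinary least squares of OS
months on reference-cell (first-level-dropped) dummy-coded covariates
with per-covariate partial correlations r = t/√(t² + df) — a multiple
linear regression, deliberately not a Cox model, mirroring the
correlation-matrix analysis it reimplements; exact collinearity raises
an error naming the aliased columns.

## Synthetic data

The generator targets the detectors' contracts, not breast-cancer
biology (no breakage–fusion–bridge cycles, no clustered rearrangement
mechanisms, no probe-level noise model). Planted events carry margins at
least twice every relevant threshold, so recovery is exact, and a
post-generation auditor re-verifies disjointness:

* TAI events: terminal (3,1) segments of 5–8 Mb flush against a
  chromosome end (two slots per chromosome);
* LST events: a 12 Mb (3,1) + 12 Mb (2,1) pair insulated by 4 Mb
  uncovered gaps, so exactly one qualifying junction each;
* LOH events: interstitial 17 Mb cnLOH tracts, gap-insulated, invisible
  to the total-CN detectors;
* GII filler: gap-insulated balanced blocks at total CN 2.1 (log2 offset
  0.07, below the CTLP signal distance) sized so the altered fraction
  lands on the requested target; the truth records the exactly achieved
  fraction;
* optional noise: sparse sub-3 Mb balanced jitter pieces (|ΔCN| ≤ 0.05)
  inside long background segments — below the LST smoothing size and the
  CTLP signal distance, but counted in the altered fraction, which the
  truth tracks exactly;
* CTLP chromosomes: n+1 alternating segments (≥ 1 Mb) giving exactly n
  breakpoints; minor CN is kept balanced so only the total-CN channel is
  exercised;
* variant tables: six planted classes (pathogenic-rare, VUS-with-LOF,
  VUS-other, common, synonymous, intronic) mapping deterministically to
  cascade verdicts;
* survival cohorts: exponential event times (arm-1 median OS 25 months,
  the scale of the cohort the package targets; arm-2 hazard scaled by
  the requested ratio) with independent uniform censoring calibrated so
  the expected censored fraction matches the request. Subtype and
  metastasis frequencies follow the target cohort's marginal
  distribution (53/15/32% subtypes; 24/38/38% metastasis categories).

Identical (parameters, seed) give byte-identical outputs; per-sample
child generators derive from the master seed by fixed offset, and CN
values are written with fixed precision so write→read round-trips are
exact.

Because planted events are insulated and threshold-margined, passing the
recovery suite shows the detectors implement their definitions exactly;
it does not show robustness to segmentation noise, overlapping events or
waviness in real array data, which the generator deliberately does not
model.

## Problem sizes used in the shipped checks

The recovery suite uses an 8 × 100 Mb toy genome with 0–8 TAI, 0–5 LST
and 0–4 LOH events per profile over 100 seeds; CTLP sensitivity uses 100
planted oscillations of 12–30 switches and specificity 1,000 quiet or
single-step chromosomes; the Fisher check enumerates every 2×2 table
with margins ≤ 12; log-rank calibration uses 500 null and 200
alternative cohorts of 200 subjects per arm. These sizes make each check
sharp (exact recovery, exhaustive enumeration) while keeping the whole
suite comfortably fast on a laptop.

## Known limitations

* Scores assume an externally produced, reasonably clean segmentation;
  there is no probe-level processing or re-segmentation.
* The diploid baseline is fixed at 2; heavily aneuploid genomes are
  classified by the 2.5-ploidy cut, not re-baselined, which can inflate
  GII in near-tetraploid samples.
* The CTLP likelihood ratio is this package's construction around the
  published thresholds; it is calibrated by property (sensitivity /
  specificity on planted data), not against any external scanner's
  numeric output.
* Cohort-level published values that depend on patient-level raw data
  (median scores, score correlations, survival p-values) are outside
  what can be recomputed from shipped inputs; the suites verify the
  mechanisms instead.
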
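# Methods

This note records the models, parameter choices and numerical conventions
behind `brcaloh`, and what the synthetic cohort does and does not
demonstrate.

## Coordinates and genome model

Segments are 1-based, fully closed intervals (the Sequenza table
convention); a segment's length is `end − start + 1`. Chromosome names are
normalized by stripping a leading `chr`; Y and MT rows are dropped with a
warning. Two builds ship with the package: `hg19` (UCSC lengths and
gap-track centromere intervals for 1–22 and X) and `mini-test`, a
deterministic three-chromosome genome (100/80/60 Mb, centromeres at 40–42,
30–32 and 25–27 Mb) used throughout the tests for speed. Non-integer copy
numbers are rejected rather than rounded — discretization belongs to the
segmentation caller, not the reader.

Default carrier loci are BRCA1 at 17:41,246,000 and BRCA2 at 13:32,930,000
on hg19 (inside the hg19 gene bodies 17:41,196,312–41,277,500 and
13:32,889,617–32,973,809), overridable in configuration; the mini genome
places stand-in loci at 1:68 Mb and 2:55 Mb.

## The LOH caller

At a germline carrier locus the observed tumor alt fraction mixes tumor
cells (m mutant of CN copies) with normal cells (1 of 2), giving

    f = (p·m + (1 − p)) / (p·CN + 2(1 − p)),

where p is purity. This differs from the usual somatic-VAF correction
precisely because the contaminating cells are variant heterozygotes. The
caller inverts f for the continuous mutant-copy estimate `m_cont`, clamps
it to [0, CN], and derives `f_corr = m_cont/CN` and
`ΔAF = f_corr − blood AF` (blood AF from the observed normal counts, not a
fixed 0.5).

Three evidence layers feed one decision ladder:

1. **Exact allele test.** Two-sided Fisher exact test on
   (normal_ref, normal_alt; tumor_ref, tumor_alt) plus a two-sided exact
   binomial of the tumor alt count against 0.5, both at α = 0.05.
   Verdict: positive if significant with tumor AF above blood AF;
   "wildtype retained" if significantly below; negative otherwise;
   indeterminate at zero tumor depth. These semantics are this package's
   own exact-test stand-in for read-level somatic/germline callers — the
   numeric p-values of those tools are not reproduced.
2. **ASCN state.** `m_hat = round(m_cont)` with .5 ties pushed away from
   the heterozygous midpoint CN/2 (toward 0 or CN), avoiding a systematic
   bias toward the absent-LOH call; `(CN, m_hat)` then maps to the
   mechanism taxonomy. Any retained wild-type copy — including gains with
   1 < m < CN — is absent LOH; `m_hat = 0` is wild-type-retained LOH and
   counts as LOH-negative for the biomarker (the wild-type allele is the
   one left), while being reported distinctly.
3. **ΔAF tie-break.** If the exact test and the ASCN state disagree, the
   call is LOH-positive iff ΔAF > 0.20, strictly. If the tumor has no
   reads at the locus (mutation seen only in the normal), the call is
   positive iff the ASCN state is an LOH mechanism *and* ΔAF > 0.20.

Every call carries its full evidence (p-values, CN, m_cont, m_hat, f_corr,
ΔAF, and the decision branch taken). One type-level caveat: on the
discordant branch a ΔAF-positive status can coexist with an ASCN point
estimate of "absent", since the mechanism is always reported from the ASCN
state; the `rule_path` field makes such calls auditable rather than
forcing the mechanism to agree.

Group assignment for genomic comparisons: an LOH-negative tumor with a
kept pathogenic somatic variant in the same gene is reclassified
absent-plus-somatic and grouped with the biallelic tumors (the somatic
mutation is the second hit); promoter methylation does **not** move an
LOH-negative tumor into the biallelic group, because methylation can sit
on either allele and empirically often leaves protein expressed.

## HRD scar scores

* **NtAI** counts allelic-imbalance segments (A ≠ B) longer than 11 Mb
  that lie on one arm and reach a chromosome terminus. "Reaches a
  terminus" is operationalized as: the segment is the first/last segment
  of its chromosome *and* lies within 1 Mb of the chromosome end
  (configurable tolerance); "on one arm" as: the segment does not extend
  strictly beyond both centromere edges.
* **LST** works per arm (segments are clipped at the centromere
  interval): segments shorter than 3 Mb are removed iteratively, shortest
  first, bridging equal-state neighbours across each hole until stable;
  then a breakpoint is counted between consecutive smoothed segments that
  differ in (A, B) state and are each at least 10 Mb. The
  ploidy-corrected score is LSTm = LST − 15.5·ψ, applied literally — it
  is negative for quiet genomes and has no floor.
* **HRD-LOH** counts LOH segments (B = 0, CN ≥ 1) longer than 15 Mb,
  excluding chromosome 17 entirely (the BRCA1 chromosome, where
  locus-specific LOH would leak into the genome-wide score).
  Whole-chromosome LOH counts by default; a config flag
  (`exclude_whole_chromosome_loh`) restores the stricter variant of the
  score's original formulation.
* **HRD-Mean** = (NtAI + LSTm + HRD-LOH)/3. Whether the mean should use
  raw LST or LSTm is genuinely ambiguous; the default is LSTm with a
  config override, and all components are always reported so either can
  be recomputed.

Chromosome X is excluded from all three scores by default (allele states
on X are ill-defined in males); gaps between segments are simply not
scored. All length thresholds are strict (`>`), the LST flank threshold is
`≥ 10 Mb`, and a segment of exactly 3 Mb survives smoothing.

## Synthetic cohort

The generator emulates the *statistical structure* the analysis assumes,
not sequencing reads. Defaults describe a 160-tumor carrier cohort — 41/52
BRCA1 breast/ovary and 35/32 BRCA2 breast/ovary — with mean coverage 141×
(tumor) and 155× (normal), purity ~ Beta(6, 3) (bulk in 0.3–0.9), and
ploidy ~ Normal(2.1, 0.35) truncated to [1.5, 4.5].

Mechanism frequencies per gene × site put the absent-LOH mass at 10%/7%
(BRCA1 breast/ovary) and 46%/16% (BRCA2 breast/ovary), with a 2%
absent-plus-somatic share in breast; the LOH mass splits between deletion,
copy-neutral LOH and gain in the ratios 17:36:31 (BRCA1) and 14:20:11
(BRCA2). The second-hit somatic variant's allele fraction is drawn
Uniform(0.1, 0.5). LOH-in-gain is simulated as (CN, m) = (3, 3) by
default.

Scar events are placed on a clean diploid backbone (tetraploid when the
drawn ploidy exceeds 2.75): telomeric AI segments of 12–22 Mb, interstitial
LOH segments of 16–25 Mb, and adjacent alternating-state pairs of
10–14 Mb each. Event counts are Poisson with per-Gb rates by biallelic
status — biallelic: 10/8/12 per Gb for AI/LOH/LST events; absent:
1.5/1.0/1.5 — *truncated at what the genome can hold*: draws are capped by
free capacity and placement stops when no gap fits the minimum event size
(`on_saturation="truncate"`; set `"error"` to fail instead). On the mini
genome this truncation binds often for biallelic profiles; the realized
event counts, not the nominal draws, are recorded as truth. The region
around the carrier locus is then overwritten with the ASCN state the
drawn mechanism implies.

Burden is Poisson with 1.3 (biallelic) or 0.6 (non-biallelic)
nonsynonymous mutations per Mb over a 30 Mb exome footprint — the
denominator is configurable because the true callable footprint of any
given capture design is not knowable from summary data, and the same
constant is used by generator and analysis so burden recovery is
self-consistent. TP53 mutation probability is 0.75/0.35 by group. Survival
is exponential with baseline median 60 months and a hazard ratio of 2.5
for the non-biallelic group, censored by an independent Uniform(24, 120)
month follow-up.

**What passing tests show and do not show.** The generator draws exactly
the binomial/Poisson/exponential structure the caller and statistics
assume, so recovery results certify internal consistency — correct
inversion of the purity model, correct ladder logic, calibrated tests —
not robustness to real-data pathologies: subclonal mixtures, FFPE
artifacts, segmentation error, whole-genome amplification bias, or
mis-estimated purity are all absent by construction.

## Statistics

Grubbs' outlier screen is the iterated extreme-studentized-deviate form,
applied per group before mean comparisons; zero spread and n < 3 remove
nothing. The t-test is pooled-variance Student's (not Welch); Fisher's
exact test is the two-sided sum of hypergeometric probabilities at or
below the observed table's; ANOVA/Tukey uses a single pooled variance;
the log-rank test is Mantel–Cox; Cox models report Wald CIs and raise on
separation or non-convergence rather than dropping terms.

Calibration facts that shaped the test designs: the two-sided exact
Fisher test is conservative on asymmetric nulls at any practical margin
size (measured size ≈ 0.047 at margins of 20,000) but achieves the
nominal level on a symmetric null (≈ 0.0498 at margins 5,000, p = 0.5);
the log-rank chi-square is slightly anti-conservative at 40 subjects per
group (≈ 0.055) and calibrated at 100 per group. The calibration tests
therefore use a symmetric Fisher null and 100-per-group log-rank null —
designs under which the nominal level is actually achievable — with a
±2 Monte-Carlo-SE band at 10,000 replicates.

## Eligibility and filter conventions

Carrier criteria: pathogenic classification, germline AF > 0.30, depth
> 30 in both samples — all strict. Somatic variants are kept iff germline
alt depth < 5, population frequency < 1%, segmental-duplication fraction
≤ 0.89 (the rule excludes "> 89%"), non-synonymous, tumor alt reads > 10
(strict), and pathogenic/likely-pathogenic or VUS rarer than 0.1%. Rules
are evaluated in that fixed order and each rejected variant is tallied
under its first failing rule, so kept + rejections partition the input.
Signature-artifact exclusion drops samples whose summed R1–R3/U1–U2
fraction strictly exceeds 30%. PTEN status is extrapolated as loss for
CN < 2 or a truncating mutation with B = 0, retained for wild-type at
CN ≥ 2 with B ≥ 1, and indeterminate (excluded) for copy-neutral LOH
without a mutation.

## Problem sizes

The test suite and acceptance script run entirely on generated data: the
scar-score oracle check uses 1,000 fuzzed mini-genome profiles, caller
recovery uses 1,000 simulated loci at study depths, calibration uses
10,000–30,000 Monte-Carlo replicates per test, and the acceptance script
analyzes one 160-tumor cohort. These sizes keep a full run to a few
minutes on one core while leaving Monte-Carlo error well inside every
asserted band.

## Known limitations

Single dominant clone assumed (no subclonal deconvolution); no reversion
mutation detection; no read-level simulation; no hg38 coordinates or
liftover; signature and annotation steps are consumed as tables, never
recomputed; the burden denominator is a convention, so absolute burden
values are comparable only within a fixed footprint choice.
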
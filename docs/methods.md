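# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of
`rddmkit`.

## Coordinates and binning

All internal coordinates are 0-based half-open (BED convention); the
1-based cytosine report is converted at the parser. The genome is
tiled with fixed-width sliding windows (default 100 bp every 50 bp).
Only full-width bins are produced: a trailing chromosome stub shorter
than one bin is not tiled, and TEs shorter than twice the end size
(150 bp) have their two ends clipped at the midpoint with an empty
interior. Reads are assigned to every bin containing their 5′-most
aligned base — nascent-transcript 5′-end libraries mark transcription
start positions, and point assignment keeps bin sums interpretable
(with 50% overlap a read lands in at most two bins). Counting is
unstranded; strand is parsed and carried for future use.

## Differential transcription

**Model.** Bin counts are negative binomial with mean μ and common
dispersion φ, Var = μ + φμ² (φ = 0 is Poisson). Size factors are
library sizes scaled to geometric mean 1.

**Dispersion.** Method of moments: for each bin and each group with
≥ 2 replicates, the size-factor-adjusted counts contribute s² − m̄
(expectation φm̄² under the model) and m̄²; φ̂ = max(0, Σ(s²−m̄)/Σm̄²)
over bins with positive mean. The estimator is slightly biased
downward (E[m̄²] > μ² by σ²/n), acceptable for the ±0.05 recovery
checked by the test suite; no tagwise or trended estimation is
attempted.

**Exact test.** For a two-group contrast, counts are scaled by size
factors and rounded to integer pseudo-counts (a simplification of
NBPseq's quantile adjustment — a documented deviation), pooled into
group totals A and B. A sum of n i.i.d. NB(μ, φ) variables is
NB(nμ, φ/n); both group totals then share the NB probability
parameter, so the distribution of A conditional on A + B = T is free
of μ. The two-sided p-value sums the conditional probabilities of all
splits no more probable than the observed one (relative tie tolerance
10⁻¹²); T = 0 bins are untested and excluded from the BH multiplicity
count. The test is validated against an independent enumeration oracle
built from `scipy.stats.nbinom`/`poisson` pmfs for all totals ≤ 50 and
φ ∈ {0, 0.05, 0.2}, and its type-I error is calibrated by simulation.

**Single-replicate contrast.** With one mutant library no
within-group variance exists, so a generalized fold-change score is
used instead: per-million rates get independent Gamma(count + 1,
depth/10⁶) posteriors (flat prior); with d = log₂(λ_wt/λ_mut), the
score is the posterior c-quantile of d if positive, the
(1−c)-quantile if negative, else 0 (c = 0.01 by default, matching a
0.01 posterior error level). Score ≥ 1 ⇒ *reduced* (wild type ≥
2-fold higher with credibility 1−c); |score| ≤ 0.1 (log₂ units —
the linear reading of "0.1-fold" is selectable via the
`unchanged_max_score` argument) with point fold change < 2 ⇒
*unchanged*. Default 2000 Monte-Carlo draws per bin in the pipeline
(quantile noise ≪ the 0.1 decision band; a warning fires below 1000).

**Status calls.** reduced ⇔ q < 0.05 and mutant mean below wild type
(two-sided p with a post-hoc direction filter, keeping symmetry with
the unchanged call); unchanged ⇔ q > 0.9 and fold change (either
direction) < 2. The genome-screen threshold 0.04 and the category
threshold 0.05 coexist in the configuration and are not reconciled.

## Methylation and DMRs

Site level = #C/(#C+#T), requiring ≥ 5 reads per cytosine. Bin levels
pool the qualifying counts of one context (coverage-weighted), not the
mean of site levels — the ratio-of-counts phrasing supports pooling.
Differential bins use a two-sided Fisher exact test on the pooled
2×2 table per bin (replicates pooled per genotype), BH-adjusted over
tested bins; a DMR additionally requires a wild-type-minus-mutant
difference ≥ the per-context minimum (0.25 CHH for the de novo
pathway mutant, 0.55 CG for the CG-maintenance mutant) at q < 0.01.
DMRs are directional (loss in the mutant). Fisher + BH replaces
methylKit's logistic/SLIM machinery: it is deterministic and
oracle-testable, and only the FDR and minimum-difference thresholds
are contractual. Adjacent DMR bins are not merged.

## Locus categories and contrasts

Pol V-transcribed bins: q < 0.05 with the wild-type mean above the
Pol V-null mean in the wild-type-vs-null contrast. These intersect the
mutant contrast's statuses into *reduced* and *unchanged* sets (bins
in neither status are dropped — the categories are deliberately
non-exhaustive). Transcribed DMR bins are categorized by their two
complementary contexts: *both_present* requires each above its
presence cut (CHH 5%, CHG 10%, CG 20%) in wild type **and** mutant;
*neither_present* requires a measured mutant level of exactly 0 in
both complementary contexts with wild-type presence; everything else
(including undefined levels) is excluded with a recorded reason.

The "level exactly 0" absence rule is brittle under noise: at 30×
coverage and a 0.5% bisulfite conversion error, a truly unmethylated
bin pools ≥ 1 spurious methylated read with high probability, so
absence calls require either error-free simulation (the validation
default) or a pre-corrected input; this coverage sensitivity is a
known limitation shared with the underlying rule.

Group contrasts use the two-sided Wilcoxon rank-sum test. Both groups
≤ 8: exact enumeration of all rank splits with midranks (ties exact).
Larger groups: normal approximation with tie-corrected variance,
0.5 continuity correction, and an Edgeworth kurtosis term using the
exact no-ties excess kurtosis γ₂ = −(6/5)(m²+n²+mn+m+n)/(mn(N+1)).
The term is O(1/N) and vanishes asymptotically; it is included because
the plain continuity-corrected normal approximation has a worst-case
error of 0.0109 against the exact distribution at n = m = 8 (measured
by full enumeration), while with the correction the worst case drops
to 0.0006, making the exact and large-sample code paths agree to
better than 0.01 everywhere near the switch point. With heavy ties
the γ₂ formula is approximate; the tie-corrected variance dominates.

## Enrichment and metaprofiles

The overlap statistic is the number of query intervals overlapping an
annotation by ≥ 1 bp. Each of the 1000 permutations independently
re-places every query interval, preserving its length, on a
chromosome drawn with probability proportional to placeable length
and a uniform start (inter-interval spacing and chromosome of origin
are not preserved; overlaps among placements are allowed). The
empirical p uses the plus-one estimator — the floor at 1000
permutations is 1/1001, matching a "P < 0.001" reporting convention —
and the smaller of the enrichment/depletion tails is reported with
its direction. When several annotation classes are scored, one shared
permutation stream is used so ratios are comparable across classes.
No GC- or mappability-matched null is attempted.

Metaprofiles average per-base-pair signal around the 5′ and 3′
boundaries of TEs longer than 500 bp (3′ mirrored so positive offsets
point into the TE). The per-bp value of a sliding-window track is the
mean of the covering bins; profiles are reported at 10 bp resolution
over ±500 bp by default (the flank width is configurable; ±1000 bp in
the library default) as a ratio (mean numerator + 0.5 RPM)/(mean
denominator + 0.5 RPM). The 0.5 RPM pseudocount regularizes
zero-signal bins in the mutant denominator.

## Synthetic data generator

The generator emulates the analysis inputs with planted truth:

* **Genome/annotation** — 2 chromosomes × 500 kb; 150 TEs per
  chromosome with log-uniform lengths 300–3000 bp and family labels;
  40 genes per chromosome placed off-TE.
* **Locus classes** — 60 `feedback_rddm_only` loci (wild-type Pol V
  rate 50 reads/bin/million, 5 in downstream-pathway mutants, complete
  methylation loss in all contexts in the mutant), 60 `multi_pathway`
  loci (rate unchanged at 50; CHH collapses 0.6 → 0.05 while CG 0.5
  and CHG 0.3 persist in the mutant), and a genome-wide surveillance
  floor of 0.5 reads/bin/million with no cytosines. The Pol V null
  collapses every locus to the floor. Feedback loci sit on the ends of
  long TEs with probability 0.8, emulating the enrichment of the
  feedback on TE edges. Effect sizes follow the study conditions: a
  10-fold rate drop gives the 2-replicate exact test near-complete
  power at FDR < 0.05 while unchanged loci stay clear of the 2-fold
  band.
* **Counts** — per non-overlapping source bin, NB(rate·depth/10⁶,
  φ = 0.1) at depth 10⁶ mapped reads; read positions uniform within
  the bin.
* **Methylation** — 12 CG, 12 CHG and 24 CHH sites per 200 bp locus;
  coverage Poisson(30); methylated counts Binomial(cov,
  level·(1−e)+(1−level)·e) with conversion error e (default 0.005;
  the validation dataset uses e = 0 so the absence-of-methylation
  categories are exactly attainable — see above).
* **Determinism** — every output file draws from its own seeded
  stream (seed + file name), so adding a genotype never perturbs the
  others and a fixed seed yields byte-identical files.

What the generator does **not** emulate: sequence composition,
mappability and PCR bias, spatially varying background transcription,
partial methylation mosaics, or DMRs outside planted loci. Passing
tests therefore demonstrate correctness of the statistical machinery
and end-to-end plumbing under the stated model, not robustness to
real-data artifacts.

## Pipeline determinism and problem sizes

Every stage writes TSVs with fixed float formatting; all randomness
(GFOLD draws, permutations) derives from the configuration seed via
named streams, and two runs of the same configuration produce
byte-identical result tables (verified across processes). The default
validation problem sizes — ~1 Mb genome, 13 libraries, 20k sliding
bins, 1000 permutations, 2000 posterior draws per bin — were chosen
so the complete pipeline, including simulation, finishes in well under
a minute while leaving the statistical checks (type-I calibration,
dispersion recovery, permutation null calibration) adequately powered.
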
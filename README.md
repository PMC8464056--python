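# rddmkit

Genome-wide analysis of the positive feedback between RNA polymerase V
(Pol V) transcription and RNA-directed DNA methylation (RdDM) in
plants, built as a tested, reusable pipeline.

In *Arabidopsis*, Pol V transcribes long non-coding RNAs that guide
siRNA-directed DNA methylation to transposable elements (TEs); the
resulting methylation in turn enhances Pol V transcription, closing a
self-reinforcing loop. Because most RdDM loci are also maintained by
the CG- and CHG-maintenance pathways (MET1, CMT3), the feedback only
becomes visible at loci that lose methylation in **all** sequence
contexts in a mutant. `rddmkit` implements the computational side of
that analysis for researchers working with nascent-transcript 5′-end
libraries (IPARE-style BED read positions) and whole-genome bisulfite
cytosine reports:

* **Sliding-window counting** — 100 bp bins every 50 bp, 5′-base read
  assignment, RPM normalization.
* **Differential Pol V transcription** — Robinson–Smyth exact
  conditional negative-binomial test with a method-of-moments common
  dispersion φ (Var = μ + φμ²) for replicated contrasts; a GFOLD-style
  posterior generalized fold change (Gamma posteriors on read rates,
  score = credible bound on log₂ λ_wt/λ_mut) for single-replicate
  contrasts; Benjamini–Hochberg FDR; *reduced* (q < 0.05, mutant
  lower) vs *unchanged* (q > 0.9, fold < 2) status calls.
* **Methylation and DMRs** — per-cytosine level #C/(#C+#T) with a
  minimum of 5 reads, coverage-weighted bin levels per context,
  Fisher-exact differentially methylated bins with per-context
  minimum differences (25% CHH, 55% CG) at FDR < 0.01.
* **Locus categories** — Pol V-transcribed bins (wild type vs Pol V
  null, FDR < 0.05), DMRs split by presence (5% CHH / 10% CHG /
  20% CG) or complete absence (0%) of the complementary contexts in
  the mutant, and Wilcoxon rank-sum contrasts between categories.
* **Enrichment and profiles** — 1000-permutation observed/expected
  overlap ratios against genes, TE families, TE ends (terminal
  150 bp) and TE interiors, and average signal-ratio metaprofiles at
  the 5′/3′ ends of TEs longer than 500 bp.
* **Synthetic data** — a first-class generator that plants RdDM-only
  "feedback" loci, multi-pathway loci and background with known rates
  and methylation levels, so the whole pipeline is validated
  end-to-end against ground truth without any external download.

## Worked example

Simulate the default study conditions (a ~1 Mb two-chromosome genome,
60 feedback + 60 multi-pathway loci, two replicates per genotype and a
single met1 replicate) and run every stage:

```bash
rddmkit simulate --outdir demo --seed 1 --conversion-error 0
rddmkit run-all --config demo/pipeline.yaml
```

or equivalently from Python:

```python
from rddmkit import SyntheticConfig, export_dataset
from rddmkit.pipeline import pipeline_config_for_dataset, run_pipeline

dataset = export_dataset(SyntheticConfig(seed=1, conversion_error=0.0), "demo")
config = pipeline_config_for_dataset(dataset, "demo/results", seed=1)
run_pipeline(config)
```

`demo/results/` then contains per-contrast tables. With seed 1 the
category summary for the drm2 contrast (`summary_drm2.tsv`) reads:

```
category         n_regions  q1      median  q3      wilcoxon_p
neither_present  300        2.5     4       5.125   9.9e-100
both_present     300        26.375  38      50.75
reduced          290        2.5     4       5.0
unchanged        280        27.375  39      51.625
```

Reading this: 600 Pol V-transcribed CHH-DMR bins split evenly into the
two planted categories; bins whose CG and CHG methylation is
completely lost in the mutant ("neither_present") carry a median
mutant Pol V signal of 4 RPM versus 38 RPM where symmetric methylation
persists — the synthetic analogue of the feedback readout, significant
at p < 10⁻⁹⁹ (Wilcoxon). The enrichment table shows the
feedback-reduced bins piling onto TE edges (observed/expected ≈ 3.9 at
the permutation floor p = 1/1001), and the TE-end metaprofile of the
wild-type/mutant signal ratio is ≈ 3.4× higher at TE ends than deep
inside TEs.

Every stage can also be run individually (`rddmkit count|diff|meth|
classify|enrich|profile`); unchanged stages are cached via the run
manifest and re-running a config is a no-op.

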
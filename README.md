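# oomics

Multi-omics analysis of the growing-oocyte epigenome: broad H3K9me2
domain calling from windowed ChIP-seq counts, CpG-tiled differential
DNA methylation with domain merging and clustering, negative-binomial
differential gene expression with ERV quantification, moderated-t
differential protein abundance for TMT proteomes, and the cross-omics
integration statistics (overlap enrichment against random genomic
nulls, barcode rank enrichment, methylation–expression correlation).

The package is aimed at analysts working with low-input oocyte (or
other scarce-cell) multi-omic data, where histone marks form broad
low-amplitude domains rather than sharp peaks, methylation must be
compared on equal-CpG-content tiles, and libraries are shallow enough
that conservative fold-change filters matter. It ships a first-class
synthetic-data generator with planted truth, so the whole pipeline is
exercised end to end and every statistical engine has a
parameter-recovery test.

## The statistics at the core

* **Domains**: 10-kb tiles quantified as RPKM; artifact windows
  (input RPKM above threshold in any replicate set) masked; windows
  with log2 RPKM above threshold merged into domains across gaps
  ≤ 10 kb, with a uniformly sampled random-window null.
* **DMRs**: consecutive 100-CpG tiles with ≥ 10 observed cytosines in
  all samples; beta-binomial likelihood-ratio test per tile
  (`a = m(1−φ)/φ`, `b = (1−m)(1−φ)/φ`, pooled method-of-moments
  dispersion); calls need BH-adjusted *p* < 0.05 **and** |Δ| ≥ 20
  percentage points; same-direction DMRs merge into domains that are
  Ward-clustered into common/unique responses across genotypes.
* **DEGs**: median-of-ratios size factors; NB Wald test with trend-
  shrunk moment dispersions; calls need adjusted *p* < 0.05 **and**
  |log2FC| ≥ 1.5; hypergeometric down-sampling for cross-dataset
  comparisons; ERVs within 2 kb of genes excluded before quantifying
  ERV reads as % of library.
* **Proteins**: moderated t with trigamma-matched prior
  (posterior variance `(d0·s0² + d·s²)/(d0+d)`, t on d0+d df); calls
  need raw *p* < 0.05 and |log2FC| ≥ 0.3.
* **Integration**: two-tailed Fisher / chi-square overlap enrichment
  with Bonferroni adjustment; barcode worm (set density relative to a
  uniform spread in a 0.25·N window) with one-sided rank-sum tests;
  Spearman correlations between omic layers.

See `docs/methods.md` for models, parameter defaults and the design
decisions behind them.

## Worked example

Run the full synthetic pipeline — simulate, ChIP domains, methylome,
transcriptome, proteome, integration — on the default desk-scale
design (3 × 5 Mb genome; fold-6 planted H3K9me2 domains at 1e6 reads;
30× bisulfite with 2 replicates per genotype; 4v4 NB RNA counts with
90%-up planted fold changes; 5v5 proteome rank-coupled to the
transcriptome at ρ = 0.43):

```sh
oomics run --outdir out --seed 1
```

`out/filter_counts.json` then reports, for this seed:

```json
{
 "windows_masked": 20,   "windows_called": 76,  "domains": 12,
 "random_domains": 119,  "tiles_retained": 1343, "dmrs_called": 40,
 "dmds": 39,             "degs_up": 32,          "degs_down": 2
}
```

All 12 planted domains and all 40 planted DMR tiles are recovered; the
34 DEG calls are all planted genes (34 of 40, zero false positives,
and the 90/10 up:down planted asymmetry survives the calls); the 20
planted artifact windows are exactly the 20 masked.
`out/integration_summary.json` shows the transcript–protein coupling
of the *measured* fold changes — `spearman_rho` = 0.361
(p ≈ 1.1e-10 over 300 shared genes), attenuated from the planted
truth-level coupling of 0.43 by estimation noise on both axes, as
expected — and strong rank enrichment of up-regulated proteins among
up-regulated transcripts (`rank_p.up` ≈ 1.9e-05). Every table carries
a provenance header (package version, config hash, seed); rerunning
the command reproduces every file byte for byte.

The same stages are available piecewise (`oomics simulate`,
`oomics chip-domains`, `oomics methylome`, `oomics rnaseq`,
`oomics proteome`, `oomics integrate {overlap,barcode,correlate}`)
for real data in the standard formats: BED intervals, TSV count and
intensity matrices, per-CpG coverage files, and a TSV sample sheet.

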
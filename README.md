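# oxland

Genome-wide analysis of oxidative DNA damage landscapes from AP-seq-style
pulldown sequencing, and of their imprint on cancer mutation patterns.

Oxidative lesions — 8-oxoguanine and the apurinic/apyrimidinic (AP) sites
left behind by its repair — accumulate very unevenly across a genome:
retrotransposons are hotspots, promoters and exons are protected, and the
dependence on GC content is non-monotonic. `oxland` is a library for
quantifying that landscape from paired pulldown/input fragment libraries
and genome annotations, and for asking whether cancer single-nucleotide
variants (SNVs) attributed to oxidative mutational signatures follow it.
It is aimed at computational genomicists working with damage-enrichment
sequencing or signature-stratified tumour cohorts.

## The core statistic

Damage per genomic bin is measured as **Relative Enrichment**,

    RE(bin) = log2( (pulldown(bin)/f_p + eps) / (input(bin)/f_i + eps) ),

where coverage is mean per-bp fragment coverage and the global scaling
factors `f` are each library's mean coverage over a low-damage background —
the lowest decile of 100-kb bins ranked by mean coverage across all
libraries. This makes RE invariant to library size and antisymmetric under
swapping pulldown and input. On top of RE the package builds:

- **GC stratification** — integer-percent GC per 1-kb bin with a 10%
  undefined-sequence censoring rule, enrichment-vs-GC curves, and
  strand-folded trinucleotide spectra (32 classes) with sequence-based
  expected mutation fractions;
- **metaprofiles** — per-bp profiles around stranded anchors and
  equal-weight element means (gene-body composites, retrotransposons,
  binding sites, CpG islands, G-quadruplexes, microsatellites, expression
  and GC deciles);
- **chromatin-loop anchors** — CTCF/RAD21/SMC3 triple-overlap anchor
  calling, insulation classification from the H3K36me3:H3K27me3 log-ratio
  change across the anchor (swap ON / swap OFF / ON / OFF), and oriented
  damage differentials;
- **mutation landscape** — patient censoring and signature-exposure
  grouping (Signatures 18, 17, 10), per-patient GC-rich SNV fractions with
  rank-sum statistics, replication-timing stratification, and
  GC-normalised SNV metaprofiles;
- **a synthetic-study generator** — seeded genome, annotation, damage
  field, fragment libraries, chromatin tracks and SNV cohorts with stored
  ground truth, so every estimator is tested by parameter recovery.

## Worked example

`examples/02_relative_enrichment.py` simulates the default desk-scale study
(2 chromosomes x 5 Mb, 3 replicates, 5e5 fragments per library, planted
log2 damage effects of +2 in Alu elements and −1.5 in promoters) and runs
the full normalisation chain:

```
$ python examples/02_relative_enrichment.py
scaling factors (mean coverage in the low-damage decile):
  pulldown_0: 2.3795
  input_0: 2.4485
  pulldown_1: 2.3940
  input_1: 2.4576
  pulldown_2: 2.3412
  input_2: 2.4338
replicate 0 vs 1 Spearman over 96 100-kb bins: 0.363
alu       planted +2.0  recovered +2.036  (n=600, background RE -0.077)
promoter  planted -1.5  recovered -1.513  (n=80, background RE -0.077)
```

The scaling factors are per-library mean coverage over the shared
low-damage bin subset; the last two lines quantify each feature class by
element-level RE against matched intergenic background windows, recovering
the planted effects to within a few hundredths of a log2 unit.

The other examples walk the remaining capabilities: `01` writes a complete
synthetic study to disk (FASTA/BED/fragments), `03` recovers a planted
GC-response curve and prints trinucleotide-spectrum expectations, `04`
compiles gene-body/Alu/microsatellite profiles, `05` calls and classifies
loop anchors and tests the swap ON vs swap OFF damage asymmetry
(p < 0.001), and `06` runs the signature-stratified cohort analysis, where
GC-context-depleted tumours show a roughly threefold lower GC-rich C>A
fraction than controls.

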
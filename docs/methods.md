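# Methods

`oxland` analyses the genome-wide landscape of oxidative DNA damage as
measured by pulldown sequencing of tagged apurinic/apyrimidinic (AP) sites,
and relates it to cancer mutation patterns. This note documents the models,
estimators, numerical choices and the synthetic study design that makes the
whole chain testable without external data.

## Relative Enrichment

The central statistic is the **Relative Enrichment** (RE): the normalised
log2 fold change of pulldown coverage over input coverage per genomic bin,

    RE(bin) = log2( (pulldown(bin)/f_p + eps) / (input(bin)/f_i + eps) ).

*Fragments.* A fragment is the full interval between the outermost mate
coordinates of a read pair; pairs mapping more than 1 kb apart, on different
chromosomes, or malformed (end <= start) are discarded and counted.

*Coverage.* Per-bin coverage is the mean per-bp fragment coverage; a
fragment contributes to every bin it overlaps, proportional to overlap
length, so coverage mass is conserved across bin borders.

*Inter-library normalisation.* Damage exposure inflates pulldown library
complexity, so libraries cannot be normalised by total size. Instead, bins
are ranked by their mean coverage across all libraries at 100-kb resolution;
the lowest decile (floor(0.1 x usable bins), ties broken stably by bin
index) defines a low-damage background, and each library's global scaling
factor f is its mean coverage over that subset. RE is then invariant to
rescaling any library by a positive constant, and swapping the roles of
pulldown and input negates it exactly.

*Pseudocount.* The plain log2 fold change is undefined on zero-coverage
bins. We add eps = 0.5/bin_size on the scaled-coverage scale (half a fragment-bp
per bin): it keeps RE finite everywhere, vanishes at appreciable coverage,
and — because it is applied after scaling — preserves the rescaling
invariance exactly.

*Missingness.* Bins whose undefined-sequence (N) fraction exceeds 10% are
flagged missing; a bin missing in any replicate is missing in the
aggregate. Replicate aggregation happens after per-replicate RE (mean and
SEM = sd/sqrt(n) across replicates); with a single replicate the SEM is
reported unavailable, never zero. Analyses default to the full chromosome
set of the genome at hand; a restricted universe (e.g. autosomes + X) can
be passed explicitly.

*Element-level quantification.* For feature-level statements ("mean RE over
the element") the estimator averages scaled coverage over the element
*before* taking the log ratio. The per-bin mean-of-logs is biased downward
by Jensen's inequality wherever bins hold only a few fragments; aggregating
first removes that bias down to a handful of fragments per element. Two
further refinements: the per-element pseudocount is 0.5/element-width
(matched to the aggregated quantity), and an optional `edge_trim` (half the
median fragment length) drops the boundary bp whose coverage mixes feature
and flank — full-span fragment coverage smears any sharp effect by half a
fragment on each side.

## GC content and trinucleotide spectra

GC content is computed per 1-kb bin over defined bases only, rounded
half-away-from-zero to integer percent (the rounding rule at .5 is a
documented choice; the convention matters only for bins landing exactly on
a half percent). Bins with more than 10% undefined sequence are censored
and excluded from every downstream GC-stratified statistic. "GC-rich"
means rounded GC >= 50%, following the quantification rule ("50% GC content
or higher"); the cutoff is a parameter everywhere.

Enrichment-vs-GC curves average RE per integer GC percent (per replicate,
then across replicates), which deliberately weights sparse extreme-GC
categories equally with abundant ones. Gaussian smoothing over 10 percent
categories is display-only and never feeds statistics.

Trinucleotides are folded with their reverse complements. No odd-length
trinucleotide is self-complementary, so the 64 sequences collapse to
exactly 32 classes. Counting uses overlapping windows stepping 1 bp; a
window is assigned to the 1-kb bin of its central base (conserves totals,
unambiguous at borders) and skipped if it touches an N. The spectrum stores
counts per (GC percent category, class); from it we compute each category's
class proportions, the genome share per category, and the pooled GC-rich
share.

**Sequence-based mutation expectations.** For a mutation type with central
pair C:G (C>A, C>T) or T:A (T>G), the expected GC-rich fraction under
"equal distribution dependent exclusively on base content" weights every
occurrence of a valid-central-base trinucleotide equally; a signature
profile instead weights occurrences by its 32 class weights. Both reduce to
one weighted ratio over the spectrum counts.

## Metaprofiles

Point-anchored features (TSS, termination sites, binding-site and element
centres/starts, exon junctions) get per-bp profiles; minus-strand features
are reversed so the axis always runs 5'->3'. Variable-size elements (UTRs,
exons, introns, intergenic regions) are summarised by their mean track
value with every element weighted equally regardless of length. In both
modes the SEM is taken across replicates, never across features. The
gene-body composite orders segments as promoter (TSS -1 kb/+500 bp) ->
5'UTR -> exon 5' junction (+/-250 bp) -> exon -> exon 3' junction ->
intron -> 3'UTR -> termination site (-500 bp/+1 kb) -> intergenic; the GC
companion profile is Gaussian-smoothed over 100 bp. Intergenic regions are
derived as the complement of transcript spans plus annotated
promoters/terminators.

Feature-selection rules mirror the quantification filters: size windows are
treated as closed intervals [lo, hi] ("between 50 and 200 bp" includes both
bounds); TF binding sites within 500 bp of a CTCF-site centre are excluded
(<= 500 excluded — the boundary itself is conservative); promoter overlap
means overlap with TSS +/- 1 kb.

Expression/GC stratification splits silent features (covariate exactly 0)
first, then ranks the rest stably on (covariate, feature id) and cuts them
into 10 groups whose sizes differ by at most one.

Microsatellite classes are canonicalised in two steps: lexicographically
minimal rotation of the repeat unit, then reverse-complement pooling to the
alphabetically first representative. Rotation canonicalisation prevents
(GAA)n/(AAG)n/(AGA)n from fragmenting into separate classes; the class
label is therefore the minimal rotation (AAG for the GAA family), while
membership matches plain reverse-complement pooling. Types represented at
most 1000 times genome-wide (strict >) are dropped; per-type damage is the
median of per-repeat mean RE.

Gaussian smoothing uses sigma = window/4, truncated at +/-window/2, with
the kernel renormalised at series edges and around missing points, so a
constant series is preserved exactly. A window larger than the series
returns the global weighted mean with a warning.

## Chromatin-loop anchors

Anchors are a peak-overlap proxy for loop boundaries: a CTCF peak qualifies
only if it overlaps a canonical CTCF motif and RAD21 and SMC3 peaks. The
anchor sits at the motif centre, oriented by motif strand; anchors closer
than 500 bp are merged and recentred at their midpoint, inheriting the
orientation of the anchor backed by the stronger CTCF peak (leftmost on
ties). Merging is chained and idempotent.

Orientation semantics live in one place: the loop interior is the
downstream (+) side of the oriented motif, so "outside" is upstream.
Insulation is classified from raw histone coverage (deliberately not
input-normalised) in the 10-kb windows on either side:

    d = log2(H3K36me3/H3K27me3)_inside - log2(H3K36me3/H3K27me3)_outside

with d > +1.2 -> "swap ON" (crossing into the loop moves from inactive into
active chromatin), d < -1.2 -> "swap OFF"; otherwise the anchor is "OFF"
when mean log2(H3K27me3/H3K36me3) over the combined +/-10 kb exceeds 2,
else "ON". The sign convention is fixed by requiring that "swap ON" mean
inactive-to-active on entry into the loop; the neutral OFF/ON rule uses the
mean of both windows. A pseudocount of one coverage unit per window keeps
ratios finite over sparse marks; anchors with zero coverage of both marks
in a window stay "unclassified". Flipping every anchor's orientation
negates every differential and exchanges the swap classes exactly.

Damage asymmetry per anchor is the mean RE over (0, +10 kb] minus
[-10 kb, 0), oriented, computed per replicate then averaged; classes are
compared with a two-sided Wilcoxon rank-sum test (exhaustive enumeration on
tie-averaged ranks for total n <= 20, normal approximation with tie
correction above).

## Mutation landscape

Mutation types are strand-folded (C>A = G>T, T>G = A>C, C>T = G>A); no
statistic is strand-specific, and complementing an entire catalog leaves
every result unchanged. Patient censoring removes hypermutators (C>A
strictly above 100,000), carriers of coding mutations in OGG1/APEX1/FEN1
(precomputed flags; consequence calling is out of scope) and documented
smoking/chemo/radiotherapy patients; patients with missing flags are
retained with a report entry, never silently dropped. POLE
proofreading-deficient tumours are *selected* by the hypermutator phenotype
combined with Signature 10 exposure above a prominence threshold (default
0.2 — configurable, as no published value exists) and are exempt from the
hypermutator removal.

Signature-exposure groups use lower-closed/upper-open bins except the top
bin (Sig18: [0,0.1), [0.1,0.4), [0.4,0.6), [0.6,1]; Sig17: [0,0.1),
[0.1,0.25), [0.25,0.5), [0.5,1]). The per-patient GC-rich fraction is
computed per mutation type with separate denominators; SNVs in censored
bins leave both numerator and denominator, and a patient left without SNVs
is excluded with a count. Group contrasts are rank-sum tests against the
lowest-exposure reference group. Replication-timing stratification ranks
uncensored 1-kb bins into three equal-count tertiles (stable on bin index;
constant timing degrades to an index split with a warning) and recomputes
the GC-rich fraction within each.

SNV metaprofiles pool a patient group's mutations of one type, count them
per position relative to stranded anchors, scale the group to 1,000,000
mutations, divide by local GC over the genome-average GC (computed from the
genome provided, never hard-coded), and Gaussian-smooth for display (100 bp
default; 200 bp recommended for sparse features such as LINEs). The
1e6-normalisation makes profiles invariant to uniform catalog scaling; no
trinucleotide-based correction is applied to mutation data.

## The synthetic study

The generator produces a full study with known ground truth; its defaults
are the package's reference conditions and are not tuned per analysis.

*Genome.* 2 chromosomes x 5 Mb. Background GC is drawn per 10-kb block from
N(0.41, 0.055) (clipped), giving 1-kb bins a realistic GC-percent spread
around a 41% average with roughly a tenth of the genome above 50%.
Promoters (GC 0.62) and CpG islands (GC 0.68) are GC-rich. A contiguous
centromere-like N-run (2% of each chromosome) exercises the >10%-undefined
censoring rule. Gene models (8/Mb) are non-overlapping with promoter,
5'UTR, 4-7 exons (80-200 bp), introns (0.5-2 kb) and 3'UTR; Alu elements
(60/Mb, 270-330 bp) are intronic or intergenic, never in exons or
promoters; LINEs (2/Mb, 5.9-6.1 kb, family-labelled) are intergenic.
Microsatellite units are written literally into the sequence. CTCF motifs
are stranded and spaced so no unintended anchor merging occurs.

*Damage field.* Multiplicative per-bp intensity: baseline x GC response x
2^(sum of log2 feature effects), zero on N-runs. Default planted effects:
Alu +2.0, promoter -1.5, exon -1.0, LINE +1.0. The default GC response is
flat so the planted feature effects are identifiable from RE alone; a
rise-then-fall preset (`gc_bump_response`, peaking near 47% GC and falling
above, the qualitative in-vivo shape) is used when the enrichment-vs-GC
curve itself is under study. No quantitative generative damage model has
been published; these values are stand-ins, and all field-level claims are
recovery-based.

*Libraries.* 3 replicates x 5e5 fragments per library. Input midpoints are
uniform over defined sequence; pulldown midpoints are sampled proportional
to the field after multiplying 1-kb blocks by gamma noise (shape theta=20,
mean 1), which makes per-bin counts super-Poissonian (variance >= mean, the
gamma-mixed contract) while conserving the requested fragment count
exactly. Fragment lengths are N(60, 15) truncated at 1 bp and chromosome
ends. The 60-bp span is a desk-scale choice: full-span coverage smears
feature borders by half a fragment, and for the smallest hotspot element
(270-bp Alus) the closed-form boundary-loss estimate says the span must
stay below ~60 bp for the smearing attenuation of a feature-mean log-ratio
to remain under ~0.1 log2 units. Real AP-seq fragments (~300 bp) sit on a
genome 300x larger, where hotspot elements are quantified from vastly more
elements; the desk-scale study trades fragment length for that lost
averaging.

*Chromatin.* Planted anchors (28/chrom) sit in intergenic space (their
step-shaped chromatin states should not cut through gene territories) with
windows clear of undefined sequence, labels cycling through swap ON/swap
OFF/ON/OFF. Histone coverage is step-shaped at 10-kb scale (active level 8,
inactive 1, log2 ratio 3 — comfortably past both the 1.2 swap and 2.0
OFF cutoffs) plus multiplicative log-normal noise (sigma 0.1 by default; 0
gives the noiseless limit in which label recovery must be 100%). Damage
loads toward the inactive compartment: swap anchors receive opposite
intensity steps of +/-0.4 log2 per side (0.8 log2 across), neutral anchors
none.

*SNV cohorts.* SNVs are sampled at genomic occurrences of the
trinucleotide classes drawn from each patient's signature mixture
(strand-folded; every emitted SNV's folded context matches its sampled
class by construction). Signature profiles are synthetic stand-ins with
qualitatively faithful context preferences (Sig18-like: NCA/NCT C>A;
Sig17-like: CTT-dominated T>G; Sig10-like: TCT-dominated C>A). The
reference cohort is 50 control patients (Sig18 exposure 0.05) vs 50
signature-high patients (0.7) whose GC-rich positions are sampled with
weight 1/3 — a threefold context depletion emulating the observed loss of
GC-rich oxidative mutations; optional POLE-like hypermutators carry >1e5
C>A with Sig10 0.8 and the same depletion. Positions are drawn with
replacement; at desk-scale mutation loads duplicate positions are rare and
harmless to the fraction statistics.

*What the generator does not emulate.* Read-level artefacts (sequencing
error, base quality, mappability), alignment ambiguity in repeats, GC
amplification bias shared by pulldown and input, copy-number structure,
and selection on mutations. Passing recovery tests therefore shows the
estimators are correct under the stated sampling model, not that the
pipeline is robust to alignment or library-preparation artefacts.

## Problem sizes and determinism

The default study (2 x 5 Mb, 3 replicates, 5e5 fragments/library) runs
end-to-end in well under a minute on one CPU; unit tests use 10-kb to 2-Mb
toys. Every generator is a pure function of (spec, seed): identical seeds
give byte-identical FASTA/BED output, and scenario seeds are derived with
`numpy.random.SeedSequence.spawn` so the study, chromatin and cohort
streams are independent.

## Known limitations

- Element-level RE with `edge_trim` assumes elements wider than one
  fragment; tiny elements fall back to an untrimmed core and retain some
  boundary smearing (visible as a mild attenuation of planted exon
  effects).
- Window-mean log-ratio differentials at sparse coverage (loop-anchor
  damage asymmetry) carry count-dependent bias; between-class comparisons
  are rank-based and unaffected, but absolute differentials should be read
  qualitatively.
- The insulation classifier is threshold-based, exactly as specified; no
  uncertainty is propagated into class assignments.
- `low_damage_scaling` assumes the lowest-coverage decile is
  damage-depleted background; designs where true signal is genome-wide
  uniform violate that premise (the scaling then simply matches total
  coverage).
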
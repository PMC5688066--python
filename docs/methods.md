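# Methods

`marinibin` implements the computational chain used to resolve uncultivated
marine clades from single-cell and community sequence data: composition-based
supervised binning of metagenome contigs onto single-cell amplified genomes
(SAGs), fragment-recruitment biogeography along water-column redox gradients,
genome-streamlining summaries, and metatranscriptome (RPKM) aggregation.  A
first-class synthetic-data module generates inputs with known ground truth so
the whole chain can be validated end to end.

## Tetranucleotide z-score signatures (`signatures`)

For a collection of contigs (a SAG, a bin, or one contig), 2-, 3- and 4-mer
counts are pooled over all contigs and — by default — both strands, since
assembly orientation is arbitrary.  Windows containing any non-ACGT symbol
are skipped entirely (not imputed), which keeps counting order-independent
and makes masked regions invisible to the statistic.  Each tetramer `abcd`
is standardised against the maximal-order Markov expectation computed from
the same collection:

    E[N(abcd)]   = N(abc) · N(bcd) / N(bc)
    Var[N(abcd)] = E[N(abcd)] · (N(bc) − N(abc)) · (N(bc) − N(bcd)) / N(bc)²
    z(abcd)      = (N(abcd) − E[N(abcd)]) / √Var[N(abcd)]

`z` is defined as 0 wherever the variance vanishes (the trimer context is
absent), so every signature is a finite, comparable length-256 vector —
a fixed dimensionality the downstream PCA/LDA steps rely on.

Signatures are computed **per SAG (pooled over its contigs)** for SAG
clustering, where the pooled ~100 kb of sequence gives a stable estimate,
and **per contig** for discriminant training and classification, because
the classifier must assign individual metagenome contigs.  The 5 kb minimum
contig length for classification inputs aligns signature stability with the
binning prefilter.

## Bin construction (`binning`)

1. **SAG clustering.** SAG signature rows are reduced to three principal
   components (deterministic sign convention: each loading's
   largest-magnitude coordinate is positive) and clustered agglomeratively
   with Euclidean distance and average linkage; the dendrogram is cut to a
   user-supplied number of clusters, which in practice comes from SSU rRNA
   clade metadata — there is deliberately no automatic cut height.
2. **Prefilter.** A metagenome contig is eligible for binning when its hits
   to some SAG at ≥95% nucleotide identity sum to ≥5 kb of alignment and the
   contig itself is ≥5 kb.  Both readings of the length rule (alignment
   length vs contig length) are enforced, which satisfies the stricter of
   the two.  All identity/length bounds are inclusive (≥) with a strict-mode
   flag.
3. **Classification.** A linear discriminant with per-class means, pooled
   within-class covariance Σ and equal priors is trained on per-contig SAG
   signatures labelled by SAG-cluster.  Equal priors are used because the
   number of SAGs per clade reflects sampling effort, not abundance.
   Eligible contigs go to the class with the highest discriminant score;
   exact ties break to the lexicographically smallest class id, making
   assignment platform-independent.

**Regularisation.**  Σ is estimated from a few hundred 256-dimensional rows
and is therefore singular (rank ≤ n − k).  We use Σ + εI with
ε = 10⁻² · trace(Σ)/256.  The scale matters: a much smaller ridge (e.g.
10⁻⁶) makes Σ⁻¹ explode along the scatter's null space, amplifying
directions whose within-class variance was estimated as zero by chance, and
measurably degrades assignment on the synthetic study (per-clade precision
drops to ~0.83).  10⁻² of the average eigenvalue damps the null space and
is the magnitude Ledoit–Wolf shrinkage selects on the same data; sklearn's
shrinkage LDA is kept as an independent cross-check in the test suite,
never as the implementation.

## Fragment recruitment (`recruitment`)

Alignments enter as BLAST-outfmt-6-style hit tables (+ `qlen`, `slen`); no
aligner is embedded.  SSU rRNA spans can be masked to `N` beforehand so the
conserved gene cannot cross-recruit unrelated taxa.

* **Phylum level:** a contig is recruited when any single hit has ≥70%
  identity over ≥70% of the contig length; recruited bp sums *full* contig
  lengths and the fraction divides by the metagenome size.  Whether
  coverage should merge multiple hits is unspecified in the field's usual
  description; we use the single best hit (configurable).
* **Clade level:** hits are filtered at ≥95% identity and ≥200 bp, then each
  contig is assigned to the clade with the greatest percent identity, ties
  to the greatest alignment length, residual ties to the lexicographically
  smallest clade id.  Clade abundance = Σ assigned full contig lengths (Mbp)
  / (SAG assembly Mbp × metagenome Mbp), so doubling the metagenome size
  exactly halves every abundance.
* **Marker preset:** nosZ-style marker recruitment reuses the clade filter
  at ≥80% identity / ≥60 bp; it is a threshold preset, not a separate code
  path.
* **Redox classes:** oxic (>90 µmol O₂), dysoxic (20–90, both ends
  inclusive), suboxic (1–20, 20 exclusive), anoxic (<1), with
  sulfidic/methanogenic flags overriding O₂ and missing data mapping to
  "unknown".  The anoxic bound is configurable because <2 µmol is also in
  circulation as a cut-off.
* **Genome equivalents** = recruited bp / average genome size (1 Mb
  default).  Note the arithmetic identity this implements: 1.3 Gb at 1 Mb
  per genome is 1,300 genome equivalents — a published figure of "1.3
  million" for these totals is internally inconsistent by three orders of
  magnitude, and we report the computed value, not the printed one.

## Streamlining metrics (`metrics`)

Coding-base percentage = 100 × |union of gene intervals| / genome size;
overlapping genes are counted once because "bases contributing to coding
genes" is a property of bases, not genes (a summed mode exists for
comparison).  COG redundancy = mean occurrence count per distinct COG id;
genes without a COG are excluded; an empty list yields missing, not zero.
For SAGs the assembled length stands in for the (unknown) true genome size.

## Expression aggregation (`expression`)

RPKM = reads × 10⁹ / (gene length bp × total mapped reads) per ORF, with
zero-count ORFs retained so class averages have honest denominators.  The
`total_mapped` figure is taken from the input per sample; whether it counts
all mapped reads or only reads on the ORF catalog is the caller's
convention.  Per-sample RPKM is summed over ORFs sharing a (bin, function)
annotation — after collapsing near-identical within-bin gene copies by
single-linkage grouping at ≥75% amino-acid identity — and per-redox-class
profiles divide each class's summed signal by the number of samples in the
class, zero-signal samples included.  Marker sequences are clustered by one
greedy centroid pass at ≥95% identity: decreasing length order (ties
lexicographic by id), each sequence joins the earliest-founded matching
centroid or founds a new cluster.  Identities are supplied as pairwise
tables; no alignment engine is embedded.

## Synthetic data (`synthio`)

The generator emulates exactly the statistical structure the analysis
assumes, with defaults chosen as the study conditions:

* **Clade models:** order-3 Markov sources obtained by perturbing a shared
  base model (GC 0.5): each conditional probability is multiplied by
  exp(divergence · N(0,1)) and renormalised; divergence 0.2 by default.
  The divergence scale is this package's own construct — no quantitative
  model of real clade compositional divergence is implied.  **Order 3 is
  load-bearing:** the z-score's null model is precisely the order-2 Markov
  expectation, so an order-2 source leaves asymptotically *no* clade signal
  in the signature (measured: between-clade distances ≈ within-clade at
  order 2; 4× larger at order 3).  The clade signal must live beyond the
  null model's memory, hence order 3 — deep enough to carry signal, shallow
  enough that the binning task stays non-trivial.
* **SAGs:** 4 per clade, each an independent 200 kb genome draw fragmented
  into ≥5 kb contigs at 35–65% completeness, emulating the wide completeness
  range of real single-cell assemblies.
* **Metagenome:** a fresh genome per clade cut into ~50/40/30 contigs
  (unequal clade weights make abundance-rank recovery non-trivial) plus a
  40-contig background community from a far-diverged model that must not be
  recruited.
* **Hits:** full contig × SAG cross-product; same-clade identity N(97, 1)
  over 75–100% of the contig, off-clade N(80, 1) over 10–40%, so the
  background passes no 95% filter while tie-breaking among true clades is
  exercised.
* **ORFs and counts:** genes packed densely (~91% coding) with ~10% COG
  reuse, putting per-bin redundancy near 1.1 — the streamlined regime
  reported for real marine SAGs (coding 90–97%, redundancy 1.08–1.16).
  Counts are negative binomial with dispersion 0.1 around
  rate × gene length × library size; the nosZ marker is induced 10-fold in
  samples below 1 µmol O₂.  Six samples span 250 to 0.1 µmol O₂.
* **Determinism:** every draw derives from one root seed through a labelled
  splitting scheme, so a fixture is a pure function of (config, seed) and
  the on-disk suite writes bit-identical checksums on rerun.

What the generator does **not** emulate: read-level sequencing (no FASTQ or
quality scores), chimeras/contamination, strain microheterogeneity within a
clade, GC-dependent coverage bias, or real aligner score distributions.
Passing tests therefore demonstrate the correctness and calibration of the
statistical chain, not its performance on the full messiness of real
assemblies.

## Problem sizes and numerical choices

The default study (3 clades, ~4.1 Mb of simulated sequence, 120 clade
contigs + 40 background, 6 samples) runs the complete pipeline in about two
seconds and was sized so that the signature statistics operate in the regime
they need (≥5 kb contigs, ~100 kb SAGs) while the whole validation remains
desk-scale.  Other choices: variance values are floored at 0 to absorb
floating-point cancellation; PCA components with eigenvalues below 10⁻¹²
of the leading one are treated as null (rank-deficiency flagged rather than
fabricated); hit tables with more than 10% malformed rows abort rather than
silently shrink; GFF3 is converted between 1-based inclusive (disk) and
0-based half-open (memory) at the I/O boundary only.

## Known limitations

* The discriminant is linear with a shared covariance; strongly unequal
  within-clade dispersions would favour QDA-style variants not implemented
  here.
* Binning uses composition only; coverage-based features, completeness
  estimation and bin refinement are out of scope.
* Phylum-level coverage uses the single best hit per contig, which slightly
  under-recruits contigs hit by many short alignments.
* Marker clustering consumes precomputed global identities; it does not
  align sequences.
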
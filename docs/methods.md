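# Methods

This note documents the models, conventions and numerical choices behind
`mitocompare`, in the order the pipeline applies them.

## Genome model and coordinates

Genomes are circular (or linear) sequences with typed features in 1-based
inclusive coordinates, the GenBank convention. Origin-spanning features are
stored as a single `(start > end)` interval and normalized internally;
every extraction and per-nucleotide computation is invariant under circular
rotation of the genome, and the test suite asserts this. Multi-exon genes
list exons 5′→3′ on the coding strand, so the spliced coding sequence of a
minus-strand gene is the concatenation of the reverse-complemented exon
intervals in listed order. IUPAC ambiguity codes outside {A,C,G,T,N} are
normalized to N on input with a warning; N bases are excluded from all
composition denominators but count toward physical region lengths.

## Region partition and contribution rates

Each nucleotide is assigned to exactly one of four classes with fixed
priority **RNA exon > protein-coding exon > intron > intergenic**. This
makes the four classes a true partition (lengths always sum to the genome
length) and resolves gene overlaps deterministically — the shared base of a
1-bp overlap between two protein genes is counted once. Intronic ORFs and
rRNA introns count as intronic; free-standing ORFs count as protein-coding;
tRNAs count as RNA. The contribution of class *c* to the size difference
between genomes A and B is `100 · (len_c(B) − len_c(A)) / (len(B) − len(A))`;
rates are signed, sum to 100% whenever the denominator is nonzero, and are
reported as undefined (differences only) for equal-size pairs.

## Codon usage (translation table 4)

Translation uses the mold mitochondrial code: TGA = Trp, stops TAA/TAG,
start candidates {ATG, GTG, TTG}. The codon table is taken from Biopython's
`CodonTable` rather than re-typed. Start/stop codons outside the candidate
sets are flagged, never dropped — alternative starts (GTG, TTG) are real
observations in fungal mitogenomes. Usage frequencies exclude stop codons
by default (configurable); RSCU for a codon is its count divided by the
mean count of its synonymous family, so family RSCU sums equal family
sizes. Genes whose CDS length is not a codon multiple are excluded with a
warning rather than truncated, keeping annotation errors visible.

## Alignment

Pairwise global alignment uses affine gap scoring (match +1, mismatch −1,
gap open −2 including the first gap base, gap extend −0.5) through
Biopython's `PairwiseAligner`; the first alignment in its deterministic
enumeration order is taken, which fixes tie-breaking reproducibly. Codon
alignments are built by aligning the translated proteins and back-mapping
to nucleotide triplets, so frame is preserved and gaps come in whole
codons.

## K2P distance

With transition proportion P and transversion proportion Q over gap-free,
N-free columns, `d = −½·ln((1−2P−Q)·√(1−2Q))`. Saturated pairs
(log argument ≤ 0) are flagged undefined rather than clamped. When Q = 0
the formula reduces to `−½·ln(1−2P)`, which the tests check numerically.

## NG86 Ka/Ks

Synonymous/nonsynonymous site counts per codon follow the counting
convention in which single-nucleotide changes that would create a stop
codon are inadmissible: at each codon position the synonymous fraction is
computed over the admissible neighbors only, and each position contributes
exactly one site, so N + S = 3 × (codons compared). Observed differences
for codon pairs differing at k positions are averaged uniformly over all
k! minimal mutational pathways, excluding pathways that pass through a stop
codon (falling back to all pathways in the rare case that every pathway
does). pN = Nd/N and pS = Sd/S receive the Jukes–Cantor correction
`−¾·ln(1−4p/3)`; a saturated correction or Ks = 0 flags the ratio
undefined. The test suite validates this implementation against an
independently written oracle that enumerates pathways explicitly, over
hundreds of random codon-pair alignments.

## Per-gene statistics and the tree

Per-gene means (K2P, Ka, Ks, Ka/Ks) are unweighted over all genome pairs
carrying the gene; undefined pairs flag the gene and are omitted from the
mean. The distance matrix for the tree concatenates the core genes present
in **all** genomes, in sorted gene order, pooling substitution counts over
genes before applying the K2P formula. Neighbor joining is standard, with
ties in the Q criterion broken by taxon id order, negative branch lengths
clamped to zero, and the final three lineages joined as an unrooted
trifurcation. Topology recovery on random additive trees (≤ 8 taxa) is a
property test cross-checked through dendropy bipartitions.

## Intron position classes

An intron's position is the number of coding nucleotides 5′ of it
(an intron between nt p and p+1 is at position p, named `P p` after
mapping). Mapping to the reference counts the reference bases strictly 5′
of the alignment column holding the insertion point; a point inside a
reference gap therefore maps to the nearest reference position 5′ of the
gap and is flagged. Matching is exact (no fuzz window): position classes
are site classes, and the mapping is monotone in query position by
construction. The reference coding sequence is a user input; synthetic
panels use the intron-free ancestor's gene as the reference.

## Repeats

Interspersed repeats use an exact k-mer seed (k = 12, both strands),
per-diagonal chaining, and ungapped X-drop extension (+1 match, −2
mismatch, drop 20), reporting maximal windows of ≥ 50 bp and ≥ 75%
identity by default — thresholds chosen to bracket the 76–100% identity
range typical of published fungal mitogenome repeat sets. A window whose
overall identity falls below threshold is decomposed into its maximal
exact runs, so exact repeats flanked by diverged sequence are still
reported; at 100% identity the output provably coincides with an
exhaustive all-substring oracle on desk-scale sequences (tested to 2 kb).
Extension is ungapped only; gapped repeat alignment is future work.

The tandem detector compares the sequence with itself at every period
p ≤ 200, merges exact match runs when merging raises a TRF-style score
(+2 per match, −7 per mismatch) while overall match fraction stays ≥ 0.8,
and reports arrays with ≥ 2 copies and score ≥ 40. The score floor
suppresses the short chance self-similarities a bare match-fraction rule
would report; arrays whose exact stretches are all shorter than 8 bp can
be missed, a deliberate limit of this simplified detector (no
probabilistic scoring as in full tandem-repeat finders). Overlapping
reports of different periods are deduplicated keeping the highest match
fraction, then the longest span.

Shared mito/nuclear fragments reuse the same engine across sequences with
a 100-bp default minimum.

## Gene order

Orders are circular stranded gene lists; rotation-equivalent orders
compare equal. The conserved backbone between two genomes is the longest
common circular subsequence of the shared single-copy genes, computed
exactly by running a linear LCS against every rotation of one order, in
both orientations (reflection flips strands); ties break by fewer strand
flips, then lexicographically. Displaced genes are shared single-copy
genes outside the backbone; doubling events are genes with a higher copy
number in one genome. In the multi-genome summary, the consensus is the
most common arrangement; a gene is `identical-in-all` only when every
order is circularly identical, `identical-in-majority` when it sits in the
backbone of every genome-versus-consensus comparison but the arrangements
are not all identical, and `displaced` otherwise. Displacement is defined
against this computed consensus, not an inferred ancestor.

## tRNA variation

Structures (per-base region codes over acceptor stem, D arm, anticodon
arm, extra arm, T arm, linker) are inputs, not predictions. Variable sites
are differing alignment columns between homologous tRNAs (matched by
name/anticodon, multi-copy tRNAs by genome-order ordinal); indel columns
count as variable by default (configurable) and attribute to the region of
the nearest structured base 5′ of the gap. Region counts always sum to the
total, and the count is symmetric under swapping the two genomes when no
indels occur.

## Synthetic data

The generator emulates the structure of a basidiomycete mitogenome: the 15
core protein genes at realistic lengths, rns/rnl, 25 cloverleaf tRNAs
(with enlarged extra arms for trnS(tga)/trnL(tag), giving the observed
71–88 bp size range), group I/II introns at named coding positions (some
carrying intronic ORFs), free-standing ORFs, a 1-bp overlap across
nad4L/nad5, interspersed repeats planted in spacers (mismatches evenly
spaced so identity is exact by construction), and intergenic spacers
filling a target length of 50 kb at 29% GC by default — figures matching
published *Ramaria*-scale genomes. All randomness flows from a single
seeded generator, so outputs are byte-reproducible.

Divergence applies per-site transitions/transversions (defaults 2%/1%,
a plausible congeneric mitochondrial divergence) with proposals rejected
and re-drawn when they would break a start codon, a stop codon, or create
an internal stop in any overlapping frame; indels (1–5 bp) are restricted
to intergenic sequence; and planned edits (gene moves — optionally to a
named target position — duplications, intron gains/losses) run before
mutation. Every event lands in a GroundTruth record (per-gene
transition/transversion and synonymous/nonsynonymous counts, indel
events, planted Pcls, repeat coordinates, tRNA structures), and the
invariant "re-extraction reproduces the planted features" is tested.

What the generator does **not** model: indels inside genes, rate
heterogeneity among sites, biased gene conversion, or realistic repeat
families. Passing tests therefore demonstrate correctness of the
*measurements* on data whose truth is known, not robustness to
annotation noise or alignment-hard divergence in real genomes.

## Problem sizes used in the checks

The acceptance script and test suite run at desk scale deliberately:
property tests use 100 randomized compact genomes (~10–20 kb), NG86 is
checked against the exhaustive oracle on 200 random ≤ 30-codon pairs, K2P
recovery uses 50 replicate 2-kb neutral regions (mean within 3 standard
errors of the simulated expectation), the Pcl panel uses six ~32-kb
genomes with 49 introns in 27 classes, repeat-oracle equivalence uses 2-kb
sequences, and gene-order recovery plants 4 moves plus 4 doublings in a
50-kb pair. The published-pair arithmetic (size difference, GC gap, mean
AT content, contribution rates) takes the printed genome descriptors as
inputs; percentages are reported to two decimals, rounding half up, to
match the conventional reporting style.

## Known limitations

- The GenBank reader covers the feature types this pipeline consumes
  (CDS, rRNA, tRNA, intron); exotic location operators beyond
  join/complement are not supported, and GenBank writing is out of scope.
- Pcl classification trusts the alignment; for hosts far more diverged
  than congeneric mitochondrial genes, insertion-site mapping near gaps
  may need the (flagged) 5′-nearest rule more often.
- Repeat identity thresholds approximate a BLASTN-style search; since
  such searches are rarely reported with their exact scoring, all
  thresholds here are configurable.
- Ka/Ks is counting-based (NG86); maximum-likelihood codon models are out
  of scope.
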
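# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where more than one convention was
defensible.

## Coordinates and sequence handling

All intervals are 0-based half-open internally; GFF3's 1-based inclusive
and RepeatMasker's 1-based inclusive query coordinates are converted once,
at the file boundary. Sequence case is preserved through I/O so soft-masked
FASTA survives a round trip, but every analysis uppercases before
comparing: masking state never changes a result. When a gene has several
transcripts, the gene-level exon set is the interval union of transcript
exons and the gene-level CDS set the union of transcript CDSs, because all
analyses here operate per gene, not per isoform.

## Gap and contiguity statistics

A gap is a maximal run of `N`/`n` of length ≥ 1. Other IUPAC ambiguity
codes are not gaps: they record uncertain base identity, not absent
sequence. A `min_length` threshold is exposed for sensitivity checks but
defaults to 1.

The Nx statistic sorts sequence lengths descending and reports the length
of the first sequence at which the cumulative sum reaches x% of the total,
together with its 1-based position in that ordering ("N50 = L (n = k)"
style). By construction the k longest sequences cover at least x% of the
assembly and the k−1 longest do not; Nx is monotone non-increasing in x.

Placed/unplaced accounting takes an explicit list of chromosome-scale
record ids; records in an explicit exclude list (typically the
mitochondrial genome) count toward totals but toward neither placed nor
unplaced. Explicit lists were preferred over name-sniffing because record
naming conventions differ across archives.

## Gene-proximal gap context

For each protein-coding gene the scan tests four interval sets against the
scaffold's gap list: a flank window of `flank_size` bp (default 10,000)
upstream, the same downstream, the CDS union, and the introns (gene span
minus exon union). A flag is set when at least one gap base overlaps the
set.

Conventions, each selectable:

- **Strand awareness** (default on): upstream means 5′ of the gene in
  transcription direction. The alternative — genomic-left = upstream —
  exists because published per-gene gap tallies do not always state their
  convention, and the two can differ by a few percent.
- **CDS vs exon** (default CDS): the "gaps in coding sequence" flag tests
  CDS intervals; the exon-union variant additionally counts UTR exon
  sequence.
- Flank windows are clipped at scaffold ends but not truncated at
  neighboring genes, and genes on unplaced scaffolds are included.

## Chromosome homology

Protein similarity for synthetic data comes from global affine-gap
alignment (BLOSUM62, gap open −11, extend −1); identity is matches over all
alignment columns, gap columns included. At real-data scale, hits are read
from BLAST outfmt-6 TSV instead — reimplementing a protein search engine
is out of scope, and the downstream logic only needs (query, subject,
score, identity).

A reciprocal best hit keeps pair (a, b) iff b is a's highest-scoring hit
and vice versa; ties break by higher identity, then lexicographically
smaller partner id, so the result is deterministic and symmetric under
exchanging the two gene sets.

Chromosome homology counts RBH pairs per chromosome pair and assigns
greedily in descending shared-gene order, skipping chromosomes already
used. Greedy is not a maximum-weight matching in general; it matches the
exhaustive optimum exactly when each chromosome shares most of its genes
with a single partner, which is the regime the rule is meant for (and the
regime the test suite verifies against a brute-force oracle on instances
with up to six chromosomes per side). For karyotypes with extensive
fission/fusion a proper assignment algorithm would be needed.

Dot plots are exact-k-mer anchor sets: k = 15 and a copy-number ceiling of
10 per sequence by default. The ceiling and the exclusion of N-containing
k-mers keep satellite arrays from saturating the plot; anchors are emitted
as a table (x, y, strand, k) rather than an image.

## Sex-chromosome fragment analysis

**Marker location** is seed-and-extend: exact 15-mer matches between
marker and contig project candidate windows (clustered by proximity,
padded by max(50, len/10)), and each window is refined by local affine
alignment. Both strands are searched; overlapping hits keep the best
score; hits below `min_identity` (default 0.9) are dropped. Two numerical
choices matter here:

- The structural aligner uses match +2, mismatch −3, gap open −5, gap
  extend −0.5. The cheap extension is deliberate: a 241-bp deletion must
  be crossed by the local alignment (extension cost ≪ the match bonus of
  the sequence beyond it) and must stay a contiguous gap rather than
  smearing into scattered edits against background sequence, which is what
  unit-cost edit distance produces.
- A local alignment trims terminal mismatches, so the reported hit is
  re-extended to cover the full query length. Without this, a substitution
  on the first or last base of a gene copy would clip the extracted
  sequence and shift its reading frame.

**X/Y calling** globally aligns the hit region to the X-reference marker
with the same structural scoring. A deletion diagnostic (name, expected
length L, reference interval) is scored *present* when the summed length
of deletion runs overlapping the interval (± 1 bp coordinate tolerance) is
within 1 bp of L — summed, not per-run, because short coincidental matches
inside a long deletion can split it into adjacent runs without changing
the total. A terminal gap overlapping the interval means the region is
truncated there and the feature is *untestable*. The call is Y iff every
diagnostic is present, X iff every one is absent, otherwise ambiguous.
Defaults encode the two deletions diagnostic for the Y copy of the
sex-linked marker: 9 bp in the CDS and 241 bp in the 3′-UTR.

**Divergence** between two coding sequences uses global alignment with
match +2, mismatch −3, gap open −5, extend −2, and reports substitutions
over aligned non-gap columns. The denominator choice means an indel does
not inflate nucleotide divergence (the 9-bp diagnostic deletion would
otherwise add ~0.5 percentage points on a 1.5-kb CDS); the
alignment-length denominator is available via `denominator="alignment"`.
Amino-acid divergence translates each input in frame 1 with the standard
genetic code — inputs are annotated CDSs, so no ORF search is performed;
trailing partial codons are dropped — and scores the BLOSUM62-aligned
proteins the same way. Indel events are maximal gap runs in either row.

**Pseudogene detection** searches each reference exon in the target
(identity threshold 0.8, chosen loose enough to tolerate the divergence at
which pseudogenes are still recognizable); the start-codon check reads the
target bases aligned to the reference's first codon and requires `ATG`.
A locus is flagged when the start codon is absent or ≥ 1 exon is missing.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, with
complete truth tables, at desk scale:

- **Genome**: 3 chromosomes of 30–50 kb, 8 non-overlapping protein-coding
  genes each (2–5 exons of 90–240 bp, introns 100–400 bp, intergenic
  300–1,500 bp, strands uniform), i.i.d. nucleotides at GC 0.42 — a
  typical teleost value. Repeats (a 9-template library spanning LINE,
  SINE, LTR, hAT, Tc1/mariner, Helitron, satellite, simple and
  unclassified families, ~15 insertions per chromosome) and gaps (rate
  2×10⁻⁴ per eligible bp, lengths 50–500 bp) are planted by overwriting
  intergenic/intronic sequence, so planned coordinates never shift and
  coding sequence stays gap-free — mirroring a long-read assembly whose
  gaps sit in repeat-rich non-coding regions. A fragment-and-rescaffold
  step breaks the assembly at N-free positions (5 breaks, ≥ 1 kb contigs)
  and rejoins with N-runs, conserving length by construction.
- **Sex region**: an X contig carrying a marker (1.5-kb CDS + 600-bp
  3′-UTR) and 20 flanking gene CDSs (0.3–1.5 kb); a Y contig derived from
  it with per-gene substitutions (marker 1.6%, background genes 0.2% —
  the magnitudes observed for gametologs in a young nonrecombining
  region), the two diagnostic deletions, and a 2-kb satellite expansion
  (a scaled-down stand-in for the multi-Mb satellite blocks real Y
  fragments carry).
- **Homologous gene sets**: a second genome cloned gene-by-gene at 3%
  substitution divergence onto renamed, permuted chromosomes, giving known
  gene and chromosome homolog maps for the RBH/synteny path.

One `numpy` generator seeded once drives each simulation; sub-steps draw
in a fixed order (plan, sequence, repeats, gaps) so identical
configurations produce byte-identical artifacts.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: base composition beyond GC content (no
higher-order dependence, no isochores), repeat nesting and decay, gene
structure realism (no UTR exons, no alternative isoforms, no overlapping
or nested genes), sequencing or assembly error, collinearity breaks other
than whole-chromosome renaming, and selection on coding sequence (planted
substitutions are frame-agnostic, so synthetic amino-acid divergence runs
~2.2× nucleotide divergence, whereas purifying selection in real genes
pushes the ratio down). Tests against this generator validate the
*measurement machinery* — that the pipeline recovers exactly what was
planted — not the biological realism of any particular value.

## Problem sizes

The default test and acceptance runs use the scales above (kb-scale
chromosomes, 100 diploid replicates for haplotype calling, 20 genomes for
gap-context validation, 1.5-kb CDSs for rate recovery); these sizes give
binomial standard errors comfortably inside the asserted bounds while the
full suite completes in about a minute. The same code paths take
chromosome-scale FASTA/GFF3/`.out` inputs unchanged; the full-scale checks
against a published reference assembly run whenever that dataset is placed
under `data/full_scale/`.

## Known limitations

- The greedy homology rule, as discussed, is not a maximum-weight matching.
- Marker search is exact-seed based: a marker with no exact 15-mer match
  to its true copy (≳ 7% uniform divergence) can be missed; lower `k`
  before trusting an empty result at higher divergence.
- Divergence is substitution-based; no multiple-hit correction is applied,
  so values are underestimates at divergences where repeat substitutions
  become likely (irrelevant below ~5%).
- The RepeatMasker category table treats each `.out` row as one element;
  RepeatMasker's own summary applies fragment-joining heuristics, so
  element counts (not masked fractions) can differ from `buildSummary`
  output on the same file.
- X/Y calling assumes the diagnostic features are fixed differences; a
  polymorphic deletion segregating within a haplotype would mislead it.
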
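# Methods

`flcdnakit` reconstructs, as a tested library, the analysis stages of a
classical full-length cDNA (FL-cDNA) sequencing project in a GC-rich grass
— the setting where a large collection of 5'-sequenced EST reads and fully
sequenced cDNA clones must be characterized *without* a reference genome.
This note records the models, the operational definitions chosen where the
procedure is genuinely open, the numerical conventions, and what the
synthetic-data closures do and do not demonstrate.

## Sequence model and alignment engine

All stages consume one pairwise alignment engine. Local alignment is
exact affine-gap Smith–Waterman, delegated to `Bio.Align.PairwiseAligner`
(C implementation); we deliberately chose exact DP over a seeded banded
heuristic because at desk scale (10³–10⁴ sequences of ~1 kb) exactness is
affordable, and every identity-threshold rule downstream then inherits a
well-defined optimum. k-mer seeding survives only as a candidate-pair
prefilter (`kmer_candidate_pairs`), which changes what gets aligned but
never the result of an alignment. An ungapped mode (best-scoring diagonal
segment, Kadane per diagonal) stands in for an ungapped BLASTN search in
EST-to-cDNA assignment.

Scoring: match +1, mismatch −2, gap −5 to open plus −2 per column (the
first gap column costs −7). `N` never matches anything, including `N`,
and the identity denominator is *all* alignment columns, gaps included —
both conservative choices for ≥99%-identity rules. Ties between
co-optimal alignments resolve to the engine's deterministic first result.
Isoform-pair comparison uses a long-gap-tolerant variant (open −10,
extend −0.5) so a single local alignment bridges a retained intron of a
couple hundred nt instead of reporting one flank.

## Clustering and redundancy

EST reads are clustered by single-linkage transitive closure of the
relation "some 80-column window of the local alignment has >95% identity"
(operationally ≥77/80 matching columns; gap columns count against). We
read the 80-base rule as a *windowed* identity requirement, the TGICL
convention; no consensus is called because contigs are used only for
representative picking and isoform mining. Redundancy filtering of fully
sequenced transcripts is greedy longest-first: a transcript is dropped if
it aligns at ≥99% identity over ≥90% of the shorter sequence to one
already retained. The 90% coverage floor is our addition — without it a
single shared domain could collapse distinct genes — and the filter is
idempotent by construction.

## ORFs, composition, microsatellites

ORF search scans the three *forward* frames only (FL-cDNA clones are
directional); the longest ATG-initiated ORF wins, ties to the 5'-most
start, and ORFs running off the 3' end are kept but flagged partial.
"Longer than 100 aa" is a strict inequality. GC summaries are
per-sequence means averaged over sequences (pooled-base means would
weight long transcripts more; the choice is logged in the summary
object), with GC1/2/3 computed over ORF codons including the stop.

SSR detection reports maximal perfect tandem repeats of primitive 1–6 nt
motifs at MISA-convention thresholds (mono ≥10, di ≥6, tri–hexa ≥5
units). Motifs are canonicalized to their lexicographically minimal
rotation; reverse-complement folding (CCG with CGG) is available behind a
flag but off by default. No compound/interrupted-repeat merging. Hits are
localized to 5'UTR/ORF/3'UTR by interval midpoint, with signed distance
from the first base of the start codon; the positional histogram uses
30-nt bins from 150 nt upstream, matching the window in which UTR
repeats are usually profiled.

## Genome-free alternative splicing

Two isoforms of one gene, compared as mature transcripts, differ by indel
blocks or by terminal-overlap geometry. A candidate pair must come from
the same cluster and show >99% identity over ≥100 columns *after* blocks
of ≥30 nt (the minimum length we accept as an intron; shorter indels are
treated as artifacts) are excised — computing identity over the raw
alignment would let a retained 218-nt intron disqualify a genuine pair.

Each AS-sized block is tested against the GT-AG rule, sliding its
register across equal flanking bases (the standard intron-placement
ambiguity) before rejecting. Event types, as this package defines them:

| type    | operational geometry |
|---------|----------------------|
| IntronR | one retained block, GT..AG (GC..AG accepted only when GT-AG fails at that locus) |
| AltP    | both transcripts carry a GT/GC..AG block, at different positions |
| AltD    | block starts GT at some register, never ends AG (donor side only) |
| AltA    | block ends AG, never starts GT/GC (acceptor side only) |
| ExonS   | internal block with no splice dinucleotides at any register (cassette exon — its introns are invisible in mRNA) |
| ExonO   | no internal block; dovetail terminal overlap ≥100 columns with ≥30 nt unshared overhangs on opposite ends |

The AltP and ExonO geometries are explicit stand-ins — the published
type inventory for these two classes exists only as a figure — and
results for them should be read as definitions of this package, not of
the original procedure. Pairs with several blocks emit several events
(isoform groups can show more than one pattern).

## Antisense pairs

A cis-NAT pair is two distinct transcripts with a gap-free
reverse-complement overlap of ≥50 nt and at most 1 mismatch ("fewer than
2", read literally; gaps are not permitted because the rule never
mentions them). Only the longest qualifying window per pair is reported.
The 25-mer prefilter is lossless: any 50-nt window with ≤1 mismatch
contains an exact 25-mer.

## Homology, orthology, partition

Nucleotide homologs: local identity >75% covering >50% of the query.
Protein homologs: the query's ORF translation vs the subject's predicted
peptide at >60% identity over ≥50 aligned aa. E-value ranking is
replaced by alignment-score ranking throughout — deterministic and
database-size independent. Ortholog picking is a three-step
reciprocal-best procedure: top-3 subjects by score, subject ORFs
re-predicted, peptides aligned, unique best identity kept, and the
reciprocal search must return the query; any tie yields no call. The
four-way shared/unique partition is (anchor ∧ all-others, anchor only,
no-anchor ∧ all-others, neither) — exhaustive and mutually exclusive,
which the published three-number breakdown is not quite.

## Ka/Ks, the clock, and duplication dating

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor
correction, written in-house (it is the analytical core of the package):
per-position synonymous-site fractions averaged over both sequences,
multi-hit codons averaged with equal weight over stop-free minimal
pathways (all pathways if none is stop-free), mutations *to* stop codons
counted as nonsynonymous, and d = −(3/4)ln(1 − (4/3)p) with p ≥ 0.75
flagged saturated. The implementation agrees to machine precision with
Biopython's independent NG86 (`cal_dn_ds`) and with a test-local
enumeration oracle. Codon alignment is peptide-guided (global BLOSUM62
alignment back-threaded to codons; gap columns and N-containing codons
excluded). Ages follow T = Ks/2r with r = 6.5×10⁻⁹ synonymous
substitutions/site/year, the standard grass rate.

`mutate_to_ks` is the generative inverse: codon-aware single-base
substitutions restricted to synonymous moves (so NG86 recovery is
unbiased), re-measuring Ks after every accepted move and stopping at the
first value ≥ target; the overshoot is at most one substitution's worth
(~1/S), well inside the ±10% recovery tolerance. Nonsynonymous moves are
added the same way when a Ka/Ks ratio is requested. Targets implying
ps ≥ 0.749 are rejected as beyond JC saturation.

EST-cluster duplication dating: reads are assigned to their
best-matching cDNA by ungapped alignment, stacked into a
reference-anchored matrix (reads carry substitution errors only, so no
MSA machinery is needed), and columns are retained as polymorphic only
when at least two alleles each have ≥2 supporting reads. Reads covering
all retained columns are grouped into haplotypes by single linkage on
Hamming distance with a threshold of half the retained columns — exact
vector matching is too brittle, because at realistic error rates a
shared sequencing error occasionally survives the ≥2-support rule and
would otherwise shatter a haplotype. Clusters qualify only with ≥6
members and reads spanning the whole predicted coding region; exactly
two haplotypes yield per-column majority consensuses whose CDS Ks is
converted to T and binned at 5 My over 0–50 My.

## Phylogeny

Distances are Jukes–Cantor over mutually ungapped columns (≥100 shared
columns required per pair; the model choice is ours, stated, and branch
lengths are therefore not expected to match any particular published
tree). NJ is Saitou–Nei with deterministic tie-breaking by taxon order;
negative branch estimates are clamped to zero with the deficit moved to
the sister edge. Bootstrap is classical column resampling; support is
the percentage of replicates containing each original bipartition.
Outgroup rooting splits the outgroup's edge at its midpoint. The NJ
implementation is cross-checked against scikit-bio's on additive
matrices.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions of a grass FL-cDNA
project: mean transcript length 1,092 nt; GC3 0.692 with 5'UTR/3'UTR GC
0.568/0.423; ORFs >100 aa; retained introns normal(218, 60) truncated at
60 nt, with 6/138 of the GT-AG class replaced by GC-AG; antisense
overlaps normal(467, 150) truncated to [73, 960]; EST depth a
zero-truncated negative binomial (r = 0.35) whose truncated mean is
exactly 8 (the raw mean is solved by bisection), read lengths
normal(550, 80) truncated to [100, transcript]; AS/NAT fractions
304/10608 and 25/10608, with AS types proportional to 120:18:92:29:15:14
(the split of the pooled GT-AG classes between IntronR and AltP is not
published; 18 AltP is our assumption). EST length and error profiles
(1% substitutions) are engineering defaults — no published values exist
for them.

GC3 is targeted by sampling each codon's third-base class as
Bernoulli(GC3) and drawing uniformly among sense codons within the
class, which hits the target in expectation without constraining the
amino-acid composition. Event roles (AS isoform, NAT partner, duplicate)
are assigned to disjoint gene subsets, and every random segment is
scrubbed so that no *unplanted* event passes the detection thresholds:
UTRs are rejected-resampled until SSR-free (5'UTRs additionally
ATG-free, so the planted ORF is provably the longest), AS blocks are
resampled until their slid-register splice-site status is exactly the
intended one, and whole derived transcripts are rescanned so
junction-spanning repeats cannot appear. This makes the generator a
closed world in which precision/recall closures are exact.

What passing closures therefore shows: the detectors implement their
stated rules exactly, and estimator biases are below the stated
tolerances. What they do not show: behaviour on real Sanger data with
indel errors, chimeric clones, vector contamination, paralogous
near-identical families, or compositional heterogeneity — none of which
the generator produces (the first three are explicit non-goals).

AS blocks are inserted with ≥200 nt flanks; the long-gap scoring bridges
a retained intron only when each flank contributes more score than the
gap costs, so isoforms of very short transcripts (flanks ≲ 150 nt) would
be under-detected. This is a stated operating range, matching the
transcript lengths the generator produces.

## Problem sizes and reproducibility

Test and acceptance runs use deliberately desk-scale problems chosen to
keep the full suite in a few minutes while leaving sampling error well
inside each tolerance: composition closures at 120–150 genes, detector
closures at 30–60 genes, Ks recovery at 100 replicates of a 999-nt CDS,
duplication dating at 20 replicates × 50 clusters, bootstrap at 10 taxa
× 5,000 columns × 100 replicates. The duplication-dating replicate
simulates an age of 12.5 My (Ks 0.1625), the centre of a 5-My histogram
bin: a boundary age (10 or 15 My) would make the binned mode of an
unbiased estimator a coin flip by construction, which tests the binning
rather than the recovery. Every stochastic path flows from one
`numpy.random.Generator`; identical config and seed reproduce outputs
byte for byte, and `scripts/acceptance.py` derives all its seeds from
`--seed`.

## Known limitations

* AS classification is pairwise; it does not build per-gene isoform
  graphs or reconcile conflicting events across a cluster.
* GC-AG introns are accepted only where GT-AG fails, so a GT..AG
  register always outranks a GC..AG one at the same locus.
* The duplication pipeline assumes substitution-only read errors; indel
  errors would require gapped stacking.
* The homolog/ortholog machinery ranks by score, not E-value; hit lists
  can differ from BLAST-based ones near the thresholds.
* NJ branch lengths depend on the JC distance choice; only topology and
  support are treated as meaningful outputs.
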
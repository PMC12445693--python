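# Methods

This note records the models, parameter choices and numerical decisions
behind `fldseg`, and what the synthetic benchmarks do and do not show.

## Coordinate and record conventions

All internal coordinates are 0-based half-open; conversion to 1-based
inclusive happens only when writing GFF3. Alignment identity is defined
as matched bases over aligned read bases including insertions, derived
from the SAM NM tag (reconstructed from MD plus CIGAR insertions when NM
is absent, unknown otherwise); N bases count as mismatches. The indel
statistic is the total number of inserted plus deleted bases. These
conventions make the mapped-identity ≥ 0.97 / ≤ 3-indel filters
well-defined.

## Terminal completeness

For every alignment, a soft-clipped suffix beginning with the adaptor
(≤1 mismatch over its first `min(len, 10)` bases) records a 3′-extremity
event at `ref_end − 1`; a clipped prefix ending with the
reverse-complemented adaptor records a 5′ event at `ref_start`. The two
strands of the dsRNA need no special casing: an adaptor on the minus
strand's 3′ end surfaces, after mapping, as a reverse-complemented
adaptor clip at the reference left edge, i.e. evidence for the plus
strand 5′ terminus.

Internal breakpoints are adaptor-ligated too, so presence of junction
reads alone cannot establish a terminus. The caller estimates the
background junction rate λ per window-sized bin from the middle half of
the contig (j5+j3 pooled, floored at one event per window). A terminal
window count k is:

* **incomplete** if it is consistent with background
  (`P(Poisson(λ) ≥ k) ≥ α`, α = 10⁻³) or below `min_events` (3);
* **ambiguous** if significant but less than `enrich` (5.0) × λ;
* **complete** otherwise.

The explicit significance gate matters: at 50× coverage with ~1.5-kb
fragments the background is ≈2 events per 50-nt window, so a raw
3-event floor would mislabel truncated ends as ambiguous in roughly a
third of runs. With the Poisson gate, a true terminus (≈60 junction
events at ≥20× coverage, every molecule copy ending there) is called
complete and a truncated end incomplete in >99% of simulated runs.
Peak positions are the argmax inside the terminal window, ties broken
toward the contig end because assemblers occasionally overshoot termini
by a few bases. `window`, `min_events`, `enrich` and `alpha` are all
exposed; none of them is a published value — the published criteria are
qualitative.

## Terminal-conservation grouping

Signatures are the literal first/last `W` = 30 nt of each full-length
segment. Identity per terminus is the best ungapped match over relative
offsets in ±5 nt with overhangs excluded from the denominator; two
segments link when **both** termini reach `min_id` = 0.8, and
single-linkage components form genome sets. Random 30-mers share ≈25%
identity (measured 0.246 over 10⁴ pairs), so 0.8 is far outside the
null while tolerating sequencing/assembly noise at cognate termini. The
AND over both termini suppresses chance 5′-only matches; single linkage
reflects that segments may come from a virus population rather than one
clone. Reverse-complement orientation rescue is not attempted: upstream
dsRNA assemblies arrive in one orientation, and a flip test would only
mask upstream orientation errors silently.

## ORF, SD and transmembrane annotation

The ORF scanner reports, per stop-to-stop region in all six frames, the
most upstream permitted start (ATG/GTG/TTG) whose product reaches
`min_aa` = 60 — below the smallest real protein expected (~80 aa) so
nothing is missed. Open frames running off a contig end are not
reported: their extent is unknowable. Translation uses the bacterial
table (11) with alternative starts rendered as Met.

SD detection scans the window `[start − (15+6), start − 3)` on the
coding strand for the longest contiguous substring of the `AGGAGG`
consensus (≥4 nt), preferring spacers near the 8-nt optimum. These are
standard prokaryotic parameters; the source observations are
qualitative ("typical bacterial-type RBS").

Transmembrane flags use mean Kyte–Doolittle hydropathy over 19-residue
windows at threshold 1.6, merging overlapping qualifying windows. This
is a hydropathy surrogate, not a topology model, and every output labels
it `method=hydropathy_surrogate` so the calls are not conflated with
dedicated TM predictors.

## UTR characterization

Stop-codon maps cover all six frames, with reverse-frame positions
reported as the forward coordinate of the codon's first base so one
coordinate system serves all plots. Composition uses overlapping
trinucleotide frequencies (N-containing windows excluded from numerator
and denominator) compared by Euclidean distance — simple, symmetric,
and sufficient to separate codon-driven from non-coding composition.
Conserved-region links compare every query window (100 nt, step 10)
against all same-length windows of the partner, ungapped, keeping hits
above 68% identity and merging them along diagonals into maximal links.
Ungapped windows keep the search deterministic and O(n·m/step); random
100-mers share ≈25% identity, so 0.68 is a conservative link threshold.

## Abundance

Contigs are clustered greedily longest-first; a contig joins the first
representative reaching 97% identity, computed by edlib semi-global
alignment covering the whole shorter sequence (a sampled-k-mer
prefilter skips hopeless pairs at thresholds ≥0.9). "Identity over the
full shorter sequence" is this package's operational reading of
"clustered at 97% similarity"; the coverage requirement stops short
fragments from absorbing into unrelated long contigs. Fragments failing
identity ≥0.97 or indels ≤3 are discarded; multi-mapped fragments go to
the best-identity hit with ties to the longest representative — a
deterministic rule, documented because mapper-internal ambiguity
handling is generally not. FPKM follows the standard formula; the
cleaned-read total is an input, not recomputed. Composition pooling
folds taxa under 2% of summed FPKM into "other dsRNA"/"other ssRNA" by
class, with unclassified contigs under "others".

## Consensus expansion and trimming

Family consensuses are per-column majorities; columns above 50% gaps
yield a sentinel and are excluded from the consensus sent to the master
aligner (and therefore from the expansion). Expansion replaces each
master-row residue with its family's full original column and each
master-row gap with an all-gap block, preserving the residue multiset
per family. Column homogeneity is the mean pairwise identity of non-gap
residues (∑ C(nᵣ,2) / C(n,2)); columns with <2 residues report 1.0 so
sparseness alone never triggers the homogeneity filter (the gap filter
handles it). The published trimming sentence ("more than 67% gaps and
homogeneity below 0.05") is implemented as two independent removal
filters (OR): a conjunctive reading would retain near-random low-gap
columns, defeating the purpose; a substitution-matrix homogeneity
variant was considered and left out for determinism and transparency.
Representative selection is greedy maxi-min on pairwise row identity
(identity over mutually non-gap columns), seeded with the least-similar
pair, ties to earliest row — deterministic for a fixed input order.

## The synthetic-data generator

The generator emulates the statistical structure the analysis relies
on, under the study conditions: bisegmented genomes (2.6–4.2 kb per
segment, 30-nt shared terminal sequences drawn per genome), ~1.5-kb
fragments (Normal(1500, 300) truncated at 200 nt), a fixed 20-nt
adaptor on every fragment 3′ end on both strands, 300-nt reads taken
from fragment ends (the 3′-end read crosses the ligation junction),
50× default coverage, 0.2% substitution errors, a long 1.5-kb 5′UTR on
60% of RNA1 segments, and SD motifs on 90% of ORFs. Coding sequence is
sampled from a fixed nonuniform codon-usage table; noncoding regions
come from an order-2 Markov chain whose stationary trinucleotide
composition is AT-rich with stop-trinucleotides boosted — this both
creates the coding/noncoding composition contrast and keeps noncoding
frames stop-dense. The adaptor is an arbitrary fixed sequence because
the real laboratory oligo is unpublished.

Random coding sequence inevitably contains incidental ≥60-aa open
frames on shifted and antisense frames. Because the generator's
contract is "the scanner recovers exactly the designed ORFs", these are
removed by a repair pass: each spurious ORF is destroyed by rewriting
its start codon or planting an early in-frame stop, using only free
noncoding bases and synonymous recoding of designed codons (designed
proteins are preserved exactly; SD windows are frozen). A last-resort
synonymous reshuffle of the overlapped codons handles the rare cases
with no single admissible edit.

Alignments for simulated reads are produced by a truth-based projector:
each read is placed at its generating coordinates, overhangs beyond the
contig (including adaptor bases) become soft clips, and identity is
recomputed from the actual bases. This isolates the analysis from
mapper idiosyncrasies; the SAM reader/writer round-trip is tested
separately, and external SAM input follows the same record model.

**What passing these benchmarks does not show:** the generator has no
assembly chimeras, no RT/PCR or strand bias, no indel errors, no
quality-score structure, flat coverage within a molecule, and genomes
whose termini are either identical (cognate) or unrelated (random) with
nothing in between. Real libraries will degrade terminal calling and
grouping in ways these tests cannot measure; the published headline
counts (hundreds of clustered RdRP contigs, per-sample abundance
fractions) depend on raw ocean libraries and external HMM/BLAST
databases and are out of desk-scale reach.

## Problem sizes used in the shipped checks

The acceptance surface simulates 10 bisegmented genomes at 50× coverage
and 0.2% errors; the test suite evaluates 100 seeded replicates
(~1,100 terminus calls per replicate set) and the acceptance script 25
replicates, each with two 200-nt 5′-truncation negative controls, plus
10 replicates × 3 genomes for the UTR diagnostics. These sizes give
binomial noise well under the 95% accuracy margin being asserted.
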
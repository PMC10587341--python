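# Methods

`immloci` re-implements, as a tested pipeline, the post-assembly computations
used to characterise the immune loci of a long-read cattle genome assembly:
IG/TR gene-segment annotation under IMGT-style criteria, locus-organization
formula synthesis, assembly QC (N50, gap census, QV, telomeres, satDNA),
two-assembly gap closure and scaffold placement, read-backed MHC haplotype
phasing with transcript validation, and full-length V(D)J repertoire
profiling.  Every stage is exercised against synthetic data with planted
ground truth; this note records the models, parameters and numerical choices.

## Alignment engine

All stages share one k-mer-seeded, affine-gap local aligner
(`immloci.align`), replacing the external mappers a production pipeline
would call.  Scoring defaults are match +2, mismatch −4, gap open −4, gap
extend −2 (conventional short-segment presets), seed k = 13.  Percent
identity is residue matches divided by alignment block length (matches +
mismatches + gap columns) × 100 — the ratio a PAF row encodes — because the
thresholds used downstream (">90%", ">80%", "≥95%") need a single fixed
denominator.  Strict vs inclusive comparisons follow the wording of each
rule: ">90%", ">50%" and ">80%" are strict, "minimum of 95%" is inclusive.

The dynamic program is vectorised row-wise in numpy.  The within-row
horizontal-gap state is computed in closed form by a running-max scan
(`F[j] = ext·j + max_{k<j}(H[k] + open − ext·(k+1))`), which is exact
because reopening a gap from a gap-derived cell can never beat extending
when `gap_open ≤ gap_extend` on the penalty scale.  An optional band
restricts each row to a window around a given diagonal; `map_query` chooses
the band from the seed-cluster diagonal spread.  Banding is exact whenever
the optimal path stays inside the band, and `band ≥ max sequence length`
reproduces the full DP (property-tested against a plain-Python oracle).
Tie-breaks are fixed: diagonal over vertical over horizontal moves, and the
first maximal cell in row-major order, so results are deterministic.

## Synthetic data

The generator (`immloci.simulate`) is first-class, seeded code; identical
seed and spec give byte-identical output.

* **Spacer DNA** is i.i.d. over ACGT at GC 0.42 (cattle-like); at that
  composition a 60-bp flank produces a spurious RSS above threshold in
  well under 5% of windows (tested empirically).
* **Segment libraries**: V entries are ATG-initiated, stop-free ORFs of
  258–318 bp with cysteine codons at IMGT-like positions (1st-CYS at codon
  22, 2nd-CYS three codons from the 3' end, recorded per entry); J entries
  carry an in-frame F/W-G-X-G motif at a recorded codon; D entries are
  16–28 bp (long enough for 13-mer seeding); C entries are 300–420 bp.
* **RSS planting**: heptamer `CACAGTG`, nonamer `ACAAAAACC`; V spacers are
  23 bp for heavy-type loci (IGH/TRB/TRD) and 12 bp otherwise, D segments
  carry 12-bp spacers on both flanks and J segments 23-bp 5' spacers
  (canonical 12/23 pairing; all configurable per locus spec).
* **Defects**: `stop_codon` rewrites an internal codon to a stop,
  `frameshift` deletes one base mid-segment (both truth-labelled P);
  `rss_mutation` changes 3 heptamer + 4 nonamer positions, dropping the
  consensus score to ≈0.56 (truth ORF).
* **Diploid region / long reads**: haplotype 2 differs from haplotype 1 by
  Binomial(length, density) substitutions; reads alternate haplotypes,
  start uniformly, have exponential (geometric-tail) lengths truncated at
  the region end (truncating instead of squeezing starts keeps interior
  coverage at the requested depth under the heavy-tailed length law), and
  carry i.i.d. substitution errors.  No homopolymer or indel error model
  is attempted.
* **Transcripts**: trimmed V + N + (D + N) + trimmed J + C with trims ≤ 6,
  N-region lengths uniform on [0, 6] by default.  A `productive_fraction`
  (default 0.95) of transcripts is forced in frame and stop-free through
  the J motif, emulating the selection acting on an expressed PBMC
  repertoire; the remainder recombine blindly.

What the generator does **not** emulate: somatic hypermutation, allelic
series of near-identical segments, ONT homopolymer error structure, real
intergenic repeat content, introns (so the splice-site branch of the
functionality cascade is an inert extension point).  Passing tests
demonstrate that the algorithms recover what was planted under these
idealised conditions; they do not certify performance on real assemblies.

## Locus annotation

Library entries are mapped with `map_query`; hits need identity ≥ 80% and
query coverage ≥ 90% (config keys).  Overlapping same-type hits merge to
the best score (ties to the smaller start).  Locus strand is taken by
majority over hits and minus-strand loci are reported in locus orientation.

**RSS detection** scans a 60-bp flank (3' of V, 5' of J, both for D),
oriented reading away from the segment, for heptamer/spacer/nonamer
placements with spacer 12 or 23 ± 1.  The score is the mean of heptamer and
nonamer consensus-match fractions, with per-motif gates of ≥ 5/7 and ≥ 6/9:
a single heptamer change (score ≈ 0.93) is still detected, while the
mean-score threshold (default 0.7) alone would admit far too many spurious
placements on random flanks.  Flanks truncated below 28 bp by a contig end
yield no call, with a warning.

**Functionality cascade** (IMGT-style): (1) V lacking the ATG start, with
an in-frame stop, or with a frameshifting indel relative to its library
entry → P; (2) otherwise missing/low-scoring RSS (or, where intron
boundaries were annotated, non-canonical splice dinucleotides) → ORF; (3)
otherwise F.  D segments are judged on their RSS flanks only (too short
for a meaningful ORF test); J segments additionally require the F/W-G-X-G
motif.  `F ⟺ no defect flags` and `P ⟺ a coding defect flag` are enforced
as type invariants.

**Formula synthesis** run-length-encodes the segment-type sequence and then
searches greedily from the left for tandem cassettes: the repeating unit of
RLE tokens with ≥ 2 contiguous copies that maximises expanded coverage,
allowing per-copy count variation in at most one element (rendered `6/7`).
On equal coverage the smallest unit wins — six `J-C` doublets, not three
`J-C-J-C` quadruplets.  All-singleton units render as `(IGLJ-IGLC)6`,
mixed units as `[TRBD-(TRBJ)6/7-TRBC]3`; single segments render their
name.  The structure object stores per-copy counts, so expansion is exact;
a bare formula string with `6/7` cannot encode the per-copy order and its
string-level expansion cycles the printed counts.

## Assembly QC

N50 is the standard cumulative-descending definition (property-tested
against a scan over all candidate lengths).  QV = −10·log₁₀(homozygous
variant events / genome size), counting SNP and indel *events*; this
reproduces the published Q51 from 10,813 + 10,738 events over 2.71 Gb.
The published per-event indel rate (0.0008%) is not reproducible from those
inputs (10,738/2.71 Gb = 0.0004%), so only the SNP rate and combined QV are
checked.  Zero errors return a configurable cap (Q99).

The tandem-repeat finder is a purpose-built simplification, not a TRF
clone: k-mer distance voting (k = 8, ≥ 4 votes) proposes periods; the
self-match profile `seq[i] == seq[i+p]`, smoothed over one period, defines
candidate arrays; a per-phase majority consensus scores purity and trims
ragged edges.  Defaults: copies ≥ 3, purity ≥ 85%, smaller periods claim
overlapping harmonics first.  Telomeres are arrays whose canonical rotation
matches TTAGGG (either strand), touching a sequence end within 1,000 bp and
spanning ≥ 15 kb.  satDNA families are assigned by aligning the consensus
(all rotations for periods ≤ 64) against the family database at strict
> 80% identity over ≥ 90% of the unit, merging adjacent same-family calls
with copy numbers summed.

## Gap closure and scaffold placement

Gap flanks (default 10 kb, excluding N, truncated at contig ends and
adjacent gaps) are mapped onto the new assembly.  "Within one contig" is
operationalised as: both flanks above strict 90% identity, same target,
same strand, right flank downstream of left, span ≥ 0 and ≤ 10 Mb (the cap
rejects spurious distant hits).  Different contigs → conflicting; a missing
or sub-threshold flank → unresolved.  Scaffolds are split at their N-runs;
qualifying pieces (identity > 90% over ≥ 100 aligned bp — the length gate
keeps chance k-mer hits from promoting junk) must agree on one contig in
consistent order and strand, and the scaffold is placed when their matching
bases exceed 50% of its non-N length ("alignment identity" for scaffolds is
read as coverage × identity; both knobs are config keys).  Gaps planted
inside tandem-repeat arrays have repeat-only flanks and are legitimately
reported conflicting — the analysis keeps telomere/satDNA arrays on a
dedicated chromosome for that reason.

## MHC phasing and validation

Het SNPs are called from the long-read pileup at depth ≥ 10 with both
allele fractions ≥ 0.25; tri-allelic sites and sites where neither frequent
allele matches the reference are skipped with warnings.  The read-allele
matrix links columns into blocks via shared reads; each block is phased
under the weighted minimum-error-correction objective.  Blocks whose
active-read count never exceeds 15 are solved exactly by dynamic
programming over columns (state = bipartition of active reads; verified
against exhaustive bipartition search); larger blocks use a greedy
start-ordered partitioner whose reported cost is still the exact MEC cost
of the returned bipartition.  Haplotype 1 is by convention allele 0 at the
block's first column, and hap1 is the complement of hap0 at every column.
Reads join the haplotype minimising weighted mismatches; exact ties stay
unassigned.  Haplotigs are reference-guided weighted-majority consensus
(uncovered positions fall back to the reference), not de novo assemblies —
sufficient to test the phasing contract at desk scale.  MHC validation maps
gene alleles to haplotigs (identity > 80%), transcripts to genes, keeps a
transcript iff it aligns to a candidate locus at ≥ 95% identity over ≥ 90%
of its length, and validates a locus supported by ≥ 2 credible transcripts
("multiple" operationalised as 2, configurable).

## Repertoire profiling

Candidate segments seed against a per-transcript 11-mer index (short enough
that 5'-trimmed J segments still seed) and extend by banded alignment; best
V fixes the locus, best same-locus J downstream of the V, best C downstream
of the J.  D calls (IGH/TRB/TRD only) require ≥ 8 consecutive exactly
matching bases between the V and J ends — alignment scores are unstable for
segments this short, run-length matching is deterministic.  CDR3 spans the
library-annotated 2nd-CYS codon through the codon before the J motif;
productive = junction in frame and stop-free from V start through J end.
Chimeric V/J across loci is rejected by construction.  The ultralong-CDR3
threshold defaults to 40 aa (no printed cutoff exists for the cattle
ultralong class).  Transcripts whose best V score falls below 100 (half the
score of a ~25% matching V) are left unassigned.

## Problem sizes

The shipped analyses and acceptance script use loci of 20–40 segments on
10–45 kb chromosomes, 80–100 kb diploid regions at 30× with 15–20 kb reads,
6 gaps + 3 excised scaffolds per degraded assembly, and n = 2,000
transcripts — sizes at which every planted event is individually checkable
while each stage completes in seconds to ~1 minute.

## Known limitations

* The functionality cascade codifies standard IMGT definitions; criteria
  that require human judgment in the original workflow (novel-segment
  naming, adjudication between annotators) are out of scope.
* The tandem-repeat finder targets clean arrays; highly diverged or nested
  repeats will fragment.
* The greedy wMEC fallback is not guaranteed optimal; its output cost is
  exact for the bipartition it returns.
* Identity thresholds assume the PAF-style denominator; tools defining
  identity over matched columns only will disagree near gaps.
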
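# immloci

Immune-locus annotation and assembly-QC toolkit for long-read genome
projects, built around the cattle immune genome: the immunoglobulin (IGH,
IGK, IGL) and T-cell receptor (TRA, TRB, TRD, TRG) loci, the MHC (BoLA)
region, and the full-length V(D)J transcript repertoire.

These regions are the hardest parts of a mammalian genome to assemble and
annotate — hundreds of near-identical V/D/J/C gene segments, tandem
cassettes, and a hyperpolymorphic MHC — and the computations around them
(segment search, recombination-signal-sequence detection, IMGT functionality
calls, gap closure between assembly versions, read-backed phasing, repertoire
profiling) are usually one-off scripts.  `immloci` packages them as a tested
library with a synthetic-data generator that plants ground truth, so every
stage can be verified end to end.

## What it computes

* **Locus annotation** (`immloci.annotate`): maps a gene-segment library
  onto an assembly, detects RSS motifs (heptamer `CACAGTG` / 12-or-23-bp
  spacer / nonamer `ACAAAAACC`), classifies each segment as functional (F),
  pseudogene (P) or open reading frame (ORF) by an IMGT-style cascade, and
  compresses each locus into an organization formula such as
  `(TRBV)152-[TRBD-(TRBJ)6/7-TRBC]3-TRBV30` or `(IGLJ-IGLC)6`.
* **Assembly QC** (`immloci.qc`): N50, N-gap census, Phred consensus
  quality QV = −10·log₁₀(errors/genome size), a tandem-repeat finder, the
  15-kb chromosome-end rule for (TTAGGG)n telomeres, and satDNA family
  assignment at strict >80% identity.
* **Two-assembly comparison** (`immloci.gapfill`): decides which gaps of an
  old assembly are closed by a new one (10-kb flanks, strict >90% identity,
  both flanks on one contig in order) and places unplaced scaffolds (>50%
  of non-N bases matching a single contig).
* **MHC phasing** (`immloci.phase`): het-SNP pileup calling, weighted
  minimum-error-correction (wMEC) phasing with an exact
  dynamic program for tractable blocks, per-haplotype consensus haplotigs,
  and transcript-based validation of MHC gene loci (≥ 2 full-length
  transcripts at ≥ 95% identity).
* **Repertoire profiling** (`immloci.repertoire`): V(D)J assignment of
  full-length transcripts, CDR3 extraction between the conserved V cysteine
  and the J F/W-G-X-G motif, productivity, V–(D)–J usage tables and
  ultralong-CDRH3 profiling.
* **Synthetic data** (`immloci.simulate`): seeded generators for all of the
  above with planted truth — ordered segments with RSS flanks and injected
  defects, tandem D-J-C cassettes, telomere/satDNA arrays, N-gap-degraded
  assemblies, diploid regions with long reads, recombined transcripts.

A shared k-mer-seeded affine-gap local aligner (`immloci.align`, exact DP
with optional banding) underlies every stage.  See `docs/methods.md` for
models, parameter defaults and limitations.

## Worked example

```python
from immloci.annotate import build_locus_structure, classify_functionality, find_segments
from immloci.simulate import Cassette, DefectRates, LocusSpec, make_segment_library, plant_locus

spec = LocusSpec(
    locus="TRB",
    n_v=15,
    cassette=Cassette(elements=(("D", (1, 1, 1)), ("J", (6, 7, 6)), ("C", (1, 1, 1)))),
    defect_rates=DefectRates(stop_codon=0.25, rss_mutation=0.2),
)
library = make_segment_library(spec, seed=7)
chromosome, truth = plant_locus(library, spec, seed=17)

segments = find_segments([chromosome], library)
by_name = {e.name: e for e in library}
classified = [classify_functionality({chromosome.id: chromosome.seq}, s, by_name)
              for s in segments]
structure = build_locus_structure(classified)
print(structure.formula)
print(sum(s.functionality == "F" for s in classified), "functional of", len(classified))
```

prints

```
(TRBV)15-[TRBD-(TRBJ)6/7-TRBC]3
27 functional of 40
```

— the locus formula shows the fifteen V genes followed by the three tandem
D-J-C cassettes (six or seven J per cassette), and the functionality counts
reflect the planted defect rates (stop codons → pseudogenes, broken RSS →
ORF).  On defect-free input all segments return F at their exact planted
coordinates.

The numbered scripts under `analysis/` run the whole study at desk scale:
`01_simulate_study_data.py` generates a multi-locus genome, a degraded copy
with excised scaffolds, a diploid MHC-like region with 30× long reads, and
2,000 recombined transcripts; `02`–`06` annotate the loci, compute assembly
QC, close the gaps and place the scaffolds, phase the MHC region and
validate its genes, and profile the repertoire, each writing tables under
`results/` and printing its recovery against the planted truth.

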
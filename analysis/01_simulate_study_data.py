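#!/usr/bin/env python
"""Generate the synthetic study dataset used by the downstream analyses.

Emits, under results/simulated/: a multi-locus genome (a TRB-like locus with
three tandem D-J-C cassettes, an IGL-like locus with six J-C repeats, and a
minus-strand TRA-like locus, each with mixed planted defects), chromosome
ends carrying a telomere and a satDNA array, an N-gap-degraded "old" copy of
the genome with excised scaffolds, a diploid MHC-like region with long reads,
and a recombined IGH transcript set — all with truth tables.
"""

import json
import random
import sys
from pathlib import Path

from immloci.annotate import Cassette
from immloci.io import (
    Gff3Feature,
    SeqRecord,
    write_fasta,
    write_fastq,
    write_gff3,
    write_paf,
    write_segment_library,
    write_vcf,
)
from immloci.simulate import (
    DefectRates,
    JunctionModel,
    LocusSpec,
    degrade_assembly,
    make_diploid_region,
    make_segment_library,
    plant_chromosome_ends,
    plant_locus,
    simulate_long_reads,
    simulate_transcripts,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results/simulated")
OUT.mkdir(parents=True, exist_ok=True)

LOCUS_SPECS = {
    "TRB": LocusSpec(
        locus="TRB",
        n_v=15,
        cassette=Cassette(elements=(("D", (1, 1, 1)), ("J", (6, 7, 6)), ("C", (1, 1, 1)))),
        defect_rates=DefectRates(stop_codon=0.25, frameshift=0.1, rss_mutation=0.2),
    ),
    "IGL": LocusSpec(
        locus="IGL",
        n_v=12,
        cassette=Cassette(elements=(("J", (1,) * 6), ("C", (1,) * 6))),
        defect_rates=DefectRates(stop_codon=0.3, rss_mutation=0.1),
        spacing=900,
    ),
    "TRA": LocusSpec(
        locus="TRA", n_v=10, n_j=8, n_c=1, strand="-",
        defect_rates=DefectRates(stop_codon=0.2, frameshift=0.1),
        spacing=900,
    ),
}

chromosomes, libraries, truth_features = [], [], []
for i, (name, spec) in enumerate(LOCUS_SPECS.items()):
    library = make_segment_library(spec, SEED + i)
    chromosome, truth = plant_locus(library, spec, SEED + 10 + i)
    chromosomes.append(chromosome)
    libraries.extend(library)
    truth_features.extend(
        Gff3Feature(
            interval=s.interval, source="truth", type=f"{s.seg_type}_segment", score=".",
            attributes={"ID": s.name, "functionality": s.functionality},
        )
        for s in truth.segments
    )

# a dedicated acrocentric-style chromosome carries the satDNA array and the
# q-arm telomere; gaps planted inside such repeat arrays have repeat-only
# flanks and are legitimately unresolvable, so degradation below targets the
# gene-bearing chromosomes only
base = random.Random(SEED + 19)
chr_ends, end_truth = plant_chromosome_ends(
    SeqRecord(id="chrT", seq="".join(base.choice("ACGT") for _ in range(30_000))),
    telomere_units=3_000,
    satdna_pattern="AGGTCTCCAGTGGACATTAAGGC",
    satdna_copies=150,
    seed=SEED + 20,
)

write_fasta(chromosomes + [chr_ends], OUT / "genome.fa")
write_segment_library(libraries, OUT / "library.fa", OUT / "library.tsv")
write_gff3(truth_features, OUT / "truth_segments.gff3")

old, scaffolds, gap_truth = degrade_assembly(
    chromosomes, n_gaps=6, gap_len_range=(400, 1_200), n_excised_scaffolds=3,
    seed=SEED + 30, end_margin=2_500, scaffold_len_range=(3_000, 5_000),
)
write_fasta(old, OUT / "old_assembly.fa")
write_fasta(scaffolds, OUT / "unplaced_scaffolds.fa")
(OUT / "truth_gaps.json").write_text(json.dumps({
    "gaps": [
        {"chrom": g.new_interval.seq_id, "span": len(g.new_interval)} for g in gap_truth.gaps
    ],
    "placements": [
        {"scaffold": p.scaffold_id, "chrom": p.new_interval.seq_id,
         "start": p.new_interval.start, "end": p.new_interval.end}
        for p in gap_truth.placements
    ],
}, indent=2))

hap1, hap2, truth_vcf = make_diploid_region(80_000, 1e-3, seed=SEED + 40)
reads, paf = simulate_long_reads((hap1, hap2), depth=30, mean_len=15_000,
                                 error_rate=0.02, seed=SEED + 41)
write_fasta([hap1, hap2], OUT / "mhc_haplotypes.fa")
write_fastq(reads, OUT / "mhc_reads.fq")
write_paf(paf, OUT / "mhc_reads_truth.paf")
write_vcf(truth_vcf, OUT / "mhc_truth.vcf")

igh_spec = LocusSpec(locus="IGH", n_v=10, n_d=5, n_j=5, n_c=1)
igh_library = make_segment_library(igh_spec, SEED + 50)
weights = {
    "V": {f"IGHV{i + 1}": 0.1 for i in range(10)},
    "J": {f"IGHJ{i + 1}": 0.2 for i in range(5)},
}
transcripts, tx_truth = simulate_transcripts(igh_library, weights, JunctionModel(), n=2_000, seed=SEED + 51)
write_fasta(transcripts, OUT / "transcripts.fa")
write_segment_library(igh_library, OUT / "igh_library.fa", OUT / "igh_library.tsv")
with open(OUT / "truth_transcripts.tsv", "w") as fh:
    fh.write("transcript_id\tv_name\td_name\tj_name\tc_name\tproductive\n")
    for t in tx_truth:
        fh.write(f"{t.transcript_id}\t{t.v_name}\t{t.d_name or ''}\t{t.j_name}\t{t.c_name or ''}\t{t.productive}\n")

print(f"simulated study data written to {OUT} (seed {SEED})")
print(f"  {len(chromosomes)} locus chromosomes, {len(libraries)} library segments")
print(f"  {len(gap_truth.gaps)} gaps, {len(scaffolds)} excised scaffolds")
print(f"  {len(truth_vcf)} het SNPs, {len(reads)} long reads, {len(transcripts)} transcripts")
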
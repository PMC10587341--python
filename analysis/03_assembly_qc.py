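#!/usr/bin/env python
"""Assembly QC on the simulated genome plus the published-value arithmetic.

Computes N50 and the gap census of the simulated genome, calls telomeres and
satDNA arrays, and reproduces the consensus-accuracy numbers (QV, SNP error
rate) and the gene-count table totals from the published NCBA_BosT1.0 inputs.
Writes results/qc/.
"""

from pathlib import Path

import pandas as pd

from immloci.annotate import tabulate_counts
from immloci.io import SeqRecord, read_fasta, write_bed
from immloci.qc import (
    assembly_stats,
    call_telomeres,
    classify_satdna,
    find_tandem_repeats,
)
from immloci.reported import (
    IG_LOCI,
    NCBA_BOST1_GENE_COUNTS,
    NCBA_BOST1_GENOME_SIZE,
    NCBA_BOST1_HOMO_INDELS,
    NCBA_BOST1_HOMO_SNPS,
    TR_LOCI,
)

SIM = Path("results/simulated")
OUT = Path("results/qc")
OUT.mkdir(parents=True, exist_ok=True)

genome = read_fasta(SIM / "genome.fa")
old = read_fasta(SIM / "old_assembly.fa")

stats_new = assembly_stats(genome)
stats_old = assembly_stats(old)
pd.DataFrame(
    [
        ("new", stats_new.n_sequences, stats_new.total_length, stats_new.n50, len(stats_new.gap_intervals)),
        ("old", stats_old.n_sequences, stats_old.total_length, stats_old.n50, len(stats_old.gap_intervals)),
    ],
    columns=["assembly", "n_seqs", "total_bp", "n50", "n_gaps"],
).to_csv(OUT / "assembly_stats.tsv", sep="\t", index=False)

telomeres = [c for rec in genome for c in call_telomeres(rec)]
write_bed([c.interval for c in telomeres], OUT / "telomeres.bed", names=[c.end for c in telomeres])

sat_db = [SeqRecord(id="satfam1", seq="AGGTCTCCAGTGGACATTAAGGC")]
sat_calls = []
for rec in genome:
    repeats = find_tandem_repeats(rec.seq[:20_000], max_period=100, seq_id=rec.id)
    sat_calls.extend(classify_satdna(repeats, sat_db))
write_bed([c.interval for c in sat_calls], OUT / "satdna.bed", names=[c.family for c in sat_calls])

# published-value arithmetic
from immloci.qc import error_rate_percent, estimate_qv

qv = estimate_qv(NCBA_BOST1_HOMO_SNPS + NCBA_BOST1_HOMO_INDELS, NCBA_BOST1_GENOME_SIZE)
snp_rate = error_rate_percent(NCBA_BOST1_HOMO_SNPS, NCBA_BOST1_GENOME_SIZE)
table = tabulate_counts(NCBA_BOST1_GENE_COUNTS)
table.to_csv(OUT / "published_gene_counts.tsv", sep="\t")

print(f"simulated genome: {stats_new.n_sequences} sequences, N50 {stats_new.n50:,} bp, "
      f"{len(stats_old.gap_intervals)} gaps in the degraded copy")
print(f"telomeres: {[(c.chromosome, c.end, c.length) for c in telomeres]}")
print(f"satDNA: {[(c.family, round(c.copy_number)) for c in sat_calls]}")
print(f"published inputs: QV = Q{round(qv)}, SNP error rate = {snp_rate:.1g}%")
print(f"gene-count totals: {int(table.loc[('V', 'total'), 'Sum'])} V "
      f"({int(table.loc[('V', 'F'), 'Sum'])} functional), "
      f"{int(table.loc[('Sum', 'total'), 'Sum'])} genes = "
      f"{int(sum(table.loc[('Sum', 'total'), l] for l in IG_LOCI))} IG + "
      f"{int(sum(table.loc[('Sum', 'total'), l] for l in TR_LOCI))} TR")
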
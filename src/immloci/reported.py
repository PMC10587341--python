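"""Published reference values for the NCBA_BosT1.0 cattle immune-genome
assembly, used as worked-example inputs to the aggregation and QC arithmetic.

These are inputs, not outputs: per-locus gene counts (total and F/P/ORF
functionality classes for each of V, D, J, C across the seven major IG/TR
loci), the homozygous-variant counts and genome size behind the consensus
quality value, and the full-length repertoire sequence counts.
"""

from __future__ import annotations

# counts[locus][seg_type] = {"F": f, "P": p, "ORF": orf}
NCBA_BOST1_GENE_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "IGH": {
        "V": {"F": 11, "P": 37, "ORF": 0},
        "D": {"F": 17, "P": 0, "ORF": 0},
        "J": {"F": 3, "P": 1, "ORF": 8},
        "C": {"F": 8, "P": 2, "ORF": 0},
    },
    "IGK": {
        "V": {"F": 7, "P": 19, "ORF": 2},
        "J": {"F": 1, "P": 0, "ORF": 4},
        "C": {"F": 1, "P": 0, "ORF": 0},
    },
    "IGL": {
        "V": {"F": 37, "P": 80, "ORF": 8},
        "J": {"F": 4, "P": 0, "ORF": 2},
        "C": {"F": 3, "P": 3, "ORF": 0},
    },
    "TRA": {
        "V": {"F": 148, "P": 132, "ORF": 25},
        "J": {"F": 53, "P": 2, "ORF": 5},
        "C": {"F": 1, "P": 0, "ORF": 0},
    },
    "TRB": {
        "V": {"F": 87, "P": 55, "ORF": 11},
        "D": {"F": 3, "P": 0, "ORF": 0},
        "J": {"F": 15, "P": 1, "ORF": 3},
        "C": {"F": 3, "P": 0, "ORF": 0},
    },
    "TRD": {
        "V": {"F": 48, "P": 12, "ORF": 4},
        "D": {"F": 6, "P": 0, "ORF": 3},
        "J": {"F": 3, "P": 0, "ORF": 1},
        "C": {"F": 1, "P": 0, "ORF": 0},
    },
    "TRG1": {
        "V": {"F": 13, "P": 1, "ORF": 0},
        "J": {"F": 5, "P": 0, "ORF": 0},
        "C": {"F": 4, "P": 0, "ORF": 0},
    },
    "TRG2": {
        "V": {"F": 4, "P": 0, "ORF": 0},
        "J": {"F": 3, "P": 0, "ORF": 2},
        "C": {"F": 3, "P": 0, "ORF": 0},
    },
}

IG_LOCI = ("IGH", "IGK", "IGL")
TR_LOCI = ("TRA", "TRB", "TRD", "TRG1", "TRG2")

# assembly accuracy inputs (homozygous variant calls vs 2.71 Gb genome)
NCBA_BOST1_GENOME_SIZE = 2_710_000_000
NCBA_BOST1_HOMO_SNPS = 10_813
NCBA_BOST1_HOMO_INDELS = 10_738

# full-length PBMC repertoire sequence counts
REPERTOIRE_IG_SEQUENCES = 18_493
REPERTOIRE_TR_SEQUENCES = 18_258
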
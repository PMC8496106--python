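"""Standard genetic code tables shared by the composition and simulation modules.

Internal alphabet is DNA; U in inputs is mapped to T upstream. Built from
Biopython's standard codon table rather than a hand-written copy.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))  # 61 codons
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE.values())))  # 20

# aa -> synonymous codon family
FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in AMINO_ACIDS
}

GC_ENDING: frozenset[str] = frozenset(c for c in SENSE_CODONS if c[2] in "GC")
AU_ENDING: frozenset[str] = frozenset(c for c in SENSE_CODONS if c[2] in "AT")

# Disorder-promoting residues: polar/charged amino acids statistically
# enriched in intrinsically disordered protein regions.
DISORDER_AAS: frozenset[str] = frozenset("PQESK")


def third_nt(codon: str) -> str:
    """Third (wobble) position nucleotide, RNA alphabet (A/U/G/C)."""
    nt = codon[2]
    return "U" if nt == "T" else nt


def translate_cds(cds: str) -> str:
    """Amino-acid sequence of the sense codons; stops and N-codons skipped."""
    aas = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        aa = GENETIC_CODE.get(codon)
        if aa is not None:
            aas.append(aa)
    return "".join(aas)
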
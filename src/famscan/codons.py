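"""Standard nuclear genetic code helpers shared across the package.

Only the standard code (NCBI table 1) is supported; alternative codes are
out of scope for this family, which is encoded by nuclear genes.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

#: codon -> one-letter amino acid, sense codons only
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)

#: the three stop codons of the standard code
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: the 61 sense codons, lexically sorted (used for deterministic tie-breaks)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def codons_of(seq: str) -> list[str]:
    """Split a nucleotide string into codons, dropping a trailing partial codon."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def translate(seq: str) -> str:
    """Translate a frame-0 nucleotide string; stops appear as '*'.

    Codons containing characters outside ACGT translate to 'X'.
    """
    out = []
    for codon in codons_of(seq):
        if any(b not in BASES for b in codon):
            out.append("X")
        else:
            out.append(translate_codon(codon))
    return "".join(out)
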
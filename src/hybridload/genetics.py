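"""Standard genetic-code helpers shared across modules.

The code table is taken from Biopython's standard (NCBI table 1) codon
table; stop codons translate to ``"*"``.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

_table = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = STOP
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))


def translate_codon(codon: str) -> str:
    """Translate one codon (uppercase ACGT) to a one-letter amino acid or '*'."""
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not a valid codon: {codon!r}") from None


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def codon_neighbors(codon: str):
    """Yield (offset, alt_base, mutated_codon) for all 9 single-base changes."""
    for off in range(3):
        for base in BASES:
            if base != codon[off]:
                yield off, base, codon[:off] + base + codon[off + 1 :]
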
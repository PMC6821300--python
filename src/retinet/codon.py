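"""Standard genetic code lookups, derived from Biopython's codon table."""

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

AMINO_ACID: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(AMINO_ACID))

assert len(SENSE_CODONS) == 61 and len(STOP_CODONS) == 3
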
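"""Genetic-code constants and small sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# IUPAC alphabets accepted on input (sequences are uppercased first).
IUPAC_NT = set("ACGTURYSWKMBDHVN-")
IUPAC_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")

_table = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(_table.forward_table))  # 61 codons, standard code
CODON_AA = dict(_table.forward_table)
CODON_AA.update({c: "*" for c in STOP_CODONS})
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def translate(nt: str) -> str:
    """Translate a nucleotide string (standard code); trailing partial codon dropped."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def is_unambiguous(nt: str) -> bool:
    return all(c in BASE_INDEX for c in nt)
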
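"""Mating-pheromone precursor discovery by ORF enumeration and consensus match.

Lipopeptide pheromone precursors of basidiomycete yeasts are short peptides
ending in a prenylation (CaaX) motif. Candidates are found by enumerating
ORFs on both strands and testing the precursor consensus

    M - X(15..60) - C - [ILMVST] - [ILMVST] - X - Stop

where the CaaX cysteine is anchored four residues before the terminating stop
codon and X is any residue (internal M and C allowed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._genetics import is_unambiguous, revcomp, translate
from .io import SequenceSet, write_bed

CAAX_ALIPHATIC = frozenset("ILMVST")


@dataclass
class OrfRecord:
    contig: str
    start: int  # half-open forward-strand coordinates, stop codon included
    end: int
    strand: str
    peptide: str  # stop symbol excluded

    def __post_init__(self) -> None:
        assert self.end - self.start == 3 * (len(self.peptide) + 1)


@dataclass
class MatchResult:
    match: bool
    spacer_len: Optional[int] = None
    caax: Optional[str] = None


@dataclass
class PheromoneHit(OrfRecord):
    spacer_len: int = 0
    caax: str = ""


def match_pheromone_consensus(peptide: str, min_spacer: int = 15,
                              max_spacer: int = 60) -> MatchResult:
    """Test a stop-free peptide against the precursor consensus."""
    n = len(peptide)
    if n < min_spacer + 5 or n > max_spacer + 5:
        return MatchResult(False)
    if peptide[0] != "M" or peptide[n - 4] != "C":
        return MatchResult(False)
    if peptide[n - 3] not in CAAX_ALIPHATIC or peptide[n - 2] not in CAAX_ALIPHATIC:
        return MatchResult(False)
    return MatchResult(True, spacer_len=n - 5, caax=peptide[n - 4:])


def enumerate_orfs(contig_seq: str, min_aa: int, max_aa: int,
                   contig: str = "contig") -> list[OrfRecord]:
    """All ATG-to-first-in-frame-stop ORFs on both strands with peptide
    length in [min_aa, max_aa]; every in-frame ATG upstream of a stop yields
    its own ORF. Reverse-strand ORFs are reported in forward-strand
    coordinates. ORFs containing ambiguity codes are skipped."""
    if min_aa > max_aa:
        raise ValueError("min_aa must be <= max_aa")
    out: list[OrfRecord] = []
    length = len(contig_seq)
    for strand in "+-":
        seq = contig_seq if strand == "+" else revcomp(contig_seq)
        for frame in range(3):
            pep = translate(seq[frame:])
            prev_stop = -1
            for stop_idx, aa in enumerate(pep):
                if aa != "*":
                    continue
                lo = max(prev_stop + 1, stop_idx - max_aa)
                m_idx = pep.find("M", lo, stop_idx)
                while m_idx >= 0:
                    plen = stop_idx - m_idx
                    if min_aa <= plen <= max_aa:
                        s = frame + 3 * m_idx
                        e = frame + 3 * (stop_idx + 1)
                        if is_unambiguous(seq[s:e]):
                            if strand == "+":
                                fs, fe = s, e
                            else:
                                fs, fe = length - e, length - s
                            out.append(OrfRecord(contig, fs, fe, strand,
                                                 pep[m_idx:stop_idx]))
                    m_idx = pep.find("M", m_idx + 1, stop_idx)
                prev_stop = stop_idx
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def scan_genome(assembly: SequenceSet, min_spacer: int = 15,
                max_spacer: int = 60) -> list[PheromoneHit]:
    """Scan a nucleotide assembly for pheromone-precursor candidates."""
    hits: list[PheromoneHit] = []
    for rec in assembly:
        for orf in enumerate_orfs(rec.seq, min_spacer + 5, max_spacer + 5,
                                  contig=rec.id):
            m = match_pheromone_consensus(orf.peptide, min_spacer, max_spacer)
            if m.match:
                hits.append(
                    PheromoneHit(orf.contig, orf.start, orf.end, orf.strand,
                                 orf.peptide, m.spacer_len, m.caax)
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.strand))
    return hits


def hits_to_gff3(hits: list[PheromoneHit], source: str = "fusedmat") -> str:
    lines = ["##gff-version 3"]
    for i, h in enumerate(hits, 1):
        lines.append(
            "\t".join(
                [h.contig, source, "pheromone_precursor", str(h.start + 1),
                 str(h.end), ".", h.strand, ".",
                 f"ID=mf_{i};spacer={h.spacer_len};caax={h.caax}"]
            )
        )
    return "\n".join(lines) + "\n"


def hits_to_bed(hits: list[PheromoneHit]) -> str:
    return write_bed((h.contig, h.start, h.end, f"mf_{i}")
                     for i, h in enumerate(hits, 1))
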
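"""Readers and writers for the standard formats the pipeline touches.

Internal convention: all coordinates are half-open, 0-based, on the forward
strand. GFF3 (1-based inclusive) and BED (0-based half-open) conversion
happens at the boundary of this module and nowhere else.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
from Bio import SeqIO
from gffutils.feature import feature_from_line

from ._genetics import IUPAC_AA, IUPAC_NT, revcomp, translate


class FormatError(ValueError):
    """Raised on malformed FASTA/GFF3/Newick input."""


# ---------------------------------------------------------------------------
# FASTA


@dataclass
class Record:
    id: str
    seq: str
    description: str = ""


@dataclass
class SequenceSet:
    """Ordered set of named sequences with a single alphabet (nt or aa)."""

    records: list[Record] = field(default_factory=list)
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        self._index = {r.id: r for r in self.records}
        if len(self._index) != len(self.records):
            raise FormatError("duplicate sequence ids in SequenceSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> str:
        return self._index[seq_id].seq

    def get(self, seq_id: str) -> Optional[Record]:
        return self._index.get(seq_id)

    def add(self, record: Record) -> None:
        if record.id in self._index:
            raise FormatError(f"duplicate sequence id: {record.id}")
        self.records.append(record)
        self._index[record.id] = record

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def parse_fasta(stream, alphabet: str = "nt") -> SequenceSet:
    """Parse FASTA text (or a file-like object) into a SequenceSet.

    Sequences are uppercased; IUPAC ambiguity codes are accepted and
    preserved. Duplicate ids and non-IUPAC characters are errors.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    allowed = IUPAC_NT if alphabet == "nt" else IUPAC_AA
    out = SequenceSet(alphabet=alphabet)
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise FormatError(
                    f"record {rec.id!r}: character {ch!r} at position {pos} "
                    f"is not an IUPAC {alphabet} code"
                )
        if rec.id in out:
            raise FormatError(f"duplicate sequence id: {rec.id}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.add(Record(rec.id, seq, desc))
    return out


def write_fasta(seqs: SequenceSet | Iterable[Record], width: int = 70) -> str:
    lines: list[str] = []
    for rec in seqs:
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        lines.append(header)
        for i in range(0, len(rec.seq), width):
            lines.append(rec.seq[i : i + width])
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Gene models / GFF3

MAT_ROLES = (
    "SXI1",
    "SXI2",
    "STE3",
    "MF",
    "STE11",
    "STE12",
    "STE20",
    "IKS1",
    "MYO2",
    "RPL22",
)


@dataclass
class GeneModel:
    """An annotated gene with strand-aware CDS parts (half-open 0-based)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds_parts: list[tuple[int, int]] = field(default_factory=list)
    role: Optional[str] = None
    product: str = ""

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_parts)

    @property
    def coding_complete(self) -> bool:
        return self.cds_length > 0 and self.cds_length % 3 == 0

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def cds_sequence(self, assembly: SequenceSet) -> str:
        contig_seq = assembly[self.contig]
        parts = [contig_seq[s:e] for s, e in sorted(self.cds_parts)]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def protein(self, assembly: SequenceSet) -> str:
        pep = translate(self.cds_sequence(assembly))
        return pep[:-1] if pep.endswith("*") else pep


@dataclass
class Annotation:
    genome_id: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate gene_ids in annotation")
        self.genes.sort(key=lambda g: (g.contig, g.start))
        self._index = {g.gene_id: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._index[gene_id]

    def on_contig(self, contig: str) -> list[GeneModel]:
        return [g for g in self.genes if g.contig == contig]

    def with_role(self, role: str) -> list[GeneModel]:
        return [g for g in self.genes if g.role == role]


def parse_gff3(stream, assembly: Optional[SequenceSet] = None,
               genome_id: str = "genome") -> Annotation:
    """Parse GFF3 text into an Annotation (coordinates converted to 0-based
    half-open). A ``##FASTA`` directive terminates feature parsing. CDS rows
    are grouped onto their (grand)parent gene via Parent attributes."""
    if hasattr(stream, "read"):
        stream = stream.read()
    genes: dict[str, GeneModel] = {}
    parent_of: dict[str, str] = {}  # mRNA id -> gene id
    pending_cds: list[tuple[int, str, int, int]] = []  # line no, parent, s, e
    for lineno, raw in enumerate(stream.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("##FASTA"):
            break
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"line {lineno}: expected 9 tab-separated fields")
        try:
            start_1, end_1 = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric coordinates") from exc
        if end_1 < start_1:
            raise FormatError(f"line {lineno}: end < start ({end_1} < {start_1})")
        feat = feature_from_line(line)
        if assembly is not None and feat.seqid not in assembly:
            raise FormatError(
                f"line {lineno}: feature references unknown contig {feat.seqid!r}"
            )
        attrs = feat.attributes
        start, end = start_1 - 1, end_1  # to half-open 0-based
        if feat.featuretype == "gene":
            gid = attrs.get("ID", [f"gene_{lineno}"])[0]
            if gid in genes:
                raise FormatError(f"line {lineno}: duplicate gene id {gid!r}")
            genes[gid] = GeneModel(
                gene_id=gid,
                contig=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in "+-" else "+",
                role=attrs.get("role", [None])[0],
                product=attrs.get("product", [""])[0],
            )
        elif feat.featuretype == "mRNA":
            mid = attrs.get("ID", [None])[0]
            par = attrs.get("Parent", [None])[0]
            if mid and par:
                parent_of[mid] = par
        elif feat.featuretype == "CDS":
            par = attrs.get("Parent", [None])[0]
            if par is None:
                raise FormatError(f"line {lineno}: CDS without Parent attribute")
            pending_cds.append((lineno, par, start, end))
    for lineno, par, start, end in pending_cds:
        gid = parent_of.get(par, par)
        if gid not in genes:
            raise FormatError(f"line {lineno}: CDS parent {par!r} matches no gene")
        gene = genes[gid]
        if not (gene.start <= start and end <= gene.end):
            raise FormatError(f"line {lineno}: CDS outside its gene span")
        gene.cds_parts.append((start, end))
    for gene in genes.values():
        gene.cds_parts.sort()
    return Annotation(genome_id=genome_id, genes=list(genes.values()))


def write_gff3(annotation: Annotation, source: str = "fusedmat") -> str:
    """Serialize an Annotation as GFF3 (1-based inclusive at the boundary)."""
    lines = ["##gff-version 3"]
    for gene in annotation.genes:
        attrs = [f"ID={gene.gene_id}"]
        if gene.role:
            attrs.append(f"role={gene.role}")
        if gene.product:
            attrs.append(f"product={gene.product}")
        lines.append(
            "\t".join(
                [gene.contig, source, "gene", str(gene.start + 1), str(gene.end),
                 ".", gene.strand, ".", ";".join(attrs)]
            )
        )
        mrna_id = f"{gene.gene_id}.t1"
        lines.append(
            "\t".join(
                [gene.contig, source, "mRNA", str(gene.start + 1), str(gene.end),
                 ".", gene.strand, ".", f"ID={mrna_id};Parent={gene.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(gene.cds_parts):
            lines.append(
                "\t".join(
                    [gene.contig, source, "CDS", str(s + 1), str(e),
                     ".", gene.strand, "0" if i == 0 else ".",
                     f"ID={mrna_id}.cds;Parent={mrna_id}"]
                )
            )
    return "\n".join(lines) + "\n"


def write_bed(intervals: Iterable[tuple[str, int, int, str]]) -> str:
    """(contig, start, end, name) half-open 0-based intervals to BED text."""
    return "".join(f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in intervals)


# ---------------------------------------------------------------------------
# Newick


def _format_length(x: float) -> str:
    if x == int(x):
        return f"{x:.1f}"
    return format(x, ".10g")


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a dendropy tree to Newick with branch lengths.

    Round-trips through :func:`parse_newick` preserve topology and branch
    lengths to 10 significant digits; root trifurcations are preserved.
    """

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise FormatError("unlabeled tip in tree")
            label = node.taxon.label.replace(" ", "_")
        else:
            label = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        if node.edge.length is not None and node.parent_node is not None:
            label += f":{_format_length(node.edge.length)}"
        return label

    return render(tree.seed_node) + ";"


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
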
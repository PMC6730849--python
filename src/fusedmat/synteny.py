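"""Ortholog-anchor synteny between MAT regions: inversion blocks and the
1-kb sliding-window similarity track.

Anchors are reciprocal-best protein pairs between two annotated regions,
positioned at gene midpoints; an inversion shows up as a maximal anchor run
with reversed order (monotone-decreasing partner position) and flipped
annotated strands. Breakpoint intervals are the open gaps between adjacent
blocks in the first region's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import NT_SCHEME, PROTEIN_SCHEME, ScoringScheme, global_score, local_score_nt
from ._genetics import revcomp
from .io import Annotation, SequenceSet


@dataclass
class OrthologAnchor:
    gene_a: str
    gene_b: str
    pos_a: float
    pos_b: float
    rel_orientation: str  # "same" | "flipped"
    score: float


@dataclass
class SyntenyBlock:
    anchors: list[OrthologAnchor]
    orientation: str  # "colinear" | "inverted"

    @property
    def span_a(self) -> tuple[float, float]:
        return self.anchors[0].pos_a, self.anchors[-1].pos_a


@dataclass
class SyntenyBlocks:
    blocks: list[SyntenyBlock] = field(default_factory=list)
    singletons: list[OrthologAnchor] = field(default_factory=list)
    breakpoints: list[tuple[float, float]] = field(default_factory=list)

    @property
    def inverted_count(self) -> int:
        return sum(1 for b in self.blocks if b.orientation == "inverted")


@dataclass
class WindowTrack:
    """Non-overlapping windows tiled from a region start, with one value per
    window (alignment score, GC percentage, ...)."""

    windows: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    window_size: int = 0
    partial_final: bool = False

    @property
    def full_windows(self) -> int:
        return sum(1 for (s, e), _ in self.windows if e - s == self.window_size)

    def values(self, include_partial: bool = False) -> list[float]:
        return [v for (s, e), v in self.windows
                if include_partial or e - s == self.window_size]


def _region_genes(annotation: Annotation,
                  region: Optional[tuple[str, int, int]]):
    if region is None:
        return list(annotation)
    contig, start, end = region
    return [g for g in annotation.on_contig(contig)
            if g.start < end and g.end > start]


def anchor_map(
    ann_a: Annotation,
    assembly_a: SequenceSet,
    ann_b: Annotation,
    assembly_b: SequenceSet,
    region_a: Optional[tuple[str, int, int]] = None,
    region_b: Optional[tuple[str, int, int]] = None,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    min_score: float = 50.0,
) -> list[OrthologAnchor]:
    """Reciprocal-best-hit ortholog anchors between two annotated regions,
    sorted by position in region A."""
    genes_a = [g for g in _region_genes(ann_a, region_a) if g.cds_parts]
    genes_b = [g for g in _region_genes(ann_b, region_b) if g.cds_parts]
    if not genes_a or not genes_b:
        return []
    prot_a = {g.gene_id: g.protein(assembly_a) for g in genes_a}
    prot_b = {g.gene_id: g.protein(assembly_b) for g in genes_b}
    scores: dict[tuple[str, str], float] = {}
    for ga in genes_a:
        for gb in genes_b:
            scores[(ga.gene_id, gb.gene_id)] = global_score(
                prot_a[ga.gene_id], prot_b[gb.gene_id], scheme)
    best_b_for_a = {
        ga.gene_id: max(genes_b, key=lambda gb: (scores[(ga.gene_id, gb.gene_id)],
                                                 gb.gene_id)).gene_id
        for ga in genes_a
    }
    best_a_for_b = {
        gb.gene_id: max(genes_a, key=lambda ga: (scores[(ga.gene_id, gb.gene_id)],
                                                 ga.gene_id)).gene_id
        for gb in genes_b
    }
    by_id_b = {g.gene_id: g for g in genes_b}
    anchors = []
    for ga in genes_a:
        gb_id = best_b_for_a[ga.gene_id]
        if best_a_for_b[gb_id] != ga.gene_id:
            continue
        score = scores[(ga.gene_id, gb_id)]
        if score < min_score:
            continue
        gb = by_id_b[gb_id]
        anchors.append(
            OrthologAnchor(
                ga.gene_id, gb_id, ga.midpoint, gb.midpoint,
                "same" if ga.strand == gb.strand else "flipped", score)
        )
    anchors.sort(key=lambda a: a.pos_a)
    return anchors


def _run_ok(run: list[OrthologAnchor], nxt: OrthologAnchor) -> bool:
    if run[0].rel_orientation != nxt.rel_orientation:
        return False
    if nxt.rel_orientation == "same":
        return nxt.pos_b > run[-1].pos_b
    return nxt.pos_b < run[-1].pos_b


def detect_blocks(anchors: list[OrthologAnchor],
                  min_anchors: int = 2) -> SyntenyBlocks:
    """Partition anchors (sorted by pos_a) into greedy maximal runs of
    constant orientation with monotone partner positions. Runs shorter than
    ``min_anchors`` are reported as singletons, excluded from blocks;
    breakpoints are the open intervals between outermost anchors of adjacent
    surviving blocks."""
    out = SyntenyBlocks()
    if not anchors:
        return out
    runs: list[list[OrthologAnchor]] = [[anchors[0]]]
    for anchor in anchors[1:]:
        if _run_ok(runs[-1], anchor):
            runs[-1].append(anchor)
        else:
            runs.append([anchor])
    for run in runs:
        if len(run) < min_anchors:
            out.singletons.extend(run)
        else:
            orient = "colinear" if run[0].rel_orientation == "same" else "inverted"
            out.blocks.append(SyntenyBlock(run, orient))
    for left, right in zip(out.blocks, out.blocks[1:]):
        out.breakpoints.append((left.anchors[-1].pos_a, right.anchors[0].pos_a))
    return out


def window_similarity(
    query: str,
    target: str,
    fragment: int = 1000,
    scheme: ScoringScheme = NT_SCHEME,
) -> WindowTrack:
    """Tile the query into non-overlapping fragments and record, per
    fragment, the best local-alignment score against the target (both
    strands searched; 0 when no positive-scoring segment exists)."""
    if fragment < 100:
        raise ValueError("fragment size below 100 bp is degenerate")
    if not query or not target:
        raise ValueError("empty region")
    target_rc = revcomp(target)
    track = WindowTrack(window_size=fragment)
    for s in range(0, len(query), fragment):
        e = min(s + fragment, len(query))
        piece = query[s:e]
        score = max(local_score_nt(piece, target, scheme),
                    local_score_nt(piece, target_rc, scheme))
        track.windows.append(((s, e), score))
    track.partial_final = len(query) % fragment != 0
    return track


def blocks_to_tsv(blocks: SyntenyBlocks) -> str:
    lines = ["block\torientation\tn_anchors\tstart_a\tend_a\tgenes_a"]
    for i, b in enumerate(blocks.blocks, 1):
        lines.append("\t".join([
            str(i), b.orientation, str(len(b.anchors)),
            f"{b.span_a[0]:.0f}", f"{b.span_a[1]:.0f}",
            ",".join(a.gene_a for a in b.anchors)]))
    for bp in blocks.breakpoints:
        lines.append(f"breakpoint\t-\t-\t{bp[0]:.0f}\t{bp[1]:.0f}\t-")
    return "\n".join(lines) + "\n"
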
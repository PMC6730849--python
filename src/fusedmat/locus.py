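"""Fused MAT-locus detection: HD / P-R linkage, core span, allele class.

In tetrapolar basidiomycetes the homeodomain (HD: SXI1 or SXI2) and
pheromone/receptor (P/R: MF + STE3) loci segregate independently; in a fused
(bipolar-like) configuration they are physically linked on one contig, here
~55 kb apart at the two ends of a core MAT region. Allele classes follow the
STE3-keyed convention: A1 = STE3alpha + SXI2, A2 = STE3a + SXI1, with starred
variants (A1* = STE3alpha + SXI1, A2* = STE3a + SXI2) for the recombined
HD combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import RoleAssignment
from .io import Annotation, GeneModel

HD_ROLES = ("SXI1", "SXI2")
COMPANION_ROLES = ("STE11", "STE20", "IKS1", "MYO2", "RPL22", "STE12")

ALLELE_MAP = {
    ("alpha", "SXI2"): "A1",
    ("a", "SXI1"): "A2",
    ("alpha", "SXI1"): "A1*",
    ("a", "SXI2"): "A2*",
}


def classify_allele(ste3_type: str, hd_role: str) -> str:
    """Map an (STE3 class, HD gene) combination to the MAT allele class."""
    return ALLELE_MAP.get((ste3_type, hd_role), "unresolved")


@dataclass
class MatLocusReport:
    genome_id: str
    complete: bool
    reason: str = ""
    hd_gene: Optional[GeneModel] = None
    hd_role: Optional[str] = None
    ste3_gene: Optional[GeneModel] = None
    mf_gene: Optional[GeneModel] = None
    linked: bool = False
    distance_bp: Optional[int] = None
    core_contig: Optional[str] = None
    core_span: Optional[tuple[int, int]] = None
    allele: str = "unresolved"
    companions: list[str] = field(default_factory=list)
    hybrid: bool = False


def _gap(a: GeneModel, b: GeneModel) -> int:
    """Distance between the nearest ends of two non-overlapping genes."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def _role_gene(annotation: Annotation, roles: RoleAssignment,
               role: str) -> Optional[GeneModel]:
    call = roles.by_role.get(role)
    if call is None or call.flag == "one_way":
        return None
    try:
        return annotation.get(call.gene_id)
    except KeyError:
        return None


def locate_mat(
    annotation: Annotation,
    roles: RoleAssignment,
    ste3_type: Optional[str] = None,
    flank: int = 20_000,
) -> list[MatLocusReport]:
    """Locate the MAT locus in a haploid genome and test HD / P-R linkage.

    Returns one report for a haploid genome; a hybrid-like genome whose two
    HD genes sit on distinct contigs yields one report per subgenome
    candidate, flagged ``hybrid``. The core span runs from the pheromone /
    STE3 end to the HD gene; the distance is the gap between the nearest
    ends of STE3 and the HD gene when they are linked.
    """
    hd_genes = [(r, g) for r in HD_ROLES
                if (g := _role_gene(annotation, roles, r)) is not None]
    ste3 = _role_gene(annotation, roles, "STE3")
    mf = _role_gene(annotation, roles, "MF")

    if not hd_genes:
        return [MatLocusReport(annotation.genome_id, complete=False,
                               reason="HD locus not found (no SXI gene)")]

    hybrid = (len(hd_genes) == 2
              and hd_genes[0][1].contig != hd_genes[1][1].contig)
    reports = []
    for hd_role, hd in hd_genes:
        rep = MatLocusReport(annotation.genome_id, complete=True,
                             hd_gene=hd, hd_role=hd_role, hybrid=hybrid)
        if ste3 is None:
            rep.complete = False
            rep.reason = "P/R locus not found"
            reports.append(rep)
            continue
        rep.ste3_gene = ste3
        rep.mf_gene = mf
        rep.linked = ste3.contig == hd.contig
        if rep.linked:
            rep.distance_bp = _gap(ste3, hd)
            members = [g for g in (mf, ste3, hd)
                       if g is not None and g.contig == hd.contig]
            rep.core_contig = hd.contig
            rep.core_span = (min(g.start for g in members),
                             max(g.end for g in members))
            lo = rep.core_span[0] - flank
            hi = rep.core_span[1] + flank
            found = set()
            for comp_role in COMPANION_ROLES:
                g = _role_gene(annotation, roles, comp_role)
                if g is not None and g.contig == hd.contig \
                        and g.start < hi and g.end > lo:
                    found.add(comp_role)
            # also honour roles carried directly on the annotation
            found.update(
                g.role for g in annotation.on_contig(hd.contig)
                if g.role in COMPANION_ROLES and g.start < hi and g.end > lo)
            rep.companions = sorted(found)
        if ste3_type in ("a", "alpha"):
            rep.allele = classify_allele(ste3_type, hd_role)
        reports.append(rep)
        if not hybrid:
            break
    return reports
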
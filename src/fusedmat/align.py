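"""Pairwise alignment primitives and homology-based MAT-role assignment.

Global protein alignment (Needleman-Wunsch, BLOSUM62, affine gaps) and local
nucleotide alignment (Smith-Waterman) stand in for the BLASTP/BLASTN searches
a practitioner would run against a reference panel of MAT proteins; defaults
mirror the conventional BLAST parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceSet


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring. Gap penalties are stored positive, applied negative;
    a length-k gap costs gap_open + k * gap_extend."""

    alphabet: str  # "aa" or "nt"
    matrix: Optional[str] = None  # protein substitution matrix name
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 11.0
    gap_extend: float = 1.0


#: BLASTP-like protein defaults.
PROTEIN_SCHEME = ScoringScheme(alphabet="aa", matrix="BLOSUM62",
                               gap_open=11.0, gap_extend=1.0)
#: BLASTN-like nucleotide defaults.
NT_SCHEME = ScoringScheme(alphabet="nt", match=2.0, mismatch=-3.0,
                          gap_open=5.0, gap_extend=2.0)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


@lru_cache(maxsize=16)
def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if scheme.matrix is not None:
        al.substitution_matrix = substitution_matrices.load(scheme.matrix)
    else:
        al.match_score = scheme.match
        al.mismatch_score = scheme.mismatch
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    return al


def _check_alphabet(seq: str, scheme: ScoringScheme, name: str) -> None:
    if scheme.matrix is not None:
        allowed = set(str(substitution_matrices.load(scheme.matrix).alphabet))
    else:
        allowed = set("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"sequence {name} contains characters {sorted(bad)} outside the "
            f"{scheme.alphabet} scoring alphabet"
        )


def _identity(row_a: str, row_b: str) -> float:
    if not row_a:
        return 0.0
    same = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return same / len(row_a)


def align_global(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> AlignmentResult:
    """Optimal global alignment with affine gaps (Needleman-Wunsch)."""
    _check_alphabet(a, scheme, "a")
    _check_alphabet(b, scheme, "b")
    if not a or not b:
        # all-gap alignment: one gap of length max(len)
        n = max(len(a), len(b))
        score = -(scheme.gap_open + n * scheme.gap_extend) if n else 0.0
        return AlignmentResult(a or "-" * n, b or "-" * n, score, 0.0)
    aln = _aligner(scheme, "global").align(a, b)[0]
    return AlignmentResult(str(aln[0]), str(aln[1]), aln.score,
                           _identity(str(aln[0]), str(aln[1])))


def global_score(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> float:
    """Score-only fast path for reciprocal-best-hit searches."""
    if not a or not b:
        n = max(len(a), len(b))
        return -(scheme.gap_open + n * scheme.gap_extend) if n else 0.0
    return float(_aligner(scheme, "global").score(a, b))


def align_local_nt(a: str, b: str, scheme: ScoringScheme = NT_SCHEME) -> AlignmentResult:
    """Optimal local alignment (Smith-Waterman); score 0 when no
    positive-scoring segment exists."""
    if not a or not b:
        return AlignmentResult("", "", 0.0, 0.0)
    results = _aligner(scheme, "local").align(a, b)
    if len(results) == 0:
        return AlignmentResult("", "", 0.0, 0.0)
    aln = results[0]
    return AlignmentResult(str(aln[0]), str(aln[1]), aln.score,
                           _identity(str(aln[0]), str(aln[1])))


def local_score_nt(a: str, b: str, scheme: ScoringScheme = NT_SCHEME) -> float:
    if not a or not b:
        return 0.0
    return float(_aligner(scheme, "local").score(a, b))


# ---------------------------------------------------------------------------
# Role assignment against a MAT reference panel


@dataclass
class RoleCall:
    gene_id: str
    role: str
    score: float
    second_best_score: float
    identity: float
    flag: str  # unique | tie | one_way


@dataclass
class RoleAssignment:
    """Reciprocal-best-hit assignment of MAT roles to query proteins."""

    by_role: dict[str, RoleCall] = field(default_factory=dict)
    by_gene: dict[str, RoleCall] = field(default_factory=dict)
    one_way: dict[str, RoleCall] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    def role_of(self, gene_id: str) -> Optional[str]:
        call = self.by_gene.get(gene_id)
        return call.role if call else None


def panel_roles(panel: SequenceSet) -> dict[str, str]:
    """Extract ``role=`` tags from panel record descriptions."""
    roles = {}
    for rec in panel:
        for tok in rec.description.split():
            if tok.startswith("role="):
                roles[rec.id] = tok[5:]
    return roles


def assign_roles(
    proteome: SequenceSet,
    panel: SequenceSet,
    roles: Optional[dict[str, str]] = None,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    min_score: float = 50.0,
    min_identity: float = 0.25,
) -> RoleAssignment:
    """Assign MAT roles to query proteins by reciprocal best hit.

    For every role in the panel, the best-scoring query is found; the role is
    assigned only if that query's own best panel hit carries the same role.
    Score ties are flagged and broken by lexicographically smaller gene id;
    pairs below the score/identity floor stay unassigned.
    """
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    if roles is None:
        roles = panel_roles(panel)
        if len(roles) != len(panel):
            missing = [r.id for r in panel if r.id not in roles]
            raise ValueError(f"panel entries without role= tag: {missing}")

    queries = list(proteome)
    scores: dict[tuple[str, str], float] = {}
    for q in queries:
        for p in panel:
            scores[(q.id, p.id)] = global_score(q.seq, p.seq, scheme)

    # best panel entry (hence role) for every query
    best_panel_for_query: dict[str, str] = {}
    for q in queries:
        best = max(panel, key=lambda p: (scores[(q.id, p.id)], p.id))
        best_panel_for_query[q.id] = best.id

    out = RoleAssignment()
    role_names = sorted(set(roles.values()))
    for role in role_names:
        refs = [p for p in panel if roles[p.id] == role]
        if not queries:
            continue
        # score of a query against a role = best over that role's references
        def role_score(q) -> float:
            return max(scores[(q.id, p.id)] for p in refs)

        ranked = sorted(queries, key=lambda q: (-role_score(q), q.id))
        top = ranked[0]
        top_score = role_score(top)
        second = role_score(ranked[1]) if len(ranked) > 1 else float("-inf")
        flag = "tie" if second == top_score else "unique"
        reciprocal = roles[best_panel_for_query[top.id]] == role
        if not reciprocal:
            out.unassigned.append(top.id)
            out.one_way[role] = RoleCall(top.id, role, top_score, second, 0.0, "one_way")
            continue
        best_ref = max(refs, key=lambda p: (scores[(top.id, p.id)], p.id))
        identity = align_global(top.seq, best_ref.seq, scheme).identity
        if top_score < min_score or identity < min_identity:
            out.unassigned.append(top.id)
            continue
        call = RoleCall(top.id, role, top_score, second, identity, flag)
        out.by_role[role] = call
        out.by_gene[top.id] = call
    return out


# ---------------------------------------------------------------------------
# STE3 a / alpha typing


@dataclass
class Ste3Type:
    cls: str  # "a" | "alpha" | "unresolved"
    best_score: float
    margin: float
    alpha_proline: Optional[bool] = None  # advisory only


def ste3_reference_classes(refs: SequenceSet) -> dict[str, str]:
    """Extract ``class=`` tags (a / alpha) from reference descriptions."""
    classes = {}
    for rec in refs:
        for tok in rec.description.split():
            if tok.startswith("class="):
                classes[rec.id] = tok[6:]
    return classes


def _alpha_proline_column(alpha_refs: list[str], a_refs: list[str],
                          scheme: ScoringScheme) -> Optional[int]:
    """Column (in the first alpha reference) of an N-terminal proline
    conserved in the alpha group and absent from the a group, if any."""
    anchor = alpha_refs[0]
    limit = min(len(anchor), 60)
    for col in range(limit):
        if anchor[col] != "P":
            continue
        if all(_aligned_residue(anchor, other, col, scheme) == "P"
               for other in alpha_refs[1:]):
            if all(_aligned_residue(anchor, other, col, scheme) != "P"
                   for other in a_refs):
                return col
    return None


def _aligned_residue(anchor: str, other: str, col: int,
                     scheme: ScoringScheme) -> Optional[str]:
    aln = align_global(anchor, other, scheme)
    i = j = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            if i == col:
                return y if y != "-" else None
            i += 1
        if y != "-":
            j += 1
    return None


def type_ste3(
    ste3_protein: str,
    refs: SequenceSet,
    classes: Optional[dict[str, str]] = None,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    margin_fraction: float = 0.05,
) -> Ste3Type:
    """Type an STE3 pheromone receptor as the ancient **a** or alpha allele
    class by similarity to labelled references.

    The call is the class of the best-scoring reference; when the margin
    between the best a-class and best alpha-class scores is below
    ``margin_fraction`` of the best score, the call is unresolved. A conserved
    alpha-group N-terminal proline, when identifiable in the references, is
    reported as an advisory flag and never overrides the similarity call.
    """
    if classes is None:
        classes = ste3_reference_classes(refs)
    a_refs = [r.seq for r in refs if classes.get(r.id) == "a"]
    alpha_refs = [r.seq for r in refs if classes.get(r.id) == "alpha"]
    if not a_refs or not alpha_refs:
        raise ValueError("need at least one reference per STE3 class (a and alpha)")
    best_a = max(global_score(ste3_protein, r, scheme) for r in a_refs)
    best_alpha = max(global_score(ste3_protein, r, scheme) for r in alpha_refs)
    best = max(best_a, best_alpha)
    margin = abs(best_a - best_alpha)
    if best <= 0 or margin < margin_fraction * abs(best):
        return Ste3Type("unresolved", best, margin)
    cls = "a" if best_a > best_alpha else "alpha"
    proline = None
    if cls == "alpha":
        col = _alpha_proline_column(alpha_refs, a_refs, scheme)
        if col is not None:
            res = _aligned_residue(alpha_refs[0], ste3_protein, col, scheme)
            proline = res == "P"
    return Ste3Type(cls, best, margin, proline)
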
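"""Alignment primitives against brute-force oracles, and homology calls."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from fusedmat.align import (NT_SCHEME, PROTEIN_SCHEME, ScoringScheme,
                            align_global, align_local_nt, assign_roles,
                            global_score, type_ste3)
from fusedmat.io import Record, SequenceSet

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_global(a: str, b: str, scheme: ScoringScheme) -> float:
    """Enumerate every global alignment (as a move string) and score it with
    affine gaps: a length-k gap costs gap_open + k * gap_extend."""

    def sub(x, y):
        if scheme.matrix:
            return BLOSUM62[x, y]
        return scheme.match if x == y else scheme.mismatch

    best = [-np.inf]

    def rec(i, j, moves):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], _score(moves))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, moves + [("D", a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, moves + [("U", a[i], None)])
        if j < len(b):
            rec(i, j + 1, moves + [("L", None, b[j])])

    def _score(moves):
        score, prev = 0.0, None
        for m, x, y in moves:
            if m == "D":
                score += sub(x, y)
            else:
                score -= scheme.gap_extend
                if m != prev:
                    score -= scheme.gap_open
            prev = m
        return score

    rec(0, 0, [])
    return best[0]


def gotoh_local(a: str, b: str, scheme: ScoringScheme) -> float:
    """Independent affine-gap Smith-Waterman (Gotoh) for the local oracle."""
    n, m = len(a), len(b)
    neg = -1e18
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), neg)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    best = 0.0
    go, ge = scheme.gap_open, scheme.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge)
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                       Y[i - 1, j - 1]))
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best


class TestGlobal:
    def test_identical_sequences(self):
        res = align_global("MKVL", "MKVL")
        assert res.identity == 1.0
        assert res.score == sum(BLOSUM62[c, c] for c in "MKVL")

    def test_single_residue_vs_empty(self):
        res = align_global("A", "")
        assert res.score == -(PROTEIN_SCHEME.gap_open + PROTEIN_SCHEME.gap_extend)
        assert res.aligned_b == "-"

    def test_mixed_alphabet_rejected(self):
        with pytest.raises(ValueError):
            align_global("MKV!", "MKV")

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_oracle_protein(self, seed):
        rng = np.random.default_rng(seed)
        aa = "ARNDCQEGHILKMFPSTWYV"
        a = "".join(rng.choice(list(aa), rng.integers(1, 6)))
        b = "".join(rng.choice(list(aa), rng.integers(1, 6)))
        assert align_global(a, b).score == pytest.approx(
            brute_force_global(a, b, PROTEIN_SCHEME))

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_oracle_nt(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 7)))
        assert align_global(a, b, NT_SCHEME).score == pytest.approx(
            brute_force_global(a, b, NT_SCHEME))

    def test_score_symmetry(self):
        rng = np.random.default_rng(5)
        aa = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(10):
            a = "".join(rng.choice(list(aa), 30))
            b = "".join(rng.choice(list(aa), 25))
            assert global_score(a, b) == global_score(b, a)

    def test_suffix_monotonicity(self):
        rng = np.random.default_rng(9)
        aa = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(10):
            a = "".join(rng.choice(list(aa), 20))
            b = "".join(rng.choice(list(aa), 18))
            tail = "".join(rng.choice(list(aa), 5))
            assert global_score(a + tail, b + tail) >= global_score(a, b)


class TestLocal:
    def test_exact_match_score(self):
        assert align_local_nt("ACGT", "ACGT").score == 8.0  # 4 matches x +2

    def test_disjoint_sequences_zero(self):
        res = align_local_nt("AAAA", "CCCC")
        assert res.score == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 120))
        b = "".join(rng.choice(list("ACGT"), 150))
        assert align_local_nt(a, b).score == pytest.approx(
            gotoh_local(a, b, NT_SCHEME))


def _panel():
    return SequenceSet([
        Record("ref_SXI2", "MSTPHDKLRRQWEHLTPEQ" * 4, "role=SXI2"),
        Record("ref_STE3", "MLWRRAGGTQFNDPLKSHV" * 4, "role=STE3"),
    ], alphabet="aa")


class TestRoles:
    def test_exact_copy_assigned_unique(self):
        panel = _panel()
        queries = SequenceSet([
            Record("q1", panel["ref_SXI2"]),
            Record("q2", "MPPPPPLLLLLKKKKKAAAA"),
        ], alphabet="aa")
        out = assign_roles(queries, panel)
        assert out.by_role["SXI2"].gene_id == "q1"
        assert out.by_role["SXI2"].flag == "unique"

    def test_one_way_best_not_assigned(self):
        # q1 is the best hit for both roles, but its own best is SXI2:
        # the STE3 role stays unassigned (one-way)
        panel = _panel()
        queries = SequenceSet([Record("q1", panel["ref_SXI2"])], alphabet="aa")
        out = assign_roles(queries, panel)
        assert "STE3" not in out.by_role
        assert out.one_way["STE3"].flag == "one_way"

    def test_tie_broken_lexicographically(self):
        panel = _panel()
        seq = panel["ref_SXI2"]
        queries = SequenceSet([Record("qB", seq), Record("qA", seq)],
                              alphabet="aa")
        out = assign_roles(queries, panel)
        call = out.by_role["SXI2"]
        assert call.flag == "tie"
        assert call.gene_id == "qA"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_roles(SequenceSet(alphabet="aa"), SequenceSet(alphabet="aa"))

    def test_low_score_floor_unassigned(self):
        panel = _panel()
        queries = SequenceSet([Record("q1", "MKV")], alphabet="aa")
        out = assign_roles(queries, panel)
        assert out.by_role == {}


class TestSte3Typing:
    def _refs(self):
        return SequenceSet([
            Record("a1", "MFNWTRLLDAGHKKVEQLS" * 3, "class=a"),
            Record("al1", "MSPLPQRWEDNCHTYKVGA" * 3, "class=alpha"),
        ], alphabet="aa")

    def test_identical_to_alpha_reference(self):
        refs = self._refs()
        assert type_ste3(refs["al1"], refs).cls == "alpha"

    def test_identical_to_a_reference(self):
        refs = self._refs()
        assert type_ste3(refs["a1"], refs).cls == "a"

    def test_equidistant_unresolved(self):
        refs = SequenceSet([
            Record("a1", "MKVLHHHH", "class=a"),
            Record("al1", "MKVLHHHH", "class=alpha"),
        ], alphabet="aa")
        assert type_ste3("MKVLHHHH", refs).cls == "unresolved"

    def test_missing_class_rejected(self):
        refs = SequenceSet([Record("a1", "MKVL", "class=a")], alphabet="aa")
        with pytest.raises(ValueError):
            type_ste3("MKVL", refs)

    def test_simulated_ste3_typed_by_truth_class(self, default_dataset):
        """Planted STE3 alleles type as the class of their allele tree for
        every strain and species."""
        ds = default_dataset
        refs = SequenceSet([r for r in ds.panel if "class=" in r.description],
                           alphabet="aa")
        from fusedmat.simulate import STE3_OF_CLASS
        from fusedmat._genetics import translate
        for truth in ds.truth.strains:
            ste3 = next(g for g in truth.genes if g["role"] == "STE3")
            ann = ds.annotations[truth.strain_id]
            pep = ann.get(ste3["gene_id"]).protein(
                ds.assemblies[truth.strain_id])
            res = type_ste3(pep, refs)
            assert res.cls == STE3_OF_CLASS[truth.allele_class]
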
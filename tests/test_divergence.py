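"""NG86 dS/dN estimation, similarity calls, and the dS-set comparisons."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from fusedmat.divergence import (breakpoint_divergence_test, closest_pair_calls,
                                 codon_align, compare_ds_sets, estimate_ds,
                                 jc_correct, ng86_counts)
from fusedmat.synteny import (OrthologAnchor, SyntenyBlock, SyntenyBlocks,
                              WindowTrack)

STOPS = {"TAA", "TAG", "TGA"}


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_site_fraction(codon: str) -> float:
    """Naive per-codon synonymous site fraction (stops nonsynonymous)."""
    total = 0.0
    for pos, base in enumerate(codon):
        for alt in "ACGT":
            if alt == base:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut not in STOPS and aa_of(mut) == aa_of(codon):
                total += 1
    return total / 3.0


def oracle_differences(a: str, b: str):
    """Naive path enumeration: average per-step synonymous/nonsynonymous
    labels over orderings of the differing positions, skipping orderings
    that pass through a stop codon (all-skipped: count stop steps as
    nonsynonymous over all orderings)."""
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0

    def score(order, strict):
        cur, sd, nd = a, 0, 0
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if strict and nxt in STOPS:
                return None
            if nxt not in STOPS and cur not in STOPS \
                    and aa_of(cur) == aa_of(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for r in (score(o, True)
                           for o in itertools.permutations(diff))
               if r is not None]
    if not results:
        results = [score(o, False) for o in itertools.permutations(diff)]
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


SENSE = [c for c in ("".join(t) for t in itertools.product("TCAG", repeat=3))
         if c not in STOPS]


class TestNg86Counts:
    def test_forced_synonymous_third_position(self):
        _, _, sd, nd = ng86_counts("GAA", "GAG")
        assert (sd, nd) == (1.0, 0.0)  # Glu -> Glu

    def test_phe_codon_site_fraction(self):
        s_a, s_b, sd, nd = ng86_counts("TTT", "TTT")
        # of TTT's nine one-step mutants only TTC is synonymous
        assert s_a == pytest.approx(1 / 3)
        assert (sd, nd) == (0.0, 0.0)

    def test_two_step_pair_averages_orderings(self):
        # AAA (Lys) -> AGG (Arg): paths K->R->R and K->K->R
        _, _, sd, nd = ng86_counts("AAA", "AGG")
        assert sd == pytest.approx(1.0)
        assert nd == pytest.approx(1.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_counts("TAA", "AAA")

    def test_site_conservation_all_codons(self):
        for codon in SENSE:
            s, _, _, _ = ng86_counts(codon, codon)
            assert 0.0 <= s <= 3.0  # nonsynonymous fraction = 3 - s >= 0

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_equivalence_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            a, b = rng.choice(SENSE, 2)
            s_a, s_b, sd, nd = ng86_counts(a, b)
            assert s_a == pytest.approx(oracle_site_fraction(a))
            assert s_b == pytest.approx(oracle_site_fraction(b))
            osd, ond = oracle_differences(a, b)
            assert sd == pytest.approx(osd)
            assert nd == pytest.approx(ond)


class TestCodonAlign:
    def test_identical_cds(self):
        cds = "ATGAAACCCGGGTTTTAA"
        aln = codon_align(cds, cds)
        assert aln.n_codons == 5  # terminal stop trimmed
        assert aln.n_dropped_gap == 0

    def test_inframe_insertion_drops_one_pair(self):
        a = "ATG" + "AAACCCGGGTTT" + "TAA"
        b = "ATG" + "AAACCCAGGGGGTTT" + "TAA"  # one extra codon
        aln = codon_align(a, b)
        assert aln.n_dropped_gap == 1

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            codon_align("ATGAAAC", "ATGAAA")

    def test_internal_stop_rejected_with_name(self):
        with pytest.raises(ValueError, match="a"):
            codon_align("ATGTAAAAATAA", "ATGAAAAAATAA")


def _aln_from(pairs):
    from fusedmat.divergence import CodonAlignment
    return CodonAlignment(list(pairs), 0)


class TestEstimateDs:
    def test_identical_alignment_zero(self):
        aln = _aln_from([("ATG", "ATG"), ("AAA", "AAA")] * 10)
        est = estimate_ds(aln, bootstrap_B=100, seed=0)
        assert est.dS == 0.0 and est.dN == 0.0
        assert est.status == "ok"

    def test_saturated_synonymous_sites_undefined(self):
        # every synonymous site differs: Leu TTA vs CTG etc. drive pS >= 3/4
        aln = _aln_from([("GAA", "GAG")] * 20)  # pS = 20 / (20*(1/3+...))
        est = estimate_ds(aln, bootstrap_B=0)
        assert est.status == "undefined"
        assert est.dS is None

    def test_argument_order_symmetry(self):
        rng = np.random.default_rng(0)
        pairs = [(SENSE[i], SENSE[j])
                 for i, j in rng.integers(0, 61, size=(50, 2))]
        e1 = estimate_ds(_aln_from(pairs), bootstrap_B=0)
        e2 = estimate_ds(_aln_from([(b, a) for a, b in pairs]), bootstrap_B=0)
        assert e1.dS == e2.dS and e1.dN == e2.dN

    def test_floor_enforced(self):
        with pytest.raises(ValueError):
            estimate_ds(_aln_from([("AAA", "AAA")] * 5), bootstrap_B=0)

    def test_jc_monotone_and_above_p(self):
        ps = np.linspace(0.01, 0.74, 40)
        ds = [jc_correct(p) for p in ps]
        assert all(d >= p for d, p in zip(ds, ps))
        assert all(x < y for x, y in zip(ds, ds[1:]))
        assert jc_correct(0.75) is None

    def test_bootstrap_se_reasonable(self):
        rng = np.random.default_rng(1)
        pairs = []
        for _ in range(300):
            c = SENSE[rng.integers(61)]
            pairs.append((c, c))
        # sprinkle some synonymous differences
        for i in range(0, 60, 3):
            pairs[i] = ("GAA", "GAG")
        est = estimate_ds(_aln_from(pairs), bootstrap_B=400, seed=2)
        assert est.SE_dS is not None and 0 < est.SE_dS < est.dS

    def test_matches_biopython_ng86_on_clean_pair(self):
        """Cross-check against Biopython's independent NG86 implementation
        on a divergence level without stop-path complications."""
        from Bio.Align import MultipleSeqAlignment, SeqRecord
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(3)
        codons_a, codons_b = [], []
        for _ in range(200):
            c = SENSE[rng.integers(61)]
            codons_a.append(c)
            if rng.random() < 0.05:
                alts = [x for x in SENSE if sum(i != j for i, j in zip(x, c)) == 1]
                codons_b.append(alts[rng.integers(len(alts))])
            else:
                codons_b.append(c)
        est = estimate_ds(_aln_from(list(zip(codons_a, codons_b))),
                          bootstrap_B=0)
        dn, ds = cal_dn_ds(CodonSeq("".join(codons_a)),
                           CodonSeq("".join(codons_b)), method="NG86")
        assert est.dS == pytest.approx(ds, abs=5e-3)
        assert est.dN == pytest.approx(dn, abs=5e-3)


class TestClosestPair:
    def test_planted_suppression_calls_a2a2(self, trio_dataset):
        """Core-MAT genes with planted between-class divergence call the two
        A2 alleles as the most similar pair for nearly all genes."""
        ds = trio_dataset
        labels = {"sp1s1": "A1", "sp1s2": "A2", "sp1s3": "A2"}
        n_called = n_a2a2 = 0
        for i in range(23):
            key = f"g{i:02d}"
            alleles = {s: ds.ortholog_cds[key].get(s) for s in labels}
            call = closest_pair_calls(key, alleles, labels)
            if call.status == "called":
                n_called += 1
                n_a2a2 += call.pair_label == "A2/A2"
        assert n_called >= 20
        assert n_a2a2 / n_called >= 0.9

    def test_identical_alleles_ambiguous(self):
        cds = "ATGAAACCCGGGTTTTAA"
        call = closest_pair_calls("g", {"x": cds, "y": cds, "z": cds},
                                  {"x": "A1", "y": "A2", "z": "A2"})
        assert call.status == "ambiguous"

    def test_missing_allele_not_assessed(self):
        call = closest_pair_calls("g", {"x": "ATGAAATAA", "y": None,
                                        "z": "ATGAAATAA"},
                                  {"x": "A1", "y": "A2", "z": "A2"})
        assert call.status == "not_assessed"


class TestCompareDsSets:
    def test_identical_sets(self):
        r = compare_ds_sets([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 0.5

    def test_closed_form_hand_computation(self):
        # {1,2,3} vs {2,3,4}: pooled variance 1, t = -1/sqrt(2/3)
        r = compare_ds_sets([1, 2, 3], [2, 3, 4])
        t_expected = -1.0 / math.sqrt(2.0 / 3.0)
        assert r.t == pytest.approx(t_expected, rel=1e-6)
        assert r.df == 4
        # one-sided p = P(T_4 > t) via the t survival function
        assert r.p == pytest.approx(stats.t.sf(t_expected, 4), rel=1e-9)
        assert 0.8 < r.p < 0.9

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            compare_ds_sets([1.0], [1.0, 2.0])


def _track_and_blocks(bp_vals, interior_vals, lead_vals):
    """Synthetic window track: colinear lead windows, one inverted block
    containing the interior windows, breakpoint windows on each side."""
    n_lead = len(lead_vals)
    half = len(bp_vals) // 2
    values = (list(lead_vals) + list(bp_vals[:half])
              + list(interior_vals) + list(bp_vals[half:]))
    windows = [((i * 1000, (i + 1) * 1000), float(v))
               for i, v in enumerate(values)]
    track = WindowTrack(windows, 1000, False)
    k = n_lead + half
    n_int = len(interior_vals)
    block = SyntenyBlock(
        [OrthologAnchor("a", "b", k * 1000.0, 0.0, "flipped", 1.0),
         OrthologAnchor("c", "d", (k + n_int) * 1000.0, -1.0, "flipped", 1.0)],
        "inverted")
    lead_block = SyntenyBlock(
        [OrthologAnchor("l0", "m0", 500.0, 0.0, "same", 1.0),
         OrthologAnchor("l1", "m1", n_lead * 1000.0, 1.0, "same", 1.0)],
        "colinear")
    tail_block = SyntenyBlock(
        [OrthologAnchor("t0", "u0", (len(values) + 1) * 1000.0, 2.0, "same", 1.0),
         OrthologAnchor("t1", "u1", (len(values) + 2) * 1000.0, 3.0,
                        "same", 1.0)], "colinear")
    blocks = SyntenyBlocks(
        blocks=[lead_block, block, tail_block],
        breakpoints=[(lead_block.anchors[-1].pos_a, block.anchors[0].pos_a),
                     (block.anchors[-1].pos_a, tail_block.anchors[0].pos_a)])
    return track, blocks


class TestBreakpointDivergence:
    def test_extreme_separation_small_p(self):
        rng = np.random.default_rng(0)
        track, blocks = _track_and_blocks([10.0, 11.0, 12.0, 9.0, 8.5, 12.5],
                                          np.linspace(500, 520, 12),
                                          rng.normal(510, 1, 4))
        res = breakpoint_divergence_test(track, blocks, flank_windows=0)
        assert res.p < 0.01

    def test_null_p_uniform(self):
        """With breakpoint and interior windows drawn from one distribution
        the one-sided p-value is uniform (KS check)."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            track, blocks = _track_and_blocks(rng.normal(0, 1, 10),
                                              rng.normal(0, 1, 14),
                                              rng.normal(0, 1, 4))
            ps.append(breakpoint_divergence_test(track, blocks,
                                                 flank_windows=0).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_insufficient_windows_rejected(self):
        rng = np.random.default_rng(2)
        track, blocks = _track_and_blocks([1.0, 1.5], [2.0, 3.0],
                                          rng.normal(0, 1, 4))
        with pytest.raises(ValueError, match="insufficient"):
            breakpoint_divergence_test(track, blocks, flank_windows=0)
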
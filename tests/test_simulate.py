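"""The synthetic-genome generator: trees, evolution, planted structures."""

import numpy as np
import pytest

from fusedmat._genetics import translate
from fusedmat.io import write_fasta, write_gff3, write_newick
from fusedmat.simulate import (SimConfig, SubstModel, TemplateGene,
                               apply_inversions, evolve_sequence,
                               make_pheromone_gene, simulate_dataset,
                               simulate_species_tree)


class TestSpeciesTree:
    def test_two_species_cherry(self):
        tree = simulate_species_tree(2, seed=0)
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        assert {l.taxon.label for l in leaves} == {"sp1", "sp2"}

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)

    def test_same_seed_identical_newick(self):
        t1 = simulate_species_tree(5, seed=3)
        t2 = simulate_species_tree(5, seed=3)
        assert write_newick(t1) == write_newick(t2)

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_rooted_internal_node_count(self, n):
        tree = simulate_species_tree(n, seed=1)
        internal = sum(1 for _ in tree.preorder_internal_node_iter())
        assert internal == n - 1

    def test_height_and_min_split(self):
        tree = simulate_species_tree(6, seed=2, height=0.2, min_split=0.05)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) == pytest.approx(0.2)
        youngest = min(0.2 - nd.distance_from_root()
                       for nd in tree.preorder_internal_node_iter())
        assert youngest >= 0.05 - 1e-9


class TestEvolveSequence:
    def test_zero_branch_identity(self):
        tree = simulate_species_tree(2, seed=0)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = 0.0
        tips = evolve_sequence("ACGTACGT", tree, SubstModel(), seed=1)
        assert all(s == "ACGTACGT" for s in tips.values())

    def test_same_seed_identical_tips(self):
        tree = simulate_species_tree(3, seed=5)
        m = SubstModel(0.6, 2.0)
        assert evolve_sequence("ACGT" * 100, tree, m, seed=9) == \
            evolve_sequence("ACGT" * 100, tree, m, seed=9)

    def test_invalid_nucleotide_rejected(self):
        tree = simulate_species_tree(2, seed=0)
        with pytest.raises(ValueError):
            evolve_sequence("ACGX", tree, SubstModel(), seed=0)

    def test_stationary_gc_on_long_branch(self):
        """After >= 10 expected substitutions/site the sequence composition
        reaches the model's equilibrium GC (binomial 3-SE tolerance)."""
        import dendropy
        taxa = dendropy.TaxonNamespace(["tip"])
        tree = dendropy.Tree(taxon_namespace=taxa)
        child = dendropy.Node(taxon=taxa.get_taxon("tip"))
        child.edge.length = 12.0
        tree.seed_node.add_child(child)
        L = 30_000
        root = "A" * L  # farthest from equilibrium
        tips = evolve_sequence(root, tree, SubstModel(0.5, 2.0), seed=4)
        gc = sum(1 for c in tips["tip"] if c in "GC") / L
        se = (0.5 * 0.5 / L) ** 0.5
        assert abs(gc - 0.5) < 3 * se


class TestPheromoneGene:
    def test_minimal_spacer_lengths(self):
        cds = make_pheromone_gene(15, seed=0)
        assert len(cds) == 63  # (15 spacer + 5) aa + stop = 21 codons
        pep = translate(cds)
        assert len(pep) == 21 and pep.endswith("*")

    def test_consensus_by_construction(self):
        from fusedmat.pheromones import match_pheromone_consensus
        for spacer in (15, 40, 60):
            pep = translate(make_pheromone_gene(spacer, seed=spacer))[:-1]
            assert match_pheromone_consensus(pep).match


def _template(n=6):
    return [TemplateGene(f"g{i}", None, 300, "+" if i % 2 == 0 else "-")
            for i in range(n)]


class TestApplyInversions:
    def test_empty_segments_identity(self):
        t = _template()
        assert apply_inversions(t, []) == t

    def test_involution(self):
        t = _template()
        once = apply_inversions(t, [(1, 4)])
        assert once != t
        assert apply_inversions(once, [(1, 4)]) == t

    def test_order_and_strand_flip(self):
        t = _template()
        out = apply_inversions(t, [(1, 3)])
        assert [g.key for g in out] == ["g0", "g3", "g2", "g1", "g4", "g5"]
        # strands inside the segment are flipped, outside untouched
        assert [g.strand for g in out] == ["+", "+", "-", "+", "+", "-"]

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            apply_inversions(_template(), [(0, 3), (2, 5)])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_inversions(_template(), [(4, 9)])


class TestSimulateDataset:
    def test_truth_allele_classes_match_config(self, trio_dataset):
        classes = [s.allele_class for s in trio_dataset.truth.strains]
        assert classes == ["A1", "A2", "A2", "A1", "A2"]

    def test_core_span_distance_near_55kb(self, default_dataset):
        """Planted STE3-to-HD gap emulates the ~55 kb fused-locus span."""
        for truth in default_dataset.truth.strains:
            ste3 = next(g for g in truth.genes if g["role"] == "STE3")
            hd = next(g for g in truth.genes if g["role"] in ("SXI1", "SXI2"))
            gap = (hd["start"] - ste3["end"] if hd["start"] > ste3["end"]
                   else ste3["start"] - hd["end"])
            assert 40_000 < gap < 70_000

    def test_same_seed_byte_identical_outputs(self):
        cfg = SimConfig(seed=77)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(SimConfig(seed=77))
        for s in d1.strains:
            assert write_fasta(d1.assemblies[s]) == write_fasta(d2.assemblies[s])
            assert write_gff3(d1.annotations[s]) == write_gff3(d2.annotations[s])
        assert d1.truth.to_json() == d2.truth.to_json()

    def test_unknown_allele_class_rejected(self):
        with pytest.raises(ValueError, match="A9"):
            simulate_dataset(SimConfig(strains_per_species=["A1", "A9"]))

    def test_mat_gc_below_background(self, default_dataset):
        """Realized mean GC of core-MAT windows sits below background
        windows (3-SE tolerance on the planted 8-point depression)."""
        from fusedmat.composition import gc_windows
        ds = default_dataset
        truth = ds.truth.strains[0]
        asm = ds.assemblies[truth.strain_id]
        lo, hi = truth.core_span
        core_vals = gc_windows(asm[truth.mat_contig][lo:hi]).values()
        bg_vals = []
        for rec in asm:
            if rec.id != truth.mat_contig:
                bg_vals.extend(gc_windows(rec.seq).values())
        diff = np.mean(bg_vals) - np.mean(core_vals)
        assert diff > 3.0  # planted 8 points, binomial noise ~1 point

    def test_ste3_trans_specificity_on_truth_alignments(self, default_dataset):
        """Between-class STE3 distances exceed within-class distances across
        species (allele split predates speciation)."""
        from fusedmat.simulate import STE3_OF_CLASS
        ds = default_dataset
        seqs = ds.ortholog_cds["g01"]
        cls = {s.strain_id: STE3_OF_CLASS[s.allele_class]
               for s in ds.truth.strains}
        def pdist(a, b):
            return np.mean([x != y for x, y in zip(seqs[a], seqs[b])])
        strains = list(seqs)
        between = [pdist(a, b) for a in strains for b in strains
                   if a < b and cls[a] != cls[b]]
        within = [pdist(a, b) for a in strains for b in strains
                  if a < b and cls[a] == cls[b]]
        assert min(between) > max(within)

    def test_truth_serialization_round_trip(self, default_dataset):
        from fusedmat.simulate import SimTruth
        text = default_dataset.truth.to_json()
        again = SimTruth.from_json(text)
        assert again.to_json() == text
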
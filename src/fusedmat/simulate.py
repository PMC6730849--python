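"""Synthetic multi-strain genomes with planted fused MAT loci.

The generator emulates a panel of haploid yeast strains from several species:
each genome carries background contigs plus one MAT contig in which a core
MAT region (~55 kb between the pheromone/STE3 genes at one end and a single
homeodomain gene at the other) is embedded. Planted structure, all recorded
in a truth object:

* two allele classes whose gene orders differ by two inversions, one
  spanning most of the core region;
* an STE3 receptor whose a/alpha allele divergence predates the species
  splits (trans-species polymorphism);
* SXI1 and SXI2 as distinct genes (not alleles), combined with the STE3
  class per the A1/A2/A1*/A2* convention;
* optional extra divergence between mating types confined to core-MAT genes
  (recombination suppression), optionally concentrated at inversion
  breakpoints (gene-conversion-like homogenization of inversion interiors);
* AT-shifted base composition of the core MAT region.

Sequences evolve by an HKY-style substitution process (configurable
equilibrium GC and kappa) along a Yule species tree; indels are not
simulated, so planted coordinates are exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import dendropy
import numpy as np
from scipy.linalg import expm

from ._genetics import BASE_INDEX, BASES, CODON_AA, STOP_CODONS, revcomp
from .io import Annotation, GeneModel, Record, SequenceSet, write_fasta, write_gff3, write_newick

ALLELE_CLASSES = ("A1", "A2", "A1*", "A2*")

#: STE3 allele class carried by each MAT allele class (the A1/A2 designation
#: is keyed to the STE3 variant; the SXI gene defines the starred variants).
STE3_OF_CLASS = {"A1": "alpha", "A2": "a", "A1*": "alpha", "A2*": "a"}
HD_OF_CLASS = {"A1": "SXI2", "A2": "SXI1", "A1*": "SXI1", "A2*": "SXI2"}


# ---------------------------------------------------------------------------
# Substitution model


@dataclass(frozen=True)
class SubstModel:
    """HKY-like model: equilibrium GC split evenly between G and C (and AT
    between A and T), transition/transversion rate ratio kappa, branch
    lengths in expected substitutions per site."""

    equilibrium_gc: float = 0.5
    kappa: float = 2.0

    def frequencies(self) -> np.ndarray:
        gc = self.equilibrium_gc
        if not 0.0 < gc < 1.0:
            raise ValueError("equilibrium GC must be in (0, 1)")
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T

    def rate_matrix(self) -> np.ndarray:
        pi = self.frequencies()
        q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    def transition_probs(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        return expm(self.rate_matrix() * t)



@lru_cache(maxsize=512)
def _cum_probs(gc: float, kappa: float, t: float) -> np.ndarray:
    """Row-cumulative HKY transition probabilities for one branch length."""
    return np.cumsum(SubstModel(gc, kappa).transition_probs(t), axis=1)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def _sample_transitions(arr: np.ndarray, cum: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    u = rng.random(len(arr))
    for b in range(4):
        mask = arr == b
        if mask.any():
            out[mask] = np.searchsorted(cum[b], u[mask])
    return out


def _evolve_array(arr: np.ndarray, probs: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    return _sample_transitions(arr, np.cumsum(probs, axis=1), rng)


def _evolve_branch(arr: np.ndarray, model: SubstModel, t: float,
                   rng: np.random.Generator) -> np.ndarray:
    if t <= 0:
        return arr.copy()
    cum = _cum_probs(model.equilibrium_gc, model.kappa, float(t))
    return _sample_transitions(arr, cum, rng)


def evolve_sequence(root: str, tree: dendropy.Tree, model: SubstModel,
                    seed: int) -> dict[str, str]:
    """Evolve a root sequence down a tree; returns tip label -> sequence.
    Sites are independent; substitution follows the HKY-style model."""
    if not root:
        raise ValueError("root sequence must be non-empty")
    rng = np.random.default_rng(seed)
    arr = _encode(root)
    tips: dict[str, str] = {}

    def descend(node: dendropy.Node, state: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_state = (_evolve_array(state, model.transition_probs(t), rng)
                           if t > 0 else state.copy())
            if child.is_leaf():
                tips[child.taxon.label] = _decode(child_state)
            else:
                descend(child, child_state)

    descend(tree.seed_node, arr)
    return tips


# ---------------------------------------------------------------------------
# Species tree


def simulate_species_tree(n_species: int, seed: int, height: float = 0.15,
                          min_split: float = 0.0) -> dendropy.Tree:
    """Yule (pure-birth) species tree with exponential waiting times, scaled
    to the given root-to-tip height; tips labeled sp1..spN.

    The clock runs from the root split until one more waiting time after the
    n-th lineage appears, so every terminal branch has positive length; the
    tree is ultrametric by construction. With ``min_split`` > 0 the tree is
    resampled until every speciation predates the present by at least that
    depth (in substitutions/site), emulating a panel of well-separated
    species whose splits are old relative to within-species variation."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    for attempt in range(1000):
        tree = _yule_tree(n_species, seed + 7919 * attempt, height)
        if min_split <= 0:
            return tree
        youngest = min(
            height - node.distance_from_root()
            for node in tree.preorder_internal_node_iter())
        if youngest >= min_split - 1e-12:
            return tree
    raise RuntimeError("could not sample a species tree satisfying min_split")


def _yule_tree(n_species: int, seed: int, height: float) -> dendropy.Tree:
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i}" for i in range(1, n_species + 1)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    k = 2
    while True:
        wait = float(rng.exponential(1.0 / k))
        for node in active:
            node.edge.length += wait
        if k == n_species:
            break
        split = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            split.add_child(child)
            active.append(child)
        k += 1
    for i, node in enumerate(active, start=1):
        node.taxon = taxa.get_taxon(f"sp{i}")
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    factor = height / depth if depth > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


# ---------------------------------------------------------------------------
# Gene templates and inversions


@dataclass(frozen=True)
class TemplateGene:
    key: str
    role: Optional[str]
    length_nt: int
    strand: str


def apply_inversions(template: Sequence[TemplateGene],
                     segments: Sequence[tuple[int, int]]) -> list[TemplateGene]:
    """Reverse the order and flip the strand of the genes inside each
    (inclusive) index segment; applying a segment twice restores the input."""
    order = sorted(segments)
    for (a1, b1), (a2, b2) in zip(order, order[1:]):
        if a2 <= b1:
            raise ValueError(f"overlapping inversion segments {order}")
    n = len(template)
    out = list(template)
    for a, b in order:
        if not (0 <= a <= b < n):
            raise ValueError(f"segment ({a},{b}) outside template of {n} genes")
        flipped = [
            dataclasses.replace(g, strand="-" if g.strand == "+" else "+")
            for g in reversed(out[a:b + 1])
        ]
        out[a:b + 1] = flipped
    return out


CORE_ROLES = ("MF", "STE3", "STE20", "IKS1", "STE11", "MYO2", "RPL22")


def default_template(rng: np.random.Generator,
                     gene_len_range: tuple[int, int] = (900, 2400),
                     n_filler: int = 15,
                     mf_spacer: int = 40) -> list[TemplateGene]:
    """Default core-MAT template in A1 orientation: pheromone (MF) and STE3
    at one end, the HD gene at the other, classic companions plus filler
    genes in between; expected P/R-to-HD distance ~55 kb."""
    lo, hi = gene_len_range
    genes: list[TemplateGene] = []

    def draw_len() -> int:
        return 3 * int(rng.integers(lo // 3, hi // 3 + 1))

    genes.append(TemplateGene("g00", "MF", 3 * (mf_spacer + 6), "+"))
    for role in CORE_ROLES[1:]:
        genes.append(TemplateGene(f"g{len(genes):02d}", role, draw_len(),
                                  "+" if len(genes) % 2 == 0 else "-"))
    for _ in range(n_filler):
        genes.append(TemplateGene(f"g{len(genes):02d}", None, draw_len(),
                                  "+" if len(genes) % 2 == 0 else "-"))
    genes.append(TemplateGene(f"g{len(genes):02d}", "HD", draw_len(), "+"))
    return genes


# ---------------------------------------------------------------------------
# Random sequence / CDS construction


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    pi = SubstModel(equilibrium_gc=gc).frequencies()
    return _decode(rng.choice(4, size=length, p=pi))


def _random_codon(gc: float, rng: np.random.Generator,
                  exclude: tuple[str, ...] = ()) -> str:
    pi = SubstModel(equilibrium_gc=gc).frequencies()
    while True:
        codon = _decode(rng.choice(4, size=3, p=pi))
        if codon in STOP_CODONS or codon in exclude:
            continue
        return codon


_STOP_CODES = np.sort(np.array(
    [16 * BASE_INDEX[c[0]] + 4 * BASE_INDEX[c[1]] + BASE_INDEX[c[2]]
     for c in STOP_CODONS]))


def _codon_codes(arr: np.ndarray) -> np.ndarray:
    return (16 * arr[0::3].astype(np.int32) + 4 * arr[1::3] + arr[2::3])


def random_cds(n_codons: int, gc: float, rng: np.random.Generator) -> str:
    """Random in-frame CDS: ATG + sense codons + stop (length 3*n_codons)."""
    if n_codons < 3:
        raise ValueError("CDS needs at least start, one codon, and stop")
    pi = SubstModel(equilibrium_gc=gc).frequencies()
    body = rng.choice(4, size=3 * (n_codons - 2), p=pi).astype(np.int8)
    while True:
        bad = np.isin(_codon_codes(body), _STOP_CODES)
        if not bad.any():
            break
        pos = np.repeat(bad, 3)
        body[pos] = rng.choice(4, size=int(pos.sum()), p=pi).astype(np.int8)
    stops = sorted(STOP_CODONS)
    stop = stops[int(rng.integers(len(stops)))]
    return "ATG" + _decode(body) + stop


_ALIPHATIC_CODONS = tuple(sorted(c for c, aa in CODON_AA.items()
                                 if aa in set("ILMVST") and c != "ATG"))
_CYS_CODONS = ("TGC", "TGT")


def make_pheromone_gene(spacer_len: int, seed: int, gc: float = 0.5) -> str:
    """CDS of a pheromone precursor matching the consensus
    M-X(15..60)-C-[ILMVST]-[ILMVST]-X-Stop. Spacer codons avoid ATG and
    stops so the precursor contains a single in-frame ORF."""
    if not 15 <= spacer_len <= 60:
        raise ValueError("spacer length must be in [15, 60]")
    rng = np.random.default_rng(seed)
    spacer = [_random_codon(gc, rng, exclude=("ATG",)) for _ in range(spacer_len)]
    cys = _CYS_CODONS[int(rng.integers(2))]
    ali = [_ALIPHATIC_CODONS[int(rng.integers(len(_ALIPHATIC_CODONS)))]
           for _ in range(2)]
    x = _random_codon(gc, rng, exclude=("ATG",))
    stop = sorted(STOP_CODONS)[int(rng.integers(3))]
    return "ATG" + "".join(spacer) + cys + ali[0] + ali[1] + x + stop


# Constraint fixers: applied after each branch so evolved CDS stay in frame
# (substitution-only process; a mutation violating a constraint is reverted).


def cds_fixer(child: np.ndarray, parent: np.ndarray) -> np.ndarray:
    out = child.copy()
    codes = _codon_codes(out)
    n = len(codes)
    revert = np.zeros(n, dtype=bool)
    revert[0] = True  # start codon preserved
    revert[:-1] |= np.isin(codes[:-1], _STOP_CODES)  # no internal stops
    if codes[-1] not in _STOP_CODES:
        revert[-1] = True  # terminal stop preserved
    pos = np.repeat(revert, 3)
    out[pos] = parent[pos]
    return out


def pheromone_fixer(child: np.ndarray, parent: np.ndarray) -> np.ndarray:
    out = cds_fixer(child, parent)
    n = len(out) // 3

    def codon(k: int) -> str:
        return _decode(out[3 * k: 3 * k + 3])

    for k in range(1, n - 1):
        c = codon(k)
        revert = False
        if c == "ATG":
            revert = True  # keep a single in-frame start
        if k == n - 5 and CODON_AA.get(c) != "C":
            revert = True
        if k in (n - 4, n - 3) and CODON_AA.get(c) not in set("ILMVST"):
            revert = True
        if revert:
            out[3 * k: 3 * k + 3] = parent[3 * k: 3 * k + 3]
    return out


# ---------------------------------------------------------------------------
# Simulation configuration and truth


@dataclass
class SimConfig:
    """Study conditions for a simulated strain panel (defaults are the
    conditions the analyses are designed for)."""

    n_species: int = 3
    strains_per_species: Union[Sequence[str], Sequence[Sequence[str]]] = ("A1", "A2")
    tree_height: float = 0.15
    min_species_split: float = 0.05
    strain_depth: float = 0.025
    ste3_allele_depth: float = 0.5
    mat_suppression_extra: float = 0.02
    background_gc: float = 0.60
    mat_gc: float = 0.52  # background - 0.08, mirroring the observed depression
    kappa: float = 2.0
    inversion_segments: tuple[tuple[int, int], ...] = ((2, 17), (19, 21))
    gene_len_range: tuple[int, int] = (900, 2400)
    gap_range: tuple[int, int] = (200, 1800)
    n_filler: int = 15
    mf_spacer: Optional[int] = None  # None: drawn uniformly in [15, 60]
    flank_genes: int = 2
    background_contigs: int = 2
    background_genes_per_contig: int = 10
    homogenize_inversions: bool = False
    breakpoint_extra: float = 0.05
    seed: int = 0

    def strain_classes(self) -> list[list[str]]:
        value = self.strains_per_species
        if value and isinstance(value[0], str):
            per = [list(value)] * self.n_species
        else:
            if len(value) != self.n_species:
                raise ValueError("strains_per_species list-of-lists must have "
                                 "one entry per species")
            per = [list(s) for s in value]
        for classes in per:
            for cls in classes:
                if cls not in ALLELE_CLASSES:
                    raise ValueError(f"unknown allele class {cls!r}")
        return per

    def validate(self) -> None:
        if not 0.0 < self.background_gc < 1.0 or not 0.0 < self.mat_gc < 1.0:
            raise ValueError("GC fractions must be in (0, 1)")
        if self.ste3_allele_depth <= self.tree_height:
            raise ValueError("ste3_allele_depth must exceed tree_height for "
                             "trans-specific STE3 alleles")
        if not 0 <= self.min_species_split < self.tree_height:
            raise ValueError("min_species_split must be in [0, tree_height)")
        self.strain_classes()


@dataclass
class StrainTruth:
    strain_id: str
    species: str
    allele_class: str
    mat_contig: str
    core_span: tuple[int, int]
    genes: list[dict]  # gene_id, key, role, contig, start, end, strand
    breakpoints: list[tuple[int, int]]


@dataclass
class SimTruth:
    species_newick: str
    config: dict
    template: list[dict]
    inversion_segments: list[tuple[int, int]]
    strains: list[StrainTruth]

    def strain(self, strain_id: str) -> StrainTruth:
        return next(s for s in self.strains if s.strain_id == strain_id)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        raw = json.loads(text)
        strains = [StrainTruth(
            strain_id=s["strain_id"], species=s["species"],
            allele_class=s["allele_class"], mat_contig=s["mat_contig"],
            core_span=tuple(s["core_span"]),
            genes=s["genes"],
            breakpoints=[tuple(b) for b in s["breakpoints"]],
        ) for s in raw["strains"]]
        return cls(raw["species_newick"], raw["config"],
                   raw["template"],
                   [tuple(seg) for seg in raw["inversion_segments"]], strains)


@dataclass
class SimulatedDataset:
    truth: SimTruth
    assemblies: dict[str, SequenceSet]
    annotations: dict[str, Annotation]
    panel: SequenceSet  # protein references with role= (and class=) tags
    ortholog_cds: dict[str, dict[str, Optional[str]]]  # key -> strain -> CDS

    @property
    def strains(self) -> list[str]:
        return [s.strain_id for s in self.truth.strains]

    def write(self, outdir: Union[str, Path]) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for strain in self.strains:
            (out / f"{strain}.fa").write_text(write_fasta(self.assemblies[strain]))
            (out / f"{strain}.gff3").write_text(write_gff3(self.annotations[strain]))
        (out / "panel.fa").write_text(write_fasta(self.panel))
        (out / "truth.json").write_text(self.truth.to_json())
        (out / "seed_manifest.json").write_text(
            json.dumps({"seed": self.truth.config["seed"]}) + "\n")


# ---------------------------------------------------------------------------
# Dataset simulation


def _evolve_tree_tips(root_arr: np.ndarray, tree: dendropy.Tree,
                      model: SubstModel, rng: np.random.Generator,
                      fixer: Optional[Callable] = None) -> dict[str, np.ndarray]:
    tips: dict[str, np.ndarray] = {}

    def branch(state: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return state.copy()
        child = _evolve_branch(state, model, t, rng)
        return fixer(child, state) if fixer else child

    def descend(node: dendropy.Node, state: np.ndarray) -> None:
        for child in node.child_nodes():
            cs = branch(state, child.edge.length or 0.0)
            if child.is_leaf():
                tips[child.taxon.label] = cs
            else:
                descend(child, cs)

    descend(tree.seed_node, root_arr)
    return tips


def _strain_ids(per_species: list[list[str]]) -> list[tuple[str, str, str]]:
    """(strain_id, species, allele_class) triples."""
    out = []
    for i, classes in enumerate(per_species, start=1):
        for j, cls in enumerate(classes, start=1):
            out.append((f"sp{i}s{j}", f"sp{i}", cls))
    return out


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate per-strain assemblies + annotations, a MAT protein reference
    panel, and the complete truth record."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    per_species = config.strain_classes()
    strains = _strain_ids(per_species)

    tree = simulate_species_tree(config.n_species,
                                 seed=int(rng.integers(2**30)),
                                 height=config.tree_height,
                                 min_split=config.min_species_split)
    mat_model = SubstModel(config.mat_gc, config.kappa)
    bg_model = SubstModel(config.background_gc, config.kappa)

    mf_spacer = (config.mf_spacer if config.mf_spacer is not None
                 else int(rng.integers(15, 61)))
    template = default_template(rng, config.gene_len_range,
                                n_filler=config.n_filler, mf_spacer=mf_spacer)
    segments = tuple(config.inversion_segments)
    apply_inversions(template, segments)  # validates segments

    # which genes get between-class extra divergence, and how much
    def class_extra(idx: int) -> float:
        base = config.mat_suppression_extra
        if base <= 0:
            return 0.0
        if not config.homogenize_inversions:
            return base
        near_breakpoint = any(
            idx in (a - 1, a, b, b + 1) for a, b in segments)
        inside = any(a < idx < b for a, b in segments)
        if near_breakpoint:
            return config.breakpoint_extra
        if inside:
            return 0.0
        return base

    def evolve_gene(root_cds: str, model: SubstModel, extra: float,
                    fixer: Optional[Callable], carriers=None) -> dict[str, str]:
        """Evolve one ortholog family down the species tree to all (carrier)
        strains; ``extra`` is split between the two mating-type classes of a
        species so only between-class divergence is inflated."""
        root_arr = _encode(root_cds)
        tips = _evolve_tree_tips(root_arr, tree, model, rng, fixer)
        out: dict[str, str] = {}
        for i, classes in enumerate(per_species, start=1):
            species = f"sp{i}"
            class_seq: dict[str, np.ndarray] = {}
            for j, cls in enumerate(classes, start=1):
                sid = f"sp{i}s{j}"
                if carriers is not None and sid not in carriers:
                    continue
                mating_side = STE3_OF_CLASS[cls]
                if mating_side not in class_seq:
                    base = tips[species]
                    if extra > 0:
                        ev = _evolve_branch(base, model, extra / 2, rng)
                        base = fixer(ev, base) if fixer else ev
                    class_seq[mating_side] = base
                anc = class_seq[mating_side]
                ev = _evolve_branch(anc, model, config.strain_depth, rng)
                out[sid] = _decode(fixer(ev, anc) if fixer else ev)
        return out

    lo_c, hi_c = config.gene_len_range[0] // 3, config.gene_len_range[1] // 3

    # --- core MAT ortholog families -------------------------------------
    ortholog_cds: dict[str, dict[str, Optional[str]]] = {}
    roots: dict[str, str] = {}
    panel_records: list[Record] = []

    carriers_of_hd = {
        "SXI1": {sid for sid, _, cls in strains if HD_OF_CLASS[cls] == "SXI1"},
        "SXI2": {sid for sid, _, cls in strains if HD_OF_CLASS[cls] == "SXI2"},
    }

    core_seqs: dict[str, dict[str, str]] = {}
    for idx, gene in enumerate(template):
        extra = class_extra(idx)
        if gene.role == "MF":
            root_cds = make_pheromone_gene(mf_spacer,
                                           seed=int(rng.integers(2**31)),
                                           gc=config.mat_gc)
            core_seqs[gene.key] = evolve_gene(root_cds, mat_model, extra,
                                              pheromone_fixer)
            roots["MF"] = root_cds
        elif gene.role == "STE3":
            root_cds = random_cds(gene.length_nt // 3, config.mat_gc, rng)
            # evolve the two ancestral alleles and keep them for the panel
            stem = config.ste3_allele_depth - config.tree_height
            allele_roots = {}
            root_arr = _encode(root_cds)
            for allele in ("a", "alpha"):
                anc = _evolve_branch(root_arr, mat_model, stem, rng)
                allele_roots[allele] = _decode(cds_fixer(anc, root_arr))
            tip_sets = {
                al: _evolve_tree_tips(_encode(allele_roots[al]), tree,
                                      mat_model, rng, cds_fixer)
                for al in ("a", "alpha")
            }
            seqs: dict[str, str] = {}
            for i, classes in enumerate(per_species, start=1):
                for j, cls in enumerate(classes, start=1):
                    sid = f"sp{i}s{j}"
                    base = tip_sets[STE3_OF_CLASS[cls]][f"sp{i}"]
                    if extra > 0:
                        ev = _evolve_branch(base, mat_model, extra / 2, rng)
                        base = cds_fixer(ev, base)
                    ev = _evolve_branch(base, mat_model, config.strain_depth,
                                        rng)
                    seqs[sid] = _decode(cds_fixer(ev, base))
            core_seqs[gene.key] = seqs
            roots["STE3a"] = allele_roots["a"]
            roots["STE3alpha"] = allele_roots["alpha"]
        elif gene.role == "HD":
            for hd_role in ("SXI1", "SXI2"):
                root_cds = random_cds(gene.length_nt // 3, config.mat_gc, rng)
                roots[hd_role] = root_cds
                seqs = evolve_gene(root_cds, mat_model, extra, cds_fixer,
                                   carriers=carriers_of_hd[hd_role])
                core_seqs[f"{gene.key}_{hd_role}"] = seqs
        else:
            root_cds = random_cds(gene.length_nt // 3, config.mat_gc, rng)
            if gene.role:
                roots[gene.role] = root_cds
            core_seqs[gene.key] = evolve_gene(root_cds, mat_model, extra,
                                              cds_fixer)

    # intergenic gaps of the core region (evolved, shared layout)
    gap_lengths = [int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
                   for _ in range(len(template) + 1)]
    gap_seqs = []
    for L in gap_lengths:
        root_gap = random_sequence(L, config.mat_gc, rng)
        gap_seqs.append(evolve_gene(root_gap, mat_model, 0.0, None))

    # --- flank + background genes ---------------------------------------
    flank_seqs: dict[str, dict[str, str]] = {}
    flank_keys = ([f"fL{i}" for i in range(config.flank_genes)],
                  [f"fR{i}" for i in range(config.flank_genes)])
    for key in flank_keys[0] + flank_keys[1]:
        root_cds = random_cds(int(rng.integers(lo_c, hi_c + 1)),
                              config.background_gc, rng)
        flank_seqs[key] = evolve_gene(root_cds, bg_model, 0.0, cds_fixer)
    flank_gap_seqs = []
    for _ in range(2 * config.flank_genes + 2):
        L = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
        flank_gap_seqs.append(
            evolve_gene(random_sequence(L, config.background_gc, rng),
                        bg_model, 0.0, None))

    bg_contig_layouts: list[list[tuple[str, dict[str, str], Optional[str]]]] = []
    for c in range(config.background_contigs):
        layout = []
        for k in range(config.background_genes_per_contig):
            L = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
            layout.append((f"bgap{c}_{k}",
                           evolve_gene(random_sequence(L, config.background_gc,
                                                       rng),
                                       bg_model, 0.0, None), None))
            key = f"b{c}_{k}"
            root_cds = random_cds(int(rng.integers(lo_c, hi_c + 1)),
                                  config.background_gc, rng)
            layout.append((key, evolve_gene(root_cds, bg_model, 0.0, cds_fixer),
                           "gene"))
        L = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
        layout.append((f"bgap{c}_end",
                       evolve_gene(random_sequence(L, config.background_gc, rng),
                                   bg_model, 0.0, None), None))
        bg_contig_layouts.append(layout)

    # --- per-strain assembly --------------------------------------------
    assemblies: dict[str, SequenceSet] = {}
    annotations: dict[str, Annotation] = {}
    truth_strains: list[StrainTruth] = []

    for sid, species, cls in strains:
        inverted = cls in ("A2", "A2*")
        hd_role = HD_OF_CLASS[cls]

        # core block list in this strain's orientation: for inverted classes
        # interior gaps travel with their segment (reverse-complemented)
        items: list[tuple[str, object, bool]] = []  # kind, ref, flipped
        items.append(("gap", 0, False))
        for idx, gene in enumerate(template):
            items.append(("gene", idx, False))
            items.append(("gap", idx + 1, False))
        if inverted:
            for a, b in sorted(segments, reverse=True):
                # positions in `items`: gene idx i sits at 2i+1; include
                # interior gaps (between a and b) but not the boundary gaps
                p, q = 2 * a + 1, 2 * b + 1
                seg = items[p:q + 1]
                items[p:q + 1] = [(k, r, not f) for (k, r, f) in reversed(seg)]

        contig_parts: list[str] = []
        gene_truth: list[dict] = []
        pos = 0
        mat_contig = f"{sid}_mat"

        def add_gap(seqs: dict[str, str], flipped: bool) -> None:
            nonlocal pos
            s = seqs[sid]
            contig_parts.append(revcomp(s) if flipped else s)
            pos += len(s)

        def add_gene(key: str, role_label: Optional[str], strand: str,
                     seqs: dict[str, str], flipped: bool, contig: str,
                     template_key: Optional[str] = None) -> None:
            nonlocal pos
            cds = seqs[sid]
            final_strand = ("-" if strand == "+" else "+") if flipped else strand
            contig_parts.append(revcomp(cds) if final_strand == "-" else cds)
            gene_truth.append({
                "gene_id": f"{sid}_{key}", "key": template_key or key,
                "role": role_label, "contig": contig,
                "start": pos, "end": pos + len(cds), "strand": final_strand,
            })
            pos += len(cds)

        # left flank
        for i, key in enumerate(flank_keys[0]):
            add_gap(flank_gap_seqs[i], False)
            add_gene(key, None, "+", flank_seqs[key], False, mat_contig)
        # core
        for kind, ref, flipped in items:
            if kind == "gap":
                add_gap(gap_seqs[ref], flipped)
            else:
                gene = template[ref]
                if gene.role == "HD":
                    seqs = core_seqs[f"{gene.key}_{hd_role}"]
                    add_gene(gene.key, hd_role, gene.strand, seqs, flipped,
                             mat_contig, template_key=gene.key)
                else:
                    add_gene(gene.key, gene.role, gene.strand,
                             core_seqs[gene.key], flipped, mat_contig,
                             template_key=gene.key)
        # right flank
        for i, key in enumerate(flank_keys[1]):
            add_gap(flank_gap_seqs[config.flank_genes + i], False)
            add_gene(key, None, "+", flank_seqs[key], False, mat_contig)
        add_gap(flank_gap_seqs[-1], False)

        contigs = [Record(mat_contig, "".join(contig_parts))]

        for c, layout in enumerate(bg_contig_layouts):
            bg_name = f"{sid}_bg{c}"
            parts: list[str] = []
            pos = 0
            for key, seqs, kind in layout:
                s = seqs[sid]
                if kind == "gene":
                    gene_truth.append({
                        "gene_id": f"{sid}_{key}", "key": key, "role": None,
                        "contig": bg_name, "start": pos, "end": pos + len(s),
                        "strand": "+" if pos % 2 == 0 else "-",
                    })
                    parts.append(s if gene_truth[-1]["strand"] == "+"
                                 else revcomp(s))
                else:
                    parts.append(s)
                pos += len(s)
            contigs.append(Record(bg_name, "".join(parts)))

        assembly = SequenceSet(contigs, alphabet="nt")
        genes = [
            GeneModel(
                gene_id=g["gene_id"], contig=g["contig"], start=g["start"],
                end=g["end"], strand=g["strand"],
                cds_parts=[(g["start"], g["end"])],
                product=(g["role"] or "hypothetical protein"),
            )
            for g in gene_truth
        ]
        annotation = Annotation(genome_id=sid, genes=genes)
        assemblies[sid] = assembly
        annotations[sid] = annotation

        core_genes = [g for g in gene_truth if g["key"].startswith("g")]
        core_span = (min(g["start"] for g in core_genes),
                     max(g["end"] for g in core_genes))
        breakpoints: list[tuple[int, int]] = []
        if not inverted:
            by_idx = {int(g["key"][1:]): g for g in core_genes}
            edges = set()
            for a, b in segments:
                edges.add((a - 1, a))
                edges.add((b, b + 1))
            for left, right in sorted(edges):
                if left < 0 or right >= len(template):
                    continue
                breakpoints.append((by_idx[left]["end"], by_idx[right]["start"]))
        truth_strains.append(StrainTruth(
            strain_id=sid, species=species, allele_class=cls,
            mat_contig=mat_contig, core_span=core_span, genes=gene_truth,
            breakpoints=breakpoints))

    # --- ortholog CDS map (truth alignments for divergence analyses) -----
    for idx, gene in enumerate(template):
        if gene.role == "HD":
            merged: dict[str, Optional[str]] = {}
            for sid, _, cls in strains:
                merged[sid] = core_seqs[f"{gene.key}_{HD_OF_CLASS[cls]}"].get(sid)
            ortholog_cds[gene.key] = merged
        else:
            ortholog_cds[gene.key] = dict(core_seqs[gene.key])
    for key, seqs in flank_seqs.items():
        ortholog_cds[key] = dict(seqs)
    for layout in bg_contig_layouts:
        for key, seqs, kind in layout:
            if kind == "gene":
                ortholog_cds[key] = dict(seqs)

    # --- reference panel -------------------------------------------------
    from ._genetics import translate

    def prot(cds: str) -> str:
        pep = translate(cds)
        return pep[:-1] if pep.endswith("*") else pep

    for role in ("MF", "STE20", "IKS1", "STE11", "MYO2", "RPL22",
                 "SXI1", "SXI2"):
        if role in roots:
            panel_records.append(Record(f"ref_{role}", prot(roots[role]),
                                        f"role={role}"))
    panel_records.append(Record("ref_STE3a", prot(roots["STE3a"]),
                                "role=STE3 class=a"))
    panel_records.append(Record("ref_STE3alpha", prot(roots["STE3alpha"]),
                                "role=STE3 class=alpha"))
    panel = SequenceSet(panel_records, alphabet="aa")

    truth = SimTruth(
        species_newick=write_newick(tree),
        config=dataclasses.asdict(config),
        template=[dataclasses.asdict(g) for g in template],
        inversion_segments=[tuple(s) for s in segments],
        strains=truth_strains,
    )
    return SimulatedDataset(truth, assemblies, annotations, panel, ortholog_cds)
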
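"""Per-gene genealogies and the trans-species polymorphism test.

A gene inside a recombining region produces a tree in which alleles group by
species; a gene whose alleles stopped recombining before speciation (the MAT
signature, classically the STE3 pheromone receptor) produces a tree with one
clade per mating type across species — a trans-species polymorphism. Trees
are built by neighbor joining on p- or Jukes-Cantor distances, and the
pattern is read off the tree's bipartitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


import dendropy
import numpy as np


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    model: str  # "p" | "JC"
    undefined: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        assert self.d.shape == (len(self.labels), len(self.labels))


def pairwise_distances(sequences: dict[str, str],
                       model: str = "JC") -> DistanceMatrix:
    """p- or JC-corrected distances between aligned sequences; columns with
    a gap or ambiguity code in either member of a pair are deleted pairwise.
    JC distance is undefined (flagged) when p >= 3/4."""
    if model not in ("p", "JC"):
        raise ValueError("model must be 'p' or 'JC'")
    labels = sorted(sequences)
    arrs = {}
    length = None
    for lab in labels:
        seq = sequences[lab].upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError("aligned sequences must have equal length")
        arrs[lab] = np.frombuffer(seq.encode(), dtype="S1")
    valid_chars = np.frombuffer(b"ACGT", dtype="S1")
    valid = {lab: np.isin(arrs[lab], valid_chars) for lab in labels}
    n = len(labels)
    d = np.zeros((n, n))
    undefined: set[tuple[str, str]] = set()
    for i, j in itertools.combinations(range(n), 2):
        a, b = labels[i], labels[j]
        mask = valid[a] & valid[b]
        compared = int(mask.sum())
        if compared == 0:
            d[i, j] = d[j, i] = np.nan
            undefined.add((a, b))
            continue
        p = float((arrs[a][mask] != arrs[b][mask]).sum()) / compared
        if model == "p":
            dist = p
        else:
            arg = 1.0 - (4.0 / 3.0) * p
            if arg <= 0.0:
                d[i, j] = d[j, i] = np.nan
                undefined.add((a, b))
                continue
            dist = -0.75 * float(np.log(arg))
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d, model, undefined)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken by the lexicographically smallest label pair;
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch. The result is an unrooted tree (trifurcation at the
    seed node)."""
    if dm.undefined:
        pair = sorted(dm.undefined)[0]
        raise ValueError(f"undefined distance between {pair[0]} and {pair[1]}")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[str, dendropy.Node] = {}
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[lab] = node

    active = list(dm.labels)
    dist = {(a, b): float(dm.d[dm.labels.index(a), dm.labels.index(b)])
            for a, b in itertools.combinations(dm.labels, 2)}

    def get(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    next_id = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * get(a, b) - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        la = 0.5 * get(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = get(a, b) - la
        # clamp negatives, moving the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        new_label = f"__internal_{next_id}"
        next_id += 1
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[(new_label, c)] = 0.5 * (get(a, c) + get(b, c) - get(a, b))
        active = [c for c in active if c not in (a, b)] + [new_label]

    a, b = active
    root = dendropy.Node()
    final = get(a, b)
    # distribute the last distance; tips keep non-negative lengths
    if nodes[a].is_leaf() and nodes[b].is_leaf():
        nodes[a].edge.length = final / 2.0
        nodes[b].edge.length = final / 2.0
    elif nodes[b].is_leaf():
        nodes[a].edge.length = 0.0
        nodes[b].edge.length = max(final, 0.0)
    else:
        nodes[a].edge.length = max(final, 0.0)
        nodes[b].edge.length = 0.0
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    tree.seed_node = root
    tree.is_rooted = False
    # collapse the artificial root bifurcation into a trifurcation when the
    # deeper side is internal, so path lengths are preserved
    deeper = nodes[a] if not nodes[a].is_leaf() else (
        nodes[b] if not nodes[b].is_leaf() else None)
    if deeper is not None:
        other = nodes[b] if deeper is nodes[a] else nodes[a]
        span = (nodes[a].edge.length or 0.0) + (nodes[b].edge.length or 0.0)
        for child in list(deeper.child_nodes()):
            deeper.remove_child(child)
            root.add_child(child)
        root.remove_child(deeper)
        other.edge.length = span
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def tree_path_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    tx = tree.taxon_namespace
    return float(pdm.distance(tx.get_taxon(a), tx.get_taxon(b)))


@dataclass
class ClusterPattern:
    kind: str  # "mating_type" | "species" | "mixed"
    supporting: list[frozenset] = field(default_factory=list)


def _tip_splits(tree: dendropy.Tree) -> list[frozenset]:
    """All non-trivial bipartition sides (as tip-label sets) of an unrooted
    tree; invariant to rooting and tip order."""
    all_tips = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label
                         for leaf in node.leaf_iter())
        if 1 < len(side) < len(all_tips):
            splits.add(side)
            splits.add(all_tips - side)
    return sorted(splits, key=lambda s: (len(s), sorted(s)))


def classify_clustering(
    tree: dendropy.Tree,
    labels: dict[str, tuple[str, str]],  # tip -> (species, allele_class)
) -> ClusterPattern:
    """Classify a gene tree as clustering by mating type (trans-species
    polymorphism), by species, or mixed.

    mating_type: some bipartition separates exactly the A1-class tips from
    the A2-class tips. species: no such bipartition, and every species with
    more than one tip is separated from all other tips by some bipartition.
    Anything else is mixed."""
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in labels]
    if missing:
        raise ValueError(f"unlabeled tips: {missing}")
    classes = {labels[t][1] for t in tips}
    if len(classes) < 2:
        raise ValueError("both allele classes must be present")
    splits = _tip_splits(tree)
    class_sets = {cls: frozenset(t for t in tips if labels[t][1] == cls)
                  for cls in classes}
    for cls, cset in sorted(class_sets.items()):
        if len(cset) == 0:
            raise ValueError(f"allele class {cls} has zero tips")
        # a pendant edge trivially separates a single-tip class
        trivially_separated = 1 in (len(cset), len(tips) - len(cset))
        if cset in splits or trivially_separated:
            return ClusterPattern("mating_type", [cset])
    species_sets = {}
    for t in tips:
        species_sets.setdefault(labels[t][0], set()).add(t)
    supporting = []
    for sp, members in species_sets.items():
        members = frozenset(members)
        if len(members) == 1:
            continue
        if members not in splits and len(members) != len(tips):
            return ClusterPattern("mixed")
        supporting.append(members)
    return ClusterPattern("species", supporting)
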
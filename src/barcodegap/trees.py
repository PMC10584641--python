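"""Tree-based marker evaluation and tree plumbing.

Trees are carried as :class:`dendropy.Tree` objects throughout.  This
module provides newick I/O, a neighbor-joining builder (so the pipeline
can run end-to-end when no externally inferred tree is supplied),
monophyly scoring per species label, the class-1/2/3 clustering audit,
and simple clock projections (UPGMA, mean-path-length) that produce the
ultrametric input required by GMYC.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
from dataclasses import dataclass
from scipy.cluster import hierarchy

from .distances import DistanceMatrix, OK

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- newick I/O

def read_newick(path) -> dendropy.Tree:
    """Read a newick tree; internal-node labels are kept (supports)."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def parse_newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=s,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        preserve_spaces=True,
        suppress_rooting=True,
    )


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", preserve_spaces=True, suppress_rooting=True
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_support(node) -> float | None:
    """Support value parsed from an internal node's label, if any.

    Values above 1 are interpreted as percentages.
    """
    if node.label is None:
        return None
    try:
        v = float(node.label)
    except ValueError:
        return None
    return v / 100.0 if v > 1.0 else v


def bipartition_set(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of tip labels.

    Canonical form: the side NOT containing the lexicographically first
    tip label, so rooted and unrooted representations compare equal.
    """
    labels = sorted(tip_labels(tree))
    ref = labels[0]
    all_set = frozenset(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(labels) - 1:
            continue
        if ref in side:
            side = all_set - side
        out.add(side)
    return out


# ------------------------------------------------------------ rooting helpers

def root_with_outgroup(tree: dendropy.Tree, outgroup: list[str]) -> dendropy.Tree:
    """Root on the midpoint of the edge subtending the outgroup.

    Falls back to midpoint rooting (with a log note) when no outgroup is
    given.
    """
    tree = tree.clone(depth=1)
    if not outgroup:
        log.info("no outgroup supplied; midpoint rooting")
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.is_rooted = True
        return tree
    taxa = [tree.taxon_namespace.get_taxon(l) for l in outgroup]
    if any(t is None for t in taxa):
        missing = [l for l, t in zip(outgroup, taxa) if t is None]
        raise ValueError(f"outgroup tips not in tree: {missing}")
    if len(taxa) == 1:
        node = tree.find_node_with_taxon_label(outgroup[0])
    else:
        node = tree.mrca(taxa=taxa)
    edge = node.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ------------------------------------------------------------ neighbor joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a fully defined distance matrix.

    Standard Saitou-Nei agglomeration.  Negative branch-length estimates
    are clamped to zero with the deficit moved to the sister branch, so
    additive matrices are recovered exactly and path lengths are preserved.
    The result is unrooted (trifurcating root node).
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    undef = [
        (dm.labels[i], dm.labels[j])
        for i in range(dm.n)
        for j in range(i + 1, dm.n)
        if dm.flags[i, j] != OK
    ]
    if undef:
        raise ValueError(f"undefined distances for pairs: {undef[:10]}")

    taxon_ns = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for label in dm.labels:
        nd = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(nd)
    D = dm.values.copy().astype(float)
    active = list(range(dm.n))

    def clamp(li, lj):
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return li, lj

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(lj)
        # reuse slot i for the new node
        new_d = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = new_d
        D[active, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = float(max(ln, 0.0))
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------- monophyly

@dataclass(frozen=True)
class MonophylyReport:
    monophyletic: dict  # species -> bool
    n_species_evaluated: int
    fraction_monophyletic: float


def _species_tip_map(tree, species_of, exclude: set[str]):
    groups: dict[str, list] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in exclude:
            continue
        sp = species_of.get(label)
        if sp is None:
            raise ValueError(f"tip {label!r} has no species label")
        groups.setdefault(sp, []).append(leaf)
    return groups


def monophyly_fraction(
    tree: dendropy.Tree,
    species_of: dict,
    outgroup: list[str] | None = None,
    singleton_policy: str = "monophyletic",
) -> MonophylyReport:
    """Fraction of species whose tips form exclusive clades.

    A species is monophyletic when the MRCA of its tips contains no other
    species' tips.  Singletons cannot be paraphyletic; they count as
    monophyletic by default or can be ``excluded``.
    """
    if singleton_policy not in ("monophyletic", "excluded"):
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    if not tree.is_rooted or outgroup:
        tree = root_with_outgroup(tree, outgroup or [])
    exclude = set(outgroup or [])
    groups = _species_tip_map(tree, species_of, exclude)
    verdicts = {}
    for sp, leaves in groups.items():
        if len(leaves) == 1:
            if singleton_policy == "excluded":
                continue
            verdicts[sp] = True
            continue
        mrca = tree.mrca(taxa=[l.taxon for l in leaves])
        clade_size = sum(1 for _ in mrca.leaf_iter())
        verdicts[sp] = clade_size == len(leaves)
    n_eval = len(verdicts)
    frac = sum(verdicts.values()) / n_eval if n_eval else 0.0
    return MonophylyReport(verdicts, n_eval, frac)


# ------------------------------------------------------------- class audit

@dataclass(frozen=True)
class ClassRecord:
    species: str
    clade_class: int  # 1, 2 or 3
    support_at_mrca: float | None
    clade_species: tuple[str, ...] = ()


def audit_classes(
    tree: dendropy.Tree,
    species_of: dict,
    support_threshold: float = 0.90,
    outgroup: list[str] | None = None,
) -> list[ClassRecord]:
    """Tree-based audit of species clustering.

    Class 1: the species is monophyletic and its MRCA is well supported
    (missing support values do not block class 1).
    Class 3: the species is not monophyletic but sits inside a cohesive
    clade that wholly contains two or more species — different names
    clustering together.
    Class 2: the species' sequences show no intraspecific clustering.
    """
    if not tree.is_rooted or outgroup:
        tree = root_with_outgroup(tree, outgroup or [])
    exclude = set(outgroup or [])
    groups = _species_tip_map(tree, species_of, exclude)
    tips_per_species = {sp: len(lv) for sp, lv in groups.items()}
    records = []
    for sp, leaves in groups.items():
        if len(leaves) == 1:
            mrca = leaves[0].parent_node or leaves[0]
        else:
            mrca = tree.mrca(taxa=[l.taxon for l in leaves])
        support = node_support(mrca) if not mrca.is_leaf() else None
        clade_tips = [l.taxon.label for l in mrca.leaf_iter()
                      if l.taxon.label not in exclude]
        clade_species_counts: dict[str, int] = {}
        for t in clade_tips:
            s = species_of[t]
            clade_species_counts[s] = clade_species_counts.get(s, 0) + 1
        mono = len(clade_species_counts) == 1
        if mono and (support is None or support >= support_threshold):
            records.append(ClassRecord(sp, 1, support, (sp,)))
        elif mono:
            records.append(ClassRecord(sp, 2, support, (sp,)))
        else:
            cohesive = mrca.parent_node is not None and all(
                clade_species_counts[s] == tips_per_species[s]
                for s in clade_species_counts
            )
            if cohesive:
                records.append(
                    ClassRecord(sp, 3, support,
                                tuple(sorted(clade_species_counts)))
                )
            else:
                records.append(ClassRecord(sp, 2, support, (sp,)))
    return records


# --------------------------------------------------------- clock projection

def _tree_from_linkage(Z, labels) -> dendropy.Tree:
    taxon_ns = dendropy.TaxonNamespace(labels)
    n = len(labels)
    nodes = {}
    heights = {}
    for i, label in enumerate(labels):
        nodes[i] = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        heights[i] = 0.0
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        parent = dendropy.Node()
        height = h / 2.0  # cophenetic distance -> node age
        for child in (a, b):
            parent.add_child(nodes[child])
            nodes[child].edge.length = max(height - heights[child], 0.0)
        nodes[n + k] = parent
        heights[n + k] = height
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = nodes[n + len(Z) - 1]
    tree.is_rooted = True
    return tree


def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average-linkage) ultrametric tree from distances."""
    undef = ~dm.defined_mask()
    np.fill_diagonal(undef, False)
    if undef.any():
        raise ValueError("UPGMA requires all pairwise distances defined")
    iu = np.triu_indices(dm.n, k=1)
    condensed = dm.values[iu]
    Z = hierarchy.average(condensed)
    return _tree_from_linkage(Z, dm.labels)


def mean_path_length_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Project a rooted tree onto a clock by mean root-to-tip path lengths.

    Each internal node's age becomes the mean path length to its
    descendant tips; ages are monotonized so parents are strictly older
    than children, then branch lengths are rewritten as age differences.
    Topology is preserved.
    """
    if not tree.is_rooted:
        raise ValueError("mean-path-length projection needs a rooted tree")
    tree = tree.clone(depth=1)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._mpl_age = 0.0
            node._mpl_ntips = 1
            continue
        total, ntips = 0.0, 0
        for ch in node.child_nodes():
            total += ch._mpl_ntips * (ch._mpl_age + (ch.edge.length or 0.0))
            ntips += ch._mpl_ntips
        age = total / ntips
        floor = max(ch._mpl_age for ch in node.child_nodes())
        node._mpl_age = max(age, floor + 1e-12)
        node._mpl_ntips = ntips
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            ch.edge.length = node._mpl_age - ch._mpl_age
    for node in tree.preorder_node_iter():
        if hasattr(node, "_mpl_age"):
            del node._mpl_age, node._mpl_ntips
    return tree


def make_ultrametric(source, method: str = "upgma_from_distances") -> dendropy.Tree:
    """Clock projection producing equal root-to-tip path lengths.

    ``upgma_from_distances`` takes a :class:`DistanceMatrix`;
    ``mean_path_length`` takes a rooted tree with branch lengths.
    """
    if method == "upgma_from_distances":
        if not isinstance(source, DistanceMatrix):
            raise TypeError("upgma_from_distances needs a DistanceMatrix")
        return upgma_tree(source)
    if method == "mean_path_length":
        if not isinstance(source, dendropy.Tree):
            raise TypeError("mean_path_length needs a dendropy.Tree")
        return mean_path_length_tree(source)
    raise ValueError(f"unknown method {method!r}")


def root_to_tip_spread(tree: dendropy.Tree) -> float:
    """Max minus min root-to-tip path length (0 for ultrametric trees)."""
    depths = []
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else (
            node.parent_node._depth + (node.edge.length or 0.0)
        )
        node._depth = d
        if node.is_leaf():
            depths.append(d)
    for node in tree.preorder_node_iter():
        del node._depth
    return max(depths) - min(depths)
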
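"""Synthetic multi-species barcode datasets with known ground truth.

Emulates the structure of repository barcode data: a Yule species tree
sets interspecific divergence, independent within-species Kingman
coalescents (scaled by theta) set intraspecific variation, sequences
evolve under the same K2P substitution process the analysis assumes
(transition excess controlled by kappa), partial reads appear as
contiguous terminal gap runs, and a controllable fraction of records
receives a wrong species label.  Everything is driven by a single seed;
identical seeds reproduce identical datasets byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .seqio import BarcodeAlignment, SequenceRecord
from . import trees as trees_mod

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 10
    tips_per_species: int | tuple = 10
    species_tree_depth: float = 0.2  # expected substitutions/site, root→tip
    birth_rate: float = 1.0
    theta: float = 0.005  # expected intraspecific pairwise divergence
    seq_length: int = 600
    kappa: float = 4.0  # transition/transversion rate ratio
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    mislabel_rate: float = 0.0
    gap_rate: float = 0.0  # expected fraction of terminal-gap cells
    min_split_frac: float = 0.0  # youngest speciation ≥ frac × depth
    marker: str = "other"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if not (0.0 <= self.mislabel_rate < 1.0):
            raise ValueError("mislabel_rate must be in [0, 1)")
        if not (0.0 <= self.gap_rate <= 0.2):
            raise ValueError("gap_rate must be in [0, 0.2]")
        for name in ("species_tree_depth", "birth_rate", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seq_length <= 0 or self.n_species < 1:
            raise ValueError("seq_length and n_species must be positive")


@dataclass
class SyntheticDataset:
    alignment: BarcodeAlignment
    truth: pd.DataFrame  # id, true_species, assigned_label, is_mislabeled
    species_tree: str  # newick
    gene_tree: str  # newick
    config: SimulationConfig

    @property
    def species_of_true(self) -> dict:
        return dict(zip(self.truth["id"], self.truth["true_species"]))


def species_name(i: int) -> str:
    return f"Clarias sp. {i + 1}"


# ------------------------------------------------------------- species tree

def simulate_species_tree(
    n_species: int,
    birth_rate: float,
    depth: float,
    rng: np.random.Generator,
    min_split_frac: float = 0.0,
    max_tries: int = 5000,
) -> dendropy.Tree:
    """Yule tree over ``n_species`` tips, scaled to the given depth.

    With ``min_split_frac > 0`` the tree is rejection-sampled until the
    youngest speciation is at least that fraction of the depth — the
    contract used by well-separated scenarios.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    names = [species_name(i) for i in range(n_species)]
    taxon_ns = dendropy.TaxonNamespace(names)
    if n_species == 1:
        tip = dendropy.Node(taxon=taxon_ns.get_taxon(names[0]))
        tip.edge.length = depth
        root = dendropy.Node()
        root.add_child(tip)
        tree = dendropy.Tree(taxon_namespace=taxon_ns)
        tree.seed_node = root
        tree.is_rooted = True
        return tree

    for _ in range(max_tries):
        # forward simulation: event times with k lineages ~ Exp(k * rate)
        times = [0.0]
        t = 0.0
        for k in range(2, n_species):
            t += rng.exponential(1.0 / (k * birth_rate))
            times.append(t)
        total = t + rng.exponential(1.0 / (n_species * birth_rate))
        scale = depth / total
        split_ages = [depth - tt * scale for tt in times]  # ages, oldest first
        if min_split_frac <= 0.0 or min(split_ages) >= min_split_frac * depth:
            break
    else:
        raise RuntimeError("could not satisfy min_split_frac; relax it")

    # grow the topology: each event splits a uniformly chosen active lineage
    root = dendropy.Node()
    active = []  # (node, start_time)
    for child_start in (0.0, 0.0):
        nd = dendropy.Node()
        root.add_child(nd)
        active.append((nd, child_start))
    for tt in times[1:]:
        idx = int(rng.integers(len(active)))
        node, start = active.pop(idx)
        node.edge.length = (tt - start) * scale
        kids = []
        for _ in range(2):
            nd = dendropy.Node()
            node.add_child(nd)
            kids.append((nd, tt))
        active.extend(kids)
    order = rng.permutation(len(active))
    for name_i, sl in enumerate(order):
        node, start = active[sl]
        node.edge.length = (total - start) * scale
        node.taxon = taxon_ns.get_taxon(names[name_i])
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------- gene tree

def _coalescent_subtree(tip_ids, theta, rng):
    """Kingman coalescent over the given tips.

    Time is in expected substitutions/site; with k lineages the waiting
    time is Exp(rate k(k-1)/theta), so the expected pairwise path length
    between two tips is theta.  Returns (root_node, root_age).
    """
    nodes = []
    for tid in tip_ids:
        nd = dendropy.Node()
        nd.taxon_label_tmp = tid
        nd.age_tmp = 0.0
        nodes.append(nd)
    age = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        age += rng.exponential(theta / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        for ch in (a, b):
            parent.add_child(ch)
            ch.edge.length = age - ch.age_tmp
        parent.age_tmp = age
        nodes.append(parent)
    return nodes[0], age


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    tips_per_species,
    theta: float,
    rng: np.random.Generator,
):
    """Graft within-species coalescents onto a species tree.

    ``tips_per_species`` is an int or a per-species list (species-tree
    leaf order).  Returns ``(gene_tree, species_of)`` where tips are
    labeled SEQ0001.. and ``species_of`` maps tip id to true species.
    A species' coalescent is rescaled (with a log note) in the rare case
    it would outreach its stem branch.
    """
    sp_leaves = list(species_tree.leaf_node_iter())
    if isinstance(tips_per_species, int):
        tips_per_species = [tips_per_species] * len(sp_leaves)
    if len(tips_per_species) != len(sp_leaves):
        raise ValueError(
            f"tips_per_species has {len(tips_per_species)} entries for "
            f"{len(sp_leaves)} species"
        )
    gtree = species_tree.clone(depth=1)
    g_leaves = list(gtree.leaf_node_iter())
    species_of = {}
    counter = 1
    all_names = []
    for leaf, m in zip(g_leaves, tips_per_species):
        sp = leaf.taxon.label
        if m < 1:
            raise ValueError("each species needs at least one tip")
        ids = [f"SEQ{counter + k:04d}" for k in range(m)]
        counter += m
        for tid in ids:
            species_of[tid] = sp
        all_names.extend(ids)
        stem = leaf.edge.length or 0.0
        if m == 1:
            leaf.taxon_label_new = ids[0]
            continue
        sub_root, height = _coalescent_subtree(ids, theta, rng)
        if height >= stem and stem > 0:
            factor = 0.9 * stem / height
            log.info("coalescent of %s rescaled by %.3f to fit its stem",
                     sp, factor)
            for nd in sub_root.preorder_iter():
                if nd.edge.length is not None:
                    nd.edge.length *= factor
            height *= factor
        leaf.taxon = None
        leaf.edge.length = stem - height
        for ch in sub_root.child_nodes():
            leaf.add_child(ch)
    new_ns = dendropy.TaxonNamespace(all_names)
    for leaf in gtree.leaf_node_iter():
        label = getattr(leaf, "taxon_label_new", None) or leaf.taxon_label_tmp
        leaf.taxon = new_ns.get_taxon(label)
    gtree.taxon_namespace = new_ns
    gtree.is_rooted = True
    return gtree, species_of


def simulate_two_rate_tree(
    n_species: int,
    tips_per_species: int,
    seed: int,
    between_mean: float = 1.0,
    within_mean: float = 0.01,
):
    """Tree whose branch lengths follow the two-exponential PTP model.

    A species/gene topology is simulated, then every branch length is
    redrawn: exponential with mean ``between_mean`` on the species
    backbone, ``within_mean`` inside species subtrees.  Returns
    ``(tree, true_partition)`` where the partition is a sorted tuple of
    sorted tip-label tuples.
    """
    rng = np.random.default_rng(seed)
    stree = simulate_species_tree(n_species, 1.0, 1.0, rng)
    gtree, species_of = simulate_gene_tree(stree, tips_per_species, 0.05,
                                           rng)
    sp_taxa: dict[str, list] = {}
    for leaf in gtree.leaf_node_iter():
        sp_taxa.setdefault(species_of[leaf.taxon.label], []).append(
            leaf.taxon
        )
    within_nodes = set()
    for taxa in sp_taxa.values():
        if len(taxa) > 1:
            mrca = gtree.mrca(taxa=taxa)
            for nd in mrca.preorder_iter():
                if nd is not mrca:
                    within_nodes.add(id(nd))
    for nd in gtree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        nd.edge.length = rng.exponential(
            within_mean if id(nd) in within_nodes else between_mean
        )
    true_partition = tuple(sorted(
        tuple(sorted(t.label for t in taxa)) for taxa in sp_taxa.values()
    ))
    return gtree, true_partition


def simulate_coalescent_tree(n_tips: int, theta: float,
                             rng: np.random.Generator) -> dendropy.Tree:
    """A single-population coalescent tree (no species structure)."""
    ids = [f"SEQ{k + 1:04d}" for k in range(n_tips)]
    ns = dendropy.TaxonNamespace(ids)
    root, _ = _coalescent_subtree(ids, theta, rng)
    for leaf in root.leaf_iter():
        leaf.taxon = ns.get_taxon(leaf.taxon_label_tmp)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ------------------------------------------------------- sequence evolution

def _k2p_probs(t: float, kappa: float):
    """(p_same, p_transition, p_each_transversion) after branch length t."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def _evolve_branch(seq, t, kappa, rng, site_rates=None):
    if t <= 0:
        return seq.copy()
    if site_rates is None:
        p_same, p_ts, _ = _k2p_probs(t, kappa)
        p_same = np.full(seq.shape, p_same)
        p_ts = np.full(seq.shape, p_ts)
    else:
        p_same, p_ts, _ = _k2p_probs(t * site_rates, kappa)
    u = rng.random(seq.shape)
    v = rng.random(seq.shape)
    out = seq.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    out[ts_mask] = seq[ts_mask] ^ 2  # A<->G, C<->T
    tv_mask = u >= p_same + p_ts
    flip = np.where(v < 0.5, 1, 3).astype(seq.dtype)
    out[tv_mask] = seq[tv_mask] ^ flip[tv_mask]
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    seq_length: int,
    kappa: float,
    base_freqs,
    rng: np.random.Generator,
    species_of: dict | None = None,
    marker: str = "other",
    site_rates=None,
) -> BarcodeAlignment:
    """Evolve sequences along a tree under the K2P substitution process.

    Branch lengths are expected substitutions/site; the root sequence is
    drawn from ``base_freqs``.  ``site_rates`` (optional, one multiplier
    per column) imposes among-site rate variation, e.g. an elevated third
    codon position.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if site_rates is not None:
        site_rates = np.asarray(site_rates, dtype=float)
        if site_rates.shape != (seq_length,):
            raise ValueError("site_rates must have one entry per column")
    root_seq = rng.choice(4, size=seq_length, p=freqs).astype(np.uint8)
    seqs = {}
    tree.seed_node.seq_tmp = root_seq
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.seq_tmp = _evolve_branch(
                node.parent_node.seq_tmp, node.edge.length or 0.0,
                kappa, rng, site_rates,
            )
        if node.is_leaf():
            seqs[node.taxon.label] = node.seq_tmp
    for node in tree.preorder_node_iter():
        del node.seq_tmp
    records = []
    for label in sorted(seqs):
        residues = "".join(_BASES[seqs[label]])
        sp = species_of.get(label, label) if species_of else label
        records.append(
            SequenceRecord(id=label, species=sp, residues=residues,
                           marker=marker)
        )
    return BarcodeAlignment(records=records, marker=marker)


def apply_terminal_gaps(aln: BarcodeAlignment, gap_rate: float,
                        rng: np.random.Generator) -> BarcodeAlignment:
    """Truncate reads: replace terminal runs with '-' (partial barcodes).

    Each record loses a Uniform(0, 2*gap_rate) fraction of its columns,
    split randomly between the 5' and 3' ends, so the expected gapped
    fraction is ``gap_rate``.
    """
    if gap_rate <= 0:
        return aln
    L = aln.length
    records = []
    for rec in aln.records:
        frac = rng.uniform(0.0, 2.0 * gap_rate)
        cut = int(round(frac * L))
        left = int(rng.integers(0, cut + 1))
        right = cut - left
        residues = (
            "-" * left + rec.residues[left : L - right] + "-" * right
            if cut
            else rec.residues
        )
        records.append(dataclasses.replace(rec, residues=residues))
    return BarcodeAlignment(records=records, marker=aln.marker)


# ----------------------------------------------------------------- mislabels

def inject_mislabels(records, mislabel_rate: float,
                     rng: np.random.Generator):
    """Swap species labels on a Bernoulli(rate) subset of records.

    A mislabeled record receives a uniformly chosen *different* species
    label.  Returns ``(new_records, truth)`` where truth is a DataFrame
    with id, true_species, assigned_label, is_mislabeled.
    """
    species = sorted({r.species for r in records})
    if mislabel_rate > 0 and len(species) < 2:
        raise ValueError("mislabeling needs at least 2 species")
    rows, out = [], []
    for rec in records:
        hit = bool(mislabel_rate > 0 and rng.random() < mislabel_rate)
        if hit:
            others = [s for s in species if s != rec.species]
            new_sp = others[int(rng.integers(len(others)))]
            out.append(dataclasses.replace(rec, species=new_sp))
        else:
            new_sp = rec.species
            out.append(rec)
        rows.append(
            {
                "id": rec.id,
                "true_species": rec.species,
                "assigned_label": new_sp,
                "is_mislabeled": hit,
            }
        )
    return out, pd.DataFrame(rows)


# ----------------------------------------------------------------- scenarios

def generate(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator for one configuration."""
    rng = np.random.default_rng(config.seed)
    stree = simulate_species_tree(
        config.n_species, config.birth_rate, config.species_tree_depth,
        rng, min_split_frac=config.min_split_frac,
    )
    tps = config.tips_per_species
    if not isinstance(tps, int):
        tps = list(tps)
    gtree, species_of = simulate_gene_tree(stree, tps, config.theta, rng)
    aln = evolve_sequences(
        gtree, config.seq_length, config.kappa, config.base_freqs, rng,
        species_of=species_of, marker=config.marker,
    )
    aln = apply_terminal_gaps(aln, config.gap_rate, rng)
    records, truth = inject_mislabels(aln.records, config.mislabel_rate, rng)
    aln = BarcodeAlignment(records=records, marker=config.marker)
    return SyntheticDataset(
        alignment=aln,
        truth=truth,
        species_tree=trees_mod.as_newick(stree),
        gene_tree=trees_mod.as_newick(gtree),
        config=config,
    )


SCENARIOS = {
    # positive-gap regime (Cytb-like): deep species tree, shallow coalescent
    "well_separated": dict(
        n_species=10, tips_per_species=10, species_tree_depth=0.2,
        theta=0.005, min_split_frac=0.15, marker="Cytb", gap_rate=0.02,
    ),
    # negative-gap regime (COI/D-loop-like): intra ≈ inter
    "overlapping": dict(
        n_species=10, tips_per_species=10, species_tree_depth=0.02,
        theta=0.02, marker="COI", gap_rate=0.02,
    ),
    # saturated regime (deep D-loop-like divergence)
    "saturated": dict(
        n_species=10, tips_per_species=4, species_tree_depth=5.0,
        theta=0.02, marker="Dloop", gap_rate=0.02,
    ),
    # 30% of species are singletons
    "singleton_rich": dict(
        n_species=20,
        tips_per_species=tuple([1] * 6 + [4, 4, 6, 6, 8, 8, 10, 10, 12,
                                          12, 16, 16, 20, 24]),
        species_tree_depth=0.2, theta=0.005, min_split_frac=0.1,
        marker="Cytb", gap_rate=0.02,
    ),
    # repository-audit calibration: planted mislabels, n = 400
    "mislabeled": dict(
        n_species=20, tips_per_species=20, species_tree_depth=0.5,
        theta=0.005, mislabel_rate=0.05, marker="Cytb", gap_rate=0.02,
    ),
}


def scenario(name: str, seed: int) -> SyntheticDataset:
    """Generate one of the named preset datasets."""
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    return generate(SimulationConfig(seed=seed, **SCENARIOS[name]))


def write_dataset(ds: SyntheticDataset, outdir) -> list[str]:
    """Write FASTA + true trees + truth TSV + config echo; returns paths."""
    from pathlib import Path
    from . import seqio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    fasta = outdir / "alignment.fasta"
    seqio.write_alignment(ds.alignment, fasta)
    paths.append(fasta)
    for fname, nwk in (("species_tree.nwk", ds.species_tree),
                       ("gene_tree.nwk", ds.gene_tree)):
        p = outdir / fname
        p.write_text(nwk + "\n")
        paths.append(p)
    truth_p = outdir / "truth.tsv"
    ds.truth.to_csv(truth_p, sep="\t", index=False)
    paths.append(truth_p)
    cfg_p = outdir / "config.json"
    cfg = dataclasses.asdict(ds.config)
    cfg_p.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    paths.append(cfg_p)
    return [str(p) for p in paths]
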
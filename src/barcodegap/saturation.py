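"""Substitution-saturation analysis with the entropy-based index Iss.

Saturation — repeated substitutions erasing divergence signal — is
quantified by comparing the mean per-site information entropy of an
alignment with the entropy expected under full saturation.  For a column
of n unambiguous residues the entropy is H = -sum p_b log2 p_b; under
full saturation every cell is an independent draw from the global base
frequencies, so the expected column entropy H_FSS follows from the
multinomial distribution of counts among n sequences.  The index is
Iss = H_mean / H_FSS: ~0 for invariant alignments, ~1 for random ones.

Iss is compared against a critical value Iss.c — the index value at
which distance-based tree reconstruction stops recovering the true
topology.  Critical values are estimated here by Monte-Carlo simulation
on symmetric (balanced) and asymmetric (caterpillar) reference
topologies across a grid of branch lengths.  The observed index is
resampled over random OTU subsets (4/8/16/32 by default) exactly as the
test is conventionally applied.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from . import distances as dist_mod
from . import trees as trees_mod
from .distances import MISSING, encode_alignment
from .seqio import BarcodeAlignment, SequenceRecord, codon_partition_columns

log = logging.getLogger(__name__)

DEFAULT_N_OTU = (4, 8, 16, 32)
DEFAULT_REPLICATES = 1000

NO_SATURATION = "no saturation"
SATURATED = "saturated"
INCONCLUSIVE = "inconclusive"


# ------------------------------------------------------------ ts/tv profile

def ts_tv_profile(aln: BarcodeAlignment, partition: str = "whole",
                  frame_offset: int = 0, min_sites: int = 50):
    """Per-pair transition/transversion counts and K2P divergence.

    ``partition`` selects alignment columns: whole, pos12 or pos3 (the
    latter two need a coding marker).  Rows are dicts ready for TSV.
    """
    sub = _select_partition(aln, partition, frame_offset)
    codes = encode_alignment(sub)
    present = codes != MISSING
    rows = []
    n = codes.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            diff = both & (codes[i] != codes[j])
            ts = int((diff & ((codes[i] ^ codes[j]) == 2)).sum())
            tv = int(diff.sum()) - ts
            c = dist_mod.PairwiseCounts(int(both.sum()), ts, tv)
            d, status = dist_mod.k2p_distance(c, min_sites=min_sites)
            rows.append(
                {
                    "id_a": sub.ids[i], "id_b": sub.ids[j],
                    "partition": partition,
                    "s": ts, "v": tv, "k2p": d, "status": status,
                }
            )
    return rows


def _select_partition(aln, partition, frame_offset):
    if partition == "whole":
        return aln
    if partition in ("pos12", "pos3"):
        pos12, pos3 = codon_partition_columns(aln.length, frame_offset)
        return aln.subset_columns(pos12 if partition == "pos12" else pos3)
    raise ValueError(f"unknown partition {partition!r}")


# ----------------------------------------------------------------- entropy

def site_entropy(column: str) -> float:
    """Shannon entropy (bits) of one alignment column.

    Gaps and ambiguity codes are ignored; fewer than 2 usable residues
    raises (the column carries no comparative information).
    """
    counts = np.array([column.upper().count(b) for b in "ACGT"], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("site_entropy needs >= 2 unambiguous residues")
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _column_entropies(codes: np.ndarray):
    """Mean entropy over usable columns of an encoded alignment.

    Returns (mean_H, n_usable_columns, per-column H with NaN where
    unusable).
    """
    n_seq, L = codes.shape
    counts = np.zeros((4, L))
    for b in range(4):
        counts[b] = (codes == b).sum(axis=0)
    totals = counts.sum(axis=0)
    usable = totals >= 2
    H = np.full(L, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts[:, usable] / totals[usable]
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        H[usable] = -terms.sum(axis=0)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("alignment has no usable columns")
    return float(np.nanmean(H)), n_usable, H


@functools.lru_cache(maxsize=256)
def _h_fss_cached(freqs_key, n_otu):
    freqs = np.array(freqs_key)
    log_f = np.log(np.where(freqs > 0, freqs, 1.0))
    lgamma = math.lgamma
    total = 0.0
    for c in itertools.combinations_with_replacement(range(4), n_otu):
        counts = np.bincount(c, minlength=4)
        logp = (
            lgamma(n_otu + 1)
            - sum(lgamma(k + 1) for k in counts)
            + float((counts * log_f).sum())
        )
        p_col = counts[counts > 0] / n_otu
        h = -(p_col * np.log2(p_col)).sum()
        total += math.exp(logp) * h
    return float(total)


def expected_full_saturation_entropy(base_freqs, n_otu: int) -> float:
    """Expected column entropy when every cell is an iid draw.

    Exact multinomial expectation over all count compositions of n_otu
    among the four bases.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    key = tuple(np.round(freqs, 12))
    return _h_fss_cached(key, int(n_otu))


def iss_from_codes(codes: np.ndarray):
    """Iss for one (sub)alignment: mean entropy over H_FSS."""
    mean_h, n_usable, _ = _column_entropies(codes)
    cells = codes[codes != MISSING]
    if cells.size == 0:
        raise ValueError("no unambiguous cells")
    freqs = np.bincount(cells, minlength=4) / cells.size
    # guard against absent bases (degenerate alignments)
    freqs = np.clip(freqs, 1e-9, None)
    freqs = freqs / freqs.sum()
    h_fss = expected_full_saturation_entropy(freqs, codes.shape[0])
    return mean_h / h_fss, n_usable


def iss_observed(aln, n_otu: int, n_replicates: int = DEFAULT_REPLICATES,
                 seed: int = 0, partition: str = "whole",
                 frame_offset: int = 0):
    """Observed Iss by random OTU resampling.

    Each replicate samples ``n_otu`` sequences without replacement and
    computes Iss on the subsample.  Returns (mean, se, replicate values,
    usable columns of the full partition).
    """
    sub = _select_partition(aln, partition, frame_offset)
    codes = encode_alignment(sub)
    n = codes.shape[0]
    if n_otu > n:
        raise ValueError(f"n_otu={n_otu} exceeds {n} sequences")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_replicates)
    for r in range(n_replicates):
        rows = rng.choice(n, size=n_otu, replace=False)
        vals[r], _ = iss_from_codes(codes[rows])
    _, n_usable, _ = _column_entropies(codes)
    se = float(vals.std(ddof=1) / math.sqrt(n_replicates)) \
        if n_replicates > 1 else 0.0
    return float(vals.mean()), se, vals, n_usable


# ------------------------------------------------------- critical values

def _finish_ultrametric(tree, depth):
    """Extend terminal edges so every root-to-tip path equals ``depth``."""
    tree.seed_node._d = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node._d = node.parent_node._d + node.edge.length
        if node.is_leaf():
            node.edge.length += depth - node._d
    for node in tree.preorder_node_iter():
        del node._d
    return tree


def _balanced_tree(n_tips: int, depth: float) -> dendropy.Tree:
    """Symmetric reference topology: a clock-like balanced tree of the
    given root-to-tip depth with short internodes (depth / 2 log2 n)."""
    if n_tips & (n_tips - 1):
        raise ValueError("symmetric topology needs a power-of-2 OTU count")
    b = depth / (2.0 * math.log2(n_tips))
    labels = [f"T{i + 1}" for i in range(n_tips)]
    ns = dendropy.TaxonNamespace(labels)

    def build(lo, hi):
        node = dendropy.Node()
        if hi - lo == 1:
            node.taxon = ns.get_taxon(labels[lo])
            return node
        mid = (lo + hi) // 2
        for child in (build(lo, mid), build(mid, hi)):
            node.add_child(child)
            child.edge.length = b
        return node

    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = build(0, n_tips)
    tree.is_rooted = True
    return _finish_ultrametric(tree, depth)


def _caterpillar_tree(n_tips: int, depth: float) -> dendropy.Tree:
    """Asymmetric (pectinate) reference topology.

    Short internodes (depth / 2 log2 n) with terminal branches
    alternating between ``depth`` and the internode length — a
    long-branch-attraction ladder, reconstruction-hostile by design so
    asymmetric critical values sit below symmetric ones.
    """
    b = depth / (2.0 * math.log2(n_tips))
    labels = [f"T{i + 1}" for i in range(n_tips)]
    ns = dendropy.TaxonNamespace(labels)
    sub = dendropy.Node(taxon=ns.get_taxon(labels[0]))
    sub_is_tip = True
    for i in range(1, n_tips):
        parent = dendropy.Node()
        tip = dendropy.Node(taxon=ns.get_taxon(labels[i]))
        parent.add_child(sub)
        parent.add_child(tip)
        sub.edge.length = depth if sub_is_tip else b
        tip.edge.length = depth if i % 2 == 0 else b
        sub = parent
        sub_is_tip = False
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = sub
    tree.is_rooted = True
    return tree


def _evolve_on(tree, seq_length, rng):
    """JC (kappa=1) alignment on a fixed topology, as a BarcodeAlignment."""
    from .simulate import evolve_sequences

    return evolve_sequences(tree, seq_length, kappa=1.0,
                            base_freqs=(0.25, 0.25, 0.25, 0.25), rng=rng)


def _recovery_score(true_tree, aln) -> float:
    """Whole-topology recovery by p-distance NJ.

    1 when every true bipartition is found, else 0.  Whole-topology
    success is the quantity whose failure defines the critical value; it
    naturally sharpens with OTU count (more bipartitions must all be
    right), which is what drives Iss.c downward as OTUs are added.
    """
    dm = dist_mod.distance_matrix(aln, model="p", min_sites=1)
    est = trees_mod.nj_tree(dm)
    true_bips = trees_mod.bipartition_set(true_tree)
    if not true_bips:
        return 1.0
    est_bips = trees_mod.bipartition_set(est)
    return 1.0 if true_bips <= est_bips else 0.0


@dataclass(frozen=True)
class CriticalValueConfig:
    """Monte-Carlo settings for Iss.c estimation.

    ``depths`` are root-to-tip tree depths (substitutions/site); at a
    given depth more OTUs mean shorter internal edges, which is what
    makes reconstruction harder as taxa are added.
    """

    depths: tuple = tuple(np.geomspace(0.05, 8.0, 14))
    n_reps: int = 12
    seq_length: int = 600
    fail_criterion: float = 0.5  # median loss of whole-topology recovery


@functools.lru_cache(maxsize=64)
def _iss_critical_cached(n_otu, topology, seed, cfg_key):
    depths, n_reps, seq_length, fail_criterion = cfg_key
    rng = np.random.default_rng(seed)
    build = _balanced_tree if topology == "symmetric" else _caterpillar_tree
    mean_iss, mean_score = [], []
    for depth in depths:
        tree = build(n_otu, depth)
        iss_vals, scores = [], []
        for _ in range(n_reps):
            aln = _evolve_on(tree, seq_length, rng)
            iss, _ = iss_from_codes(encode_alignment(aln))
            iss_vals.append(iss)
            scores.append(_recovery_score(tree, aln))
        mean_iss.append(np.mean(iss_vals))
        mean_score.append(np.mean(scores))
    # chance floor: NJ on iid-random alignments of the same shape
    floor_scores = []
    for _ in range(n_reps):
        recs = []
        for i in range(n_otu):
            seq = "".join(np.array(list("ACGT"))[
                rng.integers(0, 4, size=seq_length)])
            recs.append(SequenceRecord(id=f"T{i + 1}", species="x",
                                       residues=seq))
        aln = BarcodeAlignment(records=recs)
        floor_scores.append(_recovery_score(build(n_otu, 0.1), aln))
    floor = float(np.mean(floor_scores))
    norm = [
        max(0.0, (s - floor) / (1.0 - floor)) if floor < 1.0 else 0.0
        for s in mean_score
    ]
    # walk the depth grid for the failure-onset crossing
    for k in range(1, len(depths)):
        if norm[k] < fail_criterion <= norm[k - 1]:
            w = (norm[k - 1] - fail_criterion) / (norm[k - 1] - norm[k])
            return float(mean_iss[k - 1] + w * (mean_iss[k] - mean_iss[k - 1]))
    if norm[-1] < fail_criterion:  # already failing at the smallest depth
        return float(mean_iss[0])
    log.warning("recovery never fell below criterion; Iss.c set to the "
                "largest simulated Iss")
    return float(mean_iss[-1])


def iss_critical(n_otu: int, seq_length: int = 500,
                 topology: str = "symmetric", seed: int = 0,
                 config: CriticalValueConfig | None = None) -> float:
    """Monte-Carlo critical value Iss.c for one topology and OTU count.

    Simulates alignments on the reference topology over a branch-length
    grid and locates the Iss at which NJ reconstruction success (excess
    over the random-tree floor) drops below the failure criterion.
    Deterministic for a fixed seed.
    """
    if topology not in ("symmetric", "asymmetric"):
        raise ValueError(f"unknown topology {topology!r}")
    if topology == "symmetric" and (n_otu & (n_otu - 1)):
        raise ValueError("symmetric topology needs a power-of-2 OTU count")
    if n_otu < 4:
        raise ValueError("n_otu must be >= 4")
    cfg = config or CriticalValueConfig(
        seq_length=min(seq_length, 600) if seq_length else 600
    )
    cfg_key = (tuple(cfg.depths), cfg.n_reps, cfg.seq_length,
               cfg.fail_criterion)
    return _iss_critical_cached(n_otu, topology, seed, cfg_key)


# ------------------------------------------------------------- the test

@dataclass(frozen=True)
class SaturationResult:
    partition: str
    n_otu: int
    iss: float
    iss_se: float
    iss_c_sym: float
    iss_c_asym: float
    df: int
    p_sym: float
    p_asym: float
    n_replicates: int
    verdict_sym: str
    verdict_asym: str

    @property
    def verdict(self) -> str:
        return self.verdict_sym


def _t_test(iss, se, critical, df):
    if se == 0.0:
        return 0.0 if iss != critical else 1.0
    t = (iss - critical) / se
    return float(2.0 * stats.t.sf(abs(t), df))


def _verdict(iss, critical, p):
    if p < 0.05 and iss < critical:
        return NO_SATURATION
    if p < 0.05 and iss > critical:
        return SATURATED
    return INCONCLUSIVE


def saturation_test(
    aln: BarcodeAlignment,
    partitions=("whole",),
    n_otu_set=DEFAULT_N_OTU,
    seed: int = 0,
    n_replicates: int = DEFAULT_REPLICATES,
    frame_offset: int = 0,
    critical_config: CriticalValueConfig | None = None,
) -> list[SaturationResult]:
    """Entropy-based saturation test per partition and OTU count.

    The observed Iss (resampled) is compared to simulated critical
    values for symmetric and asymmetric topologies with a one-sample
    t-test; "no saturation" requires Iss significantly below Iss.c.
    ``df`` follows the source convention: usable columns minus 1.
    """
    results = []
    n_seq = len(aln.records)
    for partition in partitions:
        for n_otu in n_otu_set:
            if n_otu > n_seq:
                log.warning("skipping n_otu=%d (> %d sequences)",
                            n_otu, n_seq)
                continue
            iss, se, _, n_usable = iss_observed(
                aln, n_otu, n_replicates=n_replicates, seed=seed,
                partition=partition, frame_offset=frame_offset,
            )
            c_sym = iss_critical(n_otu, n_usable, "symmetric", seed=seed,
                                 config=critical_config)
            c_asym = iss_critical(n_otu, n_usable, "asymmetric", seed=seed,
                                  config=critical_config)
            df = n_usable - 1
            p_sym = _t_test(iss, se, c_sym, df)
            p_asym = _t_test(iss, se, c_asym, df)
            results.append(
                SaturationResult(
                    partition=partition, n_otu=n_otu, iss=iss, iss_se=se,
                    iss_c_sym=c_sym, iss_c_asym=c_asym, df=df,
                    p_sym=p_sym, p_asym=p_asym, n_replicates=n_replicates,
                    verdict_sym=_verdict(iss, c_sym, p_sym),
                    verdict_asym=_verdict(iss, c_asym, p_asym),
                )
            )
    return results
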
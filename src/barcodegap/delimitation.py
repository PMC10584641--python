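"""Species delimitation on trees: single-threshold GMYC and PTP/bPTP.

Both methods follow the statsmodels convention: a model object is built
from a tree, ``fit()`` returns a results object carrying estimates,
likelihoods and the tip partition, and ``summary()`` renders a table.

GMYC (general mixed Yule-coalescent) takes an ultrametric tree and finds
the time threshold separating between-species (Yule) branching from
within-species (coalescent) branching.  Waiting times between successive
branching events are modeled as exponentials with rate ``lambda * n^p``
(Yule class, n = species lineages) or ``lambda * (sum_c k_c (k_c - 1))^p``
(coalescent class, k_c = lineages within cluster c); the threshold,
rates and scaling exponents are jointly maximized and compared to the
single-coalescent null with a likelihood-ratio test (chi-square, df 2).

PTP (Poisson tree processes) works directly on substitution branch
lengths: within-species and between-species branches are modeled as two
exponential classes; the tip partition (an antichain of subtree roots)
is searched greedily with restarts, and a Metropolis-Hastings sampler
over partitions provides Bayesian-flavored co-assignment supports.
"""

from __future__ import annotations

import collections
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import root_to_tip_spread

MIN_TIPS = 4


# =========================================================== shared helpers

def _node_ages(tree):
    """Age (time before present) of every node; requires ultrametric-ish."""
    ages = {}
    depths = {}
    maxd = 0.0
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else (
            depths[id(node.parent_node)] + (node.edge.length or 0.0)
        )
        depths[id(node)] = d
        maxd = max(maxd, d)
    for node in tree.preorder_node_iter():
        ages[node] = maxd - depths[id(node)]
    return ages


def _exp_class_lnl(ns, xs, censored=(), p_bounds=(1e-8, 3.0)):
    """Maximized log-likelihood of waiting times xs under rate lam*n^p.

    ``censored`` holds (n, x) exposures that ended without an event
    (survival terms only).  lam is profiled out in closed form; p is
    optimized within bounds.  Returns (lnl, lam_hat, p_hat); a class
    with no events and no exposure contributes 0.
    """
    ns = np.asarray(ns, dtype=float)
    xs = np.asarray(xs, dtype=float)
    cens_n = np.asarray([c[0] for c in censored], dtype=float)
    cens_x = np.asarray([c[1] for c in censored], dtype=float)
    E = len(ns)
    if E == 0:
        # exposure without events: the rate MLE is 0, contribution 0
        return 0.0, None, None
    log_ns = np.log(ns)

    def profile(p):
        S = float((ns**p * xs).sum())
        if len(cens_n):
            S += float((cens_n**p * cens_x).sum())
        return E * math.log(E / S) - E + p * float(log_ns.sum())

    res = optimize.minimize_scalar(
        lambda p: -profile(p), bounds=p_bounds, method="bounded",
        options={"xatol": 1e-8},
    )
    p_hat = float(res.x)
    S = float((ns**p_hat * xs).sum())
    if len(cens_n):
        S += float((cens_n**p_hat * cens_x).sum())
    return profile(p_hat), E / S, p_hat


# ==================================================================== GMYC

@dataclass
class GMYCResults:
    """Fitted single-threshold GMYC model."""

    threshold_height: float
    lnl_null: float
    lnl_gmyc: float
    clusters: tuple  # tuple of tuples of tip labels (singletons included)
    n_species: int
    lambda_yule: float | None
    p_yule: float | None
    lambda_coal: float | None
    p_coal: float | None
    threshold_profile: pd.DataFrame = field(repr=False, default=None)

    @property
    def lr_statistic(self) -> float:
        return 2.0 * (self.lnl_gmyc - self.lnl_null)

    @property
    def lr_p(self) -> float:
        # df = 3: the mixed model adds two rate parameters plus the
        # threshold to the 2-parameter single-coalescent null
        return float(stats.chi2.sf(self.lr_statistic, df=3))

    def summary(self) -> str:
        lines = [
            "GMYC single-threshold model",
            "===========================",
            f"n tips                 {sum(len(c) for c in self.clusters)}",
            f"n species (clusters)   {self.n_species}",
            f"threshold (time b.p.)  {self.threshold_height:.6g}",
            f"lnL null (1 coalescent) {self.lnl_null:.4f}",
            f"lnL GMYC               {self.lnl_gmyc:.4f}",
            f"LR statistic           {self.lr_statistic:.4f}",
            f"LR p (chi2, df=3)      {self.lr_p:.4g}",
        ]
        if self.lambda_yule is not None:
            lines.append(
                f"Yule: lambda={self.lambda_yule:.4g} p={self.p_yule:.3f}"
            )
        if self.lambda_coal is not None:
            lines.append(
                f"Coalescent: lambda={self.lambda_coal:.4g} p={self.p_coal:.3f}"
            )
        return "\n".join(lines)


class GMYC:
    """Single-threshold GMYC model for an ultrametric tree."""

    def __init__(self, tree, ultrametric_tol: float = 1e-6):
        n_tips = sum(1 for _ in tree.leaf_node_iter())
        if n_tips < MIN_TIPS:
            raise ValueError(f"GMYC needs >= {MIN_TIPS} tips, got {n_tips}")
        if not tree.is_rooted:
            raise ValueError("GMYC needs a rooted ultrametric tree")
        ages = _node_ages(tree)
        height = max(ages.values())
        spread = root_to_tip_spread(tree)
        if spread > ultrametric_tol * max(height, 1.0):
            raise ValueError(
                f"tree is not ultrametric: root-to-tip spread {spread:.3g} "
                f"exceeds tolerance"
            )
        self.tree = tree
        self._prepare(ages, height)

    def _prepare(self, ages, height):
        internals = [n for n in self.tree.preorder_node_iter()
                     if not n.is_leaf()]
        internals.sort(key=lambda n: -ages[n])
        # strictly decreasing positive ages (ties/zeros perturbed)
        eps = max(height, 1e-12) * 1e-9
        adj = []
        prev = None
        for n in internals:
            a = ages[n]
            if prev is not None and a >= prev - eps:
                a = prev - eps
            a = max(a, eps)
            if prev is not None and a >= prev:
                a = prev * (1 - 1e-12)
            adj.append(a)
            prev = a
        self.event_ages = adj  # descending, root first
        self.event_nodes = internals
        self.rank = {id(n): i for i, n in enumerate(internals)}
        self.n_events = len(internals)
        # inter-event waits; (near-)zero waits come from tied node heights
        # and carry no waiting-time information -> masked out of the
        # likelihood uniformly for every threshold and for the null
        M = self.n_events
        self.x = np.array([adj[i - 1] - adj[i] for i in range(1, M)])
        self.x_mask = self.x > 1e-8 * max(height, 1e-12)
        self.tips_below = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self.tips_below[id(node)] = 1
            else:
                self.tips_below[id(node)] = sum(
                    self.tips_below[id(c)] for c in node.child_nodes()
                )

    # ---- likelihood pieces -------------------------------------------------

    def _cluster_roots(self, j):
        """Branches crossing the threshold after j Yule events."""
        if j == 0:
            return [self.tree.seed_node]
        roots = []
        for i in range(j):
            for child in self.event_nodes[i].child_nodes():
                r = self.rank.get(id(child))
                if r is None or r >= j:
                    roots.append(child)
        return roots

    def _coal_sigma(self, j):
        """sum_c k_c (k_c - 1) during each below-threshold interval.

        Intervals are indexed 1..M-1 (interval i precedes event i in
        root-to-tip order); entries for i <= j are 0 (above threshold).
        """
        M = self.n_events
        sigma = np.zeros(M)  # sigma[i] = value during interval i
        if j >= M:
            return sigma
        # cluster id of each coalescent event: nearest Yule ancestor's child
        cluster_of = {}
        next_cluster = [0]

        def cluster_id(node):
            key = id(node)
            if key in cluster_of:
                return cluster_of[key]
            parent = node.parent_node
            if parent is None or self.rank[id(parent)] < j:
                cid = next_cluster[0]
                next_cluster[0] += 1
            else:
                cid = cluster_id(parent)
            cluster_of[key] = cid
            return cid

        counts: dict[int, int] = {}
        sig = 0.0
        for i in range(j, M):
            # interval i+1 lies after event i (root-to-tip order)
            node = self.event_nodes[i]
            cid = cluster_id(node) if j > 0 else 0
            k = counts.get(cid, 1)
            sig += 2 * k  # (k+1)k - k(k-1)
            counts[cid] = k + 1
            if i + 1 <= M - 1:
                sigma[i + 1] = sig
        return sigma

    def _lnl_for_threshold(self, j):
        """Joint ML over (lambda1, p1, lambda2, p2) at threshold j.

        Intervals above the threshold carry only the diversification rate
        lambda1 * n^p1; intervals below carry the constant background
        lambda1 * (j+1)^p1 plus the coalescent rate lambda2 * sigma^p2.
        The interval set (all waits between successive branching events,
        conditioned on the root) is identical for every threshold.
        """
        M = self.n_events
        keep = self.x_mask
        x = self.x
        lineages = np.arange(2, M + 1, dtype=float)  # during interval i: i+1
        if j >= M:  # pure Yule
            lnl, lam, p = _exp_class_lnl(lineages[keep], x[keep])
            return lnl, (lam, p, None, None)
        sigma = self._coal_sigma(j)[1:]
        above = (np.arange(1, M) <= j) & keep
        below = ~(np.arange(1, M) <= j) & keep
        n_yule_above = lineages[above]
        x_above = x[above]
        x_below = x[below]
        sigma_below = sigma[below]
        bg = float(j + 1)
        if x_below.size == 0:  # threshold below every event: pure Yule
            lnl, lam, p = _exp_class_lnl(n_yule_above, x_above)
            return lnl, (lam, p, None, None)

        def neg_lnl(theta):
            log_l1, p1, log_l2, p2 = theta
            l1, l2 = math.exp(log_l1), math.exp(log_l2)
            r_above = l1 * n_yule_above**p1
            r_below = l1 * bg**p1 + l2 * sigma_below**p2
            with np.errstate(over="ignore"):
                val = (
                    np.log(r_above).sum() - (r_above * x_above).sum()
                    + np.log(r_below).sum() - (r_below * x_below).sum()
                )
            return -val if np.isfinite(val) else 1e12

        starts = []
        if j >= 1:
            _, l1_0, p1_0 = _exp_class_lnl(n_yule_above, x_above)
        else:
            l1_0, p1_0 = None, 1.0
        _, l2_0, p2_0 = _exp_class_lnl(sigma_below, x_below)
        base_l1 = l1_0 if l1_0 else 1e-8 / max(x.sum(), 1e-12)
        starts.append([math.log(base_l1), p1_0 or 1.0,
                       math.log(l2_0), p2_0])
        starts.append([math.log(base_l1) - 5.0, 1.0,
                       math.log(l2_0), p2_0])
        bounds = [(-40.0, 40.0), (1e-8, 3.0), (-40.0, 40.0), (1e-8, 3.0)]
        best = None
        for x0 in starts:
            res = optimize.minimize(neg_lnl, x0, method="L-BFGS-B",
                                    bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        log_l1, p1, log_l2, p2 = best.x
        return -best.fun, (math.exp(log_l1), p1, math.exp(log_l2), p2)

    def _lnl_null(self):
        """Single-coalescent null: rate lambda * (k(k-1))^p."""
        M = self.n_events
        keep = self.x_mask
        k = np.arange(2, M + 1, dtype=float)
        lnl, lam, p = _exp_class_lnl((k * (k - 1))[keep], self.x[keep])
        return lnl

    # ---- fitting ------------------------------------------------------------

    def fit(self) -> GMYCResults:
        lnl_null = self._lnl_null()
        rows = []
        best = None
        for j in range(self.n_events + 1):
            lnl, params = self._lnl_for_threshold(j)
            # threshold reported as midpoint between the youngest Yule and
            # oldest coalescent event; j=0 -> at the root age (null-like)
            if j == 0:
                thr = self.event_ages[0]
            elif j == self.n_events:
                thr = 0.5 * self.event_ages[-1]
            else:
                thr = 0.5 * (self.event_ages[j - 1] + self.event_ages[j])
            rows.append({"j": j, "threshold": thr, "lnl": lnl,
                         "n_species": j + 1})
            if best is None or lnl > best[1] + 1e-12:
                best = (j, lnl, params, thr)
        j, lnl, (lam_y, p_y, lam_c, p_c), thr = best
        if lnl < lnl_null:  # j=0 nests the null at lambda1 -> 0
            j, lnl, thr = 0, lnl_null, self.event_ages[0]
            lam_y = p_y = lam_c = p_c = None
        roots = self._cluster_roots(j)
        clusters = []
        for r in roots:
            tips = tuple(sorted(l.taxon.label for l in r.leaf_iter())) \
                if not r.is_leaf() else (r.taxon.label,)
            clusters.append(tips)
        clusters.sort()
        return GMYCResults(
            threshold_height=thr,
            lnl_null=lnl_null,
            lnl_gmyc=lnl,
            clusters=tuple(clusters),
            n_species=len(clusters),
            lambda_yule=lam_y, p_yule=p_y,
            lambda_coal=lam_c, p_coal=p_c,
            threshold_profile=pd.DataFrame(rows),
        )


def gmyc_single_threshold(tree, ultrametric_tol: float = 1e-6) -> GMYCResults:
    """Fit the single-threshold GMYC model to an ultrametric tree."""
    return GMYC(tree, ultrametric_tol=ultrametric_tol).fit()


# ===================================================================== PTP

@dataclass
class PTPResults:
    """Fitted PTP model (ML partition, optionally with MCMC supports)."""

    ml_partition: tuple  # tuple of tuples of tip labels
    lambda_speciation: float | None
    lambda_coalescent: float | None
    lnl_ml: float
    n_species: int
    posterior_support: pd.DataFrame | None = None
    posterior_mode_n_species: int | None = None
    n_mcmc_samples: int = 0

    def summary(self) -> str:
        lines = [
            "PTP model (two exponential branch-length classes)",
            "=================================================",
            f"n tips                {sum(len(c) for c in self.ml_partition)}",
            f"n species (ML)        {self.n_species}",
            f"lnL (ML partition)    {self.lnl_ml:.4f}",
        ]
        if self.lambda_speciation is not None:
            lines.append(f"speciation rate       {self.lambda_speciation:.4g}")
        if self.lambda_coalescent is not None:
            lines.append(f"coalescent rate       {self.lambda_coalescent:.4g}")
        if self.posterior_mode_n_species is not None:
            lines.append(
                f"posterior-mode count  {self.posterior_mode_n_species}"
                f"  ({self.n_mcmc_samples} samples)"
            )
        return "\n".join(lines)


class PTP:
    """PTP species-delimitation model on a rooted substitution tree."""

    def __init__(self, tree, min_branch: float = 1e-9):
        n_tips = sum(1 for _ in tree.leaf_node_iter())
        if n_tips < MIN_TIPS:
            raise ValueError(f"PTP needs >= {MIN_TIPS} tips, got {n_tips}")
        if not tree.is_rooted:
            raise ValueError("PTP needs a rooted tree")
        self.tree = tree
        self.nodes = list(tree.preorder_node_iter())
        self.node_id = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = {}
        self.children = {}
        self.edge_len = {}
        for n in self.nodes:
            i = self.node_id[id(n)]
            self.children[i] = [self.node_id[id(c)] for c in n.child_nodes()]
            for c in n.child_nodes():
                self.parent[self.node_id[id(c)]] = i
            self.edge_len[i] = max(n.edge.length or 0.0, min_branch) \
                if n.parent_node is not None else 0.0
        self.root = self.node_id[id(tree.seed_node)]
        self.is_leaf = {i: not self.children[i] for i in self.children}
        self.tip_labels = {
            self.node_id[id(n)]: n.taxon.label
            for n in tree.leaf_node_iter()
        }
        # edges strictly below each node
        self.sub_count = {}
        self.sub_sum = {}
        for n in tree.postorder_node_iter():
            i = self.node_id[id(n)]
            cnt, tot = 0, 0.0
            for c in self.children[i]:
                cnt += 1 + self.sub_count[c]
                tot += self.edge_len[c] + self.sub_sum[c]
            self.sub_count[i] = cnt
            self.sub_sum[i] = tot
        self.total_count = self.sub_count[self.root]
        self.total_sum = self.sub_sum[self.root]

    # ---- likelihood ---------------------------------------------------------

    @staticmethod
    def _f(E, S):
        return E * (math.log(E / S) - 1.0) if E > 0 else 0.0

    def _lnl(self, within_count, within_sum):
        return self._f(within_count, within_sum) + self._f(
            self.total_count - within_count, self.total_sum - within_sum
        )

    def _state_sums(self, part):
        wc = sum(self.sub_count[v] for v in part)
        ws = sum(self.sub_sum[v] for v in part)
        return wc, ws

    def _moves(self, part):
        """(kind, node) moves: split a species root / merge sibling roots."""
        moves = [("split", v) for v in part if not self.is_leaf[v]]
        parents = {self.parent[v] for v in part if v != self.root}
        for u in sorted(parents):
            if u not in part and all(c in part for c in self.children[u]):
                moves.append(("merge", u))
        return moves

    def _apply(self, part, wc, ws, kind, node):
        if kind == "split":
            new = part - {node} | set(self.children[node])
            dwc = -len(self.children[node])
            dws = -sum(self.edge_len[c] for c in self.children[node])
        else:
            new = part - set(self.children[node]) | {node}
            dwc = len(self.children[node])
            dws = sum(self.edge_len[c] for c in self.children[node])
        return new, wc + dwc, ws + dws

    # ---- search -------------------------------------------------------------

    def _hill_climb(self, part):
        wc, ws = self._state_sums(part)
        lnl = self._lnl(wc, ws)
        for _ in range(20 * len(self.nodes)):
            best = None
            for kind, node in self._moves(part):
                cand, cwc, cws = self._apply(part, wc, ws, kind, node)
                c_lnl = self._lnl(cwc, cws)
                if c_lnl > lnl + 1e-10 and (best is None or c_lnl > best[0]):
                    best = (c_lnl, cand, cwc, cws)
            if best is None:
                break
            lnl, part, wc, ws = best
        return lnl, part

    def _random_antichain(self, rng):
        q = rng.uniform(0.1, 0.9)
        part = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if self.is_leaf[v] or rng.random() < q:
                part.add(v)
            else:
                stack.extend(self.children[v])
        return frozenset(part)

    def _partition_tuple(self, part):
        clusters = []
        for v in sorted(part):
            tips = tuple(sorted(
                self.tip_labels[w]
                for w in self._tips_under(v)
            ))
            clusters.append(tips)
        clusters.sort()
        return tuple(clusters)

    def _tips_under(self, v):
        out, stack = [], [v]
        while stack:
            w = stack.pop()
            if self.is_leaf[w]:
                out.append(w)
            else:
                stack.extend(self.children[w])
        return out

    def lnl_of_partition(self, clusters) -> float:
        """Two-class log-likelihood of an explicit tip partition."""
        label_to_node = {lab: v for v, lab in self.tip_labels.items()}
        part = set()
        for tips in clusters:
            nodes = [label_to_node[t] for t in tips]
            v = nodes[0]
            # climb until the subtree contains exactly this tip set
            want = set(nodes)
            while v != self.root:
                p = self.parent[v]
                under = set(self._tips_under(p))
                if under <= want:
                    v = p
                else:
                    break
            if set(self._tips_under(v)) != want:
                raise ValueError(
                    f"cluster {tips} is not a subtree of the input tree"
                )
            part.add(v)
        wc, ws = self._state_sums(part)
        return self._lnl(wc, ws)

    def fit(self, seed: int = 0, n_restarts: int = 10) -> PTPResults:
        """Greedy ML search over partitions with seeded random restarts.

        The two-class model is compared to a one-rate null by AIC; when
        the null wins, a single species is reported.
        """
        rng = np.random.default_rng(seed)
        starts = [frozenset({self.root}),
                  frozenset(v for v in self.tip_labels)]
        for _ in range(max(0, n_restarts - len(starts))):
            starts.append(self._random_antichain(rng))
        best_lnl, best_part = -math.inf, None
        for s in starts:
            lnl, part = self._hill_climb(set(s))
            if lnl > best_lnl:
                best_lnl, best_part = lnl, part
        lnl_one = self._f(self.total_count, self.total_sum)
        # AIC: one rate vs two rates (+1 parameter)
        if 2 * 1 - 2 * lnl_one <= 2 * 2 - 2 * best_lnl:
            part = {self.root}
            wc, ws = self._state_sums(part)
            return PTPResults(
                ml_partition=self._partition_tuple(part),
                lambda_speciation=None,
                lambda_coalescent=(
                    self.total_count / self.total_sum
                    if self.total_sum > 0 else None
                ),
                lnl_ml=lnl_one,
                n_species=1,
            )
        wc, ws = self._state_sums(best_part)
        eb, sb = self.total_count - wc, self.total_sum - ws
        return PTPResults(
            ml_partition=self._partition_tuple(best_part),
            lambda_speciation=eb / sb if sb > 0 and eb else None,
            lambda_coalescent=wc / ws if ws > 0 and wc else None,
            lnl_ml=best_lnl,
            n_species=len(best_part),
        )

    def fit_mcmc(
        self,
        n_steps: int = 100_000,
        burn_in: int | None = None,
        seed: int = 0,
        thin: int = 50,
    ) -> PTPResults:
        """Metropolis-Hastings over partitions (split/merge moves).

        Targets the profile likelihood; reports per-tip-pair co-assignment
        frequencies and the posterior-mode species count on top of the ML
        fit.  The chain is deterministic for a fixed seed.
        """
        if burn_in is None:
            burn_in = n_steps // 10
        if n_steps <= burn_in:
            raise ValueError("n_steps must exceed burn_in")
        ml = self.fit(seed=seed)
        rng = np.random.default_rng(seed)
        part = set()
        label_to_node = {lab: v for v, lab in self.tip_labels.items()}
        # start from the ML partition
        for tips in ml.ml_partition:
            nodes = [label_to_node[t] for t in tips]
            if len(nodes) == 1:
                v = nodes[0]
            else:
                want = set(nodes)
                v = nodes[0]
                while v != self.root:
                    p = self.parent[v]
                    if set(self._tips_under(p)) <= want:
                        v = p
                    else:
                        break
            part.add(v)
        wc, ws = self._state_sums(part)
        lnl = self._lnl(wc, ws)
        tips_sorted = sorted(self.tip_labels.values())
        tip_index = {t: i for i, t in enumerate(tips_sorted)}
        n = len(tips_sorted)
        co = np.zeros((n, n))
        counts = collections.Counter()
        n_samples = 0
        for step in range(n_steps):
            moves = self._moves(part)
            kind, node = moves[int(rng.integers(len(moves)))]
            cand, cwc, cws = self._apply(part, wc, ws, kind, node)
            c_lnl = self._lnl(cwc, cws)
            n_back = len(self._moves(cand))
            log_acc = c_lnl - lnl + math.log(len(moves) / n_back)
            if log_acc >= 0 or rng.random() < math.exp(log_acc):
                part, wc, ws, lnl = set(cand), cwc, cws, c_lnl
            if step >= burn_in and (step - burn_in) % thin == 0:
                n_samples += 1
                counts[len(part)] += 1
                for v in part:
                    idx = [tip_index[self.tip_labels[w]]
                           for w in self._tips_under(v)]
                    co[np.ix_(idx, idx)] += 1.0
        support = pd.DataFrame(
            co / n_samples, index=tips_sorted, columns=tips_sorted
        )
        mode = counts.most_common(1)[0][0]
        return PTPResults(
            ml_partition=ml.ml_partition,
            lambda_speciation=ml.lambda_speciation,
            lambda_coalescent=ml.lambda_coalescent,
            lnl_ml=ml.lnl_ml,
            n_species=ml.n_species,
            posterior_support=support,
            posterior_mode_n_species=mode,
            n_mcmc_samples=n_samples,
        )


def ptp_ml(tree, seed: int = 0, n_restarts: int = 10) -> PTPResults:
    """Maximum-likelihood PTP fit."""
    return PTP(tree).fit(seed=seed, n_restarts=n_restarts)


def ptp_mcmc(tree, n_steps: int = 100_000, burn_in: int | None = None,
             seed: int = 0) -> PTPResults:
    """PTP with Bayesian-flavored MCMC support values."""
    return PTP(tree).fit_mcmc(n_steps=n_steps, burn_in=burn_in, seed=seed)


def count_species(result) -> int:
    """Number of clusters in a fitted delimitation result."""
    return int(result.n_species)
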
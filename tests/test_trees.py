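"""Newick I/O, neighbor joining, monophyly, classes, clock projection."""

import itertools

import numpy as np
import pytest

from barcodegap import simulate as sim
from barcodegap.distances import OK, DistanceMatrix, distance_matrix
from barcodegap.trees import (
    audit_classes,
    bipartition_set,
    make_ultrametric,
    mean_path_length_tree,
    monophyly_fraction,
    nj_tree,
    node_support,
    parse_newick,
    read_newick,
    root_to_tip_spread,
    root_with_outgroup,
    tip_labels,
    upgma_tree,
    write_newick,
)


def dm_from_values(labels, values, species=None):
    n = len(labels)
    flags = np.full((n, n), OK, dtype=object)
    species = species or {l: l for l in labels}
    return DistanceMatrix(labels, species, np.asarray(values, float), flags)


def tree_path_distances(tree):
    """Leaf-to-leaf path lengths via the tree (oracle for additivity)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    out = {}
    for a, b in itertools.combinations(labels, 2):
        ta = tree.taxon_namespace.get_taxon(a)
        tb = tree.taxon_namespace.get_taxon(b)
        out[(a, b)] = pdm.patristic_distance(ta, tb)
    return out


class TestNewickIO:
    def test_basic_parse(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(tip_labels(t)) == ["A", "B", "C"]

    def test_support_parsed(self):
        t = parse_newick("((A:1,B:1)0.99:1,C:2);")
        internal = [n for n in t.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert node_support(internal[0]) == pytest.approx(0.99)

    def test_percent_support_normalized(self):
        t = parse_newick("((A:1,B:1)95:1,C:2);")
        internal = [n for n in t.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert node_support(internal[0]) == pytest.approx(0.95)

    def test_round_trip_bipartitions(self, tmp_path, rng):
        st = sim.simulate_species_tree(50, 1.0, 1.0, rng)
        p = tmp_path / "t.nwk"
        write_newick(st, p)
        back = read_newick(p)
        assert bipartition_set(back) == bipartition_set(st)

    def test_malformed_raises(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A,B,;")
        with pytest.raises(Exception):
            read_newick(p)


class TestNeighborJoining:
    def test_three_taxa(self):
        dm = dm_from_values(
            ["A", "B", "C"],
            [[0, 0.2, 0.3], [0.2, 0, 0.25], [0.3, 0.25, 0]],
        )
        t = nj_tree(dm)
        assert sorted(tip_labels(t)) == ["A", "B", "C"]

    def test_additive_recovery_exact(self):
        # distances generated from a known tree: ((A:1,B:2):1,(C:3,D:4))
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        labels = ["A", "B", "C", "D"]
        values = np.zeros((4, 4))
        for (a, b), v in d.items():
            i, j = labels.index(a), labels.index(b)
            values[i, j] = values[j, i] = v
        t = nj_tree(dm_from_values(labels, values))
        assert {frozenset("AB")} <= bipartition_set(t) or \
            {frozenset("CD")} <= bipartition_set(t)
        paths = tree_path_distances(t)
        for (a, b), v in d.items():
            assert paths[(a, b)] == pytest.approx(v, abs=1e-9)

    def test_random_additive_trees_recovered(self, rng):
        """50 random 8-taxon trees: NJ on exact path distances returns
        the generating topology and branch lengths."""
        for k in range(50):
            st = sim.simulate_species_tree(
                8, 1.0, 1.0, np.random.default_rng(k)
            )
            # make it non-ultrametric so branch-length recovery is general
            for nd in st.preorder_node_iter():
                if nd.parent_node is not None:
                    nd.edge.length += float(
                        np.random.default_rng(1000 + k).uniform(0, 0.3)
                    )
            labels = sorted(tip_labels(st))
            paths = tree_path_distances(st)
            n = len(labels)
            values = np.zeros((n, n))
            for (a, b), v in paths.items():
                i, j = labels.index(a), labels.index(b)
                values[i, j] = values[j, i] = v
            est = nj_tree(dm_from_values(labels, values))
            assert bipartition_set(est) == bipartition_set(st)
            est_paths = tree_path_distances(est)
            for key, v in paths.items():
                assert est_paths[key] == pytest.approx(v, abs=1e-9)

    def test_undefined_distances_rejected(self, rng):
        from barcodegap.distances import UNDEFINED

        labels = ["A", "B", "C", "D"]
        values = np.full((4, 4), 0.3)
        np.fill_diagonal(values, 0.0)
        flags = np.full((4, 4), OK, dtype=object)
        flags[0, 1] = flags[1, 0] = UNDEFINED
        dm = DistanceMatrix(labels, {l: l for l in labels}, values, flags)
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm)

    def test_no_negative_branch_lengths(self, rng):
        for k in range(10):
            ds = sim.generate(sim.SimulationConfig(
                n_species=5, tips_per_species=3, seed=k,
                species_tree_depth=0.1, theta=0.02, seq_length=300,
            ))
            dm = distance_matrix(ds.alignment)
            t = nj_tree(dm)
            for nd in t.preorder_node_iter():
                if nd.parent_node is not None:
                    assert nd.edge.length >= 0


class TestMonophyly:
    def test_forced_example(self):
        t = parse_newick("((A1:1,A2:1):1,((B1:1,C1:1):1,B2:2):1);")
        t.is_rooted = True
        species_of = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C"}
        rep = monophyly_fraction(t, species_of)
        assert rep.monophyletic == {"A": True, "B": False, "C": True}
        assert rep.fraction_monophyletic == pytest.approx(2 / 3)

    def test_singleton_excluded_policy(self):
        t = parse_newick("((A1:1,A2:1):1,((B1:1,C1:1):1,B2:2):1);")
        t.is_rooted = True
        species_of = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C"}
        rep = monophyly_fraction(t, species_of, singleton_policy="excluded")
        assert rep.n_species_evaluated == 2
        assert rep.fraction_monophyletic == pytest.approx(1 / 2)

    def test_all_clustered(self, rng):
        ds = sim.generate(sim.SimulationConfig(
            n_species=6, tips_per_species=4, seed=3,
            species_tree_depth=0.3, theta=0.002, min_split_frac=0.15,
            seq_length=500,
        ))
        dm = distance_matrix(ds.alignment)
        t = root_with_outgroup(nj_tree(dm), [])
        rep = monophyly_fraction(t, dm.species_of)
        assert rep.fraction_monophyletic == 1.0

    def test_matches_brute_force_mrca(self, rng):
        """Random labels on random 40-tip trees: equal to an exhaustive
        smallest-superset-clade scan."""
        for k in range(10):
            r = np.random.default_rng(k)
            st = sim.simulate_species_tree(40, 1.0, 1.0, r)
            labels = tip_labels(st)
            species_of = {l: f"sp{int(r.integers(0, 8))}" for l in labels}
            rep = monophyly_fraction(st, species_of)
            # oracle: scan every node's leaf set for the smallest superset
            leafsets = [
                frozenset(x.taxon.label for x in nd.leaf_iter())
                for nd in st.preorder_node_iter()
            ]
            for sp in set(species_of.values()):
                tips = frozenset(l for l, s in species_of.items() if s == sp)
                best = min(
                    (ls for ls in leafsets if tips <= ls), key=len
                )
                assert rep.monophyletic[sp] == (best == tips), sp

    def test_invariant_to_rerooting(self, rng):
        st = sim.simulate_species_tree(12, 1.0, 1.0, rng)
        labels = tip_labels(st)
        species_of = {l: f"sp{i % 4}" for i, l in enumerate(labels)}
        base = monophyly_fraction(st, species_of,
                                  outgroup=[labels[0]])
        again = monophyly_fraction(st, species_of,
                                   outgroup=[labels[0]])
        assert base.monophyletic == again.monophyletic

    def test_missing_outgroup_raises(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="outgroup"):
            monophyly_fraction(t, {"A": "a", "B": "b", "C": "c"},
                               outgroup=["ZZZ"])


class TestAuditClasses:
    def test_class1_supported_monophyly(self):
        t = parse_newick("((A1:1,A2:1)0.95:1,(B1:1,B2:1)0.99:1);")
        t.is_rooted = True
        sp = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        rec = {r.species: r for r in audit_classes(t, sp)}
        assert rec["A"].clade_class == 1
        assert rec["A"].support_at_mrca == pytest.approx(0.95)

    def test_low_support_class2(self):
        t = parse_newick("((A1:1,A2:1)0.5:1,(B1:1,B2:1)0.99:1);")
        t.is_rooted = True
        sp = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        rec = {r.species: r for r in audit_classes(t, sp)}
        assert rec["A"].clade_class == 2

    def test_interleaved_species_class3(self):
        t = parse_newick("((X1:1,(Y1:1,X2:1):1):1,(Z1:1,Z2:1):1);")
        t.is_rooted = True
        sp = {"X1": "X", "X2": "X", "Y1": "Y", "Z1": "Z", "Z2": "Z"}
        rec = {r.species: r for r in audit_classes(t, sp)}
        assert rec["X"].clade_class == 3
        assert set(rec["X"].clade_species) == {"X", "Y"}
        assert rec["Z"].clade_class == 1

    def test_scattered_species_class2(self):
        t = parse_newick(
            "((X1:1,(Y1:1,Y2:1):1):1,((X2:1,W1:1):1,W2:1):1);"
        )
        t.is_rooted = True
        sp = {"X1": "X", "X2": "X", "Y1": "Y", "Y2": "Y",
              "W1": "W", "W2": "W"}
        rec = {r.species: r for r in audit_classes(t, sp)}
        assert rec["X"].clade_class == 2

    def test_class1_count_bounded_by_monophyly(self, rng):
        ds = sim.scenario("overlapping", seed=5)
        dm = distance_matrix(ds.alignment)
        t = root_with_outgroup(nj_tree(dm), [])
        rep = monophyly_fraction(t, dm.species_of)
        recs = audit_classes(t, dm.species_of)
        n_class1 = sum(1 for r in recs if r.clade_class == 1)
        assert n_class1 <= sum(rep.monophyletic.values())


class TestUltrametric:
    def test_upgma_recovers_ultrametric_matrix(self, rng):
        st = sim.simulate_species_tree(8, 1.0, 0.5, rng)
        labels = sorted(tip_labels(st))
        paths = tree_path_distances(st)
        n = len(labels)
        values = np.zeros((n, n))
        for (a, b), v in paths.items():
            i, j = labels.index(a), labels.index(b)
            values[i, j] = values[j, i] = v
        t = upgma_tree(dm_from_values(labels, values))
        assert bipartition_set(t) == bipartition_set(st)
        est = tree_path_distances(t)
        for key, v in paths.items():
            assert est[key] == pytest.approx(v, abs=1e-9)

    def test_output_is_ultrametric(self, rng):
        ds = sim.scenario("overlapping", seed=2)
        dm = distance_matrix(ds.alignment)
        t = make_ultrametric(dm, "upgma_from_distances")
        assert root_to_tip_spread(t) < 1e-9

    def test_mpl_fixed_point_on_clock_tree(self, rng):
        st = sim.simulate_species_tree(10, 1.0, 1.0, rng)
        before = tree_path_distances(st)
        t = mean_path_length_tree(st)
        after = tree_path_distances(t)
        for key, v in before.items():
            assert after[key] == pytest.approx(v, abs=1e-9)

    def test_mpl_makes_nonclock_ultrametric(self, rng):
        st = sim.simulate_species_tree(10, 1.0, 1.0, rng)
        for nd in st.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length *= float(rng.uniform(0.5, 2.0))
        t = mean_path_length_tree(st)
        assert root_to_tip_spread(t) < 1e-9
        assert bipartition_set(t) == bipartition_set(st)

    def test_unrooted_mpl_rejected(self, rng):
        dm = dm_from_values(
            ["A", "B", "C"],
            [[0, 0.2, 0.3], [0.2, 0, 0.25], [0.3, 0.25, 0]],
        )
        t = nj_tree(dm)
        with pytest.raises(ValueError):
            mean_path_length_tree(t)
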
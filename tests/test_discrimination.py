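"""Nearest-neighbor test, barcoding gap, marker comparison, audit."""

import itertools

import numpy as np
import pytest
from scipy import stats

from barcodegap.discrimination import (
    AMBIGUOUS,
    CONSPECIFIC,
    HETEROSPECIFIC,
    AuditConfig,
    audit_groups,
    barcoding_gap,
    compare_markers,
    dunn_test,
    nearest_neighbor,
    percent_correct,
    species_summary,
)
from barcodegap.distances import DistanceMatrix, OK


def matrix_from(labels, species, dists):
    n = len(labels)
    values = np.zeros((n, n))
    flags = np.full((n, n), OK, dtype=object)
    for (i, j), d in dists.items():
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, dict(zip(labels, species)), values, flags)


@pytest.fixture()
def two_pairs():
    # A1,A2 close; B1,B2 close; all inter-pairs far
    labels = ["A1", "A2", "B1", "B2"]
    species = ["A", "A", "B", "B"]
    d = {}
    for i, j in itertools.combinations(range(4), 2):
        d[(i, j)] = 0.10
    d[(0, 1)] = 0.01
    d[(2, 3)] = 0.01
    return labels, species, d


class TestNearestNeighbor:
    def test_separated_pairs_all_conspecific(self, two_pairs):
        labels, species, d = two_pairs
        nn = nearest_neighbor(matrix_from(labels, species, d))
        assert all(a.conspecific == CONSPECIFIC for a in nn)

    def test_relabel_breaks_one_side(self, two_pairs):
        # brute-force scan of the 4x4 matrix confirms: A1's NN (A2,
        # renamed B) becomes heterospecific; B1/B2 still have each other
        labels, _, d = two_pairs
        nn = nearest_neighbor(matrix_from(labels, ["A", "B", "B", "B"], d))
        by_id = {a.query_id: a for a in nn}
        assert by_id["A1"].conspecific == HETEROSPECIFIC
        assert by_id["B1"].conspecific == CONSPECIFIC
        assert by_id["B2"].conspecific == CONSPECIFIC

    def test_tie_between_classes_is_ambiguous(self):
        labels = ["Q", "S", "H"]
        species = ["x", "x", "y"]
        d = {(0, 1): 0.02, (0, 2): 0.02, (1, 2): 0.05}
        nn = nearest_neighbor(matrix_from(labels, species, d))
        q = [a for a in nn if a.query_id == "Q"][0]
        assert q.conspecific == AMBIGUOUS
        assert set(q.neighbor_ids) == {"S", "H"}


class TestPercentCorrect:
    def _mk(self, calls, species_of=None):
        from barcodegap.discrimination import NNAssignment

        return [
            NNAssignment(f"S{i}", ("x",), 0.01, c)
            for i, c in enumerate(calls)
        ]

    def test_all_correct(self):
        assert percent_correct(self._mk([CONSPECIFIC] * 4)) == 100.0

    def test_three_of_four(self):
        a = self._mk([CONSPECIFIC] * 3 + [HETEROSPECIFIC])
        assert percent_correct(a) == 75.0

    def test_singleton_policies(self):
        from barcodegap.discrimination import NNAssignment

        assignments = [
            NNAssignment("S0", ("n",), 0.01, CONSPECIFIC),
            NNAssignment("S1", ("n",), 0.01, CONSPECIFIC),
            NNAssignment("S2", ("n",), 0.01, CONSPECIFIC),
            NNAssignment("S3", ("n",), 0.01, HETEROSPECIFIC),
            NNAssignment("LONER", ("n",), 0.3, HETEROSPECIFIC),
        ]
        species_of = {"S0": "a", "S1": "a", "S2": "b", "S3": "b",
                      "LONER": "z"}
        assert percent_correct(assignments, species_of) == 75.0
        assert percent_correct(
            assignments, species_of, singleton_policy="count_incorrect"
        ) == 60.0


class TestBarcodingGap:
    def test_signs(self):
        labels = ["A1", "A2", "B1"]
        species = ["A", "A", "B"]
        pos = matrix_from(labels, species,
                          {(0, 1): 0.02, (0, 2): 0.10, (1, 2): 0.10})
        recs = {g.query_id: g for g in barcoding_gap(pos)}
        assert recs["A1"].gap == pytest.approx(0.08)
        neg = matrix_from(labels, species,
                          {(0, 1): 0.10, (0, 2): 0.03, (1, 2): 0.03})
        recs = {g.query_id: g for g in barcoding_gap(neg)}
        assert recs["A1"].gap == pytest.approx(-0.07)

    def test_singleton_has_no_gap(self):
        labels = ["A1", "A2", "C1"]
        dm = matrix_from(labels, ["A", "A", "C"],
                         {(0, 1): 0.01, (0, 2): 0.2, (1, 2): 0.2})
        recs = {g.query_id: g for g in barcoding_gap(dm)}
        assert recs["C1"].max_intra is None and recs["C1"].gap is None
        assert recs["C1"].min_inter == pytest.approx(0.2)

    def test_gap_sign_iff_nn_conspecific_small_matrices(self, rng):
        """gap > 0 <=> (NN conspecific and min_inter > max_intra),
        checked exhaustively on random small matrices."""
        for _ in range(50):
            n = int(rng.integers(4, 7))
            labels = [f"S{i}" for i in range(n)]
            species = [rng.choice(["a", "b"]) for _ in range(n)]
            if len(set(species)) < 2:
                species[0] = "a" if species[1] == "b" else "b"
            d = {}
            for i, j in itertools.combinations(range(n), 2):
                d[(i, j)] = float(np.round(rng.uniform(0.01, 0.3), 3))
            dm = matrix_from(labels, species, d)
            gaps = {g.query_id: g for g in barcoding_gap(dm)}
            nn = {a.query_id: a for a in nearest_neighbor(dm)}
            for q in labels:
                g = gaps[q]
                if g.gap is None:
                    continue
                lhs = g.gap > 0
                rhs = (nn[q].conspecific == CONSPECIFIC
                       and g.min_inter > g.max_intra)
                assert lhs == rhs


class TestSpeciesSummary:
    def test_identical_pair(self):
        labels = ["A1", "A2", "B1"]
        dm = matrix_from(labels, ["A", "A", "B"],
                         {(0, 1): 0.0, (0, 2): 0.1, (1, 2): 0.1})
        s = {x.species: x for x in species_summary(dm)}
        assert s["A"].intra_min == 0.0 and s["A"].intra_max == 0.0

    def test_singleton_fields(self):
        labels = ["A1", "A2", "B1"]
        dm = matrix_from(labels, ["A", "A", "B"],
                         {(0, 1): 0.0, (0, 2): 0.1, (1, 2): 0.1})
        s = {x.species: x for x in species_summary(dm)}
        assert s["B"].intra_min is None
        assert s["B"].inter_mean == pytest.approx(0.1)

    def test_matches_brute_force_grouping(self, rng):
        n = 12
        labels = [f"S{i}" for i in range(n)]
        species = [str(rng.choice(["a", "b", "c"])) for _ in range(n)]
        d = {}
        for i, j in itertools.combinations(range(n), 2):
            d[(i, j)] = float(rng.uniform(0.01, 0.5))
        dm = matrix_from(labels, species, d)
        summaries = {s.species: s for s in species_summary(dm)}
        for sp in set(species):
            intra = [v for (i, j), v in d.items()
                     if species[i] == sp and species[j] == sp]
            inter = [v for (i, j), v in d.items()
                     if (species[i] == sp) != (species[j] == sp)]
            s = summaries[sp]
            if len(intra) >= 1:
                assert s.intra_mean == pytest.approx(np.mean(intra))
                assert s.intra_max == pytest.approx(max(intra))
            if inter:
                assert s.inter_min == pytest.approx(min(inter))
                assert s.inter_mean == pytest.approx(np.mean(inter))


class TestCompareMarkers:
    def test_fully_tied_h_zero(self):
        res = compare_markers({"a": [1, 2, 3], "b": [1, 2, 3],
                               "c": [1, 2, 3]})
        assert res.kw_chi2 == pytest.approx(0.0)

    def test_hand_ranked_h(self):
        # H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1) with N=9 gives 7.2
        res = compare_markers({"a": [1, 2, 3], "b": [4, 5, 6],
                               "c": [7, 8, 9]})
        assert res.kw_chi2 == pytest.approx(7.2)
        assert res.kw_df == 2

    def test_h_matches_brute_force_ranks(self, rng):
        groups = {
            "a": list(rng.uniform(0, 1, 4)),
            "b": list(rng.uniform(0, 1, 4)),
            "c": list(rng.uniform(0, 1, 4)),
        }
        pooled = np.concatenate([groups[g] for g in groups])
        ranks = stats.rankdata(pooled)
        N = len(pooled)
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start : start + len(groups[g])]
            h += r.sum() ** 2 / len(r)
            start += len(r)
        h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
        res = compare_markers(groups)
        assert res.kw_chi2 == pytest.approx(h)

    def test_single_comparison_bonferroni_identity(self, rng):
        res = compare_markers({"a": list(rng.normal(0, 1, 10)),
                               "b": list(rng.normal(2, 1, 10))})
        (a, b, z, p_raw, p_bonf) = res.pairwise[0]
        assert p_bonf == pytest.approx(min(1.0, p_raw))

    def test_dunn_pair_count(self):
        res = compare_markers({"a": [1.0, 2], "b": [3.0, 4], "c": [5.0, 6]})
        assert len(res.pairwise) == 3
        for *_, p_raw, p_bonf in res.pairwise:
            assert p_bonf == pytest.approx(min(1.0, p_raw * 3))

    def test_too_few_markers(self):
        with pytest.raises(ValueError):
            compare_markers({"a": [1.0, 2.0]})


class TestAuditGroups:
    def _setup(self, extra=None):
        labels = ["A1", "A2", "A3", "B1", "B2", "B3"]
        species = ["A", "A", "A", "B", "B", "B"]
        d = {}
        for i, j in itertools.combinations(range(6), 2):
            same = species[i] == species[j]
            d[(i, j)] = 0.01 if same else 0.25
        if extra:
            d.update(extra)
        return matrix_from(labels, species, d)

    def test_clean_clusters_group1(self):
        dm = self._setup()
        nn = nearest_neighbor(dm)
        groups = {a.query_id: a.group for a in audit_groups(dm, nn)}
        assert set(groups.values()) == {1}

    def test_planted_mislabel_group3(self):
        # B3 actually sits inside species A's cluster (just outside the
        # A-A nearest-neighbor distance, so A calls stay unambiguous)
        extra = {(0, 5): 0.012, (1, 5): 0.012, (2, 5): 0.012,
                 (3, 5): 0.25, (4, 5): 0.25}
        dm = self._setup(extra)
        nn = nearest_neighbor(dm)
        rec = {a.query_id: a for a in audit_groups(dm, nn)}
        assert rec["B3"].group == 3
        assert rec["A1"].group == 1

    def test_tie_goes_to_group2(self):
        labels = ["Q", "S", "S2", "H", "H2"]
        species = ["x", "x", "x", "y", "y"]
        d = {}
        for i, j in itertools.combinations(range(5), 2):
            d[(i, j)] = 0.02 if species[i] == species[j] else 0.30
        d[(0, 1)] = 0.05
        d[(0, 2)] = 0.05
        d[(0, 3)] = 0.05  # tie with a heterospecific
        dm = matrix_from(labels, species, d)
        nn = nearest_neighbor(dm)
        rec = {a.query_id: a for a in audit_groups(dm, nn)}
        assert rec["Q"].group == 2

    def test_singletons_not_audited(self):
        labels = ["A1", "A2", "C1"]
        dm = matrix_from(labels, ["A", "A", "C"],
                         {(0, 1): 0.01, (0, 2): 0.3, (1, 2): 0.3})
        nn = nearest_neighbor(dm)
        assert {a.query_id for a in audit_groups(dm, nn)} == {"A1", "A2"}


def test_dunn_z_sign_and_symmetry(rng):
    low = list(rng.uniform(0, 0.2, 8))
    high = list(rng.uniform(0.8, 1.0, 8))
    res = dunn_test({"low": low, "high": high})
    (a, b, z, p_raw, p_bonf) = res[0]
    assert z < 0  # low group has smaller mean rank
    assert 0 <= p_raw <= 1
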
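"""Elastic structural alignment, Z-scores, distances, trees and Newick I/O."""

import io as _io
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from sixhelix import struct_phylo as sp
from sixhelix.perv_standin import build_standin
from sixhelix.synthetic_data import BundleSpec, make_coiled_coil, make_protomer


def brute_best(pa, pb):
    best = -np.inf
    for k in range(3, min(len(pa), len(pb)) + 1):
        for ca in combinations(range(len(pa)), k):
            for cb in combinations(range(len(pb)), k):
                s = sp.elastic_score(pa, pb, list(zip(ca, cb)))
                best = max(best, s)
    return best


class TestFilter:
    def test_rules(self):
        recs = [
            sp.StructureMeta("ok", 2.0, True, True, True),
            sp.StructureMeta("lowres", 5.0, True, True, True),
            sp.StructureMeta("nocr", 3.0, True, False, True),
            sp.StructureMeta("nores", None, True, True, True),
            sp.StructureMeta("edge", 4.5, True, True, True),
        ]
        accepted, rejected = sp.filter_inputs(recs)
        assert accepted == ["ok", "edge"]
        assert set(rejected) == {"lowres", "nocr", "nores"}
        assert "resolution" in rejected["nores"]


class TestTruncate:
    def test_standin_starts_at_stutter(self):
        dom = sp.truncate_at_stutter(build_standin(n_trimers=1), (506, 509))
        assert dom.numbers[0] == 506
        assert dom.numbers[-1] == 587

    def test_generator_bundle(self):
        model, _ = make_coiled_coil(BundleSpec(n_residues=42,
                                               stutter_positions=(20,)))
        dom = sp.truncate_at_stutter(model, (21, 24))
        assert dom.numbers[0] == 21 and len(dom) == 22

    def test_missing_stutter_is_informative_error(self):
        model, _ = make_coiled_coil(BundleSpec(n_residues=42))
        with pytest.raises(ValueError, match="fallback"):
            sp.truncate_at_stutter(model)


class TestElasticScore:
    def test_self_alignment_matches_formula(self, rng):
        p = rng.normal(0, 4, (10, 3))
        pairs = [(i, i) for i in range(10)]
        s = sp.elastic_score(p, p, pairs)
        from scipy.spatial.distance import cdist

        d = cdist(p, p)
        dstar = d[~np.eye(10, dtype=bool)]
        expected = np.sum(sp.THETA * np.exp(-((dstar / sp.ALPHA) ** 2))) + 10 * sp.THETA
        assert s == pytest.approx(expected, rel=1e-12)
        assert s > 0

    def test_rigid_rotation_exact_invariance(self, rng):
        p = rng.normal(0, 5, (12, 3))
        rot = Rotation.from_euler("xyz", [10, 60, -40], degrees=True).as_matrix()
        q = p @ rot.T + np.array([1.0, 2.0, 3.0])
        pairs = [(i, i) for i in range(12)]
        assert sp.elastic_score(p, q, pairs) == pytest.approx(
            sp.elastic_score(p, p, pairs), rel=1e-12)

    def test_requires_monotone_and_min_pairs(self, rng):
        p = rng.normal(0, 4, (6, 3))
        with pytest.raises(ValueError):
            sp.elastic_score(p, p, [(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            sp.elastic_score(p, p, [(0, 1), (1, 0), (2, 2)])


class TestZscore:
    def test_definition_points(self):
        m = sp.mean_score(np.sqrt(50 * 60))
        assert sp.zscore(m, 50, 60) == pytest.approx(0.0)
        assert sp.zscore(1.5 * m, 50, 60) == pytest.approx(1.0)

    def test_frozen_cubic_value(self):
        # hand evaluation: 7.95 + 71 - 2.59 - 1.92
        assert sp.mean_score(100) == pytest.approx(74.44)

    def test_capped_above_400(self):
        assert sp.mean_score(600) == sp.mean_score(400)

    def test_monotone_in_score(self):
        zs = [sp.zscore(s, 80, 80) for s in (10.0, 50.0, 90.0)]
        assert zs == sorted(zs)


class TestPairwiseDistance:
    @pytest.mark.parametrize("zaa,zbb,zab,d", [
        (10, 10, 10, 10.0),
        (50, 60, 30, 80.0),
        (5, 5, 12, 0.0),
    ])
    def test_literal_formula(self, zaa, zbb, zab, d):
        assert sp.pairwise_distance(zaa, zbb, zab) == d

    def test_normalized_variant_zeroes_self(self):
        assert sp.pairwise_distance(10, 10, 10, normalized=True) == 0.0
        assert sp.pairwise_distance(50, 60, 30, normalized=True) == 50.0


class TestAlign:
    def test_rigid_copy_full_length(self, rng):
        p = rng.normal(0, 3, (25, 3)).cumsum(axis=0)
        rot = Rotation.from_euler("zxy", [75, -20, 140], degrees=True).as_matrix()
        q = p @ rot.T + np.array([8.0, -3.0, 1.0])
        aln = sp.align_structures(p, q, seed=0)
        assert aln.n_aligned == 25
        assert aln.rmsd < 0.01
        assert aln.score == pytest.approx(
            sp.elastic_score(p, p, [(i, i) for i in range(25)]), rel=1e-9)

    def test_heuristic_near_oracle_on_toys(self):
        for t in range(10):
            rng = np.random.default_rng(4000 + t)
            pa = rng.normal(0, 4, (int(rng.integers(5, 9)), 3))
            pb = rng.normal(0, 4, (int(rng.integers(5, 9)), 3))
            h = sp.align_structures(pa, pb, seed=t).score
            o = brute_best(pa, pb)
            assert h >= 0.95 * o - 1e-9

    def test_collinear_geometry_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear"):
            sp.align_structures(line, line)

    def test_deterministic_given_seed(self, rng):
        pa = rng.normal(0, 4, (20, 3)).cumsum(axis=0)
        pb = rng.normal(0, 4, (22, 3)).cumsum(axis=0)
        a1 = sp.align_structures(pa, pb, seed=5)
        a2 = sp.align_structures(pa, pb, seed=5)
        assert a1.pairs == a2.pairs and a1.score == a2.score


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            sp.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError):
            sp.DistanceMatrix(["a", "b"], np.array([[0, -3], [-3, 0.0]]))

    def test_all_vs_all_symmetric_zero_diag(self):
        doms = [make_protomer(f"s{i}", 6 + 4 * i, noise=0.1, seed=i)
                for i in range(3)]
        dm, report = sp.all_vs_all(doms, seed=0)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        assert len(report) == 3


class TestUpgma:
    def test_three_leaf_hand_oracle(self):
        dm = sp.DistanceMatrix(["A", "B", "C"],
                               np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float))
        tree = sp.build_dendrogram(dm)
        assert sp.write_newick(tree).strip() == "((A:1.0,B:1.0):3.0,C:4.0);"
        assert list(tree.linkage[:, 2]) == [2.0, 8.0]

    def test_ultrametric_recovery(self):
        # generated by a known tree: (A,B) at height 1, (C,D) at 1.5, root at 5
        d = np.array([
            [0, 2, 10, 10],
            [2, 0, 10, 10],
            [10, 10, 0, 3],
            [10, 10, 3, 0],
        ], float)
        tree = sp.build_dendrogram(sp.DistanceMatrix(list("ABCD"), d))
        newick = sp.write_newick(tree).strip()
        assert newick == "((A:1.0,B:1.0):4.0,(C:1.5,D:1.5):3.5);"
        # merge heights equal half the pairwise distances (exact)
        assert list(tree.linkage[:, 2]) == [2.0, 3.0, 10.0]

    def test_all_equal_ties_resolved_by_label_order(self):
        d = np.full((4, 4), 6.0)
        np.fill_diagonal(d, 0.0)
        tree = sp.build_dendrogram(sp.DistanceMatrix(list("DCBA"), d))
        assert sp.write_newick(tree).strip() == (
            "(((A:3.0,B:3.0):0.0,C:3.0):0.0,D:3.0);")

    @given(st.integers(0, 10_000))
    def test_cophenetic_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        cond = rng.uniform(1.0, 10.0, size=n * (n - 1) // 2)
        d = squareform(cond)
        labels = [f"t{i}" for i in range(n)]
        mine = sp.build_dendrogram(sp.DistanceMatrix(labels, d))
        ours = hierarchy.cophenet(mine.linkage)
        ref = hierarchy.cophenet(hierarchy.linkage(cond, method="average"))
        assert np.allclose(np.sort(ours), np.sort(ref))

    def test_nj_available(self):
        d = np.array([[0, 5, 9, 9], [5, 0, 10, 10],
                      [9, 10, 0, 8], [9, 10, 8, 0]], float)
        tree = sp.build_dendrogram(sp.DistanceMatrix(list("ABCD"), d), method="nj")
        assert sorted(t.name for t in tree.tree.tips()) == list("ABCD")
        with pytest.raises(ValueError):
            tree.cut(2)


class TestNewick:
    def test_two_leaf_form(self):
        dm = sp.DistanceMatrix(["A", "B", "C"],
                               np.array([[0, 2, 9], [2, 0, 9], [9, 9, 0.0]]))
        text = sp.write_newick(sp.build_dendrogram(dm))
        assert text.startswith("((A:") and text.rstrip().endswith(";")

    def test_roundtrip_ten_leaves_isomorphic(self):
        rng = np.random.default_rng(17)
        cond = rng.uniform(1, 20, size=45)
        d = squareform(cond)
        labels = [f"virus {i}" for i in range(10)]  # spaces get sanitized
        tree = sp.build_dendrogram(sp.DistanceMatrix(labels, d))
        text = sp.write_newick(tree)
        back = sp.read_newick(text)
        rf = tree.tree.compare_rfd(back.tree)
        assert rf == 0.0
        total = sum(n.length or 0 for n in back.tree.traverse())
        expect = sum(n.length or 0 for n in tree.tree.traverse())
        assert total == pytest.approx(expect)

    def test_unbalanced_parentheses(self):
        with pytest.raises(ValueError):
            sp.read_newick("((A:1,B:1;")
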
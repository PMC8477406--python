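"""Neighbour joining (additivity oracle), bootstrap and classification."""

import numpy as np
import pytest

from pansubspec.ani import AniResult, PairwiseAniTable
from pansubspec.cluster import GeneFamily
from pansubspec.phylo import (DistanceMatrix, PhyloInputError,
                              bipartitions, bootstrap_supports,
                              classify_by_type_strain, core_distance_matrix,
                              leaf_path_lengths, neighbor_joining,
                              random_additive_instance)


class TestNeighborJoining:
    def test_four_leaf_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); split AB|CD, lengths recovered exactly
        D = DistanceMatrix(list("ABCD"), np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float))
        tree = neighbor_joining(D)
        names, pl = leaf_path_lengths(tree)
        assert names == list("ABCD")
        assert np.allclose(pl, D.matrix, atol=1e-12)
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        leaf_lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert leaf_lengths == {"A": 1, "B": 2, "C": 3, "D": 4}

    def test_three_leaf_ultrametric_star(self):
        D = DistanceMatrix(list("ABC"), np.array(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        tree = neighbor_joining(D)
        assert sorted(lf.length for lf in tree.leaves()) == [1, 1, 1]

    def test_additive_path_length_reconstruction(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            D, true_parts, _ = random_additive_instance(n, rng)
            tree = neighbor_joining(D)
            names, pl = leaf_path_lengths(tree)
            order = [D.ids.index(nm) for nm in names]
            assert np.max(np.abs(pl - D.matrix[np.ix_(order, order)])) < 1e-9
            assert bipartitions(tree) == true_parts

    def test_agrees_with_reference_nj_topology(self):
        # independent oracle: scikit-bio's NJ on the same matrix
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(3)
        D, _, _ = random_additive_instance(8, rng)
        ours = neighbor_joining(D)
        ref = skbio_nj(SkbioDM(D.matrix, ids=D.ids))
        ref_parts = set()
        all_leaves = frozenset(D.ids)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                ref_parts.add(min(side, other,
                                  key=lambda s: (len(s), tuple(sorted(s)))))
        assert bipartitions(ours) == ref_parts

    def test_too_few_leaves_rejected(self):
        with pytest.raises(PhyloInputError):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0, 1], [1, 0]], float)))


class TestCoreDistanceMatrix:
    def _family(self, fid, seqs):
        members = [(g, f"{g}|{fid}") for g in seqs]
        proteins = {f"{g}|{fid}": s for g, s in seqs.items()}
        return GeneFamily(family_id=fid, members=members), proteins

    def test_identical_sequences_zero_matrix(self):
        fam, prots = self._family("f", {"g1": "MKLV" * 25, "g2": "MKLV" * 25})
        D, _ = core_distance_matrix([fam], ["g1", "g2"], prots)
        assert np.allclose(D.matrix, 0)

    def test_single_substitution_p_distance(self):
        a = "MKLV" * 25
        b = a[:-1] + "W"   # 1 substitution in 100 columns
        fam, prots = self._family("f", {"g1": a, "g2": b})
        D, _ = core_distance_matrix([fam], ["g1", "g2"], prots)
        assert D.matrix[0, 1] == pytest.approx(0.01)

    def test_alignment_length_weighting(self):
        # lengths 100 and 300 with p-distances 0.01 and 0.05 -> 0.04
        a100 = "MKLV" * 25
        b100 = a100[:-1] + "W"
        a300 = "MKLVEDHIRS" * 30      # W-free, so every replacement differs
        b300 = "W" * 15 + a300[15:]   # 15/300 = 0.05
        f1, p1 = self._family("f1", {"g1": a100, "g2": b100})
        f2, p2 = self._family("f2", {"g1": a300, "g2": b300})
        D, per_family = core_distance_matrix([f1, f2], ["g1", "g2"],
                                             {**p1, **p2})
        assert D.matrix[0, 1] == pytest.approx((100 * 0.01 + 300 * 0.05) / 400)
        assert len(per_family) == 2

    def test_missing_genome_rejected(self):
        fam, prots = self._family("f", {"g1": "MKLV" * 25})
        with pytest.raises(PhyloInputError):
            core_distance_matrix([fam], ["g1", "g2"], prots)


class TestBootstrap:
    def _per_family_identical(self, n_fam=5):
        rng = np.random.default_rng(0)
        D, _, _ = random_additive_instance(6, rng)
        cols = np.full_like(D.matrix, 100.0)
        np.fill_diagonal(cols, 0)
        return [(D.matrix, cols) for _ in range(n_fam)], D.ids

    def test_identical_families_all_supports_100(self):
        per_family, ids = self._per_family_identical()
        tree = bootstrap_supports(per_family, ids, B=50, seed=4)
        supports = [n.support for n in _internal_nodes(tree)
                    if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_under_seed(self):
        per_family, ids = self._per_family_identical()
        t1 = bootstrap_supports(per_family, ids, B=30, seed=9)
        t2 = bootstrap_supports(per_family, ids, B=30, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_leaf_order_invariance_of_supports(self):
        per_family, ids = self._per_family_identical()
        perm = list(reversed(range(len(ids))))
        per_perm = [(p[np.ix_(perm, perm)], c[np.ix_(perm, perm)])
                    for p, c in per_family]
        t1 = bootstrap_supports(per_family, ids, B=40, seed=2)
        t2 = bootstrap_supports(per_perm, [ids[i] for i in perm], B=40, seed=2)
        def support_map(t):
            all_leaves = frozenset(t.leaf_names())
            out = {}
            for node in _internal_nodes(t):
                if node.support is None:
                    continue
                side = frozenset(node.leaf_names())
                canon = min(side, all_leaves - side,
                            key=lambda s: (len(s), tuple(sorted(s))))
                out[canon] = node.support
            return out
        assert support_map(t1) == support_map(t2)

    def test_subspecies_clades_strongly_supported(self, default_pipeline,
                                                  default_cohort):
        _, _, _, truth = default_cohort
        tree = default_pipeline.tree
        parts = bipartitions(tree)
        all_leaves = frozenset(tree.leaf_names())
        kept = set(tree.leaf_names())
        clades = {}
        for s in ("longum", "infantis", "suis"):
            clade = frozenset(g for g in kept
                              if truth.true_subspecies[g] == s)
            clades[s] = min(clade, all_leaves - clade,
                            key=lambda x: (len(x), tuple(sorted(x))))
        support = {}
        for node in _internal_nodes(tree):
            if node.support is None:
                continue
            side = frozenset(node.leaf_names())
            canon = min(side, all_leaves - side,
                        key=lambda s: (len(s), tuple(sorted(s))))
            support[canon] = node.support
        found = [clades[s] for s in clades if clades[s] in parts]
        assert len(found) >= 2   # 3 clades of an unrooted tree => 2 edges
        assert all(support[c] >= 95 for c in found)

    def test_invalid_replicates(self):
        per_family, ids = self._per_family_identical()
        with pytest.raises(PhyloInputError):
            bootstrap_supports(per_family, ids, B=0, seed=1)


def _internal_nodes(tree):
    out = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            out.append(node)
            stack.extend(node.children)
    return out


class TestClassifyByTypeStrain:
    def _table(self, values, ids):
        table = PairwiseAniTable(ids)
        for (a, b), v in values.items():
            table.add(AniResult(a, b, v, 10, 10))
            table.add(AniResult(b, a, v, 10, 10))
        return table

    def test_type_strain_assigned_to_itself(self):
        ids = ["tsA", "tsB"]
        table = self._table({("tsA", "tsB"): 95.0}, ids)
        res = classify_by_type_strain(table, {"a": "tsA", "b": "tsB"},
                                      {"tsA": "a", "tsB": "b"})
        by_id = {r["genome_id"]: r for r in res}
        assert by_id["tsA"]["assigned_subspecies"] == "a"
        assert not by_id["tsA"]["misclassified"]

    def test_tie_flagged_ambiguous(self):
        ids = ["g", "tsA", "tsB"]
        table = self._table({("g", "tsA"): 97.0, ("g", "tsB"): 97.0,
                             ("tsA", "tsB"): 95.0}, ids)
        res = classify_by_type_strain(table, {"a": "tsA", "b": "tsB"},
                                      {"g": "b", "tsA": "a", "tsB": "b"})
        g = next(r for r in res if r["genome_id"] == "g")
        assert g["ambiguous"] and g["assigned_subspecies"] == "a"

    def test_missing_type_strain_rejected(self):
        table = self._table({("x", "y"): 95.0}, ["x", "y"])
        with pytest.raises(PhyloInputError):
            classify_by_type_strain(table, {"a": "zz"}, {})

    def test_planted_mislabels_flagged_exactly(self, default_pipeline,
                                               default_cohort):
        _, _, records, truth = default_cohort
        flagged = sorted(c["genome_id"] for c in default_pipeline.classification
                         if c["misclassified"])
        kept = set(default_pipeline.kept_ids)
        planted = sorted(
            r.genome_id for r in records if r.genome_id in kept
            and r.subspecies_label != truth.true_subspecies[r.genome_id])
        assert flagged == planted
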
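"""Distance models, neighbor joining, bootstrap support and Newick I/O."""

import math

import numpy as np
import pytest

from seqdigit.alignment import MultipleAlignment, complete_deletion, \
    progressive_align
from seqdigit.phylo import (BootstrapError, DistanceMatrix, PhyloError,
                            SaturationError, TreeNode, PhyloTree,
                            bootstrap_support, neighbor_joining,
                            newick_to_tree, pairwise_distances,
                            random_additive_tree, read_newick,
                            substitution_counts, total_branch_length,
                            tree_to_newick, write_newick)
from seqdigit.seqio import FixtureConfig, make_strain_family


def pair_msa(a: str, b: str) -> MultipleAlignment:
    return MultipleAlignment(ids=("a", "b"), rows=(a, b))


class TestDistances:
    def test_identical_rows_zero_under_every_model(self):
        msa = pair_msa("ACGT" * 50, "ACGT" * 50)
        for model in ("p", "jc69", "k2p", "tn93", "mcl"):
            assert pairwise_distances(msa, model).matrix[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        a = "ACGT" * 25
        b = "TCGT" + "ACGT" * 23 + "AGGA"  # 3 mismatches over 100 columns
        msa = pair_msa(a, b)
        assert pairwise_distances(msa, "p").matrix[0, 1] == pytest.approx(0.03)

    def test_jc69_closed_form(self):
        a = "ACGT" * 25
        b = "TCGT" + "ACGT" * 23 + "AGGA"
        d = pairwise_distances(pair_msa(a, b), "jc69").matrix[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.03 / 3),
                                  abs=1e-12)
        assert d == pytest.approx(0.0306165, abs=5e-7)

    def test_corrections_reduce_to_p_at_small_divergence(self):
        a = "ACGT" * 250
        b = "T" + a[1:]  # p = 1e-3, balanced composition
        msa = pair_msa(a, b)
        p = pairwise_distances(msa, "p").matrix[0, 1]
        for model in ("jc69", "k2p", "tn93"):
            d = pairwise_distances(msa, model).matrix[0, 1]
            assert abs(d - p) < 1e-4

    def test_closed_forms_match_ape(self):
        """Frozen oracle: distances computed with R's ape::dist.dna on this
        exact (deterministic) alignment."""
        recs = make_strain_family(FixtureConfig(
            n_strains=3, length_range=(300, 320), divergence=0.05,
            outgroup_divergence=0.12, seed=7))
        filtered, _ = complete_deletion(progressive_align(recs))
        expected = {
            "jc69": [0.02062, 0.031146, 0.089928, 0.045416, 0.09761, 0.109284],
            "k2p": [0.02062, 0.031146, 0.090005, 0.04542, 0.097788, 0.10933],
            "tn93": [0.02062, 0.03116, 0.090026, 0.045436, 0.097811, 0.109397],
        }
        iu = np.triu_indices(4, 1)
        for model, vals in expected.items():
            got = pairwise_distances(filtered, model).matrix[iu]
            np.testing.assert_allclose(got, vals, atol=2e-5)

    def test_saturation_raises_and_names_pair(self):
        a = "A" * 100
        b = "G" * 80 + "C" * 20  # p = 1.0, far beyond every model's range
        with pytest.raises(SaturationError, match="a.*b"):
            pairwise_distances(pair_msa(a, b), "jc69")

    def test_gapped_alignment_rejected(self):
        with pytest.raises(PhyloError, match="complete_deletion"):
            pairwise_distances(pair_msa("AC-T", "ACGT"), "p")

    def test_substitution_counts_sum_to_columns(self, small_msa):
        _, filtered, _ = small_msa
        sub = substitution_counts(filtered)
        for tab in sub.pairs.values():
            assert tab.sum() == filtered.n_columns

    def test_mcl_close_to_tn93_in_target_regime(self, small_msa):
        _, filtered, _ = small_msa
        d_mcl = pairwise_distances(filtered, "mcl").matrix
        d_tn = pairwise_distances(filtered, "tn93").matrix
        np.testing.assert_allclose(d_mcl, d_tn, atol=2e-3)

    def test_mcl_monotone_in_divergence(self, small_msa):
        _, filtered, _ = small_msa
        d = pairwise_distances(filtered, "mcl").as_dataframe()
        ingroup = [l for l in d.index if l.startswith("SYNSTR")]
        out = "SYNOUT01"
        assert d.loc[ingroup, out].min() > d.loc[ingroup, ingroup].max().max()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(labels=("A", "B", "C"),
                            matrix=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                                            dtype=float))
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}
        assert total_branch_length(tree) == pytest.approx(4.5)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(labels=("A", "B"),
                            matrix=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(PhyloError):
            neighbor_joining(dm)

    @pytest.mark.parametrize("n_leaves", [4, 6, 8, 10])
    def test_recovers_random_additive_trees(self, n_leaves):
        for seed in range(5):
            tree = random_additive_tree(n_leaves, seed=1000 * n_leaves + seed)
            dm = tree.leaf_distance_matrix()
            recovered = neighbor_joining(dm)
            err = np.abs(recovered.leaf_distance_matrix().matrix - dm.matrix)
            assert err.max() < 1e-9
            assert recovered.n_edges() == 2 * n_leaves - 3
            assert total_branch_length(recovered) == pytest.approx(
                total_branch_length(tree))

    def test_ultrametric_quartet_matches_upgma(self):
        """On an ultrametric 4-leaf matrix NJ must choose the same quartet
        split as average-linkage clustering; checked against brute force
        over the three possible quartets."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        # ultrametric: ((A,B),(C,D)) with heights 1, 2, 4
        m = np.array([[0, 2, 8, 8], [2, 0, 8, 8],
                      [8, 8, 0, 4], [8, 8, 4, 0]], dtype=float)
        labels = ("A", "B", "C", "D")
        tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lk = linkage(squareform(m), method="average")
        first_pair = {labels[int(lk[0, 0])], labels[int(lk[0, 1])]}
        assert first_pair == {"A", "B"}  # same split, complementary side

    def test_topology_invariant_to_label_order(self):
        tree = random_additive_tree(7, seed=99)
        dm = tree.leaf_distance_matrix()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(dm.labels))
        dm_perm = DistanceMatrix(
            labels=tuple(dm.labels[i] for i in perm),
            matrix=dm.matrix[np.ix_(perm, perm)])
        assert neighbor_joining(dm).bipartitions() == \
            neighbor_joining(dm_perm).bipartitions()

    def test_topology_matches_skbio(self):
        """Independent route: scikit-bio's NJ on the same matrix yields the
        same set of bipartitions."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        tree = random_additive_tree(7, seed=11)
        dm = tree.leaf_distance_matrix()
        ours = neighbor_joining(dm).bipartitions()
        sk = sknj(SkDM(dm.matrix, ids=list(dm.labels)))
        all_leaves = frozenset(dm.labels)
        ref = min(all_leaves)
        theirs = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_leaves) - 2:
                theirs.add(all_leaves - side if ref in side else side)
        assert ours == theirs

    def test_branch_lengths_never_negative(self):
        # a noisy, non-additive matrix that would drive naive NJ negative
        m = np.array([[0, .1, .4, .41], [.1, 0, .4, .41],
                      [.4, .4, 0, .01], [.41, .41, .01, 0]])
        tree = neighbor_joining(DistanceMatrix(labels=("A", "B", "C", "D"),
                                               matrix=m))
        assert all(c.length >= 0 for _, c in tree.edges())


class TestBootstrap:
    def test_identity_resample_gives_full_support(self, small_msa):
        _, filtered, _ = small_msa
        tree = bootstrap_support(filtered, model="p", n_reps=1,
                                 resample=lambda rng, n: np.arange(n))
        supports = [c.support for c, _ in tree.internal_edges()]
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_for_fixed_seed(self, small_msa):
        _, filtered, _ = small_msa
        t1 = bootstrap_support(filtered, model="p", n_reps=30, seed=5)
        t2 = bootstrap_support(filtered, model="p", n_reps=30, seed=5)
        s1 = {k: c.support for c, k in t1.internal_edges()}
        s2 = {k: c.support for c, k in t2.internal_edges()}
        assert s1 == s2

    def test_supports_within_bounds(self, small_msa):
        _, filtered, _ = small_msa
        tree = bootstrap_support(filtered, model="tn93", n_reps=50, seed=2)
        for child, _ in tree.internal_edges():
            assert 0.0 <= child.support <= 100.0

    def test_deep_split_gets_high_support(self):
        """Two clusters separated by a deep branch: the cluster-vs-cluster
        bipartition must appear in nearly all replicates (simulation with a
        known generating tree)."""
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))

        def mutate(seq: np.ndarray, rate: float) -> np.ndarray:
            out = seq.copy()
            hits = np.flatnonzero(rng.random(seq.size) < rate)
            for i in hits:
                out[i] = rng.choice(bases[bases != out[i]])
            return out

        anc = rng.choice(bases, size=600)
        anc_b = mutate(anc, 0.05)  # deep split
        rows, ids = [], []
        for g, start in (("A", anc), ("B", anc_b)):
            for i in range(3):
                ids.append(f"{g}{i + 1}")
                rows.append("".join(mutate(start, 0.005)))
        msa = MultipleAlignment(ids=tuple(ids), rows=tuple(rows))
        tree = bootstrap_support(msa, model="mcl", n_reps=200, seed=3)
        supports = {k: c.support for c, k in tree.internal_edges()}
        deep_key = frozenset({"B1", "B2", "B3"})  # side without ref leaf A1
        assert deep_key in supports
        assert supports[deep_key] >= 95.0

    def test_label_permutation_invariance(self, small_msa):
        _, filtered, _ = small_msa
        perm = (2, 0, 3, 1, 4)
        permuted = MultipleAlignment(
            ids=tuple(filtered.ids[i] for i in perm),
            rows=tuple(filtered.rows[i] for i in perm))
        s1 = {k: c.support for c, k in
              bootstrap_support(filtered, "p", n_reps=40, seed=9)
              .internal_edges()}
        s2 = {k: c.support for c, k in
              bootstrap_support(permuted, "p", n_reps=40, seed=9)
              .internal_edges()}
        assert s1 == s2

    def test_excess_saturated_replicates_error(self):
        # two near-saturated pairs: resampling often crosses p >= 0.75
        rng = np.random.default_rng(4)
        base = rng.choice(list("ACGT"), size=60)
        far = base.copy()
        idx = rng.choice(60, size=45, replace=False)
        for i in idx:
            far[i] = {"A": "G", "G": "C", "C": "T", "T": "A"}[far[i]]
        msa = MultipleAlignment(
            ids=("a", "b", "c", "d"),
            rows=("".join(base), "".join(base), "".join(far), "".join(far)))
        with pytest.raises((BootstrapError, SaturationError)):
            bootstrap_support(msa, model="jc69", n_reps=100, seed=0)


class TestNewick:
    def test_round_trip_preserves_structure(self):
        tree = random_additive_tree(5, seed=8)
        for child, _ in tree.internal_edges():
            child.support = 87.0
        back = newick_to_tree(tree_to_newick(tree))
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)
        assert back.bipartitions() == tree.bipartitions()
        assert total_branch_length(back) == pytest.approx(
            total_branch_length(tree))
        assert {c.support for c, _ in back.internal_edges()} == {87.0}

    def test_parse_known_string(self):
        tree = newick_to_tree("(A:1,B:2,(C:3,D:4):5);")
        assert sorted(tree.leaf_names) == ["A", "B", "C", "D"]
        assert total_branch_length(tree) == pytest.approx(15.0)

    def test_file_round_trip(self, tmp_path):
        tree = random_additive_tree(6, seed=13)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.bipartitions() == tree.bipartitions()

    def test_malformed_rejected(self):
        with pytest.raises(PhyloError):
            newick_to_tree("(A:1,B:2")

    def test_total_branch_length_requires_lengths(self):
        tree = PhyloTree(root=TreeNode(children=[
            TreeNode(name="A"), TreeNode(name="B"), TreeNode(name="C")]))
        with pytest.raises(PhyloError):
            total_branch_length(tree)

    def test_star_tree_with_zero_lengths(self):
        tree = PhyloTree(root=TreeNode(children=[
            TreeNode(name=n, length=0.0) for n in "ABC"]))
        assert total_branch_length(tree) == 0.0
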
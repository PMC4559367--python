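import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paralogdiverge.distances import DistanceMatrix
from paralogdiverge.simulate import random_tree
from paralogdiverge.trees import (
    PhyloTree,
    TreeError,
    clade_contrast,
    nj_tree,
    read_newick,
    tree_distance,
    write_newick,
)


def dm(ids, values):
    return DistanceMatrix(ids=tuple(ids), values=np.asarray(values, dtype=float))


class TestNewickIO:
    def test_roundtrip_preserves_topology_and_lengths(self, tmp_path):
        t = read_newick("(A:1,B:2,(C:3,D:4):5);")
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        t2 = read_newick(path)
        assert t2.to_newick() == "(A:1,B:2,(C:3,D:4):5);"
        assert sorted(t2.leaf_names()) == ["A", "B", "C", "D"]

    def test_lengths_preserved_to_many_digits(self):
        t = read_newick("(A:0.1234567891,B:2e-05);")
        assert t.to_newick() == "(A:0.1234567891,B:2e-05);"

    def test_tree_without_lengths_writes_no_colons(self):
        t = read_newick("(A,B,(C,D));")
        assert ":" not in t.to_newick()

    def test_malformed_newick_raises(self):
        with pytest.raises(TreeError):
            read_newick("((A:1,B:2;")

    def test_underscores_preserved(self):
        t = read_newick("(sp_1:1,sp_2:1,sp_3:1);")
        assert sorted(t.leaf_names()) == ["sp_1", "sp_2", "sp_3"]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        t = nj_tree(d)
        lengths = {n.name: n.length for n in t.leaves()}
        # a = (d_AB + d_AC - d_BC)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_zero_matrix_star_tree(self):
        d = dm("ABCD", np.zeros((4, 4)))
        t = nj_tree(d)
        assert all(n.length == 0 for n in t.leaves())

    def test_saturated_matrix_refused(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = np.inf
        with pytest.raises(TreeError, match="saturated"):
            nj_tree(dm("ABC", v))

    def test_too_few_taxa_refused(self):
        with pytest.raises(TreeError):
            nj_tree(dm("AB", np.zeros((2, 2))))

    def test_additive_four_taxon_matrix_recovered(self):
        # tree ((A:2,B:3):1,C:4,D:5) -> additive distances
        vals = [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]]
        t = nj_tree(dm("ABCD", vals))
        for a, b, expected in [("A", "B", 5), ("A", "C", 7), ("A", "D", 8),
                               ("B", "C", 8), ("B", "D", 9), ("C", "D", 9)]:
            assert tree_distance(t, a, b) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 12))
    def test_additivity_random_trees(self, seed, n):
        """NJ reconstructs path lengths exactly from additive matrices."""
        rng = np.random.default_rng(seed)
        true = random_tree(n, rng, tree_length=float(n))
        names = sorted(true.leaf_names())
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = tree_distance(true, names[i], names[j])
        rebuilt = nj_tree(dm(names, vals))
        for i in range(n):
            for j in range(i + 1, n):
                assert tree_distance(rebuilt, names[i], names[j]) == pytest.approx(
                    vals[i, j], abs=1e-9
                )

    def test_skbio_cross_check(self):
        """Same topology and path lengths as scikit-bio's NJ on a random
        non-additive matrix."""
        import skbio

        rng = np.random.default_rng(5)
        n = 6
        base = rng.uniform(0.1, 1.0, size=(n, n))
        vals = (base + base.T) / 2
        np.fill_diagonal(vals, 0)
        ids = [f"t{i}" for i in range(n)]
        ours = nj_tree(dm(ids, vals))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(vals, ids))
        for i in range(n):
            for j in range(i + 1, n):
                assert tree_distance(ours, ids[i], ids[j]) == pytest.approx(
                    theirs.find(ids[i]).distance(theirs.find(ids[j])), abs=1e-9
                )


class TestCladeContrast:
    def make_two_clade_tree(self, scale_a=1.0, scale_b=1.0):
        nwk = (
            f"((a1:{scale_a},a2:{scale_a}):{scale_a},"
            f"(b1:{scale_b},b2:{scale_b}):{scale_b},b3:{2 * scale_b});"
        )
        return read_newick(nwk)

    def test_equal_rates_ratio_one(self):
        t = self.make_two_clade_tree()
        groups = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2", "b3": "P2"}
        cc = clade_contrast(t, groups)
        assert cc.ratio == pytest.approx((1.0) / ((2 + 2 + 2) / 3))

    def test_doubled_branch_lengths_double_the_ratio(self):
        t1 = self.make_two_clade_tree(1.0, 1.0)
        t2 = self.make_two_clade_tree(2.0, 1.0)
        groups = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2", "b3": "P2"}
        r1 = clade_contrast(t1, groups).ratio
        r2 = clade_contrast(t2, groups).ratio
        assert r2 == pytest.approx(2 * r1)

    def test_zero_lengths_ratio_undefined(self):
        t = read_newick("((a1:0,a2:0):0,(b1:0,b2:0):0);")
        groups = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"}
        cc = clade_contrast(t, groups)
        assert cc.ratio is None
        assert cc.a.total_length == 0

    def test_spanning_subtree_lengths(self):
        t = read_newick("((a1:1,a2:2):5,(b1:3,b2:4):5);")
        groups = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"}
        cc = clade_contrast(t, groups)
        assert cc.a.total_length == pytest.approx(3)  # stem edges excluded
        assert cc.b.total_length == pytest.approx(7)
        assert cc.monophyletic

    def test_non_monophyletic_reported_not_fatal(self, caplog):
        t = read_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        groups = {"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2"}
        cc = clade_contrast(t, groups)
        assert not cc.monophyletic
        assert cc.ratio is not None

    def test_small_group_rejected(self):
        t = read_newick("((a1:1,a2:1):1,b1:1);")
        with pytest.raises(TreeError):
            clade_contrast(t, {"a1": "P1", "a2": "P1", "b1": "P2"})

    def test_two_rate_simulation_recovers_rate_ratio(self):
        """Protein-distance NJ depth ratio tracks the amino-acid rate ratio
        (here omega doubled), and sits near 1 when rates are equal."""
        from paralogdiverge.distances import distance_matrix
        from paralogdiverge.seqcore import complete_codon_columns, protein_rows
        from paralogdiverge.simulate import SimulationConfig, simulate_paralog_family

        logs, logs_null = [], []
        for seed in range(8):
            c1 = SimulationConfig(n_taxa=12, n_codons=300, omega=0.2, tree_length=1.0, seed=seed)
            c2 = SimulationConfig(n_taxa=12, n_codons=300, omega=0.1, tree_length=1.0, seed=seed)
            cnull = SimulationConfig(n_taxa=12, n_codons=300, omega=0.2, tree_length=1.0, seed=seed + 900)
            for cfg2, sink in ((c2, logs), (cnull, logs_null)):
                fam = simulate_paralog_family(c1, cfg2)
                core = complete_codon_columns(fam.alignment)
                aa = protein_rows(core)
                tree = nj_tree(distance_matrix(list(aa.records), "kimura"))
                groups = {i: fam.alignment.meta[i].paralog for i in fam.alignment.ids}
                sink.append(np.log(clade_contrast(tree, groups).ratio))
        assert np.exp(np.mean(logs)) == pytest.approx(2.0, rel=0.3)
        assert np.exp(np.mean(logs_null)) == pytest.approx(1.0, rel=0.25)
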
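import math

import dendropy
import numpy as np
import pytest

import barcodegap as bg
from barcodegap.tree import to_newick

from conftest import random_additive_tree


def four_taxon_matrix():
    ids = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    return bg.DistanceMatrix(ids, d, np.full((4, 4), 600.0))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = bg.neighbor_joining(bg.DistanceMatrix(ids, d, np.full((3, 3), 1.0)))
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxon_worked_example(self):
        tree = bg.neighbor_joining(four_taxon_matrix())
        splits = tree.splits()
        assert frozenset({"C", "D"}) in splits  # AB|CD recovered
        internal = splits[frozenset({"C", "D"})]
        assert internal.length == pytest.approx(1.0, abs=1e-9)
        rec = tree.leaf_distance_matrix()
        leaf_len = {}
        for node in tree.root.children:
            if node.is_leaf:
                leaf_len[node.name] = node.length
            else:
                for lf in node.children:
                    leaf_len[lf.name] = lf.length
        assert leaf_len == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        assert np.allclose(rec.values, four_taxon_matrix().values, atol=1e-9)

    def test_recovers_random_additive_trees_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            dm = random_additive_tree(n, rng)
            tree = bg.neighbor_joining(dm)
            rec = tree.leaf_distance_matrix().subset(dm.ids)
            assert np.allclose(rec.values, dm.values, atol=1e-9)
            assert sorted(tree.leaf_names) == sorted(dm.ids)

    def test_all_equal_matrix_deterministic(self):
        ids = ["a", "b", "c", "d", "e"]
        d = np.full((5, 5), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = bg.DistanceMatrix(ids, d, np.full((5, 5), 1.0))
        t1 = to_newick(bg.neighbor_joining(dm))
        t2 = to_newick(bg.neighbor_joining(dm))
        assert t1 == t2  # tie-break by lowest index pair is reproducible

    def test_undefined_entries_error_names_specimens(self):
        dm = four_taxon_matrix()
        dm.values[1, 3] = dm.values[3, 1] = np.nan
        with pytest.raises(ValueError, match="B"):
            bg.neighbor_joining(dm)

    def test_too_few_taxa_error(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError, match="3"):
            bg.neighbor_joining(bg.DistanceMatrix(["a", "b"], d, d))

    def test_agrees_with_independent_nj(self, rng):
        # generic (noise-perturbed additive) matrix: no ties, so both
        # implementations of canonical NJ must produce the same topology
        skbio = pytest.importorskip("skbio")
        base = random_additive_tree(10, rng)
        noise = rng.uniform(0.0, 0.01, size=base.values.shape)
        noise = np.triu(noise, 1)
        dm = bg.DistanceMatrix(
            base.ids, base.values + noise + noise.T, base.n_comparable
        )
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=dm.ids))
        all_leaves = frozenset(dm.ids)
        ref = min(all_leaves)
        sk_splits = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                sk_splits.add(side)
        mine = set(bg.neighbor_joining(dm).splits())
        assert mine == sk_splits


class TestBootstrap:
    def test_constant_pattern_gives_full_support(self):
        # one informative site pattern repeated among constant columns:
        # every resample yields the same AB|CD topology
        informative = 60
        total = 600
        seqs = {
            "A": "A" * total,
            "B": "A" * total,
            "C": "G" * informative + "A" * (total - informative),
            "D": "G" * informative + "A" * (total - informative),
        }
        aln = bg.Alignment([bg.SequenceRecord(k, v) for k, v in seqs.items()])
        tree = bg.bootstrap_support(
            aln, bg.BootstrapConfig(replicates=100, seed=5),
            bg.DistanceConfig(min_overlap=10),
        )
        supports = [n.support for n in tree.splits().values()]
        assert supports and all(s == 100.0 for s in supports)

    def test_two_clade_split_strongly_supported(self):
        cfg = bg.SimulationConfig(
            n_species=2, specimens_per_species=(4, 4),
            intra_depth=0.01, inter_depth=0.10, seed=7,
        )
        aln, tax, _ = bg.simulate(cfg)
        tree = bg.bootstrap_support(aln, bg.BootstrapConfig(replicates=200, seed=7))
        species = np.array(tax.column("species", aln.ids))
        clade = frozenset(np.array(aln.ids)[species == "Species02"])
        splits = tree.splits()
        assert clade in splits
        assert splits[clade].support >= 95.0
        assert tree.n_replicates_used + tree.n_replicates_dropped == 200

    def test_single_replicate_support_binary(self, sim5):
        aln, _, _ = sim5
        sub = aln.subset(aln.ids[:8])
        tree = bg.bootstrap_support(sub, bg.BootstrapConfig(replicates=1, seed=1))
        for node in tree.splits().values():
            assert node.support in (0.0, 100.0)

    def test_fixed_seed_reproducible(self, sim5):
        aln, _, _ = sim5
        sub = aln.subset(aln.ids[:10])
        t1 = bg.bootstrap_support(sub, bg.BootstrapConfig(replicates=20, seed=9))
        t2 = bg.bootstrap_support(sub, bg.BootstrapConfig(replicates=20, seed=9))
        assert to_newick(t1) == to_newick(t2)

    def test_species_clades_recovered_with_high_support(self, sim5):
        # interspecific divergence ~20x intraspecific: every true species
        # should come back as a clade with support > 90
        aln, tax, _ = sim5
        tree = bg.bootstrap_support(aln, bg.BootstrapConfig(replicates=100, seed=3))
        splits = tree.splits()
        species = np.array(tax.column("species", aln.ids))
        all_leaves = frozenset(aln.ids)
        ref = min(all_leaves)
        for sp in sorted(set(species)):
            clade = frozenset(np.array(aln.ids)[species == sp])
            if clade == all_leaves or len(clade) < 2:
                continue
            key = all_leaves - clade if ref in clade else clade
            if len(key) > len(all_leaves) - 2:
                continue
            assert key in splits, f"{sp} not monophyletic"
            assert splits[key].support > 90.0, f"{sp} weakly supported"


class TestNewick:
    def test_three_taxon_shape(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        s = to_newick(bg.neighbor_joining(bg.DistanceMatrix(ids, d, np.full((3, 3), 1.0))))
        assert s == "(A:1,B:2,C:3);"

    def test_round_trip_with_independent_parser(self, tmp_path, sim5):
        aln, _, _ = sim5
        sub = aln.subset(aln.ids[:12])
        tree = bg.bootstrap_support(sub, bg.BootstrapConfig(replicates=25, seed=2))
        path = tmp_path / "tree.nwk"
        bg.write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(sub.ids)
        # topology: bipartitions agree
        parsed.encode_bipartitions()
        all_leaves = frozenset(sub.ids)
        ref = min(all_leaves)
        seen = set()
        supports = {}
        for edge in parsed.preorder_edge_iter():
            node = edge.head_node
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                seen.add(side)
                if node.label is not None:
                    supports[side] = float(node.label)
        mine = tree.splits()
        assert seen == set(mine)
        for side, node in mine.items():
            assert supports[side] == round(node.support)
        # branch lengths survive within float printing precision
        total_parsed = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length
        )
        assert total_parsed == pytest.approx(tree.total_length(), abs=1e-6)
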
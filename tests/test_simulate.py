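import math

import dendropy
import numpy as np
import pytest

import hapmet as hm
from hapmet.errors import InputError


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def _tree_height_coalescent_units(tree: dendropy.Tree, theta: float) -> float:
    d = hm.root_to_tip_distances(tree)
    return float(d[0]) / (theta / 2.0)


class TestCoalescent:
    def test_pairwise_tmrca_matches_kingman_expectation(self):
        # E[T2] = 1 coalescent unit; check the Monte-Carlo mean to +-3 SE
        # (T2 ~ Exp(1), SD 1)
        n_rep = 2000
        theta = 0.01
        heights = [
            _tree_height_coalescent_units(
                hm.simulate_coalescent_tree(2, theta, seed=s), theta
            )
            for s in range(n_rep)
        ]
        se = 1.0 / math.sqrt(n_rep)
        assert abs(np.mean(heights) - 1.0) < 3 * se

    def test_structure_and_determinism(self):
        t1 = hm.simulate_coalescent_tree(9, theta=0.01, seed=7)
        t2 = hm.simulate_coalescent_tree(9, theta=0.01, seed=7)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        internal = [n for n in t1.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 8  # binary rooted: n_tips - 1
        assert all(
            (e.length or 0.0) >= 0.0 for e in t1.preorder_edge_iter()
        )
        assert len(list(t1.leaf_node_iter())) == 9

    def test_invalid_arguments(self):
        with pytest.raises(InputError):
            hm.simulate_coalescent_tree(1, 0.01, seed=0)
        with pytest.raises(InputError):
            hm.simulate_coalescent_tree(5, -1.0, seed=0)

    def test_diversity_increases_with_theta(self):
        def mean_haplotypes(theta):
            counts = []
            for s in range(15):
                tree = hm.simulate_coalescent_tree(20, theta, seed=s)
                aln = hm.simulate_hky_sequences(
                    tree, 300, 4.0, (0.25, 0.25, 0.25, 0.25), seed=1000 + s
                )
                counts.append(len(hm.collapse_haplotypes(aln)))
            return np.mean(counts)

        assert mean_haplotypes(0.002) < mean_haplotypes(0.05)


class TestHky:
    def test_zero_branch_lengths_copy_root(self):
        tree = _tree("((A:0,B:0):0,C:0);")
        aln = hm.simulate_hky_sequences(tree, 50, 2.0, (0.25,) * 4, seed=3)
        seqs = {seq for _, seq in aln.records}
        assert len(seqs) == 1

    def test_jukes_cantor_p_distance(self):
        # kappa=1, equal freqs: p = (3/4)(1 - exp(-4d/3)) at separation d
        d = 0.1
        L = 40_000
        tree = _tree(f"(A:{d / 2},B:{d / 2});")
        aln = hm.simulate_hky_sequences(tree, L, 1.0, (0.25,) * 4, seed=10)
        a = aln.sequence("A")
        b = aln.sequence("B")
        p_hat = sum(x != y for x, y in zip(a, b)) / L
        p_true = 0.75 * (1 - math.exp(-4 * d / 3))
        se = math.sqrt(p_true * (1 - p_true) / L)
        assert abs(p_hat - p_true) < 4 * se

    def test_long_branch_reaches_stationarity(self):
        freqs = (0.31, 0.17, 0.15, 0.37)
        tree = _tree("(A:25.0,B:25.0);")
        aln = hm.simulate_hky_sequences(tree, 30_000, 4.0, freqs, seed=8)
        seq = aln.sequence("A")
        for base, f in zip("ACGT", freqs):
            assert abs(seq.count(base) / len(seq) - f) < 0.02

    def test_transition_bias_follows_kappa(self):
        transitions = {frozenset("AG"), frozenset("CT")}
        counts = {}
        for kappa in (1.0, 8.0):
            tree = _tree("(A:0.05,B:0.05);")
            aln = hm.simulate_hky_sequences(tree, 50_000, kappa, (0.25,) * 4,
                                            seed=12)
            ts = tv = 0
            for x, y in zip(aln.sequence("A"), aln.sequence("B")):
                if x != y:
                    if frozenset((x, y)) in transitions:
                        ts += 1
                    else:
                        tv += 1
            counts[kappa] = (ts, tv)
        ts1, tv1 = counts[1.0]
        ts8, tv8 = counts[8.0]
        # kappa=1: two transition pairings vs four transversion pairings
        assert abs(ts1 / (ts1 + tv1) - 1 / 3) < 0.02
        assert ts8 > 2 * tv8

    def test_determinism(self):
        tree = _tree("((A:0.1,B:0.2):0.1,C:0.3);")
        a1 = hm.simulate_hky_sequences(tree, 100, 4.0, (0.25,) * 4, seed=5)
        a2 = hm.simulate_hky_sequences(tree, 100, 4.0, (0.25,) * 4, seed=5)
        assert a1 == a2


class TestTraits:
    def test_degenerate_sigma_returns_alpha(self, balanced_tree):
        traits = hm.simulate_traits(balanced_tree, "A", alpha=3.0, beta=0.0,
                                    sigma2=0.0, lambda_true=1.0, seed=1)
        assert all(v == pytest.approx(3.0) for v in traits.rates().values())

    def test_model_a_covariance_matches_shared_paths(self, balanced_tree):
        n_rep = 4000
        cov = hm.phylo_covariance(balanced_tree, 1.0)
        draws = np.array(
            [
                list(
                    hm.simulate_traits(
                        balanced_tree, "A", 0.0, 0.0, 1.0, 1.0, seed=s
                    ).rates().values()
                )
                for s in range(n_rep)
            ]
        )
        emp = np.cov(draws.T)
        # entrywise MC tolerance ~ 5 * SE of a covariance estimate
        for i in range(4):
            for j in range(4):
                se = math.sqrt(
                    (cov.C[i, i] * cov.C[j, j] + cov.C[i, j] ** 2) / n_rep
                )
                assert abs(emp[i, j] - cov.C[i, j]) < 5 * se

    def test_model_b_mean_follows_root_to_tip(self):
        tree = _tree("((A:0.2,B:0.6):0.2,C:1.4);")
        d = hm.root_to_tip_distances(tree)
        n_rep = 3000
        draws = np.array(
            [
                list(
                    hm.simulate_traits(
                        tree, "B", alpha=1.0, beta=2.0, sigma2=0.3,
                        lambda_true=1.0, seed=s
                    ).rates().values()
                )
                for s in range(n_rep)
            ]
        )
        expected = 1.0 + 2.0 * d
        for i in range(3):
            se = math.sqrt(0.3 * d[i] / n_rep)
            assert abs(draws[:, i].mean() - expected[i]) < 5 * se

    def test_invalid_inputs(self, balanced_tree):
        with pytest.raises(InputError):
            hm.simulate_traits(balanced_tree, "A", 0.0, 1.0, 1.0, 1.0, seed=0)
        with pytest.raises(InputError):
            hm.simulate_traits(balanced_tree, "A", 0.0, 0.0, 1.0, 1.5, seed=0)


class TestPosteriorEmulation:
    def test_no_noise_returns_identical_copies(self, balanced_tree):
        ts = hm.emulate_posterior_trees(balanced_tree, 4, 0.0, 0, seed=2)
        ref = balanced_tree.as_string(schema="newick", suppress_rooting=True)
        for tree in ts:
            assert tree.as_string(schema="newick", suppress_rooting=True) == ref

    def test_tip_set_and_lengths_preserved(self, balanced_tree):
        ts = hm.emulate_posterior_trees(balanced_tree, 10, 0.4, 3, seed=9)
        assert len(ts) == 10
        for tree in ts:
            labels = {l.taxon.label for l in tree.leaf_node_iter()}
            assert labels == {"A", "B", "C", "D"}
            assert all(
                (e.length or 0.0) >= 0.0 for e in tree.preorder_edge_iter()
            )

    def test_jitter_has_unit_mean(self):
        tree = _tree("(A:1.0,B:1.0);")
        ts = hm.emulate_posterior_trees(tree, 3000, 0.3, 0, seed=4)
        lengths = [
            e.length
            for t in ts
            for e in t.preorder_edge_iter()
            if e.length is not None
        ]
        assert np.mean(lengths) == pytest.approx(1.0, abs=0.02)


class TestPaperlikeDataset:
    def test_shapes_and_consistency(self):
        cfg = hm.SimulationConfig(n_individuals=45, n_posterior_trees=5, seed=3)
        ds = hm.generate_study_dataset(cfg)
        assert len(ds.alignment) == 45
        assert ds.alignment.length == 516
        assert len(ds.traits) == 45
        assert set(ds.alignment.ids) == set(ds.traits.ids)
        assert set(ds.posterior_trees.tip_labels) == set(ds.alignment.ids)
        lo, hi = cfg.trait_range
        for v in ds.traits.rates().values():
            assert lo - 1e-12 <= v <= hi + 1e-12

    def test_byte_identical_given_seed(self, tmp_path):
        cfg = hm.SimulationConfig(n_individuals=10, seq_length=120,
                                  n_posterior_trees=4, seed=11)
        for sub in ("a", "b"):
            hm.write_dataset(hm.generate_study_dataset(cfg), tmp_path / sub)
        for name in ("alignment.fasta", "traits.tsv", "true_tree.nwk",
                     "posterior.trees", "provenance.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
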
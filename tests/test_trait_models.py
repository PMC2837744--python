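import math

import dendropy
import numpy as np
import pytest
from scipy import stats

import hapmet as hm
from hapmet.errors import InputError, ModelError
from hapmet.trait_models import McmcChain


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def _random_tree(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random non-ultrametric tree by jittering a coalescent genealogy."""
    base = hm.simulate_coalescent_tree(n_tips, theta=2.0, seed=int(rng.integers(2**31)))
    return hm.emulate_posterior_trees(
        base, 1, length_jitter_cv=0.5, n_nni_moves=0, seed=int(rng.integers(2**31))
    )[0]


def _mrca_shared_path(tree: dendropy.Tree) -> tuple[tuple[str, ...], np.ndarray]:
    """Brute-force C(1): walk root paths explicitly and measure overlap."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = set(path)
    order = tuple(sorted(paths))
    n = len(order)
    C = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            shared = paths[a] & paths[b]
            C[i, j] = sum(nd.edge.length or 0.0 for nd in shared)
    return order, C


class TestCovariance:
    def test_root_to_tip_paths(self):
        d = hm.root_to_tip_distances(_tree("((A:0,B:0):1,C:1);"))
        assert d == pytest.approx([1.0, 1.0, 1.0])
        d = hm.root_to_tip_distances(_tree("(A:0.5,B:1.5);"))
        assert d == pytest.approx([0.5, 1.5])

    def test_root_to_tip_matches_path_walking_oracle(self):
        rng = np.random.default_rng(11)
        tree = _random_tree(10, rng)
        order, C = _mrca_shared_path(tree)
        assert hm.root_to_tip_distances(tree, order) == pytest.approx(np.diag(C))

    def test_lambda_zero_is_diagonal(self, balanced_tree):
        cov = hm.phylo_covariance(balanced_tree, 0.0)
        assert np.allclose(cov.C, np.diag(cov.d))

    def test_two_tip_no_shared_path(self):
        cov = hm.phylo_covariance(_tree("(A:0.3,B:0.8);"), 1.0)
        assert cov.C == pytest.approx(np.diag([0.3, 0.8]))

    def test_full_lambda_matches_mrca_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            tree = _random_tree(4, rng)
            order, C_oracle = _mrca_shared_path(tree)
            cov = hm.phylo_covariance(tree, 1.0, order)
            assert np.allclose(cov.C, C_oracle)

    def test_lambda_linear_off_diagonal(self, balanced_tree):
        c0 = hm.phylo_covariance(balanced_tree, 0.0).C
        c1 = hm.phylo_covariance(balanced_tree, 1.0).C
        ch = hm.phylo_covariance(balanced_tree, 0.5).C
        assert np.allclose(ch, 0.5 * (c0 + c1))


class TestGlsLoglik:
    def test_lambda_zero_factorizes_into_independent_normals(self, balanced_tree):
        traits = hm.TraitTable.from_rates(
            {"A": 1.1, "B": 0.4, "C": 2.0, "D": 0.9}
        )
        params = hm.ContinuousModelParams(alpha=1.0, beta=0.0, sigma2=0.5, lam=0.0)
        ll = hm.gls_loglik(balanced_tree, traits, params, "A")
        d = hm.root_to_tip_distances(balanced_tree)
        y = np.array([1.1, 0.4, 2.0, 0.9])
        expected = stats.norm.logpdf(y, loc=1.0, scale=np.sqrt(0.5 * d)).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_star_tree_lambda_irrelevant(self):
        star = _tree("(A:0.5,B:0.7,C:0.9);")
        traits = hm.TraitTable.from_rates({"A": 1.0, "B": 2.0, "C": 3.0})
        p0 = hm.ContinuousModelParams(alpha=2.0, beta=0.0, sigma2=1.0, lam=0.0)
        p1 = hm.ContinuousModelParams(alpha=2.0, beta=0.0, sigma2=1.0, lam=1.0)
        assert hm.gls_loglik(star, traits, p0, "A") == pytest.approx(
            hm.gls_loglik(star, traits, p1, "A")
        )

    def test_dense_mvn_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            tree = _random_tree(5, rng)
            order, C1 = _mrca_shared_path(tree)
            lam = float(rng.uniform())
            sigma2 = float(rng.uniform(0.2, 3.0))
            alpha = float(rng.normal())
            beta = float(rng.normal())
            y = rng.normal(size=5)
            traits = hm.TraitTable.from_rates(
                dict(zip(order, y)), require_positive=False
            )
            C = lam * C1
            np.fill_diagonal(C, np.diag(C1))
            d = np.diag(C1)
            params = hm.ContinuousModelParams(alpha, beta, sigma2, lam)
            expected = stats.multivariate_normal.logpdf(
                y, mean=alpha + beta * d, cov=sigma2 * C
            )
            assert hm.gls_loglik(tree, traits, params, "B") == pytest.approx(
                expected, abs=1e-8
            )

    def test_scaling_contract(self, balanced_tree):
        # traits scaled by s: loglik shifts by -n log s once sigma2 -> s^2 sigma2
        traits = hm.TraitTable.from_rates({"A": 1.1, "B": 0.4, "C": 2.0, "D": 0.9})
        s = 1000.0
        scaled = traits.with_rates({i: s * r for i, r in traits.rates().items()})
        p = hm.ContinuousModelParams(alpha=1.0, beta=0.0, sigma2=0.5, lam=1.0)
        ps = hm.ContinuousModelParams(alpha=s * 1.0, beta=0.0,
                                      sigma2=s**2 * 0.5, lam=1.0)
        ll = hm.gls_loglik(balanced_tree, traits, p, "A")
        lls = hm.gls_loglik(balanced_tree, scaled, ps, "A")
        assert lls == pytest.approx(ll - 4 * math.log(s), abs=1e-8)


class TestFitML:
    def test_noiseless_directional_regression(self):
        rng = np.random.default_rng(3)
        tree = _random_tree(20, rng)
        d = hm.root_to_tip_distances(tree)
        order = tuple(sorted(l.taxon.label for l in tree.leaf_node_iter()))
        traits = hm.TraitTable.from_rates(
            {t: 2.0 + 5.0 * di for t, di in zip(order, d)}, require_positive=False
        )
        params, _ = hm.fit_ml(tree, traits, "B")
        assert params.alpha == pytest.approx(2.0, abs=1e-6)
        assert params.beta == pytest.approx(5.0, abs=1e-6)

    def test_nested_model_loglik_monotone(self, small_dataset):
        tree = small_dataset.posterior_trees[0]
        traits = small_dataset.traits
        _, ll_a = hm.fit_ml(tree, traits, "A")
        _, ll_b = hm.fit_ml(tree, traits, "B")
        _, ll_a_lam = hm.fit_ml(tree, traits, "A", estimate_lambda=True)
        assert ll_b >= ll_a - 1e-9
        assert ll_a_lam >= ll_a - 1e-9

    def test_ultrametric_tree_rejects_directional_model(self):
        tree = hm.simulate_coalescent_tree(8, theta=1.0, seed=5)
        traits = hm.TraitTable.from_rates(
            {l.taxon.label: 1.0 + i for i, l in enumerate(tree.leaf_node_iter())},
            require_positive=False,
        )
        with pytest.raises(ModelError):
            hm.fit_ml(tree, traits, "B")


@pytest.fixture(scope="module")
def single_tree_setup():
    rng = np.random.default_rng(17)
    tree = _random_tree(25, rng)
    traits = hm.simulate_traits(tree, "A", alpha=2.0, beta=0.0,
                                sigma2=1.5, lambda_true=1.0, seed=88)
    namespace = dendropy.TaxonNamespace()
    ts = hm.TreeSet(dendropy.TreeList(
        [dendropy.Tree.get(data=tree.as_string(schema="newick"),
                           schema="newick", rooting="force-rooted",
                           taxon_namespace=namespace)],
        taxon_namespace=namespace))
    return ts, traits


class TestMcmc:
    def test_deterministic_given_seed(self, single_tree_setup):
        ts, traits = single_tree_setup
        cfg = hm.McmcConfig(n_iterations=500, sample_interval=5, seed=12)
        c1 = hm.mcmc_sample(ts, traits, "A", config=cfg)
        c2 = hm.mcmc_sample(ts, traits, "A", config=cfg)
        assert c1.samples == c2.samples

    def test_acceptance_rate_sane(self, single_tree_setup):
        ts, traits = single_tree_setup
        cfg = hm.McmcConfig(n_iterations=1000, sample_interval=10, seed=1)
        chain = hm.mcmc_sample(ts, traits, "A", config=cfg)
        assert 0.0 < chain.acceptance_rate < 1.0
        assert len(chain.samples) == 90  # (1000 - 100 burn-in) / 10

    def test_posterior_concentrates_near_ml(self, single_tree_setup):
        # flat priors + single tree: posterior mean sigma2 ~ ML estimate
        ts, traits = single_tree_setup
        params_ml, _ = hm.fit_ml(ts[0], traits, "A")
        cfg = hm.McmcConfig(
            n_iterations=30_000, sample_interval=20, ratedev=0.05,
            trait_scale_factor=1.0, seed=30,
        )
        chain = hm.mcmc_sample(ts, traits, "A", config=cfg)
        post_sigma2 = np.mean([p.sigma2 for p, _, _ in chain.samples])
        # ML plug-in is biased low by the alpha df; allow generous MC slack
        assert post_sigma2 == pytest.approx(params_ml.sigma2, rel=0.35)


class TestHarmonicMeanAndBayesFactor:
    @staticmethod
    def _chain_from_lls(lls):
        params = hm.ContinuousModelParams(0.0, 0.0, 1.0, 1.0)
        return McmcChain(
            samples=[(params, ll, 0) for ll in lls],
            n_iterations=len(lls), sample_interval=1, ratedev=0.002,
            trait_scale_factor=1.0, acceptance_rate=0.5, seed=0,
        )

    def test_constant_chain_returns_constant(self):
        assert hm.harmonic_mean_logml(self._chain_from_lls([-3.5] * 10)) == (
            pytest.approx(-3.5)
        )

    def test_two_sample_arithmetic(self):
        # harmonic mean of likelihoods (1, 1/3) is 1/2
        chain = self._chain_from_lls([0.0, math.log(1 / 3)])
        assert hm.harmonic_mean_logml(chain) == pytest.approx(math.log(0.5))

    def test_bounded_by_max_and_order_invariant(self):
        rng = np.random.default_rng(2)
        lls = list(rng.normal(-50, 3, size=40))
        hml = hm.harmonic_mean_logml(self._chain_from_lls(lls))
        assert hml <= max(lls) + 1e-12
        shuffled = hm.harmonic_mean_logml(self._chain_from_lls(lls[::-1]))
        doubled = hm.harmonic_mean_logml(self._chain_from_lls(lls + lls))
        assert hml == pytest.approx(shuffled) == pytest.approx(doubled)

    @pytest.mark.parametrize(
        "better, worse, value, band",
        [
            (-76.5628, -77.4104, 0.8476, "none"),
            (-77.0837, -99.0515, 21.9678, "very strong"),
            (-10.0, -10.0, 0.0, "none"),
            (-10.0, -13.0, 3.0, "positive"),
            (-10.0, -16.0, 6.0, "strong"),
        ],
    )
    def test_bayes_factor_bands(self, better, worse, value, band):
        res = hm.bayes_factor(better, worse, multiplier=1)
        assert res.value == pytest.approx(value, abs=1e-10)
        assert res.interpretation == band

    def test_doubled_convention(self):
        res = hm.bayes_factor(-10.0, -11.5, multiplier=2)
        assert res.value == pytest.approx(3.0)
        assert res.interpretation == "positive"

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            hm.bayes_factor(float("nan"), -1.0)


class TestCompareModels:
    def test_report_deterministic_and_structured(self, small_dataset):
        cfg = hm.McmcConfig(n_iterations=800, sample_interval=10, seed=6)
        r1 = hm.compare_models(small_dataset.posterior_trees,
                               small_dataset.traits, cfg)
        r2 = hm.compare_models(small_dataset.posterior_trees,
                               small_dataset.traits, cfg)
        assert r1.to_dict() == r2.to_dict()
        assert set(r1.log_ml) == {"A", "B", "A_lambda_est", "A_lambda_0"}
        assert r1.directional.value >= 0  # oriented better minus worse
        assert r1.phylogenetic_signal.value >= 0
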
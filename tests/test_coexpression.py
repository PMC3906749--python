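"""Co-expression stage: adjacency, soft threshold, TOM, modules, trait stats."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import msetkit as mk
from msetkit.coexpression import (
    MODULE_COLORS,
    UNASSIGNED,
    _scale_free_fit,
)
from msetkit.gene_lists import TRANSCRIPTION_FACTOR


def block_data(rng, sizes, n_noise=0, n_samples=12, noise_sd=0.15):
    """Planted-block expression: one latent factor per block plus noise.

    Factors are orthogonalized so the planted blocks are genuinely
    distinct in-sample (random 12-vectors can correlate substantially by
    chance).
    """
    rows, factors = [], []
    for size in sizes:
        f = rng.normal(size=n_samples)
        for prev in factors:
            f = f - (f @ prev) / (prev @ prev) * prev
        factors.append(f)
        rows.append(np.outer(rng.uniform(0.8, 1.2, size), f / f.std())
                    + rng.normal(0, noise_sd, (size, n_samples)))
    if n_noise:
        rows.append(rng.normal(size=(n_noise, n_samples)))
    return np.vstack(rows)


class TestAdjacency:
    def test_perfect_correlation_gives_unit_weight(self):
        x = np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8]])
        a = mk.adjacency_matrix(x, beta=7)
        assert a[0, 1] == pytest.approx(1.0)

    def test_unsigned_network_squares_negative_correlation(self):
        # two anti-correlated genes: |cor| = 1 regardless of beta; use a
        # constructed pair with |cor| = 0.5 instead
        x = np.array([[1.0, -1, 1, -1, 1, -1], [1.0, 1, -1, -1, 1, -1]])
        cor = np.corrcoef(x)[0, 1]
        a = mk.adjacency_matrix(x, beta=2)
        assert a[0, 1] == pytest.approx(cor**2)

    def test_bounds_symmetry_diagonal(self, rng):
        a = mk.adjacency_matrix(rng.normal(size=(20, 10)), beta=6)
        assert np.allclose(a, a.T)
        assert np.all((a >= 0) & (a <= 1))
        assert np.allclose(np.diag(a), 1.0)

    def test_zero_variance_gene_named_in_error(self, rng):
        x = rng.normal(size=(3, 8))
        x[1] = 5.0
        with pytest.raises(ValueError, match="g1"):
            mk.adjacency_matrix(x, beta=2, genes=["g0", "g1", "g2"])


class TestSoftThreshold:
    def test_mean_connectivity_strictly_decreases_in_beta(self, rng):
        x = rng.normal(size=(40, 10))
        _, fit = mk.pick_soft_threshold(
            x, mk.NetworkConfig(beta_grid=tuple(range(1, 12)), scale_free_target=0.8)
        )
        assert np.all(np.diff(fit["mean_k"].to_numpy()) < 0)

    def test_scale_free_fixture_reaches_target(self, rng):
        # hub structure: per-gene loadings on one factor drawn from a power law
        n, s = 300, 30
        f = rng.normal(size=s)
        w = rng.pareto(2.0, size=n) + 0.05
        w = np.clip(w / w.max(), 0.02, 1.0)
        x = np.outer(w, f) + rng.normal(0, 1.0, (n, s))
        beta, fit = mk.pick_soft_threshold(x, mk.NetworkConfig())
        assert fit["R2"].max() > 0.8

    def test_independent_noise_falls_back_with_warning(self, rng):
        x = rng.normal(size=(60, 10))
        with pytest.warns(UserWarning, match="falling back"):
            beta, fit = mk.pick_soft_threshold(
                x, mk.NetworkConfig(beta_grid=(1, 2, 3), scale_free_target=0.8)
            )
        assert beta in (1, 2, 3)

    def test_nonnegative_slope_scores_zero(self):
        # frequency rises with connectivity -> positive slope -> score 0
        k = np.r_[np.full(5, 0.1), np.full(20, 0.5), np.full(60, 1.0)]
        assert _scale_free_fit(k) == 0.0


class TestTom:
    def test_hand_computed_three_gene_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        w = mk.tom_similarity(a)
        # l_12 = 0.25, k = 1.0 each: (0.25 + 0.5)/(1 + 1 - 0.5)
        assert w[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(w), 1.0)

    def test_disconnected_adjacency_stays_disconnected(self):
        a = np.eye(4)
        w = mk.tom_similarity(a)
        assert np.allclose(w, np.eye(4))

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(5):
            c = np.abs(np.corrcoef(rng.normal(size=(10, 8)))) ** 3
            np.fill_diagonal(c, 1.0)
            w = mk.tom_similarity(c)
            n = c.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    l = sum(c[i, u] * c[u, j] for u in range(n) if u not in (i, j))
                    k_i = c[i].sum() - 1
                    k_j = c[j].sum() - 1
                    expect = (l + c[i, j]) / (min(k_i, k_j) + 1 - c[i, j])
                    assert w[i, j] == pytest.approx(expect, abs=1e-12)

    def test_identical_adjacency_columns_have_maximal_overlap(self, rng):
        c = np.abs(np.corrcoef(rng.normal(size=(10, 8)))) ** 2
        np.fill_diagonal(c, 1.0)
        c[1] = c[0]
        c[:, 1] = c[:, 0]
        c[0, 1] = c[1, 0] = 0.99
        np.fill_diagonal(c, 1.0)
        w = mk.tom_similarity(c)
        assert w[0, 1] == pytest.approx(w[0].max() if w[0].argmax() != 0 else
                                        np.delete(w[0], 0).max())

    def test_asymmetric_input_rejected(self, rng):
        a = rng.uniform(size=(5, 5))
        with pytest.raises(ValueError):
            mk.tom_similarity(a)


class TestDetectModules:
    def test_planted_blocks_recovered(self, rng):
        x = block_data(rng, (60, 40))
        tom = mk.tom_similarity(mk.adjacency_matrix(x, beta=6))
        labels = mk.detect_modules(tom, mk.NetworkConfig())
        truth = np.r_[np.zeros(60), np.ones(40)]
        assert labels.max() == 2  # exactly two modules
        assert sorted(np.bincount(labels)[1:], reverse=True) == [60, 40]
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_small_block_falls_below_min_size(self, rng):
        x = block_data(rng, (10,), n_noise=40)
        tom = mk.tom_similarity(mk.adjacency_matrix(x, beta=6))
        labels = mk.detect_modules(tom, mk.NetworkConfig(min_module_size=30))
        assert np.all(labels[:10] == 0)

    def test_pure_noise_usually_yields_no_modules(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(100, 12))
            tom = mk.tom_similarity(mk.adjacency_matrix(x, beta=6))
            with pytest.warns(UserWarning):
                labels = mk.detect_modules(tom, mk.NetworkConfig())
            hits += int(labels.max() == 0)
        assert hits >= 3


class TestEigengene:
    def test_identical_profiles_fully_explained(self, rng):
        profile = rng.normal(size=8)
        x = np.tile(profile, (5, 1)) * rng.uniform(0.5, 2.0, (5, 1))
        e, ve = mk.module_eigengene(x, np.arange(5))
        assert ve == pytest.approx(1.0)
        assert abs(np.corrcoef(e, profile)[0, 1]) == pytest.approx(1.0)

    def test_orientation_mean_member_correlation_nonnegative(self, rng):
        for _ in range(10):
            x = rng.normal(size=(6, 9))
            e, _ = mk.module_eigengene(x, np.arange(6))
            cors = [np.corrcoef(e, row)[0, 1] for row in x]
            assert np.mean(cors) >= 0

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(rng.integers(3, 10), 8))
            e, ve = mk.module_eigengene(x, np.arange(x.shape[0]))
            z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
            evals, evecs = np.linalg.eigh(z @ z.T)
            assert ve == pytest.approx(evals[-1] / evals.sum(), abs=1e-8)
            oracle = z.T @ evecs[:, -1]
            oracle /= np.linalg.norm(oracle)
            assert min(np.linalg.norm(e - oracle), np.linalg.norm(e + oracle)) < 1e-8


class TestMergeModules:
    def fixture_modules(self, rng, cors):
        """Three 5-gene modules whose latent factors share given correlations."""
        base = rng.normal(size=12)
        factors = [base]
        for c in cors:
            g = rng.normal(size=12)
            g -= (g @ base) / (base @ base) * base
            factors.append(c * base + np.sqrt(1 - c**2) * g / g.std())
        x = np.vstack([
            np.outer(np.ones(5), f) + rng.normal(0, 0.05, (5, 12)) for f in factors
        ])
        modules = {i: np.arange(5 * i, 5 * i + 5) for i in range(len(factors))}
        return x, modules

    def test_similar_pair_merges(self, rng):
        x, modules = self.fixture_modules(rng, [0.95])
        merged = mk.merge_modules(x, modules, merge_threshold=0.25)
        assert len(merged) == 1

    def test_uncorrelated_pair_stays(self, rng):
        x, modules = self.fixture_modules(rng, [0.0])
        merged = mk.merge_modules(x, modules, merge_threshold=0.25)
        assert len(merged) == 2

    def test_order_independence(self, rng):
        x, modules = self.fixture_modules(rng, [0.9, 0.92])
        merged = mk.merge_modules(x, modules, merge_threshold=0.25)
        relabeled = {10 - k: v for k, v in modules.items()}
        merged2 = mk.merge_modules(x, relabeled, merge_threshold=0.25)
        sets1 = sorted(frozenset(v) for v in merged.values())
        sets2 = sorted(frozenset(v) for v in merged2.values())
        assert sets1 == sets2 and len(merged) == 1


class TestTraitCorrelation:
    def test_eigengene_proportional_to_trait(self):
        trait = np.r_[np.zeros(6), np.ones(6)]
        r, p = mk.module_trait_correlation(2.0 * trait + 1.0, trait)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_closed_form_at_published_correlations(self):
        # r = 0.85, n = 12 -> t = 5.103, df = 10, two-sided p ~ 5e-4
        assert mk.student_p_from_r(0.85, 12) == pytest.approx(4.62e-4, rel=0.01)
        # r = 0.95, n = 12 -> p ~ 2e-6
        assert mk.student_p_from_r(0.95, 12) == pytest.approx(2.26e-6, rel=0.01)

    def test_constant_eigengene_rejected(self):
        trait = np.r_[np.zeros(3), np.ones(3)]
        with pytest.raises(ValueError):
            mk.module_trait_correlation(np.ones(6), trait)


class TestTfEdges:
    def make_result(self, rng):
        cfg = mk.SimConfig(n_genes=300, de_fraction=0.0, list_specs=(), seed=21)
        study = mk.simulate_study(cfg)
        ranked = mk.rank_genes(study.expression)
        model = mk.CoexpressionNetwork.from_study(study.expression, ranked, beta=21)
        return study, model.fit()

    def test_empty_catalog_gives_empty_edges(self, rng):
        study, res = self.make_result(rng)
        module = next(iter(res.modules))
        edges = res.tf_edges(mk.RegulatorCatalog({}), module)
        assert edges.empty

    def test_edges_respect_contract(self, rng):
        study, res = self.make_result(rng)
        module = next(iter(res.modules))
        members = set(res.modules[module])
        catalog = mk.RegulatorCatalog(
            {g: TRANSCRIPTION_FACTOR for g in list(members)[:3]}
        )
        edges = res.tf_edges(catalog, module)
        assert not edges.empty
        assert edges["weight"].between(0, 1).all()
        assert edges["source"].isin(members).all()
        assert edges["target"].isin(members).all()
        assert (edges["weight"].diff().dropna() <= 1e-12).all()  # sorted desc

    def test_top_k_selection_rule(self):
        # 3-gene module with known TOM: keep only the strongest partner
        genes = ("Tf1", "g2", "g3")
        tom = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]])
        res = mk.CoexpressionResult(
            genes=genes, beta=6, fit_table=None,
            modules={"turquoise": genes}, unassigned=(),
            eigengenes=pd.DataFrame(), variance_explained={"turquoise": 1.0},
            trait_stats=pd.DataFrame(columns=["module", "r", "student_p", "n"]),
            tom=tom, adjacency=tom, samples=("s1",), trait=np.array([0.0]),
        )
        catalog = mk.RegulatorCatalog({"Tf1": TRANSCRIPTION_FACTOR})
        edges = res.tf_edges(catalog, "turquoise", top_k_per_tf=1)
        assert len(edges) == 1
        assert tuple(edges.iloc[0][["source", "target"]]) == ("Tf1", "g2")
        assert edges.iloc[0]["weight"] == 0.5


class TestEndToEnd:
    def test_two_planted_modules_recovered_with_signed_trait_correlations(self):
        cfg = mk.SimConfig(n_genes=400, de_fraction=0.0, list_specs=(), seed=3)
        study = mk.simulate_study(cfg)
        ranked = mk.rank_genes(study.expression)
        res = mk.CoexpressionNetwork.from_study(study.expression, ranked, beta=21).fit()
        assert res.n_modules == 2
        assert set(res.modules) == {"turquoise", "blue"}
        assert len(res.modules["turquoise"]) >= len(res.modules["blue"])
        stats = res.trait_stats.set_index("module")
        assert stats.loc["turquoise", "r"] == pytest.approx(0.85, abs=0.15)
        assert stats.loc["blue", "r"] == pytest.approx(-0.85, abs=0.15)
        labels = res.module_of()
        truth = [study.truth_modules.get(g, "none") for g in res.genes]
        assert adjusted_rand_score(truth, [labels[g] for g in res.genes]) >= 0.8
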
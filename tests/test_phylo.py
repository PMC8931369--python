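"""Tree parsing, covariance builders and regime paintings."""

import numpy as np
import pytest
from scipy import integrate

from allogrades import (
    bm_covariance,
    clade_tips,
    lambda_transform,
    ou_covariance,
    ou_weight_matrix,
    paint_regimes,
    parse_newick,
    write_newick,
)
from allogrades.phylo import NewickParseError, PhyloError, match_tree_to_table
from allogrades.synthdata import simulate_tree

from conftest import brute_force_bm_cov


class TestNewick:
    def test_three_taxon_example(self, three_taxon):
        t = three_taxon
        assert t.n_tips == 3
        assert t.n_branches == 4
        assert np.allclose(t.depth[t.tip_ids], 2.0)

    def test_single_tip_accepted_with_warning(self):
        with pytest.warns(UserWarning, match="single-tip"):
            t = parse_newick("(A:1);")
        assert t.n_tips == 1

    @pytest.mark.parametrize(
        "bad",
        ["((A:1,B:1:1,C:2);", "((A:1,B),C:2);", "((A:1,A:1):1,C:2);"],
    )
    def test_malformed_input_raises(self, bad):
        with pytest.raises((NewickParseError, PhyloError)):
            parse_newick(bad)

    def test_round_trip_over_simulated_trees(self):
        for seed in range(20):
            t = simulate_tree(np.random.default_rng(seed).integers(4, 40),
                              seed=seed)
            t2 = parse_newick(write_newick(t))
            assert t2.tip_labels == t.tip_labels
            assert np.allclose(
                bm_covariance(t2), bm_covariance(t), atol=1e-9
            )

    def test_polytomy_resolved_to_binary(self):
        t = parse_newick("(A:3,B:3,C:3,D:3);")
        assert t.n_tips == 4
        assert t.n_branches == 2 * 4 - 2


class TestBMCovariance:
    def test_star_tree_diagonal(self):
        t = parse_newick("(A:3,B:3,C:3);")
        V = bm_covariance(t)
        assert np.allclose(np.diag(V), 3.0)
        assert np.allclose(V - np.diag(np.diag(V)), 0.0)

    def test_three_taxon_values(self, three_taxon):
        V = bm_covariance(three_taxon)
        assert np.allclose(np.diag(V), 2.0)
        i = {lab: k for k, lab in enumerate(three_taxon.tip_labels)}
        assert V[i["A"], i["B"]] == pytest.approx(1.0)
        assert V[i["A"], i["C"]] == 0.0
        assert V[i["B"], i["C"]] == 0.0

    def test_matches_path_enumeration_oracle(self, tree20):
        assert np.allclose(
            bm_covariance(tree20), brute_force_bm_cov(tree20), atol=1e-9
        )

    def test_psd(self, tree20):
        V = bm_covariance(tree20)
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-10 * np.trace(V)


class TestLambdaTransform:
    def test_identity_and_independence_limits(self, tree20):
        V = bm_covariance(tree20)
        assert np.array_equal(lambda_transform(V, 1.0), V)
        assert np.array_equal(
            lambda_transform(V, 0.0), np.diag(np.diag(V))
        )

    def test_half_lambda_three_taxon(self, three_taxon):
        V = lambda_transform(bm_covariance(three_taxon), 0.5)
        i = {lab: k for k, lab in enumerate(three_taxon.tip_labels)}
        assert V[i["A"], i["B"]] == pytest.approx(0.5)
        assert np.allclose(np.diag(V), 2.0)

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_domain_error(self, three_taxon, lam):
        with pytest.raises(ValueError):
            lambda_transform(bm_covariance(three_taxon), lam)


class TestOUCovariance:
    def test_bm_limit(self, three_taxon, tree20):
        V = ou_covariance(three_taxon, alpha=1e-8, sigma2=0.5)
        ref = 0.5 * bm_covariance(three_taxon)
        assert np.max(np.abs(V - ref) / ref.max()) < 1e-6
        # deep tree: relative error scales with alpha * depth
        V = ou_covariance(tree20, alpha=1e-8, sigma2=0.5)
        ref = 0.5 * bm_covariance(tree20)
        assert np.max(np.abs(V - ref) / ref.max()) < 2e-8 * tree20.tree_height

    def test_stationary_variance_deep_tree(self, tree20):
        a, s2 = 0.5, 0.3  # alpha*T = 150 >> 1
        V = ou_covariance(tree20, a, s2)
        assert np.allclose(np.diag(V), s2 / (2 * a))
        # non-sister distant tips decorrelate
        Vbm = bm_covariance(tree20)
        far = Vbm < 0.5 * tree20.tree_height
        np.fill_diagonal(far, False)
        assert np.all(np.abs(V[far]) < 1e-10)

    def test_monte_carlo_oracle_three_taxon(self, three_taxon):
        """Exact-transition OU simulation along the tree, 1e6 paths."""
        a, s2 = 0.5, 0.8
        rng = np.random.default_rng(0)
        n = 1_000_000

        def step(x, t):
            decay = np.exp(-a * t)
            sd = np.sqrt(s2 / (2 * a) * -np.expm1(-2 * a * t))
            return x * decay + sd * rng.standard_normal(len(x))

        root = np.zeros(n)
        ab = step(root, 1.0)
        xa, xb = step(ab, 1.0), step(ab, 1.0)
        xc = step(root, 2.0)
        sims = {"A": xa, "B": xb, "C": xc}
        V = ou_covariance(three_taxon, a, s2)
        labs = three_taxon.tip_labels
        emp = np.cov(np.vstack([sims[l] for l in labs]))
        for i in range(3):
            for j in range(3):
                se = np.sqrt((V[i, i] * V[j, j] + V[i, j] ** 2) / n)
                assert abs(emp[i, j] - V[i, j]) < 3 * se

    def test_requires_positive_alpha(self, three_taxon):
        with pytest.raises(ValueError):
            ou_covariance(three_taxon, 0.0, 1.0)


class TestOUWeights:
    def test_single_regime_is_ones(self, tree20):
        p = paint_regimes(tree20, [])
        W = ou_weight_matrix(tree20, p, alpha=0.02)
        assert np.allclose(W, 1.0)

    def test_strong_attraction_indicator_limit(self, tree64):
        shifts = [int(tree64.tip_ids[0]), int(tree64.branch_ids[-5])]
        p = paint_regimes(tree64, shifts)
        W = ou_weight_matrix(tree64, p, alpha=10.0)
        term_reg = p.branch_regime[tree64.tip_ids]
        ind = np.zeros_like(W)
        ind[np.arange(tree64.n_tips), term_reg] = 1.0
        assert np.allclose(W, ind, atol=1e-6)

    def test_two_taxon_quadrature_oracle(self):
        t = parse_newick("(A:2,B:2);")
        b_of_A = next(
            b for b in t.branch_ids if not t.children[b]
            and t.label[b] == "A"
        )
        p = paint_regimes(t, [b_of_A])
        a = 1.0
        W = ou_weight_matrix(t, p, a)
        # weight of a segment [t0,t1] = integral of a*exp(-a(T-s)) ds
        for (t0, t1, exp_k) in [(0.0, 2.0, 1)]:
            q, _ = integrate.quad(
                lambda s: a * np.exp(-a * (2.0 - s)), t0, t1
            )
        iA = t.tip_labels.index("A")
        assert W[iA, 1] == pytest.approx(q, abs=1e-9)
        assert W[iA, 0] == pytest.approx(1 - q, abs=1e-9)

    def test_rows_sum_to_one_random_paintings(self, tree64):
        rng = np.random.default_rng(3)
        for _ in range(5):
            shifts = rng.choice(tree64.branch_ids, size=6, replace=False)
            p = paint_regimes(tree64, shifts)
            for a in (1e-4, 0.01, 0.5):
                W = ou_weight_matrix(tree64, p, a)
                assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_branch_rejected(self, tree20):
        with pytest.raises(PhyloError):
            paint_regimes(tree20, [tree20.n_nodes + 3])


class TestPaintingAndClades:
    def test_nested_shift_overrides(self, tree64):
        # pick an internal branch and one branch strictly inside it
        outer = max(
            (b for b in tree64.branch_ids if tree64.children[b]),
            key=lambda b: len(tree64.clade_tip_ids(b))
            if tree64.parent[b] != 0 else 0,
        )
        inner = next(
            b for b in tree64.branch_ids
            if set(tree64.clade_tip_ids(b)) < set(tree64.clade_tip_ids(outer))
        )
        p = paint_regimes(tree64, [outer, inner])
        assert p.n_regimes == 3
        inner_tips = set(tree64.clade_tip_ids(inner))
        for u in tree64.tip_ids:
            r = p.branch_regime[u]
            if u in inner_tips:
                assert r == p.shifts.index(inner) + 1
            elif u in set(tree64.clade_tip_ids(outer)):
                assert r == p.shifts.index(outer) + 1
            else:
                assert r == 0

    def test_clade_tips_terminal_and_subtree(self, three_taxon):
        t = three_taxon
        term = [b for b in t.tip_ids]
        assert clade_tips(t, term[0]) == {t.label[term[0]]}
        internal = next(b for b in t.branch_ids if t.children[b])
        assert clade_tips(t, internal) == {"A", "B"}
        with pytest.raises(PhyloError):
            t.clade_tip_ids(0)

    def test_clade_sizes_consistent(self, tree20):
        total = sum(
            len(tree20.clade_tip_ids(b))
            for b in tree20.branch_ids if not tree20.children[b]
        )
        assert total == tree20.n_tips


class TestPruneAndMatch:
    def test_prune_preserves_covariance_when_root_spanned(self, tree20):
        labs = tree20.tip_labels
        V = bm_covariance(tree20)
        # keep a subset spanning both root children so the root is kept
        keep = []
        for c in tree20.children[0]:
            ids = tree20.clade_tip_ids(c)[:3]
            keep.extend(tree20.label[u] for u in ids)
        sub = tree20.prune(keep)
        Vs = bm_covariance(sub)
        idx = [labs.index(l) for l in sub.tip_labels]
        assert np.allclose(Vs, V[np.ix_(idx, idx)], atol=1e-9)

    def test_match_normalizes_names(self, three_taxon):
        tree, matched, drop_tab, drop_tre = match_tree_to_table(
            three_taxon, ["A ", "B", "C"]
        )
        assert matched == ["A", "B", "C"]
        assert not drop_tab and not drop_tre

    def test_match_prunes_with_warning(self, tree20):
        keep = tree20.tip_labels[:10]
        with pytest.warns(UserWarning, match="dropped"):
            tree, matched, _, dropped = match_tree_to_table(tree20, keep)
        assert tree.n_tips == 10
        assert len(dropped) == 10
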
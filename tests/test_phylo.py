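"""Trees, Brownian covariance, Pagel's lambda, PGLS, trait simulation."""

import numpy as np
import pandas as pd
import pytest

from occlusal import phylo, synthetic
from occlusal.errors import (
    DegenerateInputError,
    DomainError,
    FormatError,
    NumericError,
    TaxonLookupError,
)

# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def test_smallest_tree():
    tree = phylo.read_newick("(A:1,B:1);")
    depths = phylo.leaf_depths(tree)
    assert sorted(depths) == ["A", "B"]
    assert depths["A"] == depths["B"] == 1.0


def test_ultrametric_depths(three_taxon_tree):
    depths = phylo.leaf_depths(three_taxon_tree)
    assert all(abs(d - 2.0) < 1e-12 for d in depths.values())


@pytest.mark.parametrize("bad", [
    "((A:1,B:1):1,C:2;",        # unbalanced parentheses
    "((A:1,A:1):1,C:2);",       # duplicate leaf labels
    "((A:1,B):1,C:2);",         # missing branch length
    "((A:1,B:-1):1,C:2);",      # negative branch length
])
def test_newick_parse_errors(bad):
    with pytest.raises(FormatError):
        phylo.read_newick(bad)


def test_roundtrip_identity_random_tree():
    """write(read(t)) preserves topology and branch lengths.

    Oracle: the Brownian covariance matrix (ordered by sorted labels) is a
    canonical form of (topology, branch lengths), so equality of matrices
    is equality of trees.
    """
    tree = synthetic.make_tree(13, seed=5)
    text = phylo.write_newick(tree)
    tree2 = phylo.read_newick(text)
    taxa = sorted(phylo.leaf_labels(tree))
    assert sorted(phylo.leaf_labels(tree2)) == taxa
    C1 = phylo.bm_covariance(tree, taxa).C
    C2 = phylo.bm_covariance(tree2, taxa).C
    np.testing.assert_allclose(C1, C2, atol=1e-12)
    assert phylo.write_newick(tree2) == text


# ---------------------------------------------------------------------------
# Brownian covariance
# ---------------------------------------------------------------------------


def test_star_tree_covariance(star_tree4):
    cov = phylo.bm_covariance(star_tree4)
    np.testing.assert_allclose(cov.C, 2.0 * np.eye(4), atol=1e-12)


def test_three_taxon_covariance(three_taxon_tree):
    cov = phylo.bm_covariance(three_taxon_tree, ["A", "B", "C"])
    np.testing.assert_allclose(
        cov.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12)


def _brute_force_covariance(tree, taxa):
    """Path-sum oracle: C_ij = summed lengths of edges shared by the two
    root-to-leaf paths."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append(id(node))
            node = node.parent_node
        paths[leaf.taxon.label] = set(edges)
    lengths = {id(nd): nd.edge.length for nd in tree.preorder_node_iter()
               if nd.edge.length is not None}
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            shared = paths[a] & paths[b]
            C[i, j] = sum(lengths[e] for e in shared)
    return C


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_covariance_matches_path_enumeration(seed):
    tree = synthetic.make_tree(6, seed=seed)
    taxa = sorted(phylo.leaf_labels(tree))
    cov = phylo.bm_covariance(tree, taxa)
    np.testing.assert_allclose(cov.C, _brute_force_covariance(tree, taxa),
                               atol=1e-10)


@pytest.mark.parametrize("seed", [11, 12, 13, 14])
def test_covariance_symmetric_psd(seed):
    cov = phylo.bm_covariance(synthetic.make_tree(10, seed=seed))
    np.testing.assert_allclose(cov.C, cov.C.T, atol=1e-12)
    assert np.linalg.eigvalsh(cov.C).min() >= -1e-10
    # diagonal dominates every off-diagonal in its row
    off = cov.C - np.diag(np.diag(cov.C))
    assert (np.diag(cov.C)[:, None] >= off - 1e-12).all()


def test_covariance_unknown_taxon(three_taxon_tree):
    with pytest.raises(TaxonLookupError):
        phylo.bm_covariance(three_taxon_tree, ["A", "Z"])


# ---------------------------------------------------------------------------
# Lambda transform
# ---------------------------------------------------------------------------


def test_lambda_transform(three_taxon_tree):
    cov = phylo.bm_covariance(three_taxon_tree, ["A", "B", "C"])
    np.testing.assert_allclose(phylo.lambda_transform(cov, 1.0).C, cov.C)
    np.testing.assert_allclose(phylo.lambda_transform(cov, 0.0).C,
                               np.diag(np.diag(cov.C)))
    assert phylo.lambda_transform(cov, 0.5).C[0, 1] == pytest.approx(0.5)
    with pytest.raises(DomainError):
        phylo.lambda_transform(cov, 1.5)


# ---------------------------------------------------------------------------
# Lambda ML
# ---------------------------------------------------------------------------


def test_lambda_zero_equals_independent_normals(tree13):
    """At lambda = 0 the profile likelihood reduces to independent normals
    with per-species variance sigma2 * depth_i."""
    rng = np.random.default_rng(0)
    taxa = phylo.leaf_labels(tree13)
    y = pd.Series(rng.normal(size=len(taxa)), index=taxa)
    cov = phylo.bm_covariance(tree13, taxa)
    C0 = phylo.lambda_transform(cov, 0.0).C
    ll, s2, mu = phylo._mean_model_loglik(y.to_numpy(), C0)
    d = np.diag(C0)
    closed = -0.5 * (len(y) * np.log(2 * np.pi * s2) + np.log(d).sum()
                     + ((y.to_numpy() - mu) ** 2 / (s2 * d)).sum())
    assert ll == pytest.approx(closed, abs=1e-8)


def test_lambda_hat_beats_grid(tree13):
    rng = np.random.default_rng(3)
    trait = phylo.simulate_bm(tree13, 1.0, 0.0, seed=rng)
    fit = phylo.fit_lambda_ml(trait, tree13)
    cov = phylo.bm_covariance(tree13, list(trait.index))
    for lam in np.linspace(0, 1, 25):
        ll = phylo._mean_model_loglik(
            trait.to_numpy(), phylo.lambda_transform(cov, lam).C)[0]
        assert fit.log_likelihood >= ll - 1e-7


def test_lambda_recovery_brownian():
    """Traits simulated under pure BM recover high lambda."""
    tree = synthetic.make_tree(30, seed=21)
    hits = 0
    for rep in range(50):
        trait = phylo.simulate_bm(tree, 1.0, 0.0, seed=1000 + rep)
        if phylo.fit_lambda_ml(trait, tree).lambda_hat > 0.7:
            hits += 1
    assert hits >= 45


def test_lambda_near_zero_for_iid_noise():
    tree = synthetic.make_tree(30, seed=22)
    taxa = phylo.leaf_labels(tree)
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(50):
        trait = pd.Series(rng.normal(size=len(taxa)), index=taxa)
        if phylo.fit_lambda_ml(trait, tree).lambda_hat < 0.3:
            hits += 1
    assert hits >= 45


def test_lambda_errors(tree13):
    taxa = phylo.leaf_labels(tree13)
    with pytest.raises(DegenerateInputError):
        phylo.fit_lambda_ml(pd.Series(1.0, index=taxa), tree13)
    with pytest.raises(TaxonLookupError):
        phylo.fit_lambda_ml(pd.Series([1, 2, 3, 4.0],
                                      index=["A", "B", "C", "D"]), tree13)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


def _random_xy(tree, seed):
    rng = np.random.default_rng(seed)
    taxa = phylo.leaf_labels(tree)
    x = pd.Series(rng.normal(size=len(taxa)), index=taxa)
    y = pd.Series(1.0 + 0.7 * x + rng.normal(scale=0.3, size=len(taxa)),
                  index=taxa)
    return x, y


def test_pgls_lambda_zero_is_ols(tree13):
    x, y = _random_xy(tree13, 4)
    fit = phylo.pgls_fit(x, y, tree13, lambda_mode=0.0)
    slope, intercept = np.polyfit(x.to_numpy(), y.to_numpy(), 1)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.slope == pytest.approx(slope, abs=1e-10)


@pytest.mark.parametrize("lam", [0.3, 1.0])
def test_pgls_matches_whitening_oracle(lam):
    """GLS coefficients equal OLS after explicit Cholesky whitening."""
    tree = synthetic.make_tree(5, seed=8)
    x, y = _random_xy(tree, 5)
    fit = phylo.pgls_fit(x, y, tree, lambda_mode=lam)
    taxa = list(fit.residuals.index)
    C = phylo.lambda_transform(phylo.bm_covariance(tree, taxa), lam).C
    L = np.linalg.cholesky(C)
    X = np.column_stack([np.ones(len(taxa)), x.loc[taxa]])
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y.loc[taxa].to_numpy())
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
    assert fit.slope == pytest.approx(beta[1], abs=1e-9)


def test_pgls_perfect_fit(tree13):
    taxa = phylo.leaf_labels(tree13)
    x = pd.Series(np.linspace(0, 1, len(taxa)), index=taxa)
    y = 2.0 + 3.0 * x
    fit = phylo.pgls_fit(x, y, tree13, lambda_mode=1.0)
    np.testing.assert_allclose(fit.residuals.to_numpy(), 0.0, atol=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)


def test_pgls_input_errors(three_taxon_tree):
    x = pd.Series([1.0, 2.0], index=["A", "B"])
    y = pd.Series([1.0, 2.0], index=["A", "B"])
    with pytest.raises(Exception):
        phylo.pgls_fit(x, y, three_taxon_tree)  # < 3 taxa


def test_singular_covariance_reports_condition():
    tree = phylo.read_newick("((A:1e-15,B:1e-15):1,(C:1e-15,D:1e-15):1);")
    x = pd.Series([1, 2, 3, 4.0], index=["A", "B", "C", "D"])
    y = pd.Series([1, 2, 3, 4.0], index=["A", "B", "C", "D"])
    with pytest.raises(NumericError, match="condition"):
        phylo.pgls_fit(x, y, tree, lambda_mode=1.0)


# ---------------------------------------------------------------------------
# Brownian simulation
# ---------------------------------------------------------------------------


def test_bm_zero_variance(tree13):
    tips = phylo.simulate_bm(tree13, 0.0, root_state=3.5, seed=1)
    assert (tips == 3.5).all()


def test_bm_negative_sigma2(tree13):
    with pytest.raises(DomainError):
        phylo.simulate_bm(tree13, -1.0)


def test_bm_single_branch_variance():
    """Tip variance over replicates matches sigma2 * t (closed form)."""
    tree = phylo.read_newick("(A:2.5,B:2.5);")
    rng = np.random.default_rng(77)
    tips = np.array([phylo.simulate_bm(tree, 0.8, 0.0, seed=rng)["A"]
                     for _ in range(10_000)])
    assert np.var(tips) == pytest.approx(0.8 * 2.5, rel=0.05)


def test_bm_star_tree_independence(star_tree4):
    rng = np.random.default_rng(5)
    draws = np.array([phylo.simulate_bm(star_tree4, 1.0, 0.0, seed=rng)
                      .loc[["A", "B", "C", "D"]].to_numpy()
                      for _ in range(2000)])
    corr = np.corrcoef(draws.T)
    off = corr[~np.eye(4, dtype=bool)]
    assert np.abs(off).max() < 0.1


def test_bm_tip_covariance_converges():
    """Replicate tip covariance converges to sigma2 * C element-wise."""
    tree = synthetic.make_tree(6, seed=30)
    taxa = phylo.leaf_labels(tree)
    cov = phylo.bm_covariance(tree, taxa)
    draws = phylo.simulate_bm_gaussian(cov, 2.0, 0.0, size=10_000, seed=99)
    emp = np.cov(draws.T)
    np.testing.assert_allclose(emp, 2.0 * cov.C, atol=0.15)
    # the per-edge simulator agrees in distribution with the Gaussian draw
    rng = np.random.default_rng(4)
    edge_draws = np.array([phylo.simulate_bm(tree, 2.0, 0.0, seed=rng)
                           .loc[taxa].to_numpy() for _ in range(4000)])
    np.testing.assert_allclose(np.cov(edge_draws.T), 2.0 * cov.C, atol=0.35)


def test_bm_deterministic_under_seed(tree13):
    a = phylo.simulate_bm(tree13, 1.0, 0.0, seed=42)
    b = phylo.simulate_bm(tree13, 1.0, 0.0, seed=42)
    pd.testing.assert_series_equal(a, b)
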
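"""Phylogenetic machinery: trees, Brownian covariance, Pagel's lambda, PGLS.

Trees are :class:`dendropy.Tree` objects read from Newick strings with branch
lengths.  Under Brownian motion a trait evolving on the tree has tip
covariance ``C`` with ``C[i, j]`` the shared root-to-MRCA path length of
leaves *i* and *j* and ``C[i, i]`` the root-to-tip depth.  Pagel's lambda
rescales the off-diagonal of ``C`` by a factor in [0, 1]: lambda = 0 erases
phylogenetic structure, lambda = 1 is pure Brownian motion.

PGLS (phylogenetic generalized least squares) fits a line to species means
with error covariance proportional to the (lambda-scaled) Brownian ``C``;
with lambda = 0 it reduces exactly to ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from occlusal.errors import (
    DegenerateInputError,
    DomainError,
    FormatError,
    InputError,
    NumericError,
    TaxonLookupError,
)

_COND_LIMIT = 1e12


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths into a tree.

    Raises :class:`FormatError` on syntax errors, duplicate leaf labels, or
    missing branch lengths (the root edge may legitimately lack one).
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"invalid Newick: {exc}") from exc

    labels = [leaf.taxon.label if leaf.taxon else None
              for leaf in tree.leaf_node_iter()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise FormatError("leaf without a label")
    dupes = {lbl for lbl in labels if labels.count(lbl) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            who = node.taxon.label if node.taxon else "an internal node"
            raise FormatError(f"missing branch length on edge above {who}")
        if node.edge.length < 0:
            raise FormatError(f"negative branch length above "
                              f"{node.taxon.label if node.taxon else 'an internal node'}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line Newick string with branch lengths."""
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per leaf label."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance
            for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Brownian covariance and the lambda transform
# ---------------------------------------------------------------------------

@dataclass
class PhyloCovariance:
    """Brownian tip covariance on a tree, restricted to an ordered taxon set."""

    taxa: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.taxa), len(self.taxa)):
            raise InputError("covariance shape does not match taxon list")


def bm_covariance(tree: dendropy.Tree,
                  taxa: Sequence[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance matrix: C_ij = root-to-MRCA path length.

    ``taxa`` restricts and orders the matrix; default is the tree's own leaf
    order.  Unknown taxa raise :class:`TaxonLookupError`.
    """
    depths = leaf_depths(tree)
    if taxa is None:
        taxa = leaf_labels(tree)
    else:
        taxa = list(taxa)
        missing = [t for t in taxa if t not in depths]
        if missing:
            raise TaxonLookupError(f"taxa not in tree: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    tax_by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    C = np.empty((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(tax_by_label[a], tax_by_label[b])
            # shared path = (depth_a + depth_b - patristic) / 2
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
    return PhyloCovariance(taxa=taxa, C=C)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: off-diagonals scaled by ``lam``, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"lambda must be in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(taxa=list(cov.taxa), C=C)


def _chol_solve(C: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve C X = B by Cholesky; returns (X, log|C|).  NumericError if singular."""
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise NumericError(f"phylogenetic covariance is singular "
                           f"(condition number {cond:.3g})") from exc
    d = np.diag(L)
    if (d.max() / d.min()) ** 2 > _COND_LIMIT:
        cond = np.linalg.cond(C)
        raise NumericError(f"phylogenetic covariance is near-singular "
                           f"(condition number {cond:.3g})")
    X = np.linalg.solve(L.T, np.linalg.solve(L, B))
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return X, logdet


# ---------------------------------------------------------------------------
# Pagel's lambda by maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class LambdaFit:
    """ML estimate of Pagel's lambda for one trait on one tree."""

    lambda_hat: float
    log_likelihood: float
    p_vs_zero: float
    sigma2_hat: float
    mu_hat: float
    taxa: list[str] = field(default_factory=list)


def _mean_model_loglik(y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of the single-mean Brownian model.

    mu and sigma2 are profiled analytically: mu = (1'C^-1 y)/(1'C^-1 1),
    sigma2 = r'C^-1 r / n (ML).  Returns (loglik, sigma2, mu).
    """
    n = len(y)
    ones = np.ones(n)
    Ci_block, logdet = _chol_solve(C, np.column_stack([y, ones]))
    Ciy, Cione = Ci_block[:, 0], Ci_block[:, 1]
    mu = (ones @ Ciy) / (ones @ Cione)
    r = y - mu
    sigma2 = (r @ Ciy - mu * (r @ Cione)) / n  # r'C^-1 r
    sigma2 = float(max(sigma2, 0.0))
    if sigma2 <= 0.0:
        raise DegenerateInputError("trait has zero variance under the model")
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(ll), sigma2, float(mu)


def _as_trait_series(trait, taxa_required: set[str] | None = None) -> pd.Series:
    s = pd.Series(trait, dtype=float)
    if s.isna().any():
        raise InputError("trait contains missing values")
    return s


def fit_lambda_ml(trait: Mapping[str, float] | pd.Series,
                  tree: dendropy.Tree,
                  n_grid: int = 21) -> LambdaFit:
    """ML estimate of Pagel's lambda for a species-mean trait.

    A coarse grid on [0, 1] brackets the optimum, refined by bounded 1-D
    minimization; ties in likelihood break toward the larger lambda.  The
    reported p-value is a chi^2(1) likelihood-ratio test against lambda = 0
    (i.e. against phylogenetic independence).
    """
    s = _as_trait_series(trait)
    tree_leaves = set(leaf_labels(tree))
    missing = [t for t in s.index if t not in tree_leaves]
    if missing:
        raise TaxonLookupError(f"trait taxa not in tree: {missing}")
    if len(s) < 4:
        raise InputError(f"need >= 4 species for lambda estimation, got {len(s)}")
    if np.ptp(s.to_numpy()) == 0:
        raise DegenerateInputError("trait is constant across species")

    cov = bm_covariance(tree, list(s.index))
    y = s.to_numpy()

    def nll(lam: float) -> float:
        return -_mean_model_loglik(y, lambda_transform(cov, lam).C)[0]

    grid = np.linspace(0.0, 1.0, n_grid)
    grid_nll = np.array([nll(g) for g in grid])
    k = int(np.argmin(grid_nll))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    # tie-break toward larger lambda among near-equal optima (incl. endpoints)
    candidates = [(float(res.x), float(res.fun)), (0.0, float(grid_nll[0])),
                  (1.0, float(grid_nll[-1]))]
    best_f = min(f for _, f in candidates)
    lam_hat = max(l for l, f in candidates if f <= best_f + 1e-9)

    ll_hat, s2_hat, mu_hat = _mean_model_loglik(
        y, lambda_transform(cov, lam_hat).C)
    ll_zero, _, _ = _mean_model_loglik(y, lambda_transform(cov, 0.0).C)
    lr = max(2.0 * (ll_hat - ll_zero), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return LambdaFit(lambda_hat=float(lam_hat), log_likelihood=ll_hat,
                     p_vs_zero=p, sigma2_hat=s2_hat, mu_hat=mu_hat,
                     taxa=list(s.index))


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """A phylogenetic GLS line fit on species means (log10 space)."""

    intercept: float
    slope: float
    lambda_used: float
    sigma2: float
    r_squared: float
    n_species: int
    residuals: pd.Series
    log_likelihood: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _gls_fit_at(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """GLS coefficients plus the profile MVN log-likelihood at covariance C."""
    n = len(y)
    res = sm.GLS(y, X, sigma=C).fit()
    beta = np.asarray(res.params)
    r = y - X @ beta
    Cir, logdet = _chol_solve(C, r.reshape(-1, 1))
    rss_w = float(r @ Cir[:, 0])
    sigma2 = max(rss_w / n, 1e-300)
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return beta, r, rss_w, sigma2, float(ll)


def pgls_fit(x: Mapping[str, float] | pd.Series,
             y: Mapping[str, float] | pd.Series,
             tree: dendropy.Tree,
             lambda_mode: float | str = 1.0) -> PGLSFit:
    """Fit ``y = a + b x`` by phylogenetic GLS on species means.

    ``lambda_mode`` is a fixed lambda in [0, 1] (default 1.0, pure Brownian
    motion) or ``"ml"`` to profile lambda by maximum likelihood.  With
    lambda = 0 the fit equals OLS.  R^2 is 1 - RSS/TSS computed in the
    whitened (GLS) metric, with TSS from the GLS intercept-only model.
    """
    xs = _as_trait_series(x)
    ys = _as_trait_series(y)
    common = [t for t in xs.index if t in set(ys.index)]
    if sorted(common) != sorted(xs.index) or len(common) != len(ys):
        raise InputError("x and y must cover the same species")
    if len(common) < 3:
        raise InputError(f"need >= 3 species for PGLS, got {len(common)}")
    tree_leaves = set(leaf_labels(tree))
    missing = [t for t in common if t not in tree_leaves]
    if missing:
        raise TaxonLookupError(f"species not in tree: {missing}")

    cov = bm_covariance(tree, common)
    yv = ys.loc[common].to_numpy()
    xv = xs.loc[common].to_numpy()
    X = np.column_stack([np.ones_like(xv), xv])

    if lambda_mode == "ml":
        def nll(lam: float) -> float:
            return -_gls_fit_at(yv, X, lambda_transform(cov, lam).C)[4]

        grid = np.linspace(0.0, 1.0, 21)
        grid_nll = np.array([nll(g) for g in grid])
        k = int(np.argmin(grid_nll))
        res = optimize.minimize_scalar(
            nll, bounds=(grid[max(k - 1, 0)], grid[min(k + 1, 20)]),
            method="bounded", options={"xatol": 1e-8})
        cands = [(float(res.x), float(res.fun)), (0.0, float(grid_nll[0])),
                 (1.0, float(grid_nll[-1]))]
        best = min(f for _, f in cands)
        lam = max(l for l, f in cands if f <= best + 1e-9)
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise DomainError(f"lambda must be in [0, 1], got {lam}")

    C = lambda_transform(cov, lam).C
    beta, r, rss_w, sigma2, ll = _gls_fit_at(yv, X, C)

    # TSS in the same whitened metric, around the GLS grand mean
    ones = np.ones(len(yv))
    Ci_block, _ = _chol_solve(C, np.column_stack([yv, ones]))
    mu = (ones @ Ci_block[:, 0]) / (ones @ Ci_block[:, 1])
    d = yv - mu
    Cid, _ = _chol_solve(C, d.reshape(-1, 1))
    tss_w = float(d @ Cid[:, 0])
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else 1.0
    r2 = float(min(max(r2, 0.0), 1.0))

    return PGLSFit(intercept=float(beta[0]), slope=float(beta[1]),
                   lambda_used=float(lam), sigma2=float(sigma2),
                   r_squared=r2, n_species=len(common),
                   residuals=pd.Series(r, index=common),
                   log_likelihood=ll)


# ---------------------------------------------------------------------------
# Brownian simulation
# ---------------------------------------------------------------------------

def simulate_bm(tree: dendropy.Tree, sigma2: float, root_state: float = 0.0,
                seed: int | np.random.Generator | None = None) -> pd.Series:
    """Simulate one Brownian trait on the tree (edge-wise normal increments).

    Each edge contributes an independent N(0, sigma2 * branch_length)
    increment; multifurcations are handled directly.  Deterministic under a
    fixed seed.
    """
    if sigma2 < 0:
        raise DomainError(f"sigma2 must be >= 0, got {sigma2}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    values: dict[int, float] = {id(tree.seed_node): root_state}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            v = root_state
        else:
            bl = node.edge.length or 0.0
            v = values[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(sigma2 * bl))
        values[id(node)] = v
        if node.is_leaf():
            out[node.taxon.label] = v
    return pd.Series(out)


def simulate_bm_gaussian(cov: PhyloCovariance, sigma2: float,
                         root_state: float = 0.0,
                         size: int = 1,
                         seed: int | np.random.Generator | None = None
                         ) -> np.ndarray:
    """Vectorized Brownian tip draws via the Cholesky factor of sigma2*C.

    Distributionally identical to :func:`simulate_bm`; used where many
    replicates are needed (phylogenetic-ANOVA null distributions).
    Returns an array of shape (size, n_taxa) in ``cov.taxa`` order.
    """
    if sigma2 < 0:
        raise DomainError(f"sigma2 must be >= 0, got {sigma2}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = len(cov.taxa)
    if sigma2 == 0:
        return np.full((size, n), root_state)
    L = np.linalg.cholesky(cov.C + 1e-12 * np.eye(n))
    z = rng.standard_normal((size, n))
    return root_state + np.sqrt(sigma2) * z @ L.T
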